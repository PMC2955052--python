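"""Cross-hybridization screening: database construction, Kane scanning,
family rescue and hit clustering."""

import itertools

import pytest

from conftest import random_degenerate, random_dna
from degenprobe.alphabet import IUPAC_SETS, STANDARD_CODE, degeneracy, expand
from degenprobe.design import ProbeCandidate
from degenprobe.screen import (
    BackgroundRecord,
    CrossHybHit,
    ScreenParams,
    build_crosshyb_db,
    cluster_hits,
    family_membership,
    is_flagged,
    kane_check,
    revcomp,
    screen_probe,
)
from degenprobe.simulate import PlantSpec, simulate_background_db


def brute_kane(probe: str, target: str):
    """All offsets, both strands, pure-Python oracle."""
    L = len(probe)
    best_pct, best_pos, best_strand, stretch = -1.0, 1, "+", 0
    for strand in "+-":
        t = target if strand == "+" else revcomp(target)
        for off in range(len(t) - L + 1):
            run = matches = 0
            longest = 0
            for j in range(L):
                if t[off + j] in IUPAC_SETS[probe[j]]:
                    matches += 1
                    run += 1
                    longest = max(longest, run)
                else:
                    run = 0
            pct = 100.0 * matches / L
            stretch = max(stretch, longest)
            if pct > best_pct:
                best_pct = pct
                best_strand = strand
                best_pos = off + 1 if strand == "+" else len(t) - (off + L) + 1
    return best_pct, stretch, best_pos, best_strand


def make_candidate(seq, probe_id="p", start=1):
    from degenprobe.alphabet import inosine_count, total_degeneracy

    return ProbeCandidate(
        probe_id, seq, start, start + len(seq) - 1,
        degeneracy(seq), inosine_count(seq), total_degeneracy(seq),
    )


def backtranslate_protein(protein: str) -> str:
    """One specific coding DNA for a protein (first codon of each residue)."""
    return "".join(sorted(STANDARD_CODE.codons_for(aa))[0] for aa in protein)


class TestDatabase:
    GENOME = {"chr1": random_dna(__import__("random").Random(7), 400)}

    def test_flanks_added_and_truncated_at_origin(self):
        (rec,) = build_crosshyb_db(self.GENOME, [("chr1", "+", 101, 200)], flank=100)
        assert len(rec.seq) == 300
        assert rec.seq == self.GENOME["chr1"][0:300]

    def test_cds_at_start_truncates_5prime_flank(self):
        (rec,) = build_crosshyb_db(self.GENOME, [("chr1", "+", 1, 60)], flank=100)
        assert rec.seq == self.GENOME["chr1"][:160]

    def test_minus_strand_reverse_complemented(self):
        (rec,) = build_crosshyb_db(self.GENOME, [("chr1", "-", 101, 200)], flank=10)
        assert rec.seq == revcomp(self.GENOME["chr1"][90:210])

    def test_out_of_bounds_cds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_crosshyb_db(self.GENOME, [("chr1", "+", 390, 500)])

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="chrX"):
            build_crosshyb_db(self.GENOME, [("chrX", "+", 1, 10)])

    def test_gff3_file_input(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t90\t210\t.\t+\t.\tID=g1\n"
            "chr1\t.\tCDS\t101\t200\t.\t+\t0\tID=c1\n"
        )
        fa = tmp_path / "g.fasta"
        fa.write_text(">chr1\n" + self.GENOME["chr1"] + "\n")
        recs = build_crosshyb_db(self.GENOME, str(gff), flank=100)
        assert len(recs) == 1 and len(recs[0].seq) == 300


class TestKaneCheck:
    def test_verbatim_probe_found(self, rng):
        probe = random_dna(rng, 23)
        target = random_dna(rng, 100) + probe + random_dna(rng, 80)
        pct, stretch, pos, strand = kane_check(probe, target)
        assert (pct, stretch, pos, strand) == (100.0, 23, 101, "+")

    def test_reverse_strand_detected(self, rng):
        probe = random_dna(rng, 23)
        target = random_dna(rng, 50) + revcomp(probe) + random_dna(rng, 50)
        pct, stretch, pos, strand = kane_check(probe, target)
        assert pct == 100.0 and strand == "-" and pos == 51

    def test_spaced_substitutions_stay_unflagged(self, rng):
        # 6 substitutions spaced every 4 nt: 17/23 = 73.9%, longest run 3
        probe = random_dna(rng, 23)
        decoy = list(probe)
        for p in (0, 4, 8, 12, 16, 20):
            decoy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[decoy[p]]
        target = random_dna(rng, 60) + "".join(decoy) + random_dna(rng, 60)
        pct, stretch, _, _ = kane_check(probe, target)
        assert pct == pytest.approx(100 * 17 / 23)
        assert not is_flagged(pct, stretch, ScreenParams())

    def test_planted_15mer_flags_by_stretch(self, rng):
        probe = random_dna(rng, 23)
        target = random_dna(rng, 100) + probe[4:19] + random_dna(rng, 85)
        pct, stretch, _, _ = kane_check(probe, target)
        assert stretch >= 15
        assert is_flagged(pct, stretch, ScreenParams())

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            probe = random_degenerate(rng, rng.randint(15, 30))
            target = random_dna(rng, rng.randint(40, 160))
            assert kane_check(probe, target) == pytest.approx(
                brute_kane(probe, target)
            )

    def test_inosine_substitution_never_hurts(self, rng):
        for _ in range(20):
            probe = random_dna(rng, 20)
            target = random_dna(rng, 120)
            pct0, s0, _, _ = kane_check(probe, target)
            pos = rng.randrange(20)
            probe_i = probe[:pos] + "I" + probe[pos + 1 :]
            pct1, s1, _, _ = kane_check(probe_i, target)
            assert pct1 >= pct0 and s1 >= s0


class TestFamilyMembership:
    PROTEIN = (
        "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPD"
        "AQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
    )

    def test_exact_backtranslation_is_family(self):
        dna = backtranslate_protein(self.PROTEIN)
        assert family_membership(dna, self.PROTEIN) is True

    def test_reverse_complement_still_family(self):
        dna = revcomp(backtranslate_protein(self.PROTEIN))
        assert family_membership(dna, self.PROTEIN) is True

    def test_random_sequence_is_not_family(self, rng):
        dna = random_dna(rng, 3 * len(self.PROTEIN))
        assert family_membership(dna, self.PROTEIN) is False

    def test_stop_rich_sequence_evaluated_over_all_frames(self):
        # in-frame stops in five frames; the sixth carries the real signal
        dna = "TAATAATAA" + backtranslate_protein(self.PROTEIN)
        assert family_membership(dna, self.PROTEIN) is True

    def test_min_bitscore_override(self):
        dna = backtranslate_protein(self.PROTEIN)
        assert family_membership(dna, self.PROTEIN, min_bitscore=1e9) is False


class TestScreenProbe:
    PROBE = "GTITGYAAYTAYCAYGGITGGGT"

    def _reference_context(self, rng):
        """A reference protein whose coding DNA embeds a probe variant."""
        from degenprobe.simulate import variants_of

        variant = variants_of(self.PROBE, seed=4)[0]
        left = backtranslate_protein("".join(rng.choice("ACDEFGHIK") for _ in range(60)))
        right = backtranslate_protein("".join(rng.choice("LMNPQRSTV") for _ in range(60)))
        gene = left + variant + right
        from Bio.Seq import Seq

        protein = str(Seq(gene[: 3 * (len(gene) // 3)]).translate()).replace("*", "A")
        return gene, protein

    def test_own_gene_is_rescued_as_family(self, rng):
        gene, protein = self._reference_context(rng)
        c = make_candidate(self.PROBE)
        hits = screen_probe(c, [BackgroundRecord("self", gene)], protein)
        assert hits and all(h.classification == "target_family" for h in hits)
        assert c.crosshyb_count == 0

    def test_planted_unrelated_decoy_counts_once(self, rng):
        gene, protein = self._reference_context(rng)
        records, _ = simulate_background_db(
            [PlantSpec(self.PROBE, "stretch", 16)], n_records=3,
            record_length=300, seed=11,
        )
        db = [BackgroundRecord(i, s) for i, s in records]
        db.append(BackgroundRecord("self", gene))
        c = make_candidate(self.PROBE)
        hits = screen_probe(c, db, protein)
        crosshyb = [h for h in hits if h.classification == "cross_hybridization"]
        assert {h.target_id for h in crosshyb} == {"decoy00"}
        assert c.crosshyb_count == 1

    def test_clean_background_yields_no_hits(self, rng):
        protein = "MKTAYIAKQRQISFVKSHFSRQLE"
        records, _ = simulate_background_db([], n_records=10, record_length=200, seed=5)
        c = make_candidate(self.PROBE)
        hits = screen_probe(c, [BackgroundRecord(i, s) for i, s in records], protein)
        assert hits == []
        assert c.crosshyb_count == 0

    def test_record_order_does_not_change_counts(self, rng):
        gene, protein = self._reference_context(rng)
        records, _ = simulate_background_db(
            [PlantSpec(self.PROBE, "exact"), PlantSpec(self.PROBE, "identity", 85)],
            n_records=4, record_length=300, seed=6,
        )
        db = [BackgroundRecord(i, s) for i, s in records]
        c1, c2 = make_candidate(self.PROBE), make_candidate(self.PROBE)
        h1 = screen_probe(c1, db, protein)
        h2 = screen_probe(c2, list(reversed(db)), protein)
        assert c1.crosshyb_count == c2.crosshyb_count
        assert {(h.target_id, h.strand, h.identity_pct) for h in h1} == {
            (h.target_id, h.strand, h.identity_pct) for h in h2
        }

    def test_degenerate_scan_equals_per_variant_brute_force(self, rng):
        # aggregation claim: best-variant identity/stretch == degenerate scan
        probe = "ACYGTIAWG"
        target = random_dna(rng, 80)
        pct, stretch, _, _ = kane_check(probe, target)
        per_variant = [brute_kane(v, target) for v in expand(probe)]
        assert pct == pytest.approx(max(p[0] for p in per_variant))
        assert stretch == max(p[1] for p in per_variant)

    def test_expansion_cap_enforced(self):
        c = make_candidate("N" * 23)
        with pytest.raises(RuntimeError, match="tighten"):
            screen_probe(
                c, [BackgroundRecord("r", "ACGT" * 20)], "MKT",
                ScreenParams(expansion_cap=100),
            )


class TestClustering:
    def _hit(self, target_id, pos=50):
        return CrossHybHit("p", "ACGT", target_id, "+", pos, 100.0, 23,
                           "cross_hybridization")

    def test_hits_on_identical_targets_cluster_together(self, rng):
        seq = random_dna(rng, 200)
        hits = cluster_hits(
            [self._hit("a"), self._hit("b")], 90.0, {"a": seq, "b": seq}, 23
        )
        assert hits[0].cluster_id == hits[1].cluster_id == 1

    def test_unrelated_targets_stay_apart(self, rng):
        hits = cluster_hits(
            [self._hit("a"), self._hit("b")], 90.0,
            {"a": random_dna(rng, 200), "b": random_dna(rng, 200)}, 23,
        )
        assert hits[0].cluster_id != hits[1].cluster_id

    def test_singleton_gets_cluster_one(self, rng):
        hits = cluster_hits([self._hit("a")], 90.0, {"a": random_dna(rng, 200)}, 23)
        assert hits[0].cluster_id == 1
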
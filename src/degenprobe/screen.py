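"""Cross-hybridization screening of degenerate probes (Kane's criteria).

A long oligonucleotide probe risks cross-hybridizing with a non-target
sequence when either empirical specificity rule is violated: more than
75% identity over the probe length, or an identical stretch of >= 15
contiguous bases.  Probes are screened by exhaustive ungapped scanning of
every offset of every background record on both strands — a complete
search of the space the original BLAST cascade sampled heuristically.
Inosine matches any base and counts as a match for both statistics.

Flagged hits whose harboring gene locally aligns (six-frame translation)
to the reference protein above threshold are reclassified as legitimate
target-family members rather than cross-hybridizations; remaining hits
are single-linkage clustered by the sequence identity of their target
regions so that near-identical background genes count once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from Bio.Seq import Seq

from .alphabet import IUPAC_SETS, validate
from .design import ProbeCandidate
from .homologs import bitscore as _bitscore, make_aligner

logger = logging.getLogger(__name__)

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = np.zeros(128, dtype=np.uint8)
for _sym, _bases in IUPAC_SETS.items():
    _MASK[ord(_sym)] = sum(_BASE_BIT[b] for b in _bases)
_MASK[ord("N")] = 15

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNI", "TGCAYRSWMKVHDBNI")


def _masks(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    m = _MASK[arr]
    if (m == 0).any():
        bad = sorted({seq[i] for i in np.nonzero(m == 0)[0]})
        raise ValueError(f"invalid nucleotide symbol(s): {bad!r}")
    return m


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BackgroundRecord:
    """One background sequence (a CDS plus flanks, read 5'->3' coding strand)."""

    id: str
    seq: str
    source_cds: tuple[str, str, int, int, int] | None = None
    # (parent id, strand, cds_start, cds_end, flank) — 1-based inclusive

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"background record {self.id!r} is empty")
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id!r} has non-ACGTN symbol(s): {sorted(bad)!r}")


@dataclass
class CrossHybHit:
    probe_id: str
    variant_seq: str
    target_id: str
    strand: str
    target_start: int  # 1-based on the record as stored
    identity_pct: float
    longest_stretch: int
    classification: str  # "cross_hybridization" | "target_family"
    cluster_id: int | None = field(default=None)


@dataclass(frozen=True)
class ScreenParams:
    identity_max_pct: float = 75.0  # flag if identity strictly above
    stretch_min: int = 15  # flag if a run of >= this many matches exists
    family_evalue_max: float = 1e-10
    family_min_bitscore: float | None = None
    cluster_min_identity: float = 90.0
    expansion_cap: int = 10**6


def build_crosshyb_db(
    genome: Sequence[tuple[str, str]] | dict[str, str],
    annotations: str | Sequence[tuple[str, str, int, int]],
    flank: int = 100,
) -> list[BackgroundRecord]:
    """Extract CDS +/- ``flank`` nt records from genome sequences.

    ``annotations`` is either a GFF3 file path (CDS features, 1-based
    inclusive coordinates) or an in-memory list of
    ``(seqid, strand, start, end)`` tuples.  Flanks are truncated at
    sequence boundaries; minus-strand features are reverse-complemented
    so every record reads 5'->3' along the coding strand.
    """
    seqs = dict(genome) if not isinstance(genome, dict) else genome
    if isinstance(annotations, (str, bytes)):
        feats = _read_gff3_cds(annotations)
    else:
        feats = list(annotations)
    records: list[BackgroundRecord] = []
    for i, (seqid, strand, start, end) in enumerate(feats):
        if seqid not in seqs:
            raise ValueError(f"CDS parent sequence {seqid!r} missing from genome")
        parent = seqs[seqid].upper()
        if not (1 <= start <= end <= len(parent)):
            raise ValueError(
                f"CDS {start}..{end} outside parent {seqid!r} (length {len(parent)})"
            )
        lo = max(1, start - flank)
        hi = min(len(parent), end + flank)
        sub = parent[lo - 1 : hi]
        if strand == "-":
            sub = revcomp(sub)
        records.append(
            BackgroundRecord(
                id=f"{seqid}|cds{i + 1}|{start}-{end}({strand})",
                seq=sub,
                source_cds=(seqid, strand, start, end, flank),
            )
        )
    return records


def _read_gff3_cds(path: str) -> list[tuple[str, str, int, int]]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    return [
        (f.seqid, f.strand if f.strand in "+-" else "+", f.start, f.end)
        for f in db.features_of_type("CDS", order_by=("seqid", "start"))
    ]


def _match_matrix(probe_mask: np.ndarray, target_mask: np.ndarray) -> np.ndarray:
    """Boolean (offsets x probe positions) match matrix for ungapped scanning."""
    windows = sliding_window_view(target_mask, len(probe_mask))
    return (windows & probe_mask) != 0


def _longest_run(matches: np.ndarray) -> int:
    """Longest horizontal run of True in a 2-D boolean matrix."""
    run = np.zeros(matches.shape[0], dtype=np.int32)
    best = 0
    for j in range(matches.shape[1]):
        run = np.where(matches[:, j], run + 1, 0)
        m = int(run.max(initial=0))
        if m > best:
            best = m
    return best


def kane_check(
    variant: str, target: BackgroundRecord | str
) -> tuple[float, int, int, str]:
    """Best ungapped alignment statistics of a probe against a record.

    Returns ``(best_identity_pct, longest_stretch, best_position, strand)``
    where position is the 1-based offset of the best-identity placement on
    the record as stored, and ``longest_stretch`` is the longest run of
    consecutive matches found anywhere on either strand.  Inosine (and any
    IUPAC set symbol) in the probe matches a target base whenever its base
    set contains it.
    """
    seq = target.seq if isinstance(target, BackgroundRecord) else target
    validate(variant)
    L = len(variant)
    if L > len(seq):
        raise ValueError("probe longer than target")
    pmask = _masks(variant)
    best = (-1.0, 0, 1, "+")
    stretch = 0
    for strand, tseq in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
        matches = _match_matrix(pmask, _masks(tseq))
        ident = matches.sum(axis=1)
        off = int(ident.argmax())
        pct = float(100.0 * ident[off] / L)
        stretch = max(stretch, _longest_run(matches))
        if pct > best[0]:
            pos = off + 1 if strand == "+" else len(seq) - (off + L) + 1
            best = (pct, 0, pos, strand)
    return (best[0], stretch, best[2], best[3])


def is_flagged(identity_pct: float, stretch: int, params: ScreenParams) -> bool:
    """Kane flagging: either specificity condition violated flags the probe."""
    return identity_pct > params.identity_max_pct or stretch >= params.stretch_min


SIX_FRAMES = tuple((strand, off) for strand in "+-" for off in (0, 1, 2))


def family_membership(
    target: BackgroundRecord | str,
    reference_protein: str,
    min_bitscore: float | None = None,
    evalue_max: float = 1e-10,
) -> bool:
    """Does the gene harboring a hit belong to the reference protein family?

    Best local alignment of all six frame translations against the
    reference protein, scored as in homolog mining.  True iff the best
    bit score reaches ``min_bitscore`` (or, by default, the bit score at
    which the estimated E-value over this search space drops to
    ``evalue_max``).
    """
    seq = (target.seq if isinstance(target, BackgroundRecord) else target).upper()
    if not seq:
        raise ValueError("empty target sequence")
    aligner = make_aligner()
    best_raw = 0.0
    for strand, off in SIX_FRAMES:
        s = seq if strand == "+" else revcomp(seq)
        frame = s[off : off + 3 * ((len(s) - off) // 3)]
        if len(frame) < 3:
            continue
        pep = str(Seq(frame).translate())
        if not pep:
            continue
        best_raw = max(best_raw, aligner.score(reference_protein, pep))
    bits = _bitscore(best_raw)
    if min_bitscore is not None:
        return bool(bits >= min_bitscore)
    space = max(1, len(reference_protein) * len(seq) * 2)
    required = math.log2(space / evalue_max)
    return bool(bits >= required)


def _best_variant(variant_window: str, probe: str, matches_row: np.ndarray) -> str:
    """Realize the expanded-probe variant achieving the best match: take the
    target base where the probe's base set covers it, else the smallest base."""
    out = []
    for j, sym in enumerate(probe):
        bases = sorted(IUPAC_SETS[sym])
        t = variant_window[j] if j < len(variant_window) else ""
        out.append(t if (matches_row[j] and t in bases) else bases[0])
    return "".join(out)


def screen_probe(
    c: ProbeCandidate,
    db: Sequence[BackgroundRecord],
    reference_protein: str,
    params: ScreenParams = ScreenParams(),
) -> list[CrossHybHit]:
    """Screen one candidate against the whole background.

    Every record is scanned exhaustively on both strands.  Because probe
    variants form a cartesian product over independent positions, the
    best identity/stretch over all expanded variants at an offset equals
    the degenerate base-set match — the scan is an exact aggregation of
    the per-variant evaluation.  One hit is kept per record per strand
    (best identity); flagged hits are classified by family membership,
    clustered, and the candidate's ``crosshyb_count`` set to the number
    of cross-hybridization clusters.
    """
    if not db:
        raise ValueError("empty background database")
    from .alphabet import total_degeneracy

    if total_degeneracy(c.seq) > params.expansion_cap:
        raise RuntimeError(
            f"probe {c.probe_id} expands to {total_degeneracy(c.seq)} variants "
            f"(cap {params.expansion_cap}); tighten the design thresholds"
        )
    pmask = _masks(c.seq)
    L = len(c.seq)
    hits: list[CrossHybHit] = []
    for rec in db:
        if len(rec.seq) < L:
            continue
        for strand in "+-":
            tseq = rec.seq.upper() if strand == "+" else revcomp(rec.seq.upper())
            matches = _match_matrix(pmask, _masks(tseq))
            ident = matches.sum(axis=1)
            off = int(ident.argmax())
            pct = float(100.0 * ident[off] / L)
            stretch = _longest_run(matches)
            if not is_flagged(pct, stretch, params):
                continue
            family = family_membership(
                rec,
                reference_protein,
                min_bitscore=params.family_min_bitscore,
                evalue_max=params.family_evalue_max,
            )
            pos = off + 1 if strand == "+" else len(rec.seq) - (off + L) + 1
            hits.append(
                CrossHybHit(
                    probe_id=c.probe_id,
                    variant_seq=_best_variant(tseq[off : off + L], c.seq, matches[off]),
                    target_id=rec.id,
                    strand=strand,
                    target_start=pos,
                    identity_pct=pct,
                    longest_stretch=stretch,
                    classification="target_family" if family else "cross_hybridization",
                )
            )
    hits.sort(key=lambda h: (h.target_id, h.strand))
    seq_by_id = {r.id: r.seq.upper() for r in db}
    hits = cluster_hits(hits, params.cluster_min_identity, seq_by_id, probe_length=L)
    crosshyb_clusters = {
        h.cluster_id for h in hits if h.classification == "cross_hybridization"
    }
    c.crosshyb_count = len(crosshyb_clusters)
    return hits


def _region(seq: str, hit: CrossHybHit, probe_length: int) -> str:
    lo = max(0, hit.target_start - 1 - probe_length)
    hi = min(len(seq), hit.target_start - 1 + 2 * probe_length)
    return seq[lo:hi]


def _region_identity(a: str, b: str) -> float:
    """Best ungapped identity (percent of the shorter) between two regions."""
    if len(a) > len(b):
        a, b = b, a
    if not a:
        return 0.0
    amask, best = _masks(a), 0
    for t in (b, revcomp(b)):
        m = _match_matrix(amask, _masks(t)).sum(axis=1)
        best = max(best, int(m.max(initial=0)))
    return 100.0 * best / len(a)


def cluster_hits(
    hits: list[CrossHybHit],
    min_identity: float = 90.0,
    target_seqs: dict[str, str] | None = None,
    probe_length: int = 23,
) -> list[CrossHybHit]:
    """Single-linkage clustering of hit target regions by ungapped identity.

    Two hits join a cluster when the sequences around their hit positions
    (+/- one probe length) share >= ``min_identity`` percent identity.
    Cluster ids are assigned by increasing smallest member index, 1-based.
    Without ``target_seqs`` every hit on the same target id clusters
    together and distinct targets stay apart.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    regions = None
    if target_seqs is not None:
        regions = [_region(target_seqs[h.target_id], h, probe_length) for h in hits]
    for i in range(n):
        for j in range(i + 1, n):
            if regions is None:
                linked = hits[i].target_id == hits[j].target_id
            else:
                linked = _region_identity(regions[i], regions[j]) >= min_identity
            if linked:
                union(i, j)
    cluster_of_root: dict[int, int] = {}
    out = []
    for i, h in enumerate(hits):
        root = find(i)
        if root not in cluster_of_root:
            cluster_of_root[root] = len(cluster_of_root) + 1
        out.append(replace(h, cluster_id=cluster_of_root[root]))
    return out
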
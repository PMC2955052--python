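"""Degenerate consensus construction and probe enumeration.

From a protein multiple alignment, every column in which the reference
sequence has a residue is backtranslated into a degenerate codon; the
codons are concatenated in reference order, giving a degenerate nucleic
consensus whose coordinates are exactly the reference CDS coordinates
(3 nt per reference residue).  Candidate probes are all fixed-length
windows of that consensus, at every nucleotide offset, that satisfy the
two design thresholds:

* ``degeneracy`` (inosine counted as 1) <= ``degeneracy_max``
* inosine fraction of the window <= ``inosine_max_fraction``

Both comparisons are inclusive.  The worst-case number of fully
specified probes a passing window can expand to is therefore
``degeneracy_max * 4**floor(L * inosine_max_fraction)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from . import alphabet
from .alphabet import GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
#: symbols that contribute nothing to a column's amino-acid set
EXCLUDED_COLUMN_CHARS = GAP_CHARS | {"X"}


@dataclass(frozen=True)
class ProteinAlignment:
    """An aligned protein family with a designated reference row."""

    records: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        if self.reference_id not in {rid for rid, _ in self.records}:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")
        if not self.reference.replace("-", "").replace(".", ""):
            raise ValueError("reference sequence is all gaps")

    @property
    def reference(self) -> str:
        return next(seq for rid, seq in self.records if rid == self.reference_id)

    @property
    def length(self) -> int:
        return len(self.records[0][1])


@dataclass(frozen=True)
class DegenerateConsensus:
    """Backtranslated consensus; ``col_to_ref`` maps codon index (0-based)
    to the 1-based reference residue it encodes."""

    seq: str
    col_to_ref: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != 3 * len(self.col_to_ref):
            raise ValueError("consensus length must be 3 x retained columns")


@dataclass(frozen=True)
class DesignParams:
    probe_length: int = 24
    degeneracy_max: int = 129
    inosine_max_fraction: float = 0.25
    trim_last_base: bool = True
    expansion_mode: str = "expand"
    expansion_cap: int = 10**6

    def __post_init__(self) -> None:
        if self.probe_length < 3:
            raise ValueError("probe_length must be >= 3")
        if self.degeneracy_max < 1:
            raise ValueError("degeneracy_max must be >= 1")
        if not 0.0 <= self.inosine_max_fraction <= 1.0:
            raise ValueError("inosine_max_fraction must be in [0, 1]")
        if self.expansion_mode not in ("expand", "keep"):
            raise ValueError("expansion_mode must be 'expand' or 'keep'")


#: strategy presets used for the PAH probe set: permissive degeneracy with
#: liberal inosine, and stringent inosine with doubled degeneracy headroom
STRATEGY_1 = DesignParams(probe_length=24, degeneracy_max=129, inosine_max_fraction=0.25)
STRATEGY_2 = DesignParams(probe_length=24, degeneracy_max=258, inosine_max_fraction=0.09)


@dataclass
class ProbeCandidate:
    probe_id: str
    seq: str
    start_nt: int  # 1-based inclusive, ungapped reference CDS coordinates
    end_nt: int
    degeneracy: int
    inosine_count: int
    total_degeneracy: int
    crosshyb_count: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.end_nt - self.start_nt + 1 != len(self.seq):
            raise ValueError("probe coordinates inconsistent with sequence length")


def build_consensus(
    aln: ProteinAlignment, code: GeneticCode = STANDARD_CODE
) -> DegenerateConsensus:
    """Backtranslate an alignment column-wise into a degenerate consensus.

    Columns where the reference is gapped are skipped; gaps and ``X`` in
    other rows are excluded from the column's amino-acid set.
    """
    codons: list[str] = []
    col_to_ref: list[int] = []
    ref_residue = 0
    reference = aln.reference
    for col in range(aln.length):
        if reference[col] in GAP_CHARS:
            continue
        ref_residue += 1
        aa_set = {
            seq[col].upper()
            for _, seq in aln.records
            if seq[col].upper() not in EXCLUDED_COLUMN_CHARS
        }
        if not aa_set:
            raise ValueError(f"alignment column {col + 1} empty after gap/X exclusion")
        codons.append(alphabet.backtranslate_column(aa_set, code))
        col_to_ref.append(ref_residue)
    return DegenerateConsensus(seq="".join(codons), col_to_ref=tuple(col_to_ref))


def max_total_degeneracy(p: DesignParams) -> int:
    """Largest total degeneracy any window passing the thresholds can have."""
    return p.degeneracy_max * 4 ** math.floor(p.probe_length * p.inosine_max_fraction)


def enumerate_probes(
    cons: DegenerateConsensus, p: DesignParams, id_prefix: str = "probe"
) -> list[ProbeCandidate]:
    """All probe-length windows of the consensus passing both thresholds.

    Windows slide one nucleotide at a time (probes need not be
    codon-aligned).  Coordinates are 1-based inclusive on the ungapped
    reference CDS, which coincides with the consensus coordinate system.
    """
    L = p.probe_length
    seq = cons.seq
    if len(seq) < L:
        logger.warning("consensus (%d nt) shorter than probe length %d", len(seq), L)
        return []
    out: list[ProbeCandidate] = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        deg = alphabet.degeneracy(window)
        ino = alphabet.inosine_count(window)
        if deg <= p.degeneracy_max and ino / L <= p.inosine_max_fraction:
            out.append(
                ProbeCandidate(
                    probe_id=f"{id_prefix}_{len(out):04d}",
                    seq=window,
                    start_nt=start + 1,
                    end_nt=start + L,
                    degeneracy=deg,
                    inosine_count=ino,
                    total_degeneracy=alphabet.total_degeneracy(window),
                )
            )
    return out


def trim_probe(c: ProbeCandidate) -> ProbeCandidate:
    """Drop the last nucleotide (typically a wobble base or inosine) and
    recompute the degeneracy statistics."""
    if len(c.seq) < 2:
        raise ValueError("cannot trim a length-1 probe")
    seq = c.seq[:-1]
    return replace(
        c,
        seq=seq,
        end_nt=c.end_nt - 1,
        degeneracy=alphabet.degeneracy(seq),
        inosine_count=alphabet.inosine_count(seq),
        total_degeneracy=alphabet.total_degeneracy(seq),
    )


def rank_probes(
    cands: Sequence[ProbeCandidate], k: int | None = None
) -> list[ProbeCandidate]:
    """Order candidates by the three sequential selection criteria.

    1. ascending cross-hybridization count (clusters, 0 for unscreened
       candidates explicitly set to 0),
    2. ascending total degeneracy (fewer specific probes to synthesize),
    3. when picking ``k`` probes, maximal spread along the reference:
       the top-ranked candidate is fixed and each subsequent pick
       maximizes its minimum start-coordinate distance to those already
       picked (ties broken by rank order).
    """
    ranked = sorted(
        cands,
        key=lambda c: (
            c.crosshyb_count if c.crosshyb_count is not None else 0,
            c.total_degeneracy,
            c.start_nt,
        ),
    )
    if k is None or k >= len(ranked):
        return ranked
    picked = [ranked[0]]
    remaining = ranked[1:]
    while len(picked) < k and remaining:
        best_i = max(
            range(len(remaining)),
            key=lambda i: (
                min(abs(remaining[i].start_nt - q.start_nt) for q in picked),
                -i,
            ),
        )
        picked.append(remaining.pop(best_i))
    return picked
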
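"""Homolog mining: local protein alignment scoring and prefilters.

Candidate family members for a reference protein are ranked by a local
Smith–Waterman alignment score (BLOSUM62, affine gaps 11/1) normalized to
a bit score through the Karlin–Altschul transform,

    S' = (lambda * S - ln K) / ln 2,      E = m * n * 2**(-S'),

with the standard gapped-BLOSUM62 constants lambda = 0.267, K = 0.041.
The resulting E-values are estimates on the same scale BLAST reports but
are not expected to match NCBI's numbers exactly (no length corrections,
no seeding heuristics); selection thresholds are applied on this
estimated scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

LAMBDA = 0.267
K = 0.041

_PROTEIN_OK = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class HomologHit:
    subject_id: str
    raw_score: float
    bitscore: float
    evalue_est: float
    subject_length: int


def _check_protein(seq: str, name: str) -> str:
    bad = set(seq.upper()) - _PROTEIN_OK
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)!r} in record {name!r}")
    return seq.upper()


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1
) -> Align.PairwiseAligner:
    """Local affine-gap protein aligner (a gap of length k costs open + k*extend)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bitscore(raw: float, lam: float = LAMBDA, k: float = K) -> float:
    return (lam * raw - math.log(k)) / math.log(2)


def evalue(bits: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bits)


def score_homologs(
    reference: str,
    db: Sequence[tuple[str, str]],
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    search_space: int | None = None,
) -> list[HomologHit]:
    """Score every subject against the reference; sort by estimated E-value.

    ``search_space`` overrides m*n (m = reference length, n = summed
    database length); ties in E-value break by ascending subject id.
    """
    if not reference:
        raise ValueError("empty reference sequence")
    if not db:
        raise ValueError("empty database")
    reference = _check_protein(reference, "reference")
    aligner = make_aligner(matrix, gap_open, gap_extend)
    m = len(reference)
    n_total = sum(len(s) for _, s in db)
    space = search_space if search_space is not None else m * n_total
    hits = []
    for sid, seq in db:
        seq = _check_protein(seq, sid)
        raw = max(aligner.score(reference, seq), 0.0)
        bits = bitscore(raw)
        hits.append(
            HomologHit(
                subject_id=sid,
                raw_score=raw,
                bitscore=bits,
                evalue_est=space * 2.0 ** (-bits),
                subject_length=len(seq),
            )
        )
    hits.sort(key=lambda h: (h.evalue_est, h.subject_id))
    return hits


def select_by_threshold(hits: Sequence[HomologHit], evalue_max: float) -> list[HomologHit]:
    """Keep hits with estimated E-value <= ``evalue_max``, order preserved."""
    return [h for h in hits if h.evalue_est <= evalue_max]


def filter_by_size_divergence(
    seqs: Sequence[tuple[str, str]],
    reference: tuple[str, str],
    tolerance: float = 0.20,
) -> list[tuple[str, str]]:
    """Drop sequences whose length diverges from the reference by more than
    ``tolerance`` (fraction of reference length, inclusive comparison).

    The reference itself is always kept if present in ``seqs``.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ValueError("tolerance must be in [0, 1]")
    ref_id, ref_seq = reference
    limit = tolerance * len(ref_seq)
    out = []
    for sid, seq in seqs:
        if sid == ref_id or abs(len(seq) - len(ref_seq)) <= limit:
            out.append((sid, seq))
    return out
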
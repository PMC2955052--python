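"""Degenerate nucleotide algebra: IUPAC codes, inosine, backtranslation.

A degenerate sequence is a plain string over the 15 IUPAC nucleotide
symbols plus ``I`` (inosine).  Every symbol denotes a set of the four
bases; inosine denotes {A,C,G,T} for matching and expansion purposes but,
unlike ``N``, counts as a *single* base in the design degeneracy (a spot
can be synthesized with inosine directly, so it does not multiply the
number of fully specified probes that must be printed on an in-situ
array).  ``total_degeneracy`` is the variant count when inosine *is*
expanded, i.e. the number of probes an in-situ synthesis actually needs.

Backtranslation maps a set of amino acids observed at one alignment
column to the degenerate codon covering the union of all their codons;
any codon position whose base set is all four bases is written ``I``
rather than ``N`` so that the universal-pairing nucleotide is used at
fully degenerate positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from Bio.Data import CodonTable

#: IUPAC nucleotide ambiguity codes plus inosine, as base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

#: Reverse map: base set -> canonical IUPAC symbol (full set -> N).
SET_TO_CODE: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_SETS.items() if k != "I"
}

DEGENERATE_ALPHABET = frozenset(IUPAC_SETS)

STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Amino-acid ambiguity symbols and their expansions.
AA_AMBIGUITY = {"B": frozenset("DN"), "Z": frozenset("EQ")}
STOP = "*"


class AlphabetError(ValueError):
    """Raised for symbols outside the degenerate nucleotide or protein alphabet."""


def validate(seq: str) -> str:
    """Return ``seq`` unchanged if it is a valid degenerate sequence."""
    bad = set(seq) - DEGENERATE_ALPHABET
    if bad:
        raise AlphabetError(
            f"invalid degenerate nucleotide symbol(s): {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table (64 codons -> amino acid or ``*``)."""

    table: dict[str, str]
    id: int = 1

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.table)}")
        missing = STANDARD_AAS - set(self.table.values())
        if missing:
            raise ValueError(f"genetic code missing amino acid(s): {sorted(missing)}")

    @classmethod
    @lru_cache(maxsize=None)
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        """Load a translation table by its NCBI identifier (1 = standard)."""
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(bio.forward_table)
        for codon in bio.stop_codons:
            table[codon] = STOP
        return cls(table=table, id=table_id)

    def codons_for(self, aa: str) -> frozenset[str]:
        """All codons translating to amino acid ``aa`` (or to STOP for ``*``)."""
        return frozenset(c for c, a in self.table.items() if a == aa)

    def translate_codon(self, codon: str) -> str:
        return self.table[codon]


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


def _expand_aa_set(aas: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for aa in aas:
        aa = aa.upper()
        if aa in STANDARD_AAS or aa == STOP:
            out.add(aa)
        elif aa in AA_AMBIGUITY:
            out |= AA_AMBIGUITY[aa]
        else:
            raise AlphabetError(f"unknown amino-acid symbol: {aa!r}")
    return out


def backtranslate_column(aas: Iterable[str], code: GeneticCode = STANDARD_CODE) -> str:
    """Degenerate codon covering every codon of every amino acid in ``aas``.

    STOP codons are excluded from the union; a column consisting solely of
    STOP symbols is an error.  Positions whose base set is {A,C,G,T} are
    written as inosine.
    """
    aa_set = _expand_aa_set(aas)
    if not aa_set:
        raise AlphabetError("empty amino-acid set")
    aa_set.discard(STOP)
    if not aa_set:
        raise AlphabetError("amino-acid set contains only STOP")
    position_sets: list[set[str]] = [set(), set(), set()]
    for aa in aa_set:
        for codon in code.codons_for(aa):
            for i in range(3):
                position_sets[i].add(codon[i])
    out = []
    for s in position_sets:
        sym = SET_TO_CODE[frozenset(s)]
        out.append("I" if sym == "N" else sym)
    return "".join(out)


def degeneracy(seq: str) -> int:
    """Variant count with inosine counted as a single base (design scale)."""
    validate(seq)
    d = 1
    for ch in seq:
        if ch != "I":
            d *= len(IUPAC_SETS[ch])
    return d


def total_degeneracy(seq: str) -> int:
    """Variant count with inosine expanded to all four bases (synthesis scale)."""
    validate(seq)
    d = 1
    for ch in seq:
        d *= len(IUPAC_SETS[ch])
    return d


def inosine_count(seq: str) -> int:
    validate(seq)
    return seq.count("I")


class ExpansionCapExceeded(RuntimeError):
    def __init__(self, count: int, cap: int):
        super().__init__(f"expansion would produce {count} sequences (cap {cap})")
        self.count = count
        self.cap = cap


def expand(seq: str, inosine_mode: str = "expand", cap: int = 10**6) -> list[str]:
    """All fully specified sequences represented by ``seq``.

    ``inosine_mode='expand'`` substitutes A/C/G/T at inosine positions
    (``total_degeneracy`` variants); ``'keep'`` retains the literal ``I``
    (``degeneracy`` variants).  Output is lexicographically sorted and
    duplicate-free by construction.
    """
    validate(seq)
    if inosine_mode not in ("expand", "keep"):
        raise ValueError(f"inosine_mode must be 'expand' or 'keep', got {inosine_mode!r}")
    n = total_degeneracy(seq) if inosine_mode == "expand" else degeneracy(seq)
    if n > cap:
        raise ExpansionCapExceeded(n, cap)
    options = []
    for ch in seq:
        if ch == "I" and inosine_mode == "keep":
            options.append(("I",))
        else:
            options.append(tuple(sorted(IUPAC_SETS[ch])))
    return ["".join(p) for p in itertools.product(*options)]


@dataclass(frozen=True)
class Translation:
    """Peptides encoded by a degenerate window, STOP-containing ones apart."""

    peptides: frozenset[str]
    with_stop: frozenset[str]


def translate_in_frame(
    seq: str, frame_offset: int = 0, code: GeneticCode = STANDARD_CODE
) -> Translation:
    """Translate every variant of ``seq`` in one frame.

    Only complete codons inside the window are translated; leading bases
    before ``frame_offset`` and any trailing partial codon are dropped.
    Codon positions are independent, so the peptide set is the cartesian
    product of per-codon amino-acid sets — no full expansion is needed.
    """
    validate(seq)
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    coding = seq[frame_offset:]
    n_codons = len(coding) // 3
    if n_codons == 0:
        raise ValueError("window shorter than one complete codon in this frame")
    aa_sets: list[set[str]] = []
    for i in range(n_codons):
        codon = coding[3 * i : 3 * i + 3]
        aas = {
            code.translate_codon("".join(bases))
            for bases in itertools.product(*(IUPAC_SETS[c] for c in codon))
        }
        aa_sets.append(aas)
    clean: set[str] = set()
    stopped: set[str] = set()
    for combo in itertools.product(*aa_sets):
        pep = "".join(combo)
        (stopped if STOP in pep else clean).add(pep)
    return Translation(peptides=frozenset(clean), with_stop=frozenset(stopped))
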
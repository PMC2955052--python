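"""Deterministic synthetic data: protein families, backgrounds, arrays.

Every generator is a pure function of its configuration and seed, and
emits ground-truth labels alongside the data so that screening and
positive-calling accuracy can be measured against a known answer.

The generators emulate the three kinds of input the pipeline consumes:

* small homologous protein families with controlled divergence (the
  alignment fed to consensus construction),
* CDS-like DNA backgrounds with planted near-identical decoys that each
  violate exactly one specificity criterion (exercising the Kane
  screen), and
* spotted-array feature tables with a smooth spatial background
  gradient, additive noise, random control probes and spiked targets
  (exercising the SNR' chain).

They model none of the physics (hybridization thermodynamics, scanner
optics); what passes here demonstrates algorithmic correctness, not
wet-lab performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .alphabet import IUPAC_SETS, STANDARD_AAS, STANDARD_CODE, GeneticCode, expand

AA_LIST = sorted(STANDARD_AAS)


@dataclass(frozen=True)
class FamilySimConfig:
    seed: int = 0
    reference_length: int = 300
    n_members: int = 8
    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    codon_usage: dict[str, dict[str, float]] | None = None  # aa -> codon -> weight

    def __post_init__(self) -> None:
        if self.reference_length < 1:
            raise ValueError("reference_length must be >= 1")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class FamilySim:
    reference_id: str
    reference: str
    members: tuple[tuple[str, str], ...]  # (id, protein) incl. reference
    coding_dna: dict[str, str]  # id -> true CDS


def _draw_codon(
    aa: str, rng: np.random.Generator, code: GeneticCode, usage
) -> str:
    codons = sorted(code.codons_for(aa))
    if usage and aa in usage:
        w = np.array([usage[aa].get(c, 0.0) for c in codons], dtype=float)
        if w.sum() > 0:
            return codons[rng.choice(len(codons), p=w / w.sum())]
    return codons[rng.integers(len(codons))]


def simulate_protein_family(
    cfg: FamilySimConfig, code: GeneticCode = STANDARD_CODE
) -> FamilySim:
    """Reference protein plus members derived by per-site substitution/indel,
    with true coding DNA drawn per codon usage (uniform by default)."""
    rng = np.random.default_rng(cfg.seed)
    ref = "".join(AA_LIST[i] for i in rng.integers(len(AA_LIST), size=cfg.reference_length))
    members: list[tuple[str, str]] = [("ref", ref)]
    for m in range(cfg.n_members):
        out = []
        for aa in ref:
            if rng.random() < cfg.indel_rate:
                op = rng.integers(2)
                if op == 0:  # deletion
                    continue
                out.append(AA_LIST[rng.integers(len(AA_LIST))])  # insertion
            if rng.random() < cfg.substitution_rate:
                choices = [a for a in AA_LIST if a != aa]
                out.append(choices[rng.integers(len(choices))])
            else:
                out.append(aa)
        members.append((f"member{m + 1}", "".join(out)))
    dna = {
        mid: "".join(_draw_codon(aa, rng, code, cfg.codon_usage) for aa in seq)
        for mid, seq in members
    }
    return FamilySim("ref", ref, tuple(members), dna)


@dataclass(frozen=True)
class PlantSpec:
    """A decoy engineered to violate exactly one specificity criterion.

    ``mode='identity'``: a probe variant mutated to a chosen identity
    percentage with every run of matches kept short of the stretch rule.
    ``mode='stretch'``: an exact 15-mer (or ``value``-mer) of a variant
    surrounded by forced mismatches, keeping overall identity low.
    ``mode='exact'``: the variant embedded verbatim.
    """

    probe: str
    mode: str  # identity | stretch | exact
    value: float | int | None = None


@dataclass(frozen=True)
class PlantTruth:
    record_id: str
    probe: str
    mode: str
    planted_start: int  # 1-based on the record
    expected_identity_pct: float
    expected_stretch: int


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _variant_of(probe: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_SETS[s])[rng.integers(len(IUPAC_SETS[s]))] for s in probe
    )


def _stats_vs_probe(insert: str, probe: str) -> tuple[float, int]:
    """Identity percent and longest match run of ``insert`` against the
    degenerate probe's base sets (the statistics the screen will see)."""
    matches = [b in IUPAC_SETS[s] for b, s in zip(insert, probe)]
    ident = 100.0 * sum(matches) / len(probe)
    best = run = 0
    for m in matches:
        run = run + 1 if m else 0
        best = max(best, run)
    return ident, best


def _mismatch_at(probe_sym: str, rng: np.random.Generator) -> str:
    outside = sorted(set("ACGT") - IUPAC_SETS[probe_sym])
    if not outside:
        raise ValueError("cannot mismatch a universal (N/I) probe position")
    return outside[rng.integers(len(outside))]


def _plant_insert(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, float, int]:
    """Build the insert for one decoy; returns (insert, identity_pct, stretch)
    measured against the degenerate probe (what the screen will report)."""
    probe = spec.probe
    var = _variant_of(probe, rng)
    L = len(var)
    # positions where a mismatch against the probe's base set is possible
    mutable = [p for p in range(L) if len(IUPAC_SETS[probe[p]]) < 4]
    if spec.mode == "exact":
        return var, 100.0, L
    if spec.mode == "identity":
        pct = float(spec.value if spec.value is not None else 85.0)
        if not 0 < pct <= 100:
            raise ValueError(f"impossible identity target: {pct}")
        n_mm = L - int(round(pct / 100.0 * L))
        if n_mm > len(mutable):
            raise ValueError(
                f"identity {pct}% needs {n_mm} mismatches but only "
                f"{len(mutable)} non-universal positions exist"
            )
        chars = list(var)
        if n_mm:
            # spread mismatches evenly so no match run reaches the stretch rule
            targets = np.linspace(0, L - 1, n_mm + 2)[1:-1]
            chosen: list[int] = []
            for t in targets:
                p = min(
                    (q for q in mutable if q not in chosen),
                    key=lambda q: abs(q - t),
                )
                chosen.append(p)
            for p in chosen:
                chars[p] = _mismatch_at(probe[p], rng)
        insert = "".join(chars)
        ident, stretch = _stats_vs_probe(insert, probe)
        return insert, ident, stretch
    if spec.mode == "stretch":
        k = int(spec.value if spec.value is not None else 15)
        if not 1 <= k <= L:
            raise ValueError(f"impossible stretch target: {k} for probe length {L}")
        start = (L - k) // 2
        chars = list(var)
        for p in mutable:
            if p < start or p >= start + k:
                chars[p] = _mismatch_at(probe[p], rng)
        insert = "".join(chars)
        ident, stretch = _stats_vs_probe(insert, probe)
        return insert, ident, stretch
    raise ValueError(f"unknown plant mode {spec.mode!r}")


def simulate_background_db(
    planted: Sequence[PlantSpec],
    n_records: int = 100,
    record_length: int = 1000,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[PlantTruth]]:
    """Random CDS-like records plus engineered decoys with ground truth.

    Decoys are appended after the clean records, one per plant spec, each
    carrying its expected best identity and longest stretch.
    """
    rng = np.random.default_rng(seed)
    records = [(f"bg{i:04d}", _random_dna(rng, record_length)) for i in range(n_records)]
    truths: list[PlantTruth] = []
    for j, spec in enumerate(planted):
        insert, ident, stretch = _plant_insert(spec, rng)
        host = _random_dna(rng, record_length)
        pos = int(rng.integers(0, record_length - len(insert) + 1))
        seq = host[:pos] + insert + host[pos + len(insert):]
        rid = f"decoy{j:02d}"
        records.append((rid, seq))
        truths.append(PlantTruth(rid, spec.probe, spec.mode, pos + 1, ident, stretch))
    return records, truths


@dataclass(frozen=True)
class ArraySimConfig:
    seed: int = 0
    n_target_probes: int = 500
    n_random_probes: int = 2000
    replicates: int = 3
    gradient: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    noise_sd: float = 5.0
    baseline: float = 100.0
    spikes: dict[str, float] = field(default_factory=dict)  # probe_id -> multiples of noise_sd


def simulate_array(cfg: ArraySimConfig) -> pd.DataFrame:
    """Feature table with a spatial background gradient, noise and spikes.

    Intensities are ``baseline + gradient(x, y) + noise`` for every spot;
    spiked target probes add ``k * noise_sd``.  Targets get ``replicates``
    randomly placed spots each (replicates scattered across the surface,
    as on the physical arrays); random control probes get one spot each.
    """
    rng = np.random.default_rng(cfg.seed)
    grad = cfg.gradient or (lambda x, y: np.zeros_like(x))
    rows: list[dict] = []
    for i in range(cfg.n_target_probes):
        pid = f"t{i:05d}"
        for rep in range(cfg.replicates):
            rows.append({"probe_id": pid, "probe_class": "target", "replicate": rep + 1})
    for i in range(cfg.n_random_probes):
        rows.append({"probe_id": f"r{i:05d}", "probe_class": "random", "replicate": 1})
    df = pd.DataFrame(rows)
    n = len(df)
    df["x"] = rng.random(n)
    df["y"] = rng.random(n)
    base = cfg.baseline + grad(df["x"].to_numpy(), df["y"].to_numpy())
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    spike = df["probe_id"].map(cfg.spikes).fillna(0.0).to_numpy() * cfg.noise_sd
    df["intensity"] = np.clip(base + noise + spike, 0.0, None)
    return df[["probe_id", "x", "y", "intensity", "probe_class", "replicate"]]


def variants_of(probe: str, seed: int = 0, k: int = 1) -> list[str]:
    """Convenience: ``k`` random fully specified variants of a degenerate probe."""
    rng = np.random.default_rng(seed)
    if k == 1:
        return [_variant_of(probe, rng)]
    pool = expand(probe)
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return [pool[i] for i in sorted(idx)]
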
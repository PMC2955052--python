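"""Spatially segmented signal-to-noise analysis of microarray features.

The scanned surface carries thousands of random control probes (random
length and sequence) that report technical background only.  The surface
is segmented into a grid of sub-squares (4 x 4 by default) by spot
coordinates; within each sub-square the random probes define a local
background position (median) and dispersion (scaled MAD by default).
Every spot's signal is then reduced and centralized as

    SNR' = (intensity - B_position) / B_dispersion

using its own sub-square's statistics, replicate SNR' values are
summarized by their median, and a probe is called positive when the
median SNR' strictly exceeds the threshold (3 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("probe_id", "x", "y", "intensity", "probe_class", "replicate")
PROBE_CLASSES = ("target", "random")

#: consistency factor making the MAD unbiased for a normal sd
MAD_SCALE = 1.4826
IQR_SCALE = 1.349


@dataclass(frozen=True)
class BackgroundStats:
    square_index: int
    b_position: float
    b_dispersion: float
    n_random: int


@dataclass(frozen=True)
class SnrRecord:
    probe_id: str
    snr_values: tuple[float, ...]
    median_snr: float
    positive: bool


def validate_features(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    bad = df.loc[~df["probe_class"].isin(PROBE_CLASSES)]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(
            f"unknown probe_class {bad['probe_class'].iloc[0]!r} at row {row}"
        )
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities in feature table")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite spot coordinates")
    return df


def _bin_index(values: np.ndarray, nbins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if nbins > 1 and hi == lo:
        raise ValueError("cannot segment a grid: all coordinates identical")
    if hi == lo:
        return np.zeros(len(values), dtype=int)
    idx = np.floor((values - lo) / (hi - lo) * nbins).astype(int)
    return np.clip(idx, 0, nbins - 1)  # closes the last interval


def segment_grid(df: pd.DataFrame, rows: int = 4, cols: int = 4) -> pd.Series:
    """Sub-square index per feature: the [min, max] coordinate ranges are cut
    into equal half-open intervals (last closed; internal boundaries go to
    the higher interval); index = row * cols + col."""
    if df.empty:
        raise ValueError("no features to segment")
    row_idx = _bin_index(df["y"].to_numpy(dtype=float), rows)
    col_idx = _bin_index(df["x"].to_numpy(dtype=float), cols)
    return pd.Series(row_idx * cols + col_idx, index=df.index, name="square_index")


def _dispersion(values: np.ndarray, estimator: str) -> float:
    if estimator == "mad":
        return MAD_SCALE * float(np.median(np.abs(values - np.median(values))))
    if estimator == "iqr":
        q75, q25 = np.percentile(values, [75, 25])
        return float(q75 - q25) / IQR_SCALE
    if estimator == "sd":
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    raise ValueError(f"unknown dispersion estimator {estimator!r}")


def background_stats(
    df: pd.DataFrame,
    square_index: pd.Series,
    min_random: int = 10,
    dispersion_floor: float = 1e-9,
    estimator: str = "mad",
) -> dict[int, BackgroundStats]:
    """Per-sub-square background from random control probes.

    Squares holding fewer than ``min_random`` random probes fall back to
    whole-array random-probe statistics (with a logged warning).
    """
    rnd = df["probe_class"] == "random"
    if not rnd.any():
        raise ValueError("no random control probes: background is not measurable")
    all_vals = df.loc[rnd, "intensity"].to_numpy(dtype=float)
    global_stats = (
        float(np.median(all_vals)),
        max(_dispersion(all_vals, estimator), dispersion_floor),
    )
    out: dict[int, BackgroundStats] = {}
    for sq in sorted(square_index.unique()):
        vals = df.loc[rnd & (square_index == sq), "intensity"].to_numpy(dtype=float)
        if len(vals) < min_random:
            logger.warning(
                "sub-square %d has %d random probes (< %d); using whole-array background",
                sq, len(vals), min_random,
            )
            pos, disp = global_stats
        else:
            pos = float(np.median(vals))
            disp = max(_dispersion(vals, estimator), dispersion_floor)
        out[sq] = BackgroundStats(int(sq), pos, disp, len(vals))
    return out


def compute_snr(
    df: pd.DataFrame, square_index: pd.Series, stats: dict[int, BackgroundStats]
) -> pd.Series:
    """SNR' per feature using its own sub-square's background."""
    pos = square_index.map({k: s.b_position for k, s in stats.items()})
    disp = square_index.map({k: s.b_dispersion for k, s in stats.items()})
    if pos.isna().any():
        raise ValueError("feature in a sub-square without background statistics")
    return ((df["intensity"] - pos) / disp).rename("snr")


def summarize_replicates(
    df: pd.DataFrame, snr: pd.Series, threshold: float = 3.0
) -> list[SnrRecord]:
    """Median SNR' across replicates per target probe; strict positive call."""
    target = df["probe_class"] == "target"
    out: list[SnrRecord] = []
    sub = df.loc[target].assign(snr=snr.loc[target])
    for probe_id, grp in sub.groupby("probe_id", sort=True):
        values = tuple(grp.sort_values("replicate")["snr"])
        if len(values) == 1:
            logger.warning("probe %s has a single replicate", probe_id)
        med = float(np.median(values))
        out.append(SnrRecord(str(probe_id), values, med, med > threshold))
    return out


def analyze_array(
    df: pd.DataFrame,
    rows: int = 4,
    cols: int = 4,
    threshold: float = 3.0,
    min_random: int = 10,
    estimator: str = "mad",
    dispersion_floor: float = 1e-9,
) -> pd.DataFrame:
    """Full chain: segment -> background -> SNR' -> replicate medians -> calls."""
    df = validate_features(df)
    sq = segment_grid(df, rows, cols)
    stats = background_stats(df, sq, min_random, dispersion_floor, estimator)
    snr = compute_snr(df, sq, stats)
    records = summarize_replicates(df, snr, threshold)
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "median_snr": [r.median_snr for r in records],
            "n_replicates": [len(r.snr_values) for r in records],
            "positive": [r.positive for r in records],
        }
    )
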
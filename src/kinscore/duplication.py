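"""Duplication-class tallies, Ka/Ks selection regimes, Ks-peak detection and
molecular-clock WGD dating.

Selection regime follows the usual reading of the Ka/Ks ratio between
homologous gene pairs: > 1 positive selection, < 1 purifying selection,
= 1 neutral evolution (within a tiny numerical band), undefined when Ks is
zero or missing.

Whole-genome duplication (WGD) events leave a hump of gene pairs at a
common synonymous distance; the hump location ks_mode converts to an age by
the molecular clock T = Ks / (2 r), with clock rate r in substitutions per
synonymous site per year (default 8.25e-9, a standard dicot rate). The
mode is found as the argmax of a Gaussian kernel density (Silverman
bandwidth) on a fixed grid. Pairs with very small Ks — recent small-scale
duplicates and near-allelic pairs — pile up against zero and would mask the
WGD hump, so peak detection is restricted to Ks in (0.2, 2] by default
(saturated Ks above 2 is equally excluded); both bounds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._util import ValidationError, round_half_up

REGIMES = ("positive", "purifying", "neutral", "undefined")


@dataclass(frozen=True)
class ClockParams:
    """Molecular clock rate r (substitutions / synonymous site / year)."""

    r: float = 8.25e-9

    def __post_init__(self):
        if not self.r > 0:
            raise ValidationError(f"clock rate must be > 0, got {self.r}")


def classify_selection(ka, ks, epsilon: float = 1e-9) -> tuple[float, str]:
    """Classify the selection regime of one gene pair.

    Returns (ratio, regime) where ratio = ka/ks (NaN when undefined) and
    regime is one of positive / purifying / neutral / undefined. A ratio
    within ``epsilon`` of 1 is called neutral; exact equality is a
    measure-zero event, so the band exists purely to absorb floating-point
    noise.
    """
    ka = float("nan") if ka is None else float(ka)
    ks = float("nan") if ks is None else float(ks)
    if np.isnan(ka) or np.isnan(ks) or ks == 0:
        return float("nan"), "undefined"
    ratio = ka / ks
    if ratio > 1 + epsilon:
        return ratio, "positive"
    if ratio < 1 - epsilon:
        return ratio, "purifying"
    return ratio, "neutral"


def add_selection_calls(pairs: pd.DataFrame, epsilon: float = 1e-9) -> pd.DataFrame:
    """Annotate a duplication-pair table with ratio and regime columns."""
    out = pairs.copy()
    calls = [classify_selection(ka, ks, epsilon)
             for ka, ks in zip(out["ka"], out["ks"])]
    out["ratio"] = [c[0] for c in calls]
    out["regime"] = [c[1] for c in calls]
    return out


def summarize_kaks(pairs: pd.DataFrame, epsilon: float = 1e-9) -> pd.DataFrame:
    """Per-duplication-class Ka/Ks summary.

    Returns one row per dup_class present: n (pairs), n_defined (pairs with
    a finite ratio), ratio_min / ratio_max / ratio_mean over defined ratios
    (NaN when none are defined), and n_positive (pairs under positive
    selection).
    """
    called = add_selection_calls(pairs, epsilon)
    rows = []
    for cls, sub in called.groupby("dup_class", sort=True):
        ratios = sub["ratio"].dropna()
        rows.append({
            "dup_class": cls,
            "n": len(sub),
            "n_defined": len(ratios),
            "ratio_min": ratios.min() if len(ratios) else float("nan"),
            "ratio_max": ratios.max() if len(ratios) else float("nan"),
            "ratio_mean": ratios.mean() if len(ratios) else float("nan"),
            "n_positive": int((sub["regime"] == "positive").sum()),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KsPeakEstimate:
    """Location of the dominant Ks mode inside the search window."""

    ks_mode: float
    bandwidth: float
    n_pairs_used: int
    ks_range_used: tuple[float, float]


def estimate_ks_peak(ks_values, ks_range: tuple[float, float] = (0.2, 2.0),
                     bandwidth=None, grid_step: float = 0.01,
                     min_values: int = 30) -> KsPeakEstimate:
    """Locate the Ks mode by Gaussian KDE argmax on a regular grid.

    ``ks_range`` is the half-open window (low, high]: values at or below
    ``low`` and above ``high`` are discarded before density estimation.
    ``bandwidth`` follows scipy's ``bw_method`` (default Silverman's rule).
    When the retained values are all identical the KDE is degenerate and
    the common value is returned directly with a minimum bandwidth of one
    grid step.
    """
    low, high = ks_range
    if not low < high:
        raise ValidationError(f"invalid ks_range {ks_range}")
    ks = np.asarray(ks_values, dtype=float)
    ks = ks[~np.isnan(ks)]
    vals = ks[(ks > low) & (ks <= high)]
    if vals.size < min_values:
        raise ValidationError(
            f"only {vals.size} Ks values inside ({low}, {high}]; need >= {min_values}"
        )
    if np.ptp(vals) == 0:
        return KsPeakEstimate(ks_mode=float(vals[0]), bandwidth=float(grid_step),
                              n_pairs_used=int(vals.size), ks_range_used=(low, high))
    kde = gaussian_kde(vals, bw_method=bandwidth if bandwidth is not None else "silverman")
    grid = np.arange(max(low, grid_step), high + grid_step / 2, grid_step)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    bw = float(kde.factor * vals.std(ddof=1))
    return KsPeakEstimate(ks_mode=mode, bandwidth=bw,
                          n_pairs_used=int(vals.size), ks_range_used=(low, high))


def date_wgd(ks: float, clock: ClockParams = ClockParams()) -> float:
    """Age of a duplication event in million years: T = Ks / (2 r) / 1e6."""
    if ks < 0:
        raise ValidationError(f"Ks must be non-negative, got {ks}")
    return ks / (2.0 * clock.r) / 1e6


def tally_duplication_classes(assignments) -> pd.DataFrame:
    """Count genes per duplication class and express each as a percent of
    the total (half-up, 2 decimals).

    ``assignments`` maps gene -> class: a dict, a Series indexed by gene, or
    a DataFrame with gene_id and dup_class columns. A gene appearing twice
    with conflicting classes is an error.
    """
    if isinstance(assignments, pd.DataFrame):
        df = assignments[["gene_id", "dup_class"]]
    else:
        s = pd.Series(assignments)
        df = pd.DataFrame({"gene_id": s.index.astype(str), "dup_class": s.values})
    if df.empty:
        raise ValidationError("no duplication-class assignments given")
    conflicts = df.groupby("gene_id")["dup_class"].nunique()
    if (conflicts > 1).any():
        g = conflicts[conflicts > 1].index[0]
        raise ValidationError(f"gene {g!r} assigned to more than one duplication class")
    df = df.drop_duplicates()
    total = len(df)
    counts = df["dup_class"].value_counts().sort_values(ascending=False)
    return pd.DataFrame({
        "dup_class": counts.index,
        "n": counts.to_numpy(),
        "percent": [round_half_up(100.0 * n / total, 2) for n in counts],
    })
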
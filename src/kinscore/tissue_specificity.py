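"""Tau tissue-specificity index on TPM expression matrices.

Tau is the standard specificity index of Yanai and colleagues:

    tau = sum_i (1 - x_i / x_max) / (N - 1)

over N >= 2 tissues with non-negative expression x_i. It is 0 for perfectly
uniform expression, 1 for expression confined to a single tissue, and
undefined (NaN) when a gene is silent in every tissue. Genes with
tau >= threshold (default 0.8) are called tissue-specific.

Tau is computed on raw TPM by default; an optional log2(TPM+1) mode is
available (log compression pulls tau toward 0, so the two modes are not
interchangeable — pick one and keep it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import ValidationError


def compute_tau(expr) -> float:
    """Tau for one gene's expression vector across N >= 2 tissues.

    Returns NaN when the vector is all-zero (specificity of a silent gene
    is undefined).
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError(f"need a 1-D vector over >= 2 tissues, got shape {x.shape}")
    if np.isnan(x).any():
        raise ValidationError("expression vector contains missing values")
    if (x < 0).any():
        raise ValidationError(f"negative expression value {x[x < 0][0]}")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def classify_tissue_specific(matrix: pd.DataFrame, threshold: float = 0.8,
                             log_transform: bool = False) -> pd.DataFrame:
    """Tau-screen every gene of a gene x tissue matrix.

    Parameters
    ----------
    matrix : DataFrame indexed by gene_id, one non-negative column per tissue.
        If several columns share a tissue (replicates), average them per
        tissue before calling this function.
    threshold : tau value at and above which a gene is called specific.
    log_transform : compute tau on log2(TPM+1) instead of raw TPM.

    Returns
    -------
    DataFrame indexed by gene_id with columns tau, max_tissue (argmax tissue,
    first column wins ties), max_tpm (on the raw scale), is_specific.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 tissue columns")
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative expression values in matrix")
    raw_max = x.max(axis=1)
    if log_transform:
        x = np.log2(x + 1.0)
    m = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / m[:, None]).sum(axis=1) / (x.shape[1] - 1)
    tau = np.where(m == 0, np.nan, tau)
    argmax = x.argmax(axis=1)  # np.argmax takes the first on ties
    out = pd.DataFrame({
        "tau": tau,
        "max_tissue": matrix.columns.to_numpy()[argmax],
        "max_tpm": raw_max,
        "is_specific": ~np.isnan(tau) & (tau >= threshold),
    }, index=matrix.index)
    return out


def specific_counts_by_tissue(results: pd.DataFrame) -> pd.Series:
    """Number of tissue-specific genes per argmax tissue (summary of a
    :func:`classify_tissue_specific` table)."""
    return results.loc[results["is_specific"], "max_tissue"].value_counts()


def fold_over_baseline(treated: pd.DataFrame, baseline: pd.Series | pd.DataFrame,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene expression fold over a baseline condition.

    Generic treatment-vs-control profiling on expression matrices (e.g.
    hormone-treated vs. untreated tissue): (treated + pseudocount) /
    (baseline + pseudocount), aligned on gene_id. The pseudocount keeps
    ratios finite for genes silent in the baseline.
    """
    if isinstance(baseline, pd.DataFrame):
        baseline = baseline.mean(axis=1)
    aligned = treated.align(baseline, axis=0, join="inner")
    t, b = aligned
    return (t.add(pseudocount)).div(b.add(pseudocount), axis=0)
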
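"""Four-method cross-study gene scoring and top-k rank-union selection.

The problem: differential-expression contrasts pooled from many independent
projects cannot be merged at the count level because of batch effects, and
stress conditions are represented by wildly unequal numbers of contrasts.
The scoring system sidesteps both issues by working only with per-contrast
DE calls and fold changes:

- a gene is *flagged* in a contrast when it passes ``|FC| > fc_threshold``
  (equivalently ``|log2FC| >= log2(fc_threshold)``) and ``p < p_threshold``;
  up- and down-regulation are flagged identically;
- **T** (total) sums the 0/1 flags over all contrasts — response *frequency*;
- **TFC** (total fold change) sums ``|log2FC|`` over flagged contrasts —
  response *intensity*;
- **AT** (average total) averages the flags within each stress group and
  sums the group means, so a stress represented by 20 contrasts weighs no
  more than one represented by 2;
- **ATFC** does the same with the fold-change magnitudes.

Genes are ranked separately under each method and the union of the four
top-k lists is the selected set; genes strong under any one view of
importance (frequency vs. intensity, raw vs. group-balanced) are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError

METHODS = ("T", "TFC", "AT", "ATFC")


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds for DE flagging and selection.

    fc_threshold is a *linear* fold change (default 2, i.e. |log2FC| >= 1);
    p_threshold is the DE p-value cut (strict, default 0.05); k is the
    per-method top-list size (default 30). use_adjusted_p switches the flag
    to the p_adj column when the stats table carries one.
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    k: int = 30
    use_adjusted_p: bool = False

    def __post_init__(self):
        if not self.fc_threshold > 1:
            raise ValidationError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if not 0 < self.p_threshold < 1:
            raise ValidationError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")

    @property
    def log2fc_threshold(self) -> float:
        return math.log2(self.fc_threshold)


def flag_de(log2fc, p_value, params: ScoringParams = ScoringParams()) -> bool:
    """Return True iff a single (log2fc, p) observation counts as
    differentially expressed: p present and < p_threshold, and
    |log2fc| >= log2(fc_threshold). Missing values never flag.

    The fold boundary is inclusive so that a gene at exactly the threshold
    magnitude contributes log2(fc_threshold) to TFC (the smallest nonzero
    contribution the score can take).
    """
    if log2fc is None or p_value is None:
        return False
    if np.isnan(log2fc) or np.isnan(p_value):
        return False
    return p_value < params.p_threshold and abs(log2fc) >= params.log2fc_threshold


def _flag_vector(log2fc: np.ndarray, p: np.ndarray, params: ScoringParams) -> np.ndarray:
    ok = ~np.isnan(log2fc) & ~np.isnan(p)
    return ok & (p < params.p_threshold) & (np.abs(log2fc) >= params.log2fc_threshold)


def compute_scores(stats: pd.DataFrame, meta: pd.DataFrame,
                   params: ScoringParams = ScoringParams()) -> pd.DataFrame:
    """Score every gene under all four methods.

    Parameters
    ----------
    stats : DataFrame with columns gene_id, contrast_id, log2fc, p_value
        (and optionally p_adj), one row per gene per contrast. Genes absent
        from a contrast simply contribute 0 there.
    meta : DataFrame with columns contrast_id, project_id, stress_group,
        tissue. Every contrast in `stats` must appear here; group sizes n_g
        are taken from `meta`, so contrasts with no row in `stats` still
        enter the group denominators.

    Returns
    -------
    DataFrame indexed by gene_id with columns T, TFC, AT, ATFC and
    rank_T, rank_TFC, rank_AT, rank_ATFC (rank 1 = best; ties broken by
    gene_id ascending). Genes never flagged anywhere keep all-zero scores
    and stay in the table.
    """
    if meta.empty:
        raise ValidationError("contrast metadata is empty; need at least one contrast")
    unknown = set(stats["contrast_id"]) - set(meta["contrast_id"])
    if unknown:
        raise ValidationError(
            f"contrast(s) {sorted(unknown)[:5]} in stats are missing from metadata"
        )

    p_col = "p_adj" if params.use_adjusted_p else "p_value"
    if p_col not in stats.columns:
        raise ValidationError(f"stats table has no column {p_col!r}")

    contrasts = pd.Index(meta["contrast_id"], name="contrast_id")
    genes = pd.Index(sorted(stats["gene_id"].unique()), name="gene_id")

    log2fc = stats["log2fc"].to_numpy(dtype=float)
    p = stats[p_col].to_numpy(dtype=float)
    flags = _flag_vector(log2fc, p, params)
    mags = np.where(flags, np.abs(log2fc), 0.0)

    work = pd.DataFrame({
        "gene_id": stats["gene_id"].to_numpy(),
        "contrast_id": stats["contrast_id"].to_numpy(),
        "flag": flags.astype(float),
        "mag": mags,
    })
    # gene x contrast matrices, absent cells = 0
    flag_mat = (work.pivot_table(index="gene_id", columns="contrast_id",
                                 values="flag", fill_value=0.0, aggfunc="sum")
                .reindex(index=genes, columns=contrasts, fill_value=0.0))
    mag_mat = (work.pivot_table(index="gene_id", columns="contrast_id",
                                values="mag", fill_value=0.0, aggfunc="sum")
               .reindex(index=genes, columns=contrasts, fill_value=0.0))

    groups = meta.set_index("contrast_id")["stress_group"]
    group_sizes = groups.value_counts()

    scores = pd.DataFrame(index=genes)
    scores["T"] = flag_mat.sum(axis=1).astype(int)
    scores["TFC"] = mag_mat.sum(axis=1)
    at = pd.Series(0.0, index=genes)
    atfc = pd.Series(0.0, index=genes)
    for g, n_g in group_sizes.items():
        cols = groups.index[groups == g]
        at += flag_mat[cols].sum(axis=1) / n_g
        atfc += mag_mat[cols].sum(axis=1) / n_g
    scores["AT"] = at
    scores["ATFC"] = atfc

    for m in METHODS:
        order = rank_by_method(scores, m)
        scores[f"rank_{m}"] = pd.Series(
            np.arange(1, len(order) + 1), index=order
        ).reindex(genes)
    return scores


def rank_by_method(scores: pd.DataFrame, method: str) -> list[str]:
    """Genes ordered best-first under one method: descending score, ties
    broken by gene_id ascending (deterministic)."""
    if method not in METHODS:
        raise ValidationError(f"unknown scoring method {method!r}; expected one of {METHODS}")
    s = scores[method]
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return order


@dataclass
class SelectionResult:
    """Top-k lists per method, their deduplicated union, and per-gene
    provenance (which methods selected each gene)."""

    k: int
    per_method: dict[str, list[str]]
    union: list[str]
    provenance: pd.DataFrame = field(repr=False)


def select_top_union(scores: pd.DataFrame, params: ScoringParams = ScoringParams(),
                     ties: str = "truncate") -> SelectionResult:
    """Take the top k genes under each of the four methods and merge them.

    ``ties="truncate"`` (default) keeps exactly k per method, resolving ties
    at the boundary by gene_id; ``ties="keep-all"`` extends each list to
    include every gene whose score equals the k-th score (for sensitivity
    analysis, since published top-k lists rarely document tie handling).
    """
    k = params.k
    if len(scores) < k:
        raise ValidationError(
            f"cannot select top {k}: only {len(scores)} genes in the score table"
        )
    if ties not in ("truncate", "keep-all"):
        raise ValidationError(f"unknown ties mode {ties!r}")

    per_method: dict[str, list[str]] = {}
    for m in METHODS:
        order = rank_by_method(scores, m)
        top = order[:k]
        if ties == "keep-all":
            cutoff = scores[m][top[-1]]
            top = [g for g in order if scores[m][g] > cutoff] + \
                  [g for g in order if scores[m][g] == cutoff]
        per_method[m] = top

    union = sorted(set().union(*per_method.values()))
    rows = []
    for g in union:
        methods = [m for m in METHODS if g in set(per_method[m])]
        rows.append({"gene_id": g, "methods": ",".join(methods),
                     "n_methods": len(methods)})
    provenance = pd.DataFrame(rows, columns=["gene_id", "methods", "n_methods"])
    return SelectionResult(k=k, per_method=per_method, union=union,
                           provenance=provenance)
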
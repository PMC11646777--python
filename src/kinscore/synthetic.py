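"""Seed-reproducible synthetic inputs with the structure the pipeline assumes.

The study generator emulates a multi-project stress-transcriptome compendium:
around ten stress groups with very unequal contrast counts (one group an
order of magnitude larger than the median, as happens when a single crop
stress attracts most of the sequencing effort), each group's contrasts
split across "projects" that carry their own additive log2-fold-change
shift (the batch effect the group-averaged scores are designed to resist).
Genes are planted in three roles: *broad* responders that are differentially
expressed with high probability in every contrast, *narrow* responders
confined to one home group, and *null* genes that only ever flag by chance.

The batch effect is modeled at the summary-statistic level (a project-wide
shift added to every log2FC) rather than at the count level, because the
pipeline consumes DE statistics, not counts. p-values are likewise drawn
marginally — Uniform(0, 0.05) for true DE events, Uniform(0, 1) otherwise —
since the scores only consume the (flag, magnitude) pair.

The expression generator plants tissue-specific genes (one high-expression
home tissue, low elsewhere) among null genes with i.i.d. log-normal TPM
across tissues; the Ks generator mixes an exponential small-scale-duplication
background with a Gaussian WGD peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError

STRESS_GROUPS = (
    "cold", "heat", "salt", "alkali", "drought",
    "flooding", "PEG6000", "low-nutrient", "sclerotinia", "orobanche",
)

#: Contrasts per stress group; drought carries 10x the median load, matching
#: the shape of public stress compendia where one stress dominates.
DEFAULT_CONTRASTS_PER_GROUP = (2, 3, 2, 2, 20, 4, 2, 3, 2, 2)

TISSUES = (
    "root", "stem", "leaf", "bract", "pollen", "stamen", "pistil",
    "DF_ovary", "DF_corolla", "RF_ovary", "RF_ligule",
)


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the synthetic multi-project DE study."""

    n_genes: int = 2000
    n_broad_responders: int = 50
    n_narrow_responders: int = 50
    contrasts_per_group: tuple[int, ...] = DEFAULT_CONTRASTS_PER_GROUP
    group_names: tuple[str, ...] = STRESS_GROUPS
    de_prob_broad: float = 0.9
    de_prob_narrow_in_home_group: float = 0.9
    effect_mean: float = 2.5      # mean |log2FC| of a true DE event
    effect_sd: float = 1.0
    effect_floor: float = 1.0     # |log2FC| never below the flagging boundary
    null_log2fc_sd: float = 0.3
    batch_shift_sd: float = 0.3   # project-level additive log2FC shift
    contrasts_per_project: int = 4
    seed: int = 0

    def __post_init__(self):
        if len(self.contrasts_per_group) != len(self.group_names):
            raise ValidationError("contrasts_per_group and group_names differ in length")
        if any(c < 1 for c in self.contrasts_per_group):
            raise ValidationError("every group needs at least one contrast")
        if self.n_broad_responders + self.n_narrow_responders > self.n_genes:
            raise ValidationError("more planted responders than genes")
        for p in (self.de_prob_broad, self.de_prob_narrow_in_home_group):
            if not 0 <= p <= 1:
                raise ValidationError(f"DE probability {p} outside [0,1]")

    @property
    def n_contrasts(self) -> int:
        return sum(self.contrasts_per_group)

    @property
    def largest_group(self) -> str:
        i = int(np.argmax(self.contrasts_per_group))
        return self.group_names[i]


def _make_meta(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for group, n_c in zip(design.group_names, design.contrasts_per_group):
        for j in range(n_c):
            project = f"{group}_p{j // design.contrasts_per_project}"
            rows.append({
                "contrast_id": f"{group}_c{j}",
                "project_id": project,
                "stress_group": group,
                "tissue": "leaf",
            })
    return pd.DataFrame(rows)


def simulate_study(design: StudyDesign = StudyDesign()):
    """Generate (stats, meta, truth) tables for one synthetic study.

    stats has one row per gene per contrast (gene_id, contrast_id, log2fc,
    p_value); meta maps contrasts to projects and stress groups; truth has
    one row per gene (gene_id, role in {broad, narrow, null}, home_group —
    the largest stress group — for narrow genes, empty otherwise).
    """
    rng = np.random.default_rng(design.seed)
    meta = _make_meta(design)
    n_genes, n_contrasts = design.n_genes, design.n_contrasts

    width = len(str(n_genes - 1))
    genes = np.array([f"g{i:0{width}d}" for i in range(n_genes)])
    roles = np.array(["null"] * n_genes, dtype=object)
    roles[: design.n_broad_responders] = "broad"
    roles[design.n_broad_responders:
          design.n_broad_responders + design.n_narrow_responders] = "narrow"
    home_group = design.largest_group

    # per-gene, per-contrast DE event probability
    group_of = meta["stress_group"].to_numpy()
    prob = np.zeros((n_genes, n_contrasts))
    prob[roles == "broad", :] = design.de_prob_broad
    prob[np.ix_(roles == "narrow", group_of == home_group)] = \
        design.de_prob_narrow_in_home_group

    event = rng.random((n_genes, n_contrasts)) < prob

    effect = np.maximum(
        rng.normal(design.effect_mean, design.effect_sd, (n_genes, n_contrasts)),
        design.effect_floor,
    )
    sign = rng.choice([-1.0, 1.0], (n_genes, n_contrasts))
    null_fc = rng.normal(0.0, design.null_log2fc_sd, (n_genes, n_contrasts))
    log2fc = np.where(event, sign * effect, null_fc)

    p = np.where(
        event,
        rng.uniform(0.0, 0.05, (n_genes, n_contrasts)),
        rng.uniform(0.0, 1.0, (n_genes, n_contrasts)),
    )

    # project-level batch shift, shared by every gene in the project
    projects = meta["project_id"].to_numpy()
    unique_projects = pd.unique(projects)
    shift_of = dict(zip(
        unique_projects,
        rng.normal(0.0, design.batch_shift_sd, len(unique_projects)),
    ))
    log2fc = log2fc + np.array([shift_of[p_] for p_ in projects])[None, :]

    stats = pd.DataFrame({
        "gene_id": np.repeat(genes, n_contrasts),
        "contrast_id": np.tile(meta["contrast_id"].to_numpy(), n_genes),
        "log2fc": log2fc.ravel(),
        "p_value": p.ravel(),
    })
    truth = pd.DataFrame({
        "gene_id": genes,
        "role": roles,
        "home_group": np.where(roles == "narrow", home_group, ""),
    })
    return stats, meta, truth


def simulate_expression(n_genes: int = 2000, tissues: tuple[str, ...] = TISSUES,
                        n_specific: int = 20, seed: int = 0,
                        high: tuple[float, float] = (5.0, 0.5),
                        low: tuple[float, float] = (-1.0, 0.7),
                        null: tuple[float, float] = (2.0, 0.5)):
    """Generate a (matrix, truth) pair for the Tau screen.

    Specific genes express log-normally high (parameters ``high`` on the log
    scale) in one randomly chosen home tissue and low (``low``) elsewhere,
    giving expected tau well above 0.9; null genes draw i.i.d. LogNormal
    (``null``) across all tissues, which keeps their tau comfortably below
    the 0.8 screening threshold. truth has columns gene_id, is_specific,
    specific_tissue.
    """
    if n_specific > n_genes:
        raise ValidationError(f"n_specific ({n_specific}) exceeds n_genes ({n_genes})")
    if len(tissues) < 2:
        raise ValidationError("need at least 2 tissues")
    rng = np.random.default_rng(seed)
    n_t = len(tissues)
    width = len(str(max(n_genes - 1, 1)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]

    x = rng.lognormal(null[0], null[1], (n_genes, n_t))
    home = rng.integers(0, n_t, n_specific)
    x[:n_specific, :] = rng.lognormal(low[0], low[1], (n_specific, n_t))
    x[np.arange(n_specific), home] = rng.lognormal(high[0], high[1], n_specific)

    matrix = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=list(tissues))
    truth = pd.DataFrame({
        "gene_id": genes,
        "is_specific": [i < n_specific for i in range(n_genes)],
        "specific_tissue": [tissues[home[i]] if i < n_specific else ""
                            for i in range(n_genes)],
    })
    return matrix, truth


def simulate_ks(n: int = 2000, background_weight: float = 0.7,
                background_mean: float = 0.15, peak_loc: float = 0.54,
                peak_sd: float = 0.08, ks_max: float = 2.0, seed: int = 0):
    """Generate (ks_values, truth) mixing a small-scale-duplication
    exponential background with a Gaussian WGD peak, truncated to (0, ks_max].

    truth is {"true_peak": peak_loc}.
    """
    if n < 100:
        raise ValidationError(f"need n >= 100 Ks values, got {n}")
    rng = np.random.default_rng(seed)
    out: list[float] = []
    while len(out) < n:
        take = n - len(out)
        from_bg = rng.random(take) < background_weight
        draw = np.where(
            from_bg,
            rng.exponential(background_mean, take),
            rng.normal(peak_loc, peak_sd, take),
        )
        draw = draw[(draw > 0) & (draw <= ks_max)]
        out.extend(draw.tolist())
    return np.array(out[:n]), {"true_peak": peak_loc}
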
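"""Descriptive kinome statistics from a per-gene catalog table.

Everything here is plain tabulation over a catalog of kinase genes with
family/subfamily labels and per-gene attributes (intron count, number of
kinase domains, transmembrane helices, signal peptide): composition counts
and percentages at both classification levels, intron-count dispersion per
subfamily, cross-species subfamily proportions, and membrane/secretion
cross-tabs. Percentages are rounded half-up (2 decimals by default) so the
printed tables match hand arithmetic on the counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import ValidationError, round_half_up


def family_composition(catalog: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Counts and percentages of catalog members at the family and the
    subfamily level. Returns a long table (level, name, n, percent) with
    percent = 100*n/total."""
    if catalog.empty:
        raise ValidationError("empty catalog")
    total = len(catalog)
    rows = []
    for level in ("family", "subfamily"):
        counts = catalog[level].value_counts().sort_values(ascending=False)
        for name, n in counts.items():
            rows.append({"level": level, "name": name, "n": int(n),
                         "percent": round_half_up(100.0 * n / total, ndigits)})
    return pd.DataFrame(rows)


def cross_species_composition(catalogs: dict[str, pd.DataFrame],
                              ndigits: int = 2) -> pd.DataFrame:
    """Subfamily proportions across species.

    ``catalogs`` maps species name -> catalog table. Returns a long table
    (species, subfamily, n, percent) covering the union of subfamilies, so
    a subfamily absent from one species appears there with n = 0.
    """
    if len(catalogs) < 2:
        raise ValidationError("need catalogs for at least 2 species")
    for sp, cat in catalogs.items():
        if cat.empty:
            raise ValidationError(f"catalog for species {sp!r} is empty")
    all_subfamilies = sorted(set().union(
        *(set(cat["subfamily"]) for cat in catalogs.values())
    ))
    rows = []
    for sp in sorted(catalogs):
        cat = catalogs[sp]
        total = len(cat)
        counts = cat["subfamily"].value_counts()
        for sub in all_subfamilies:
            n = int(counts.get(sub, 0))
            rows.append({"species": sp, "subfamily": sub, "n": n,
                         "percent": round_half_up(100.0 * n / total, ndigits)})
    return pd.DataFrame(rows)


def intron_stats(catalog: pd.DataFrame, low_intron_cutoff: int = 10):
    """Per-subfamily intron-count dispersion plus a catalog-wide summary.

    Variance is the population variance (divisor n), which is well-defined
    (0) for single-member subfamilies. The global summary reports how many
    genes have at most ``low_intron_cutoff`` introns and how many have none.

    Returns (per_subfamily DataFrame, global dict).
    """
    counts = catalog["intron_count"]
    if (counts < 0).any():
        raise ValidationError("negative intron count in catalog")
    rows = []
    for sub, grp in catalog.groupby("subfamily", sort=True):
        ic = grp["intron_count"].to_numpy(dtype=float)
        rows.append({
            "subfamily": sub,
            "n": len(ic),
            "intron_min": int(ic.min()),
            "intron_max": int(ic.max()),
            "variance": float(np.var(ic)),  # population variance
            "n_intronless": int((ic == 0).sum()),
            "pct_intronless": round_half_up(100.0 * (ic == 0).mean(), 2),
        })
    per_subfamily = pd.DataFrame(rows)
    total = len(catalog)
    n_le = int((counts <= low_intron_cutoff).sum())
    global_stats = {
        "n_genes": total,
        "n_le_cutoff": n_le,
        "pct_le_cutoff": round_half_up(100.0 * n_le / total, 1),
        "n_intronless": int((counts == 0).sum()),
        "mean_introns": float(counts.mean()),
    }
    return per_subfamily, global_stats


def membrane_secretion_summary(catalog: pd.DataFrame):
    """Cross-tab of transmembrane helices and signal peptides, plus the
    multi-kinase-domain tally.

    Returns (totals dict, per_family DataFrame). Totals cover n_TM (>=1
    helix), n_SP, n_SP_and_TM, n_SP_without_TM and n_multidomain (genes
    with >= 2 kinase domains); the per-family table breaks n_TM and n_SP
    down by family.
    """
    has_tm = catalog["n_tm_helices"] >= 1
    has_sp = catalog["has_signal_peptide"].astype(bool)
    totals = {
        "n_genes": len(catalog),
        "n_TM": int(has_tm.sum()),
        "n_SP": int(has_sp.sum()),
        "n_SP_and_TM": int((has_sp & has_tm).sum()),
        "n_SP_without_TM": int((has_sp & ~has_tm).sum()),
        "n_multidomain": int((catalog["n_kinase_domains"] >= 2).sum()),
    }
    per_family = (
        pd.DataFrame({
            "family": catalog["family"],
            "has_TM": has_tm.astype(int),
            "has_SP": has_sp.astype(int),
        })
        .groupby("family", sort=True)
        .agg(n=("has_TM", "size"), n_TM=("has_TM", "sum"), n_SP=("has_SP", "sum"))
        .reset_index()
    )
    return totals, per_family
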
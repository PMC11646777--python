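"""Readers and writers for every table the pipeline touches.

All tables are tab-separated text with a header row. Missing numeric values
are encoded as an empty field or the literal ``NA`` (the convention of
DESeq2 result exports, which set p-values to NA for low-count genes).
Readers validate domains strictly and raise :class:`FormatError` /
:class:`ValidationError` rather than silently coercing bad values; rows with
unparseable numerics are kept with the value set to missing and reported
through the package logger.

Table layouts
-------------
contrast stats   gene_id, contrast_id, log2fc, p_value [, p_adj]
contrast meta    contrast_id, project_id, stress_group, tissue
expression       gene_id, <tissue 1>, <tissue 2>, ...   (non-negative TPM)
duplication      gene_a, gene_b, dup_class, ka, ks
kinome catalog   gene_id, family, subfamily, chromosome, intron_count,
                 n_kinase_domains, n_tm_helices, has_signal_peptide [, mw, pi]
"""

from __future__ import annotations

import os
from typing import Mapping

import gffutils
import numpy as np
import pandas as pd
import yaml

from ._util import FormatError, ValidationError, logger

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}

DUP_CLASSES = ("WGD", "tandem", "proximal", "dispersed", "singleton")

#: Duplication classes that describe a *pair* of distinct genes (a singleton
#: record carries no partner, so gene_a == gene_b is tolerated there).
PAIR_CLASSES = frozenset(DUP_CLASSES) - {"singleton"}


# ---------------------------------------------------------------------------
# low-level helpers

def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _parse_numeric(series: pd.Series, name: str, path) -> pd.Series:
    """Parse a string column to float, treating MISSING_TOKENS as NaN.

    Unparseable entries become NaN but are reported, never dropped.
    """
    s = series.fillna("").astype(str).str.strip()
    is_missing = s.isin(MISSING_TOKENS)
    parsed = pd.to_numeric(s.where(~is_missing, other=np.nan), errors="coerce")
    bad = ~is_missing & parsed.isna()
    if bad.any():
        rows = list(series.index[bad][:5])
        logger.warning(
            "%s: column %s has %d unparseable value(s) (rows %s); kept as missing",
            path, name, int(bad.sum()), rows,
        )
    return parsed


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# contrast-level DE statistics

def read_contrast_stats(path) -> pd.DataFrame:
    """Read per-gene, per-contrast differential-expression statistics.

    Returns a DataFrame with columns gene_id, contrast_id, log2fc, p_value
    (floats, NaN for missing) and, when present in the file, p_adj.
    """
    df = _read_tsv(path)
    _require_columns(df, ("gene_id", "contrast_id", "log2fc", "p_value"), path)
    out = pd.DataFrame({
        "gene_id": df["gene_id"].astype(str),
        "contrast_id": df["contrast_id"].astype(str),
        "log2fc": _parse_numeric(df["log2fc"], "log2fc", path),
        "p_value": _parse_numeric(df["p_value"], "p_value", path),
    })
    if "p_adj" in df.columns:
        out["p_adj"] = _parse_numeric(df["p_adj"], "p_adj", path)

    for col in ("p_value", "p_adj"):
        if col in out.columns:
            bad = out[col].dropna()
            bad = bad[(bad < 0) | (bad > 1)]
            if not bad.empty:
                i = bad.index[0]
                raise ValidationError(
                    f"{path}: {col} outside [0,1] for gene "
                    f"{out.at[i, 'gene_id']!r} in contrast {out.at[i, 'contrast_id']!r}"
                    f" (value {bad.iloc[0]})"
                )
    dup = out.duplicated(subset=["gene_id", "contrast_id"])
    if dup.any():
        i = out.index[dup][0]
        raise ValidationError(
            f"{path}: duplicate (gene, contrast) pair "
            f"({out.at[i, 'gene_id']!r}, {out.at[i, 'contrast_id']!r})"
        )
    return out


def read_contrast_meta(path) -> pd.DataFrame:
    """Read contrast metadata mapping each contrast to project, stress group
    and tissue."""
    df = _read_tsv(path)
    _require_columns(df, ("contrast_id", "project_id", "stress_group", "tissue"), path)
    out = df[["contrast_id", "project_id", "stress_group", "tissue"]].astype(str)
    dup = out["contrast_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate contrast_id {out['contrast_id'][dup].iloc[0]!r}"
        )
    if (out["stress_group"].str.strip() == "").any():
        raise ValidationError(f"{path}: empty stress_group")
    if out.empty:
        logger.warning("%s: contrast metadata table is empty", path)
    else:
        logger.info("%s: stress groups %s", path, sorted(out["stress_group"].unique()))
    return out


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a gene x tissue TPM matrix (first column gene_id, one column per
    tissue). Returns a DataFrame indexed by gene_id."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 3:
        raise FormatError(f"{path}: need a gene_id column and at least 2 tissues")
    tissues = header[1:]
    seen = set()
    for t in tissues:
        if t in seen:
            raise ValidationError(f"{path}: duplicate tissue column {t!r}")
        seen.add(t)

    df = _read_tsv(path)
    gene_col = header[0]
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        raise ValidationError(
            f"{path}: duplicate gene_id {genes[genes.duplicated()].iloc[0]!r}"
        )
    mat = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for t in tissues:
        mat[t] = _parse_numeric(df[t], t, path).to_numpy()
    if mat.isna().any().any():
        g, t = np.argwhere(mat.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing expression value at ({mat.index[g]!r}, {mat.columns[t]!r})"
        )
    neg = mat.to_numpy() < 0
    if neg.any():
        g, t = np.argwhere(neg)[0]
        raise ValidationError(
            f"{path}: negative TPM at ({mat.index[g]!r}, {mat.columns[t]!r})"
        )
    return mat


def read_duplication_pairs(path) -> pd.DataFrame:
    """Read homologous gene pairs with duplication class and Ka/Ks values."""
    df = _read_tsv(path)
    _require_columns(df, ("gene_a", "gene_b", "dup_class", "ka", "ks"), path)
    out = pd.DataFrame({
        "gene_a": df["gene_a"].astype(str),
        "gene_b": df["gene_b"].astype(str),
        "dup_class": df["dup_class"].astype(str),
        "ka": _parse_numeric(df["ka"], "ka", path),
        "ks": _parse_numeric(df["ks"], "ks", path),
    })
    unknown = ~out["dup_class"].isin(DUP_CLASSES)
    if unknown.any():
        raise ValidationError(
            f"{path}: unknown dup_class {out['dup_class'][unknown].iloc[0]!r}"
            f" (expected one of {', '.join(DUP_CLASSES)})"
        )
    for col in ("ka", "ks"):
        neg = out[col].dropna()
        neg = neg[neg < 0]
        if not neg.empty:
            raise ValidationError(f"{path}: negative {col} ({neg.iloc[0]}) in row {neg.index[0]}")
    self_pair = out["dup_class"].isin(PAIR_CLASSES) & (out["gene_a"] == out["gene_b"])
    if self_pair.any():
        raise ValidationError(
            f"{path}: gene paired with itself ({out['gene_a'][self_pair].iloc[0]!r})"
        )
    return out


_BOOL_TOKENS = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def read_kinome_catalog(path) -> pd.DataFrame:
    """Read a per-gene kinome catalog (family/subfamily labels, chromosome,
    intron count, kinase-domain count, transmembrane helices, signal peptide,
    optional molecular weight in kDa and isoelectric point)."""
    df = _read_tsv(path)
    required = ("gene_id", "family", "subfamily", "chromosome", "intron_count",
                "n_kinase_domains", "n_tm_helices", "has_signal_peptide")
    _require_columns(df, required, path)
    out = pd.DataFrame({
        "gene_id": df["gene_id"].astype(str),
        "family": df["family"].astype(str),
        "subfamily": df["subfamily"].astype(str),
        "chromosome": df["chromosome"].astype(str),
    })
    for col, low in (("intron_count", 0), ("n_kinase_domains", 1), ("n_tm_helices", 0)):
        vals = _parse_numeric(df[col], col, path)
        if vals.isna().any():
            raise ValidationError(f"{path}: missing {col} for gene "
                                  f"{out['gene_id'][vals.isna()].iloc[0]!r}")
        if (vals < low).any():
            raise ValidationError(f"{path}: {col} below {low}")
        out[col] = vals.astype(int)
    sp = df["has_signal_peptide"].str.strip().str.lower().map(_BOOL_TOKENS)
    if sp.isna().any():
        raise ValidationError(f"{path}: unparseable has_signal_peptide value "
                              f"{df['has_signal_peptide'][sp.isna()].iloc[0]!r}")
    out["has_signal_peptide"] = sp.astype(bool)
    for col in ("mw", "pi"):
        if col in df.columns:
            out[col] = _parse_numeric(df[col], col, path)
    if out["gene_id"].duplicated().any():
        raise ValidationError(
            f"{path}: duplicate gene_id {out['gene_id'][out['gene_id'].duplicated()].iloc[0]!r}"
        )
    return out


# ---------------------------------------------------------------------------
# GFF3 intron counting

TRANSCRIPT_RULES = ("longest_mrna", "longest_cds", "first")


def count_introns_from_gff3(path, transcript_rule: str = "longest_mrna") -> dict[str, int]:
    """Count introns per gene from a GFF3 annotation.

    The intron count of a gene is the exon count of its representative
    transcript minus one. The representative transcript is chosen by
    ``transcript_rule``:

    - ``longest_mrna``: the mRNA with the most exons (ties broken by
      lexicographically smallest transcript id);
    - ``longest_cds``: the mRNA with the largest summed CDS length
      (same tie-break);
    - ``first``: the mRNA with the smallest start coordinate (same tie-break).
    """
    if transcript_rule not in TRANSCRIPT_RULES:
        raise ValueError(f"unknown transcript_rule {transcript_rule!r}; "
                         f"expected one of {TRANSCRIPT_RULES}")
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    counts: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = list(db.children(mrna, featuretype="exon"))
            if not exons:
                raise ValidationError(f"mRNA {mrna.id!r} has no exon children")
            if transcript_rule == "longest_mrna":
                key = (-len(exons), mrna.id)
            elif transcript_rule == "longest_cds":
                cds_len = sum(c.end - c.start + 1
                              for c in db.children(mrna, featuretype="CDS"))
                key = (-cds_len, mrna.id)
            else:  # first
                key = (mrna.start, mrna.id)
            candidates.append((key, len(exons)))
        if candidates:
            _, n_exons = min(candidates)
            counts[gene.id] = n_exons - 1
    return counts


# ---------------------------------------------------------------------------
# writers

def _write_sorted(df: pd.DataFrame, path, sort_by: str) -> None:
    # sorted output makes two writes of the same table byte-identical
    df.sort_values(sort_by, kind="mergesort").to_csv(path, sep="\t", index=False)


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a per-gene score table (see :func:`kinscore.scoring.compute_scores`)
    as TSV, ordered by gene_id for byte-stable output."""
    _write_sorted(scores.reset_index(), path, "gene_id")


def read_score_table(path) -> pd.DataFrame:
    """Read back a score table written by :func:`write_score_table`."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("gene_id", "T", "TFC", "AT", "ATFC"), path)
    return df.set_index("gene_id")


def write_selection_report(provenance: pd.DataFrame, path) -> None:
    """Write the top-k union selection (gene, methods, n_methods) as TSV."""
    _write_sorted(provenance, path, "gene_id")


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.sort_index().to_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write any plain table deterministically (row order as given)."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: Mapping[str, float] = {
    "fc_threshold": 2.0,
    "p_threshold": 0.05,
    "k": 30,
    "tau_threshold": 0.8,
    "clock_rate": 8.25e-9,
    "ks_min": 0.2,
    "ks_max": 2.0,
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Load a flat YAML key-value config, overlaying the package defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None and os.path.exists(path):
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a flat mapping")
        cfg.update(user)
    return cfg
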
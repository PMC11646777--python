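import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_stats():
    """One gene flagged in both cold contrasts and one of four salt contrasts."""
    return pd.DataFrame({
        "gene_id": ["g1", "g1", "g1"],
        "contrast_id": ["cold_c0", "cold_c1", "salt_c0"],
        "log2fc": [1.5, 2.5, 3.0],
        "p_value": [0.01, 0.02, 0.001],
    })


@pytest.fixture
def small_meta():
    return pd.DataFrame({
        "contrast_id": ["cold_c0", "cold_c1", "salt_c0", "salt_c1", "salt_c2", "salt_c3"],
        "project_id": ["pA", "pA", "pB", "pB", "pB", "pB"],
        "stress_group": ["cold", "cold", "salt", "salt", "salt", "salt"],
        "tissue": ["leaf"] * 6,
    })


@pytest.fixture
def random_study():
    """A randomized 200-gene x 30-contrast instance for oracle comparisons."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(200)]
    groups = ["cold", "heat", "salt", "drought", "flooding"]
    contrasts, group_of = [], []
    for g in groups:
        for j in range(6):
            contrasts.append(f"{g}_c{j}")
            group_of.append(g)
    meta = pd.DataFrame({
        "contrast_id": contrasts,
        "project_id": [c.split("_")[0] + "_p0" for c in contrasts],
        "stress_group": group_of,
        "tissue": ["leaf"] * len(contrasts),
    })
    rows = []
    for g in genes:
        for c in contrasts:
            if rng.random() < 0.2:
                continue  # gene absent from this contrast
            rows.append({
                "gene_id": g,
                "contrast_id": c,
                "log2fc": rng.normal(0, 2),
                "p_value": rng.random(),
            })
    return pd.DataFrame(rows), meta


@pytest.fixture
def gff3_file(tmp_path):
    """Hand-written annotation: geneA has one 4-exon mRNA, geneB is
    single-exon, geneC has a 3-exon and a 6-exon mRNA."""
    text = """##gff-version 3
chr1\ttest\tgene\t1\t10000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t1\t10000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\texon\t1\t1000\t.\t+\t.\tParent=geneA.t1
chr1\ttest\texon\t2000\t3000\t.\t+\t.\tParent=geneA.t1
chr1\ttest\texon\t4000\t5000\t.\t+\t.\tParent=geneA.t1
chr1\ttest\texon\t6000\t10000\t.\t+\t.\tParent=geneA.t1
chr1\ttest\tgene\t20000\t21000\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t20000\t21000\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\ttest\texon\t20000\t21000\t.\t-\t.\tParent=geneB.t1
chr2\ttest\tgene\t1\t9000\t.\t+\t.\tID=geneC
chr2\ttest\tmRNA\t1\t8000\t.\t+\t.\tID=geneC.t1;Parent=geneC
chr2\ttest\texon\t1\t1000\t.\t+\t.\tParent=geneC.t1
chr2\ttest\texon\t2000\t3000\t.\t+\t.\tParent=geneC.t1
chr2\ttest\texon\t4000\t8000\t.\t+\t.\tParent=geneC.t1
chr2\ttest\tmRNA\t1\t9000\t.\t+\t.\tID=geneC.t2;Parent=geneC
chr2\ttest\texon\t1\t500\t.\t+\t.\tParent=geneC.t2
chr2\ttest\texon\t1000\t1500\t.\t+\t.\tParent=geneC.t2
chr2\ttest\texon\t2000\t2500\t.\t+\t.\tParent=geneC.t2
chr2\ttest\texon\t3000\t3500\t.\t+\t.\tParent=geneC.t2
chr2\ttest\texon\t4000\t4500\t.\t+\t.\tParent=geneC.t2
chr2\ttest\texon\t5000\t9000\t.\t+\t.\tParent=geneC.t2
"""
    path = tmp_path / "test.gff3"
    path.write_text(text)
    return path


def make_catalog(spec_rows):
    """Build a kinome catalog from (family, subfamily, n, intron_count) rows."""
    frames = []
    idx = 0
    for family, subfamily, n, introns in spec_rows:
        frames.append(pd.DataFrame({
            "gene_id": [f"k{idx + i:05d}" for i in range(n)],
            "family": family,
            "subfamily": subfamily,
            "chromosome": "chr1",
            "intron_count": introns,
            "n_kinase_domains": 1,
            "n_tm_helices": 0,
            "has_signal_peptide": False,
        }))
        idx += n
    return pd.concat(frames, ignore_index=True)
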
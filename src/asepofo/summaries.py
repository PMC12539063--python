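"""Plot-ready summary tables: gene-level and SNP-level paternal frequencies.

The gene-level paternal allele frequency per sample is the pooled ratio —
paternal and total counts are summed over a gene's exonic SNPs before
dividing — not the mean of per-SNP ratios, so deep SNPs carry their weight.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel

GENE_SUMMARY_COLUMNS = (
    "gene_id",
    "sample_id",
    "paternal_sum",
    "total_sum",
    "gene_paternal_freq",
    "n_snps",
)


def gene_level_paternal_frequency(
    sites: pd.DataFrame, combine_strands: bool = True
) -> pd.DataFrame:
    """Pooled per-(gene, sample) paternal allele frequency over phased SNPs."""
    rows = sites[sites["paternal_allele"].isin(["ref", "alt"])]
    if rows.empty:
        return pd.DataFrame(columns=list(GENE_SUMMARY_COLUMNS))
    if combine_strands:
        rows = rows.groupby(
            ["gene_id", "sample_id", "contig", "position"], as_index=False
        )[["paternal_count", "total_count"]].sum()
    grouped = rows.groupby(["gene_id", "sample_id"], as_index=False).agg(
        paternal_sum=("paternal_count", "sum"),
        total_sum=("total_count", "sum"),
        n_snps=("position", "nunique"),
    )
    grouped["gene_paternal_freq"] = grouped["paternal_sum"] / grouped["total_sum"]
    grouped["paternal_sum"] = grouped["paternal_sum"].astype(int)
    grouped["total_sum"] = grouped["total_sum"].astype(int)
    return grouped[list(GENE_SUMMARY_COLUMNS)]


def snp_plot_data(
    gene_id: str,
    sites: pd.DataFrame,
    gene_model: GeneModel,
    highlight_sample: str | None = None,
) -> dict:
    """Per-SNP frequencies plus merged-exon boundaries for one gene's plot.

    Returns a dict with ``snps`` (position, sample, paternal_freq rows),
    ``exon_boundaries`` (1-based start/end per merged exon), and, when a
    highlight sample is given, its SNP count and median paternal frequency.
    """
    sub = sites[(sites["gene_id"] == gene_id) & sites["paternal_allele"].isin(["ref", "alt"])]
    if gene_model.gene_id != gene_id:
        raise KeyError(f"gene model mismatch: {gene_model.gene_id} != {gene_id}")
    snps = sub[["sample_id", "position", "paternal_freq"]].sort_values(
        ["position", "sample_id"]
    ).reset_index(drop=True)
    boundaries = [coord for s, e in gene_model.merged_exons for coord in (s + 1, e)]
    out = {
        "gene_id": gene_id,
        "snps": snps,
        "exon_boundaries": boundaries,
        "strand": gene_model.strand,
    }
    if highlight_sample is not None:
        hs = snps[snps["sample_id"] == highlight_sample]
        out["highlight_sample"] = highlight_sample
        out["highlight_snp_count"] = int(len(hs))
        out["highlight_median_freq"] = (
            float(hs["paternal_freq"].median()) if len(hs) else float("nan")
        )
    return out


def contamination_matrix(gene_contam: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-(sample, gene) maternal contamination into a matrix."""
    if gene_contam.empty:
        return pd.DataFrame()
    return gene_contam.pivot_table(
        index="gene_id", columns="sample_id", values="est", aggfunc="first"
    )


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def plot_gene_snps(plot_data: dict, path: str | Path) -> None:
    """Optional scatter of per-SNP paternal frequencies with exon boundaries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    snps = plot_data["snps"]
    ax.scatter(snps["position"], snps["paternal_freq"], s=12, alpha=0.6)
    for b in plot_data["exon_boundaries"]:
        ax.axvline(b, color="grey", lw=0.5)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("position")
    ax.set_ylabel("paternal allele frequency")
    ax.set_title(plot_data["gene_id"])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
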
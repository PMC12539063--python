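"""Cross-contamination estimates from homozygous and reference sites.

Reads carrying the allele a homozygous genotype cannot produce must come
from another sample (contamination or mislabeling) or from sequencing
error.  Per sample we average the non-alternative-allele frequency over
hom-alt sites and the non-reference-allele frequency over hom-ref sites.
For maternal-contamination settings (e.g. placental tissue), the
non-reference frequency at offspring hom-ref sites where the mother
carries a non-reference genotype is additionally averaged per gene.

All estimates are unweighted means of per-site frequencies (not pooled
count ratios), so one very deep site cannot dominate.  Strands are pooled
per site first: contamination is not strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_SITES = 5

_SITE_KEY = ["sample_id", "contig", "position"]


@dataclass
class ContaminationEstimate:
    sample_id: str
    est_homalt: float | None
    est_ref: float | None
    n_sites_homalt: int
    n_sites_ref: int

    @property
    def max_defined(self) -> float | None:
        vals = [v for v in (self.est_homalt, self.est_ref) if v is not None]
        return max(vals) if vals else None


def site_opposite_freq(
    ref_count: int, alt_count: int, other_bases: int, gclass: str, min_depth: int = DEFAULT_MIN_DEPTH
) -> float | None:
    """Fraction of reads at a homozygous site not matching the genotype.

    other_bases join both numerator and denominator: contaminant reads need
    not carry the on-panel alternate base.  Returns None below min_depth.
    """
    if gclass not in ("hom_ref", "hom_alt"):
        raise ValueError(f"site_opposite_freq requires a homozygous site, got {gclass!r}")
    denom = ref_count + alt_count + other_bases
    if denom < min_depth:
        return None
    if gclass == "hom_alt":
        return (ref_count + other_bases) / denom
    return (alt_count + other_bases) / denom


def _pool_strands(sites: pd.DataFrame) -> pd.DataFrame:
    pooled = (
        sites.groupby(_SITE_KEY + ["gclass"], as_index=False)[
            ["ref_count", "alt_count", "other_bases"]
        ].sum()
    )
    return pooled


def sample_contamination(
    sites: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Per-sample contamination from hom-alt and hom-ref sites.

    ``sites`` needs unified count columns plus ``gclass``.  An estimate is
    defined only when at least ``min_sites`` sites pass ``min_depth``;
    otherwise it is NaN ("when measurable").
    """
    hom = sites[sites["gclass"].isin(["hom_ref", "hom_alt"])]
    pooled = _pool_strands(hom)
    denom = pooled["ref_count"] + pooled["alt_count"] + pooled["other_bases"]
    opp = np.where(
        pooled["gclass"] == "hom_alt",
        pooled["ref_count"] + pooled["other_bases"],
        pooled["alt_count"] + pooled["other_bases"],
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.divide(opp, denom, out=np.full(len(pooled), np.nan), where=denom > 0)
    pooled = pooled.assign(opposite_freq=np.where(denom >= min_depth, freq, np.nan))

    rows = []
    for sample_id in sorted(sites["sample_id"].unique()):
        sub = pooled[pooled["sample_id"] == sample_id]
        out = {"sample_id": sample_id}
        for gclass, est_col, n_col in (
            ("hom_alt", "est_homalt", "n_sites_homalt"),
            ("hom_ref", "est_ref", "n_sites_ref"),
        ):
            vals = sub.loc[sub["gclass"] == gclass, "opposite_freq"].dropna()
            out[n_col] = len(vals)
            out[est_col] = float(vals.mean()) if len(vals) >= min_sites else np.nan
        rows.append(out)
    return pd.DataFrame(
        rows, columns=["sample_id", "est_homalt", "est_ref", "n_sites_homalt", "n_sites_ref"]
    )


def gene_maternal_contamination(
    sites: pd.DataFrame,
    maternal_genotypes: pd.DataFrame,
    min_depth: int = 0,
) -> pd.DataFrame:
    """Per-(sample, gene) maternal contamination estimate.

    Uses offspring hom-ref sites inside the gene's union exons where the
    mother carries a non-reference genotype (het or hom-alt); the non-
    reference reads there are attributed to maternal tissue.  Samples
    without a maternal VCF simply contribute no rows.
    """
    if maternal_genotypes is None or maternal_genotypes.empty:
        return pd.DataFrame(columns=["sample_id", "gene_id", "est", "n_sites"])
    qualifying_mom = maternal_genotypes[
        maternal_genotypes["gclass"].isin(["het", "hom_alt"])
    ][["sample_id", "contig", "position"]]
    sub = sites[(sites["gclass"] == "hom_ref") & sites["gene_id"].notna()]
    sub = sub.merge(qualifying_mom, on=_SITE_KEY, how="inner")
    if sub.empty:
        return pd.DataFrame(columns=["sample_id", "gene_id", "est", "n_sites"])
    pooled = (
        sub.groupby(["sample_id", "gene_id", "contig", "position"], as_index=False)[
            ["ref_count", "alt_count", "other_bases"]
        ].sum()
    )
    denom = pooled["ref_count"] + pooled["alt_count"] + pooled["other_bases"]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (pooled["alt_count"] + pooled["other_bases"]) / denom
    pooled["nonref_freq"] = freq.where(denom >= max(min_depth, 1))
    grouped = pooled.dropna(subset=["nonref_freq"]).groupby(
        ["sample_id", "gene_id"], as_index=False
    )
    out = grouped.agg(est=("nonref_freq", "mean"), n_sites=("nonref_freq", "size"))
    return out[["sample_id", "gene_id", "est", "n_sites"]]


def estimates_to_frame(estimates: list[ContaminationEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "est_homalt": np.nan if e.est_homalt is None else e.est_homalt,
                "est_ref": np.nan if e.est_ref is None else e.est_ref,
                "n_sites_homalt": e.n_sites_homalt,
                "n_sites_ref": e.n_sites_ref,
            }
            for e in estimates
        ]
    )
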
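"""Union-exon gene models and SNP annotation.

Every isoform's exons are merged per gene into a union exon set: maximal
sorted, non-overlapping, non-adjacent intervals in 0-based half-open
coordinates.  SNP count records are joined to every gene whose union exons
contain them, then phased genotypes assign each heterozygous site's counts
to the paternal and maternal alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

ANNOT_COLUMNS = (
    "gene_id",
    "symbol",
    "gene_type",
    "exon_index",
)

PHASE_CONVENTIONS = ("first_is_paternal", "first_is_maternal")


class GtfFormatError(ValueError):
    pass


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals, joining overlapping and book-ended runs.

    Book-ended intervals ([100, 200) + [200, 300)) describe contiguous
    transcribed sequence and collapse into one.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if end <= start:
            raise GtfFormatError(f"empty or inverted interval [{start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class GeneModel:
    """A gene with its merged union-exon interval set (0-based half-open)."""

    gene_id: str
    symbol: str
    gene_type: str
    contig: str
    strand: str  # '+' or '-'
    merged_exons: list[tuple[int, int]]

    @property
    def n_bases(self) -> int:
        return sum(e - s for s, e in self.merged_exons)

    def contains(self, position_1based: int) -> int | None:
        """Return the exon index covering a 1-based position, or None."""
        p = position_1based - 1
        for i, (s, e) in enumerate(self.merged_exons):
            if s <= p < e:
                return i
        return None


def build_union_exons(gtf: str | Path) -> dict[str, GeneModel]:
    """Read exon features from a GTF and build per-gene union exon models.

    Accepts Ensembl/GENCODE attribute dialects (gene_name or absent symbol,
    gene_type or gene_biotype).  Genes with exons on more than one contig are
    skipped with a warning.
    """
    import pyranges as pr

    df = pr.read_gtf(str(gtf)).df
    if df.empty:
        return {}
    df = df[df["Feature"] == "exon"]
    if "gene_id" not in df.columns:
        raise GtfFormatError(f"{gtf}: exon features lack gene_id attribute")
    if (df["End"] <= df["Start"]).any():
        bad = df[df["End"] <= df["Start"]].iloc[0]
        raise GtfFormatError(
            f"{gtf}: exon with end <= start at {bad['Chromosome']}:{bad['Start']}"
        )
    symbol_col = "gene_name" if "gene_name" in df.columns else None
    type_col = next((c for c in ("gene_type", "gene_biotype") if c in df.columns), None)

    genes: dict[str, GeneModel] = {}
    for gene_id, sub in df.groupby("gene_id", sort=True):
        contigs = sub["Chromosome"].unique()
        if len(contigs) > 1:
            logger.warning("gene %s spans contigs %s; skipped", gene_id, list(contigs))
            continue
        strand = str(sub["Strand"].iloc[0]) if "Strand" in sub.columns else "+"
        genes[str(gene_id)] = GeneModel(
            gene_id=str(gene_id),
            symbol=str(sub[symbol_col].iloc[0]) if symbol_col else str(gene_id),
            gene_type=str(sub[type_col].iloc[0]) if type_col else "unknown",
            contig=str(contigs[0]),
            strand=strand,
            merged_exons=merge_intervals(zip(sub["Start"], sub["End"])),
        )
    return genes


def _exon_trees(genes: dict[str, GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes.values():
        tree = trees.setdefault(g.contig, IntervalTree())
        for i, (s, e) in enumerate(g.merged_exons):
            tree[s:e] = (g.gene_id, i)
    return trees


def assign_snps_to_genes(
    records: pd.DataFrame,
    genes: dict[str, GeneModel],
    strand_specific: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join count records to every gene whose union exons contain them.

    Returns ``(annotated, unassigned)``: one annotated row per
    (record, gene) pair, and a side table of records matching no gene so
    nothing is silently dropped.  With ``strand_specific`` a record only
    joins genes on its own strand ('forward' ~ '+', 'reverse' ~ '-').
    """
    trees = _exon_trees(genes)
    strand_of = {"forward": "+", "reverse": "-"}
    hits: list[dict] = []
    matched = np.zeros(len(records), dtype=bool)
    for pos_idx, row in enumerate(records.itertuples(index=False)):
        tree = trees.get(row.contig)
        if tree is None:
            continue
        for iv in tree[row.position - 1]:
            gene_id, exon_index = iv.data
            gene = genes[gene_id]
            if strand_specific:
                rec_strand = strand_of.get(row.strand_label)
                if rec_strand is not None and rec_strand != gene.strand:
                    continue
            hit = row._asdict()
            hit.update(
                gene_id=gene.gene_id,
                symbol=gene.symbol,
                gene_type=gene.gene_type,
                exon_index=exon_index,
            )
            hits.append(hit)
            matched[pos_idx] = True
    columns = list(records.columns) + list(ANNOT_COLUMNS)
    annotated = pd.DataFrame(hits, columns=columns)
    unassigned = records.loc[~matched].reset_index(drop=True)
    return annotated, unassigned


def attach_genotypes(annotated: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Left-join per-sample genotype class and phase onto annotated sites."""
    out = annotated.merge(
        genotypes[["sample_id", "contig", "position", "gclass", "phased", "first_allele"]],
        on=["sample_id", "contig", "position"],
        how="left",
    )
    out["gclass"] = out["gclass"].fillna("unknown")
    out["phased"] = out["phased"].fillna(False).astype(bool)
    return out


def assign_parental_alleles(
    sites: pd.DataFrame, convention: str = "first_is_paternal"
) -> pd.DataFrame:
    """Assign paternal/maternal counts at phased heterozygous sites.

    The phase convention decides whether the first phased allele (the left
    side of ``a|b``) is the paternal or the maternal haplotype; pedigree
    phasing tools differ, so this is explicit.  Unphased or non-het rows get
    paternal_allele='unknown' and NaN parental counts.
    """
    if convention not in PHASE_CONVENTIONS:
        raise ValueError(f"convention must be one of {PHASE_CONVENTIONS}")
    out = sites.copy()
    phased_het = (out["gclass"] == "het") & out["phased"] & out["first_allele"].notna()
    first = out["first_allele"].where(phased_het)
    if convention == "first_is_paternal":
        paternal = first
    else:
        paternal = first.map({"ref": "alt", "alt": "ref"})
    out["paternal_allele"] = paternal.fillna("unknown")

    pat_is_ref = out["paternal_allele"] == "ref"
    pat_is_alt = out["paternal_allele"] == "alt"
    out["paternal_count"] = np.select(
        [pat_is_ref, pat_is_alt], [out["ref_count"], out["alt_count"]], default=np.nan
    )
    out["maternal_count"] = np.select(
        [pat_is_ref, pat_is_alt], [out["alt_count"], out["ref_count"]], default=np.nan
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = out["paternal_count"] / out["total_count"]
    out["paternal_freq"] = freq.where(out["total_count"] > 0)
    return out


def annotate(
    records: pd.DataFrame,
    genes: dict[str, GeneModel],
    genotypes: pd.DataFrame,
    strand_specific: bool = False,
    convention: str = "first_is_paternal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full annotation stage: gene join, genotype join, parental assignment."""
    annotated, unassigned = assign_snps_to_genes(records, genes, strand_specific)
    annotated = attach_genotypes(annotated, genotypes)
    annotated = assign_parental_alleles(annotated, convention)
    return annotated, unassigned


def write_merged_exon_bed(genes: dict[str, GeneModel], path: str | Path) -> None:
    """Write the union exon set as BED (0-based half-open) for plotting."""
    rows = []
    for g in sorted(genes.values(), key=lambda g: (g.contig, g.merged_exons[0][0])):
        for i, (s, e) in enumerate(g.merged_exons):
            rows.append((g.contig, s, e, f"{g.gene_id}_exon{i}", 0, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
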
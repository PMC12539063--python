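"""Synthetic allele-specific expression datasets with known ground truth.

The generator emits exactly the inputs the ingestion layer consumes —
ASEReadCounter-format count tables per sample and strand, per-sample phased
VCFs, maternal VCFs, a GTF of synthetic genes, and a sample sheet — plus a
truth record (per-gene PofO effects, per-SNP genetic effects, per-subject
random effects, contamination fraction, phase orientations) so every
downstream stage can be validated against known parameters.

Mean structure per heterozygous (subject i, SNP j):

    E[Y_paternal] = exp(mu0 + d_j + e_i + po/2 + b_j * x_pat)
    E[Y_maternal] = exp(mu0 + d_j + e_i - po/2 + b_j * x_mat)

with x = +1/2 for the ref and -1/2 for the alt allele, d_j a per-SNP
log-normal depth offset, e_i a subject-level random effect shared by all of
a subject's rows (the within-cluster correlation the sandwich must absorb),
and b_j a per-SNP genetic-ASE effect.  Counts are Poisson or negative
binomial.  Homozygous sites inside gene exons carry only the genotype's
allele until contamination is injected: a Binomial(total, c) subset of each
site's reads is re-labelled according to the contaminant (maternal)
genotype, conserving totals.

Defaults put the median total depth near 50 per SNP, comfortably above the
10-read retention rule.  All output is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .count_io import ASE_COLUMNS

CONTIG = "chr1"
CONTIG_LEN = 200_000_000
REF_BASE = "A"
ALT_BASE = "G"

_EXONS_PER_GENE = 3
_EXON_LEN = 600
_INTRON_LEN = 200
_GENE_SPACING = 100_000
_GENE_OFFSET = 10_000


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_subjects: int = 20
    n_genes: int = 5
    snps_per_gene: int = 4
    het_prob: float = 0.5
    phase_orientation_prob: float = 0.5  # P(paternal allele is ref)
    baseline_log_mean: float = math.log(25.0)  # per-allele; total ~ 50
    subject_sd: float = 0.3
    genetic_sd: float = 0.5
    po_true: float | list[float] = 0.0
    dispersion: str = "poisson"  # 'poisson' | 'negbin'
    theta: float = 10.0  # negbin size; larger -> closer to Poisson
    contamination: float = 0.0
    n_hom_sites: int = 200
    depth_sd: float = 0.4
    maternal_alt_prob: float = 0.5  # P(mother hom_alt | offspring hom_ref)
    stranded: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_prob", "phase_orientation_prob", "contamination", "maternal_alt_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("subject_sd", "genetic_sd", "depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion not in ("poisson", "negbin"):
            raise ValueError("dispersion must be 'poisson' or 'negbin'")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    def po_for_gene(self, g: int) -> float:
        if isinstance(self.po_true, (list, tuple, np.ndarray)):
            return float(self.po_true[g])
        return float(self.po_true)


@dataclass
class SimTruth:
    """Ground-truth parameters emitted alongside a simulated dataset."""

    po_true: dict[str, float]
    genetic_effects: dict[str, list[float]]
    subject_effects: dict[str, float]
    contamination: float
    phase_orientation: dict[str, str]  # "sample|gene|position" -> "ref"/"alt"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    outdir: Path
    sheet_path: Path
    gtf_path: Path
    truth_path: Path
    truth: SimTruth
    sample_ids: list[str]


def gene_exons(g: int) -> list[tuple[int, int]]:
    """Union exons of synthetic gene ``g`` (0-based half-open)."""
    start = _GENE_OFFSET + g * _GENE_SPACING
    return [
        (start + i * (_EXON_LEN + _INTRON_LEN), start + i * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN)
        for i in range(_EXONS_PER_GENE)
    ]


def gene_strand(g: int) -> str:
    return "+" if g % 2 == 0 else "-"


def _exonic_positions(g: int, n: int, phase: int) -> list[int]:
    """n distinct 1-based exonic positions; phase offsets het vs hom panels."""
    exons = gene_exons(g)
    bases: list[int] = []
    for s, e in exons:
        bases.extend(range(s, e))
    step = max(len(bases) // (n + 1), 1)
    return [bases[(i + 1) * step + phase] + 1 for i in range(n)]


def _draw_counts(rng: np.random.Generator, mean: float, cfg: SimConfig) -> int:
    if cfg.dispersion == "poisson":
        return int(rng.poisson(mean))
    p = cfg.theta / (cfg.theta + mean)
    return int(rng.negative_binomial(cfg.theta, p))


def simulate_gene_sites(
    cfg: SimConfig,
    rng: np.random.Generator,
    gene_index: int = 0,
    subject_effects: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Phased annotated-style site rows for one gene, plus its truth record.

    This is the fast in-memory path used for statistical validation; the
    file-emitting :func:`simulate_dataset` builds on the same row generator.
    """
    g = gene_index
    gene_id = f"SIMG{g:04d}"
    po = cfg.po_for_gene(g)
    b = rng.normal(0.0, cfg.genetic_sd, size=cfg.snps_per_gene)
    d = rng.normal(0.0, cfg.depth_sd, size=cfg.snps_per_gene)
    if subject_effects is None:
        subject_effects = rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)
    positions = _exonic_positions(g, cfg.snps_per_gene, phase=0)

    rows = []
    orientations = {}
    for i in range(cfg.n_subjects):
        sample_id = f"S{i:03d}"
        for j, pos in enumerate(positions):
            if rng.random() >= cfg.het_prob:
                continue
            pat_is_ref = rng.random() < cfg.phase_orientation_prob
            z_ref = 0.5 if pat_is_ref else -0.5
            base = cfg.baseline_log_mean + d[j] + subject_effects[i]
            mean_ref = math.exp(base + po * z_ref + b[j] * 0.5)
            mean_alt = math.exp(base - po * z_ref - b[j] * 0.5)
            ref_count = _draw_counts(rng, mean_ref, cfg)
            alt_count = _draw_counts(rng, mean_alt, cfg)
            orientations[f"{sample_id}|{gene_id}|{pos}"] = "ref" if pat_is_ref else "alt"
            rows.append(
                {
                    "sample_id": sample_id,
                    "contig": CONTIG,
                    "position": pos,
                    "gene_id": gene_id,
                    "ref_count": ref_count,
                    "alt_count": alt_count,
                    "total_count": ref_count + alt_count,
                    "other_bases": 0,
                    "gclass": "het",
                    "phased": True,
                    "first_allele": "ref" if pat_is_ref else "alt",
                    "paternal_allele": "ref" if pat_is_ref else "alt",
                    "paternal_count": ref_count if pat_is_ref else alt_count,
                    "maternal_count": alt_count if pat_is_ref else ref_count,
                    "strand_label": "forward" if gene_strand(g) == "+" else "reverse",
                }
            )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["paternal_freq"] = frame["paternal_count"] / frame["total_count"]
    truth = {
        "gene_id": gene_id,
        "po_true": po,
        "b": b.tolist(),
        "positions": positions,
        "orientations": orientations,
    }
    return frame, truth


def inject_contamination(
    table: pd.DataFrame,
    c: float,
    contaminant_ref_prob: pd.Series | float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Re-label a Binomial(total, c) subset of each site's reads.

    ``contaminant_ref_prob`` is the probability a contaminant-origin read
    carries the reference base (1 for a hom-ref contaminant, 0.5 het,
    0 hom-alt), scalar or aligned per-row.  Per-site totals are conserved:
    the relabelled reads are removed hypergeometrically from the existing
    ref/alt composition and re-added with the contaminant profile.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("contamination fraction must lie in [0, 1]")
    out = table.copy()
    if c == 0.0 or out.empty:
        return out
    p_ref = (
        contaminant_ref_prob.to_numpy()
        if isinstance(contaminant_ref_prob, pd.Series)
        else np.full(len(out), float(contaminant_ref_prob))
    )
    ref = out["ref_count"].to_numpy(copy=True)
    alt = out["alt_count"].to_numpy(copy=True)
    total = ref + alt
    for i in range(len(out)):
        if total[i] == 0:
            continue
        n_c = rng.binomial(total[i], c)
        if n_c == 0:
            continue
        removed_ref = rng.hypergeometric(ref[i], alt[i], n_c)
        added_ref = rng.binomial(n_c, p_ref[i])
        ref[i] = ref[i] - removed_ref + added_ref
        alt[i] = total[i] - ref[i]
    out["ref_count"] = ref
    out["alt_count"] = alt
    out["total_count"] = ref + alt
    return out


def _simulate_hom_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Homozygous panel sites inside gene exons, with maternal genotypes.

    Offspring hom-alt sites get a hom-ref mother and offspring hom-ref
    sites a hom-alt mother with probability ``maternal_alt_prob`` (else
    hom-ref), so the injected contamination fraction maps directly onto the
    opposite-allele read frequency.
    """
    per_gene = max(cfg.n_hom_sites // max(cfg.n_genes, 1), 1)
    rows = []
    for g in range(cfg.n_genes):
        het_pos = set(_exonic_positions(g, cfg.snps_per_gene, phase=0))
        positions = [
            p + 2 if p in het_pos else p for p in _exonic_positions(g, per_gene, phase=1)
        ]
        for i in range(cfg.n_subjects):
            sample_id = f"S{i:03d}"
            for pos in positions:
                gclass = "hom_alt" if rng.random() < 0.5 else "hom_ref"
                total = int(rng.poisson(math.exp(cfg.baseline_log_mean + math.log(2.0)
                                                 + rng.normal(0.0, cfg.depth_sd))))
                if gclass == "hom_alt":
                    ref_count, alt_count = 0, total
                    mom = "hom_ref"
                else:
                    ref_count, alt_count = total, 0
                    mom = "hom_alt" if rng.random() < cfg.maternal_alt_prob else "hom_ref"
                rows.append(
                    {
                        "sample_id": sample_id,
                        "contig": CONTIG,
                        "position": pos,
                        "gene_index": g,
                        "ref_count": ref_count,
                        "alt_count": alt_count,
                        "total_count": total,
                        "other_bases": 0,
                        "gclass": gclass,
                        "maternal_gclass": mom,
                        "strand_label": "forward" if gene_strand(g) == "+" else "reverse",
                    }
                )
    return pd.DataFrame(rows)


def _write_gtf(cfg: SimConfig, path: Path) -> None:
    with open(path, "w") as fh:
        for g in range(cfg.n_genes):
            gene_id = f"SIMG{g:04d}"
            strand = gene_strand(g)
            for s, e in gene_exons(g):
                attrs = (
                    f'gene_id "{gene_id}"; gene_name "{gene_id}"; '
                    f'gene_type "protein_coding"; transcript_id "{gene_id}.t1";'
                )
                fh.write(
                    f"{CONTIG}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                )


def _write_ase_table(rows: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ASE_COLUMNS) + "\n")
        for r in rows.sort_values(["contig", "position"]).itertuples(index=False):
            total = r.ref_count + r.alt_count
            fh.write(
                f"{r.contig}\t{r.position}\tsnp_{r.position}\t{REF_BASE}\t{ALT_BASE}\t"
                f"{r.ref_count}\t{r.alt_count}\t{total}\t0\t0\t{total}\t{r.other_bases}\t0\n"
            )


def _write_vcf(records: list[tuple[int, str, bool, str]], sample_id: str, path: Path) -> None:
    """records: (position, gclass, phased, first_allele) sorted by position."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add(CONTIG, length=CONTIG_LEN)
    header.add_sample(sample_id)
    gt_map = {"hom_ref": (0, 0), "hom_alt": (1, 1), "het": (0, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos, gclass, phased, first in sorted(records):
            rec = vcf.new_record(
                contig=CONTIG,
                start=pos - 1,
                stop=pos,
                alleles=(REF_BASE, ALT_BASE),
                id=f"snp_{pos}",
            )
            if gclass == "het" and phased:
                gt = (0, 1) if first == "ref" else (1, 0)
            else:
                gt = gt_map[gclass]
            rec.samples[sample_id]["GT"] = gt
            rec.samples[sample_id].phased = bool(phased and gclass == "het")
            vcf.write(rec)


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> SimulatedDataset:
    """Emit a complete synthetic dataset under ``outdir``.

    Files: per-sample forward/reverse (or single unstranded) count tables,
    per-sample phased VCFs, maternal VCFs, a GTF of the synthetic genes, a
    sample sheet CSV, and truth.json.  Deterministic given (cfg, cfg.seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    subject_effects = rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)
    gene_frames, gene_truths = [], []
    for g in range(cfg.n_genes):
        frame, truth = simulate_gene_sites(cfg, rng, g, subject_effects)
        gene_frames.append(frame)
        gene_truths.append(truth)
    het = pd.concat([f for f in gene_frames if len(f)], ignore_index=True) \
        if any(len(f) for f in gene_frames) else pd.DataFrame()

    hom = _simulate_hom_sites(cfg, rng)
    if cfg.contamination > 0 and len(hom):
        p_ref = hom["maternal_gclass"].map({"hom_ref": 1.0, "het": 0.5, "hom_alt": 0.0})
        hom = inject_contamination(hom, cfg.contamination, p_ref, rng)

    sample_ids = [f"S{i:03d}" for i in range(cfg.n_subjects)]
    gtf_path = outdir / "genes.gtf"
    _write_gtf(cfg, gtf_path)

    sheet_rows = []
    for sid in sample_ids:
        het_s = het[het["sample_id"] == sid] if len(het) else pd.DataFrame()
        hom_s = hom[hom["sample_id"] == sid]
        combined = pd.concat([f for f in (het_s, hom_s) if len(f)], ignore_index=True) \
            if len(het_s) or len(hom_s) else pd.DataFrame(
                columns=["contig", "position", "ref_count", "alt_count", "other_bases",
                         "strand_label"])
        row = {"sample_id": sid, "vcf_file": f"{sid}.vcf", "maternal_vcf_file": f"{sid}.mother.vcf"}
        if cfg.stranded:
            fwd = combined[combined["strand_label"] == "forward"]
            rev = combined[combined["strand_label"] == "reverse"]
            _write_ase_table(fwd, outdir / f"{sid}.forward.tsv")
            _write_ase_table(rev, outdir / f"{sid}.reverse.tsv")
            row["count_file_forward"] = f"{sid}.forward.tsv"
            row["count_file_reverse"] = f"{sid}.reverse.tsv"
        else:
            _write_ase_table(combined, outdir / f"{sid}.counts.tsv")
            row["count_file_forward"] = f"{sid}.counts.tsv"
            row["count_file_reverse"] = ""
        vcf_records = [
            (int(r.position), "het", True, r.first_allele)
            for r in het_s.itertuples(index=False)
        ] if len(het_s) else []
        vcf_records += [
            (int(r.position), r.gclass, False, None) for r in hom_s.itertuples(index=False)
        ]
        _write_vcf(vcf_records, sid, outdir / f"{sid}.vcf")
        mom_records = [
            (int(r.position), r.maternal_gclass, False, None)
            for r in hom_s.itertuples(index=False)
        ]
        _write_vcf(mom_records, f"{sid}_mother", outdir / f"{sid}.mother.vcf")
        sheet_rows.append(row)

    sheet_path = outdir / "samples.csv"
    pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "count_file_forward", "count_file_reverse",
                 "vcf_file", "maternal_vcf_file"],
    ).to_csv(sheet_path, index=False)

    truth = SimTruth(
        po_true={t["gene_id"]: t["po_true"] for t in gene_truths},
        genetic_effects={t["gene_id"]: t["b"] for t in gene_truths},
        subject_effects={sid: float(e) for sid, e in zip(sample_ids, subject_effects)},
        contamination=cfg.contamination,
        phase_orientation={
            k: v for t in gene_truths for k, v in t["orientations"].items()
        },
    )
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    return SimulatedDataset(
        outdir=outdir,
        sheet_path=sheet_path,
        gtf_path=gtf_path,
        truth_path=truth_path,
        truth=truth,
        sample_ids=sample_ids,
    )
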
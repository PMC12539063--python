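"""Ingest of per-SNP allelic count tables, sample sheets, and VCF genotypes.

Count tables follow the GATK ASEReadCounter tab-separated layout (13 named
columns; extra trailing columns are tolerated).  Each parsed row is stamped
with the sample it came from and a strand label, and per-sample/per-strand
tables are concatenated into one unified table keyed by
(sample_id, contig, position, strand_label).

Coordinates stay 1-based as printed by the external formats; interval
arithmetic elsewhere converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

STRAND_LABELS = ("forward", "reverse", "unstranded")

#: Required leading columns of the ASEReadCounter output.
ASE_COLUMNS = (
    "contig",
    "position",
    "variantID",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
    "lowMAPQDepth",
    "lowBaseQDepth",
    "rawDepth",
    "otherBases",
    "improperPairs",
)

#: Canonical columns of the unified count table.
COUNT_COLUMNS = (
    "sample_id",
    "contig",
    "position",
    "variant_id",
    "ref_allele",
    "alt_allele",
    "ref_count",
    "alt_count",
    "total_count",
    "other_bases",
    "strand_label",
)

_KEY = ["sample_id", "contig", "position", "strand_label"]


class CountFormatError(ValueError):
    """Raised when a count table does not conform to the expected layout."""


class IntegrityError(ValueError):
    """Raised when concatenated tables violate the unique-key contract."""


@dataclass(frozen=True)
class GenotypeCall:
    """A single-sample genotype at one biallelic SNP.

    ``phased`` is True only for heterozygotes written with the ``|``
    separator; the phase of a homozygote carries no information and is
    normalised away.  ``first_allele`` records which allele the first
    haplotype carries ('ref' for 0|1, 'alt' for 1|0) and is None when
    unphased.
    """

    sample_id: str
    contig: str
    position: int
    gclass: str  # hom_ref | het | hom_alt
    phased: bool = False
    first_allele: str | None = None

    def __post_init__(self) -> None:
        if self.phased and self.gclass != "het":
            raise ValueError("only heterozygous calls may be phased")


@dataclass
class SampleSheet:
    """Sample sheet mapping each sample to its count files and VCFs."""

    rows: list[dict] = field(default_factory=list)

    REQUIRED = ("sample_id", "count_file_forward", "vcf_file")
    OPTIONAL = ("count_file_reverse", "maternal_vcf_file")

    @classmethod
    def read(cls, path: str | Path, check_exists: bool = True) -> "SampleSheet":
        path = Path(path)
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in cls.REQUIRED if c not in header]
            if missing:
                raise CountFormatError(
                    f"sample sheet {path} missing required column(s): {missing}"
                )
            rows = []
            seen: set[str] = set()
            for raw in reader:
                row = {k: (raw.get(k) or "").strip() for k in cls.REQUIRED + cls.OPTIONAL}
                sid = row["sample_id"]
                if not sid:
                    continue
                if sid in seen:
                    raise IntegrityError(f"duplicate sample_id in sheet: {sid!r}")
                seen.add(sid)
                rows.append(row)
        sheet = cls(rows)
        if check_exists:
            base = path.parent
            for row in sheet.rows:
                for key in ("count_file_forward", "count_file_reverse",
                            "vcf_file", "maternal_vcf_file"):
                    if row[key]:
                        p = Path(row[key])
                        if not p.is_absolute():
                            p = base / p
                        if not p.exists():
                            raise FileNotFoundError(
                                f"sample {row['sample_id']}: {key} not found: {p}"
                            )
                        row[key] = str(p)
        return sheet

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def parse_ase_counts(path: str | Path, sample_id: str, strand_label: str) -> pd.DataFrame:
    """Parse one ASEReadCounter table into unified-table rows.

    Rows whose printed ``totalCount`` disagrees with refCount + altCount are
    repaired (total recomputed as ref + alt) with a warning, since GATK's
    total may include bases removed by its own quality filters.
    """
    if strand_label not in STRAND_LABELS:
        raise ValueError(f"strand_label must be one of {STRAND_LABELS}")
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise CountFormatError(f"{path}: empty file, expected header")
        header = header_line.split("\t")
        for col in ASE_COLUMNS:
            if col not in header:
                raise CountFormatError(f"{path}: missing required column {col!r}")
        idx = {col: header.index(col) for col in ASE_COLUMNS}
        records: list[dict] = []
        n_repaired = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                raise CountFormatError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                position = int(parts[idx["position"]])
                ref_count = int(parts[idx["refCount"]])
                alt_count = int(parts[idx["altCount"]])
                total = int(parts[idx["totalCount"]])
                other = int(parts[idx["otherBases"]])
            except ValueError as exc:
                raise CountFormatError(f"{path}:{lineno}: non-integer count ({exc})") from exc
            if total != ref_count + alt_count:
                n_repaired += 1
                total = ref_count + alt_count
            records.append(
                {
                    "sample_id": sample_id,
                    "contig": parts[idx["contig"]],
                    "position": position,
                    "variant_id": parts[idx["variantID"]],
                    "ref_allele": parts[idx["refAllele"]],
                    "alt_allele": parts[idx["altAllele"]],
                    "ref_count": ref_count,
                    "alt_count": alt_count,
                    "total_count": total,
                    "other_bases": other,
                    "strand_label": strand_label,
                }
            )
    if n_repaired:
        warnings.warn(
            f"{path}: recomputed totalCount as refCount+altCount on {n_repaired} row(s)",
            stacklevel=2,
        )
    return pd.DataFrame(records, columns=list(COUNT_COLUMNS))


def parse_genotypes(
    path: str | Path, sample_id: str | None = None
) -> tuple[dict[tuple[str, int], GenotypeCall], int]:
    """Read biallelic SNP genotypes for one sample from a VCF.

    Returns a ``(contig, position) -> GenotypeCall`` map plus the number of
    skipped records (multi-allelic genotypes or missing calls).  ``sample_id``
    defaults to the single sample in the file.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if sample_id is None:
            if len(samples) != 1:
                raise ValueError(f"{path}: sample_id required, file has {len(samples)} samples")
            sample_id = samples[0]
        if sample_id not in samples:
            raise KeyError(f"{path}: sample {sample_id!r} not in VCF")
        calls: dict[tuple[str, int], GenotypeCall] = {}
        n_skipped = 0
        for rec in vcf:
            sample = rec.samples[sample_id]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                n_skipped += 1
                continue
            a, b = gt
            if a > 1 or b > 1:
                n_skipped += 1
                continue
            n_alt = a + b
            if n_alt == 0:
                gclass = "hom_ref"
            elif n_alt == 2:
                gclass = "hom_alt"
            else:
                gclass = "het"
            phased = bool(sample.phased) and gclass == "het"
            first = None
            if phased:
                first = "ref" if a == 0 else "alt"
            calls[(rec.contig, rec.pos)] = GenotypeCall(
                sample_id=sample_id,
                contig=rec.contig,
                position=rec.pos,
                gclass=gclass,
                phased=phased,
                first_allele=first,
            )
    if n_skipped:
        logger.warning("%s: skipped %d non-biallelic/missing genotype record(s)", path, n_skipped)
    return calls, n_skipped


def genotypes_to_frame(calls: Mapping[tuple[str, int], GenotypeCall]) -> pd.DataFrame:
    """Flatten a genotype map into a joinable DataFrame."""
    rows = [
        {
            "sample_id": c.sample_id,
            "contig": c.contig,
            "position": c.position,
            "gclass": c.gclass,
            "phased": c.phased,
            "first_allele": c.first_allele,
        }
        for c in calls.values()
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "contig", "position", "gclass", "phased", "first_allele"]
    )


def concat_counts(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-sample/per-strand tables into one unified table.

    (sample_id, contig, position, strand_label) must be unique across the
    result; a collision means the same file was ingested twice and raises.
    """
    frames = [t for t in tables if t is not None and len(t)]
    if not frames:
        return pd.DataFrame(columns=list(COUNT_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    dup = out.duplicated(subset=_KEY, keep=False)
    if dup.any():
        first = out.loc[dup, _KEY].iloc[0].tolist()
        raise IntegrityError(f"duplicate count-table key {tuple(first)}")
    out = out.sort_values(_KEY, kind="mergesort").reset_index(drop=True)
    return out


def load_sample_counts(sheet: SampleSheet) -> pd.DataFrame:
    """Ingest every count file referenced by a sample sheet."""
    tables = []
    for row in sheet:
        if row["count_file_reverse"]:
            tables.append(parse_ase_counts(row["count_file_forward"], row["sample_id"], "forward"))
            tables.append(parse_ase_counts(row["count_file_reverse"], row["sample_id"], "reverse"))
        else:
            tables.append(parse_ase_counts(row["count_file_forward"], row["sample_id"], "unstranded"))
    return concat_counts(tables)


def load_sheet_genotypes(sheet: SampleSheet, maternal: bool = False) -> pd.DataFrame:
    """Load offspring (or maternal) genotypes for every sample in the sheet."""
    frames = []
    for row in sheet:
        key = "maternal_vcf_file" if maternal else "vcf_file"
        if not row[key]:
            continue
        calls, _ = parse_genotypes(row[key])
        frame = genotypes_to_frame(calls)
        # genotype map is keyed by the VCF's own sample name; restamp with the
        # sheet's sample_id so maternal genotypes join onto offspring rows
        frame["sample_id"] = row["sample_id"]
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "contig", "position", "gclass", "phased", "first_allele"]
        )
    return pd.concat(frames, ignore_index=True)


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Re-read a unified count table written by :func:`write_counts`."""
    table = pd.read_csv(path, sep="\t", dtype={"contig": str, "variant_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise CountFormatError(f"{path}: missing unified-table column(s) {missing}")
    return table
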
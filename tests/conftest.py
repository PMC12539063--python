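import numpy as np
import pandas as pd
import pytest

from asepofo.count_io import ASE_COLUMNS


def write_ase_file(path, rows):
    """Write an ASEReadCounter-format table; rows are (contig, pos, ref, alt) counts."""
    with open(path, "w") as fh:
        fh.write("\t".join(ASE_COLUMNS) + "\n")
        for contig, pos, ref, alt in rows:
            total = ref + alt
            fh.write(
                f"{contig}\t{pos}\tsnp_{pos}\tA\tG\t{ref}\t{alt}\t{total}\t0\t0\t{total}\t0\t0\n"
            )
    return path


def write_vcf_file(path, sample_id, records):
    """Write a minimal VCF; records are (contig, pos, gt_string) tuples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = sorted({c for c, _, _ in records})
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=100000000>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for contig, pos, gt in sorted(records):
            alt = "G,T" if gt.replace("|", "/").split("/")[-1] == "2" else "G"
            fh.write(f"{contig}\t{pos}\t.\tA\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
    return path


def phased_gene_frame(entries, gene_id="g1", contig="chr1"):
    """Annotated-style phased site rows from (sample, pos, ref, alt, paternal)."""
    rows = []
    for sample, pos, ref, alt, paternal in entries:
        rows.append(
            {
                "gene_id": gene_id,
                "sample_id": sample,
                "contig": contig,
                "position": pos,
                "ref_count": ref,
                "alt_count": alt,
                "total_count": ref + alt,
                "paternal_allele": paternal,
                "paternal_count": ref if paternal == "ref" else alt,
                "maternal_count": alt if paternal == "ref" else ref,
                "strand_label": "forward",
            }
        )
    frame = pd.DataFrame(rows)
    frame["paternal_freq"] = frame["paternal_count"] / frame["total_count"]
    return frame


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
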
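"""Readers and writers for the plain-text formats shared by all stages.

FASTA and multiple alignments go through Biopython; VCF reading goes through
cyvcf2. GFF3 here carries single ``gene`` features only (plus
``##sequence-region`` pragmas for chromosome lengths), and VCF output is
GT-only biallelic v4.2, so those writers emit the text directly.

Tabular outputs are tab-separated with a header line; lines starting with
``#`` are comments. BED output is 0-based half-open; everything else is
1-based closed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FormatError, GeneModel, GenotypeMatrix, ProteinRecord

# ---------------------------------------------------------------- FASTA


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(s), id=str(i), description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_alignment(path, fmt: Optional[str] = None) -> list[str]:
    """Read an aligned FASTA or Stockholm file into equal-length rows."""
    if fmt is None:
        fmt = "stockholm" if str(path).endswith((".sto", ".stk")) else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = [str(rec.seq).upper() for rec in aln]
    if len({len(r) for r in rows}) > 1:
        raise FormatError(f"ragged alignment in {path}")
    return rows


# ----------------------------------------------------------------- GFF3


def write_gff3(genes: Iterable[GeneModel], path,
               chrom_lengths: Optional[dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tnlr_atlas\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path) -> tuple[list[GeneModel], dict[str, int]]:
    """Read gene features and ``##sequence-region`` lengths from a GFF3."""
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                chrom_lengths[chrom] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"bad GFF3 line ({len(fields)} columns): {line[:80]}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise FormatError(f"gene feature without ID attribute: {line[:80]}")
            genes.append(
                GeneModel(gene_id, chrom, int(start), int(end),
                          strand if strand in "+-" else "+")
            )
    return genes, chrom_lengths


# ------------------------------------------------------------------ VCF

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path,
              chrom_lengths: Optional[dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=nlr_atlas\n')
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        sites = gm.sites
        for i in range(gm.n_sites):
            row = sites.iloc[i]
            calls = "\t".join(_GT_STR[int(v)] for v in gm.gt[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path, panel: pd.DataFrame) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF through cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, pos, ref, alt, rows = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(f"multi-allelic site at {v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = -1  # cyvcf2 UNKNOWN
        rows.append(gt)
    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    gt = (np.vstack(rows) if rows
          else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(sites, gt, samples, panel)


# ------------------------------------------------------------ panel/TSV


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.reset_index()
    out.columns = ["sample", "group", "lineage"]
    out.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample", "group"):
        if col not in panel.columns:
            raise FormatError(f"panel file lacks required column {col!r}")
    if "lineage" not in panel.columns:
        panel["lineage"] = panel["group"]
    return panel.set_index("sample")[["group", "lineage"]]


def write_table(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_pairs_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene1", "gene2"], usecols=[0, 1])
    return list(df.itertuples(index=False, name=None))


# ------------------------------------------------------------------ BED


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start_1based, end_1based, *rest) as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end, *rest in intervals:
            cols = [chrom, str(int(start) - 1), str(int(end))] + [str(x) for x in rest]
            fh.write("\t".join(cols) + "\n")


# ----------------------------------------------------------- expression


def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="sample")
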
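"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text: a simplified 6-column pileup dialect,
GFF3 gene rows, FASTA references, VCF 4.2 for discovered SNPs, and TSV/CSV
for matrices and tables.  All genomic coordinates are 1-based inclusive.
Writers prepend a provenance header (``# peppermap ...``) that readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

PILEUP_COLUMNS = ["chrom", "pos", "ref", "depth", "bases", "qual"]


def provenance_header(seed: int | None = None,
                      config: Mapping | None = None) -> str:
    h = ""
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        h = hashlib.sha1(blob).hexdigest()[:12]
    parts = [f"# peppermap {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if h:
        parts.append(f"config={h}")
    return " ".join(parts)


def write_pileup(df: pd.DataFrame, path: str | Path,
                 header: str | None = None) -> None:
    """Write a 6-column pileup table (chrom, pos, ref, depth, bases, qual)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  columns=PILEUP_COLUMNS)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=PILEUP_COLUMNS, comment="#",
                     dtype={"chrom": str, "pos": int, "ref": str,
                            "depth": int, "bases": str, "qual": str})
    df["bases"] = df["bases"].fillna("")
    return df


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene rows (gene_id, chrom, start, end) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genes.iterrows():
            fh.write("\t".join([
                str(row["chrom"]), "peppermap", "gene",
                str(int(row["start"])), str(int(row["end"])),
                ".", "+", ".", f"ID={row['gene_id']}",
            ]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({"gene_id": attrs.get("ID", ""), "chrom": f[0],
                         "start": int(f[3]), "end": int(f[4])})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def write_vcf(snps: Sequence, path: str | Path, samples: Sequence[str] = (),
              seed: int | None = None) -> None:
    """Write discovered SNPs as VCF 4.2 with CATEGORY and GENE INFO keys."""
    samples = list(samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=peppermap-{__version__}\n")
        if seed is not None:
            fh.write(f"##peppermap_seed={seed}\n")
        fh.write('##INFO=<ID=CATEGORY,Number=1,Type=String,'
                 'Description="Phenotype set: blocky, hot or both">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,'
                 'Description="Containing gene id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT"] + samples
        fh.write("\t".join(cols) + "\n")
        for snp in snps:
            info = []
            if snp.category:
                info.append(f"CATEGORY={snp.category}")
            if snp.gene:
                info.append(f"GENE={snp.gene}")
            row = [snp.chrom, str(snp.pos), f"{snp.chrom}_{snp.pos}",
                   snp.ref, snp.alt, ".", "PASS", ";".join(info) or "."]
            if samples:
                row.append("GT")
                for s in samples:
                    gt = snp.genotypes.get(s, "--")
                    if gt == "--":
                        row.append("./.")
                    else:
                        idx = ["." if a not in (snp.ref, snp.alt)
                               else ("0" if a == snp.ref else "1") for a in gt]
                        row.append("/".join(idx))
            fh.write("\t".join(row) + "\n")


def write_matrix_tsv(df: pd.DataFrame, path: str | Path,
                     header: str | None = None) -> None:
    """Write a table with an optional provenance comment line on top."""
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t")


def read_matrix_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, **kwargs)


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.Series(labels, name="group").rename_axis("sample").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", comment="#", index_col=0)["group"]
    return {str(k): str(v) for k, v in s.items()}
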
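"""Plain-text readers and writers: pooled VCF/TSV, FASTQ, BED, barcode tables.

Pooled counts travel as a VCF with two sample columns (MUT, WT) carrying AD
and DP, or as an equivalent 9-column TSV. All positions are 1-based in
VCF/TSV and 0-based half-open in BED.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

POOLSITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "mut_ref",
    "mut_alt",
    "wt_ref",
    "wt_alt",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsakit
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence label">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_pool_vcf(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a PoolSite table as an uncompressed two-sample (MUT, WT) VCF."""
    has_csq = "consequence" in sites.columns
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = pd.unique(sites["chrom"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMUT\tWT\n")
        for row in sites.itertuples(index=False):
            info = f"CSQ={row.consequence}" if has_csq else "."
            mut_dp = int(row.mut_ref) + int(row.mut_alt)
            wt_dp = int(row.wt_ref) + int(row.wt_alt)
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:g}\t.\t{info}\tAD:DP\t"
                f"{int(row.mut_ref)},{int(row.mut_alt)}:{mut_dp}\t"
                f"{int(row.wt_ref)},{int(row.wt_alt)}:{wt_dp}\n"
            )


def read_pool_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a two-sample pooled VCF back into a PoolSite table.

    The first sample column is taken as the mutant pool and the second as
    the wild-type pool; a CSQ INFO field, when present, becomes the
    ``consequence`` column. Multiallelic records keep their comma-joined alt
    string so downstream biallelic filters can see them.
    """
    vcf = VCF(str(path))
    if len(vcf.samples) < 2:
        raise ValueError("pooled VCF needs two sample columns (MUT, WT)")
    rows = []
    any_csq = False
    for rec in vcf:
        ad = rec.format("AD")
        csq = rec.INFO.get("CSQ")
        any_csq = any_csq or csq is not None
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": ",".join(rec.ALT),
                "qual": rec.QUAL if rec.QUAL is not None else float("nan"),
                "mut_ref": int(ad[0][0]),
                "mut_alt": int(ad[0][1]),
                "wt_ref": int(ad[1][0]),
                "wt_alt": int(ad[1][1]),
                "consequence": csq,
            }
        )
    df = pd.DataFrame(rows, columns=POOLSITE_COLUMNS + ["consequence"])
    if not any_csq:
        df = df.drop(columns=["consequence"])
    return df


def write_pool_table(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_pool_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POOLSITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pool table missing columns: {missing}")
    return df


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )


def write_fastq(reads, path: str | os.PathLike, qual_char: int = 40) -> None:
    """Write reads (objects with read_id/sequence or (id, seq) pairs) as FASTQ."""
    records = []
    for read in reads:
        rid, seq = (
            (read.read_id, read.sequence) if hasattr(read, "read_id") else (read[0], read[1])
        )
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [qual_char] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_truth_table(reads, path: str | os.PathLike) -> None:
    """Sidecar TSV of read truth labels for simulated amplicon reads."""
    pd.DataFrame(
        [(r.read_id, r.true_isoform) for r in reads],
        columns=["read_id", "true_isoform"],
    ).to_csv(path, sep="\t", index=False)


def read_barcode_table(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV (sample, barcode) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "barcode"])
    return dict(zip(df["sample"].astype(str), df["barcode"].astype(str)))
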
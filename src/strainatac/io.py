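"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED6 for peaks and H3K27ac regions, uncompressed VCF 4.x sites
(SNVs only), two-column chrom-sizes TSV, 4-column offset maps, count
matrices and sample sheets as TSV, and FASTA via Biopython.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import OffsetMap, ValidationError

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into chrom/start/end(/id/score/strand)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: fewer than 3 BED columns")
            rec = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
            }
            if len(parts) >= 4:
                rec["id"] = parts[3]
            if len(parts) >= 5:
                rec["score"] = float(parts[4]) if parts[4] != "." else 0.0
            if len(parts) >= 6:
                rec["strand"] = parts[5]
            rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValidationError(f"{path}: malformed interval at record {bad}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("id", "score", "strand"):
        if extra in df.columns:
            cols.append(extra)
        else:
            break
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_vcf_snvs(path: str | Path) -> pd.DataFrame:
    """Read SNV records from an uncompressed VCF; skip others with a count.

    Positions are converted to 0-based. Returns chrom/pos/ref_allele/
    alt_allele/variant_id.
    """
    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            alt = alt.split(",")[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                skipped += 1
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos) - 1,
                    "ref_allele": ref,
                    "alt_allele": alt,
                    "variant_id": vid if vid != "." else f"{chrom}_{pos}",
                }
            )
    if skipped:
        logger.info("skipped %d non-SNV VCF records in %s", skipped, path)
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref_allele", "alt_allele", "variant_id"]
    )


def write_vcf_snvs(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in df.itertuples():
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.variant_id}\t{r.ref_allele}\t"
                f"{r.alt_allele}\t.\tPASS\t.\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, n in sizes.items():
            fh.write(f"{c}\t{n}\n")


def read_offset_map(path: str | Path) -> OffsetMap:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "src_start", "src_end", "delta"],
    )
    return OffsetMap(df)


def write_offset_map(omap: OffsetMap, path: str | Path) -> None:
    omap.blocks.to_csv(path, sep="\t", header=False, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Features x samples integer count matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "strain", "diet"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: sample sheet needs columns {required}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_ids")
    return df


def read_tss_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss_pos", "strand"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: TSS table needs columns {required}")
    if "expressed" not in df.columns:
        df["expressed"] = True
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_sets_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
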
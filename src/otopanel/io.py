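"""Plain-text serialization of calls, counts and pileups.

TSV tables go through pandas.  VCF output is a minimal self-contained
VCFv4.2 writer for this package's own records (single synthetic contig,
INFO keys DP/AC/AF, FILTER entries for the reportability and confirmation
flags, symbolic <DEL>/<DUP>/<CN0> records for CNVs); the matching reader
accepts the same subset and is used for truth sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .caller import (
    FLAG_LOW_CONFIDENCE,
    FLAG_NEEDS_CONFIRMATION,
    FLAG_REPORTABLE,
    VariantCall,
)
from .cnv import CnvCall
from .qc import TruthSet, TruthVariant

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=otopanel
##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered read depth">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate-allele read count">
##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=END,Number=1,Type=Integer,Description="End of a symbolic CNV record">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number of a symbolic CNV record">
##FILTER=<ID=reportable,Description="Meets the stricter reportability thresholds">
##FILTER=<ID=needs_confirmation,Description="Inside a homologous conflictive region; orthogonal confirmation required">
##FILTER=<ID=low_confidence,Description="Passes permissive but fails stricter thresholds">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_calls_vcf(calls: Iterable[VariantCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in calls:
            filters = []
            if FLAG_REPORTABLE in c.flags:
                filters.append("reportable")
            if FLAG_NEEDS_CONFIRMATION in c.flags:
                filters.append("needs_confirmation")
            if FLAG_LOW_CONFIDENCE in c.flags:
                filters.append("low_confidence")
            filt = ";".join(filters) or "PASS"
            info = f"DP={c.depth};AC={c.alt_count};AF={c.vaf:.4f}"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}\n")


def write_cnv_vcf(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Symbolic CNV records; the ID column carries the target span (panel
    targets are labels, not genomic coordinates, so END counts targets)."""
    symbolic = {0: "<CN0>", 1: "<DEL>", 3: "<DUP>"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in calls:
            info = f"CN={c.state};END={c.n_targets}"
            fh.write(
                f"{c.gene}\t1\t{c.first_target}..{c.last_target}\tN\t{symbolic[c.state]}\t.\tPASS\t{info}\n"
            )


def read_truth_vcf(path: str | Path, target_positions: int) -> TruthSet:
    """Read a truth set from a VCF whose INFO carries AF."""
    variants = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _qual, _filt, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            variants.append(
                TruthVariant(chrom, int(pos), ref, alt, float(fields.get("AF", 1.0)))
            )
    return TruthSet(tuple(variants), target_positions=target_positions)


def write_truth_vcf(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in truth.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tAF={v.af:.4f}\n")


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    """Pileup table with columns chrom, pos, ref, allele, count, depth."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "allele": str})
    required = {"chrom", "pos", "ref", "allele", "count", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV lacks columns: {sorted(missing)}")
    return df


def write_pileup_tsv(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a targets x samples read-count matrix (first column target_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("target_id").to_csv(path, sep="\t")


def write_cnv_tsv(calls: Sequence[CnvCall], path: str | Path) -> None:
    rows = [
        {
            "gene": c.gene,
            "first_target": c.first_target,
            "last_target": c.last_target,
            "n_targets": c.n_targets,
            "copy_number": c.state,
            "mean_log2_ratio": c.mean_log2_ratio,
            "evidence": ",".join(sorted(c.evidence)),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
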
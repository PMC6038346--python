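"""Threshold-based SNV/indel calling from quality-filtered pileup evidence.

The caller emits a variant call for every non-reference allele whose
evidence clears three inclusive thresholds simultaneously:

* total quality-filtered read depth  >= ``min_depth``   (default 6)
* alternate-allele read count        >= ``min_alt``     (default 3)
* variant allele fraction (VAF)      >= ``min_vaf``     (default 0.1)

Base- and mapping-quality filtering (BQ >= 20, MQ >= 30 by default) happens
at pileup construction: a :class:`PileupColumn` carries only reads that
passed those cutoffs, and the VAF denominator is that filtered depth.

A stricter gate (depth >= 10, alt reads >= 4) selects *reportable* calls;
calls passing the permissive but failing the stricter thresholds keep a
``low_confidence`` flag so that downstream review can rescue them instead of
losing them silently.

Two equivalent entry points are provided: :func:`call_variants` consumes a
stream of :class:`PileupColumn` objects; :func:`call_variants_table` is a
vectorized fast path over a pileup table (one row per observed non-reference
allele) used for whole-panel simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

FLAG_REPORTABLE = "reportable"
FLAG_LOW_CONFIDENCE = "low_confidence"
FLAG_NEEDS_CONFIRMATION = "needs_orthogonal_confirmation"
FLAG_BLEED_THROUGH = "suspected_bleed_through"

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
HEMIZYGOUS = "hemizygous"


@dataclass(frozen=True)
class CallerParams:
    """Calling and reportability thresholds (all comparisons inclusive)."""

    min_depth: int = 6
    min_alt: int = 3
    min_vaf: float = 0.1
    min_base_quality: int = 20
    min_mapping_quality: int = 30
    reportable_min_depth: int = 10
    reportable_min_alt: int = 4
    hom_vaf: float = 0.80  # VAF at or above which a diploid call is homozygous

    def __post_init__(self) -> None:
        if not (0 < self.min_vaf <= 1):
            raise ValueError(f"min_vaf must be in (0, 1], got {self.min_vaf}")
        if self.reportable_min_depth < self.min_depth:
            raise ValueError("reportable_min_depth must be >= min_depth")
        if self.reportable_min_alt < self.min_alt:
            raise ValueError("reportable_min_alt must be >= min_alt")


@dataclass(frozen=True)
class PileupColumn:
    """Per-position evidence: quality-passing read counts per allele.

    ``counts`` maps allele -> read count and includes the reference allele;
    alleles use VCF-style strings (indels are anchored: ref "AT" / alt "A"
    for a deletion, ref "A" / alt "AT" for an insertion).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for allele, count in self.counts.items():
            if count < 0:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: negative count for allele {allele!r}"
                )

    @property
    def filtered_depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_type: str
    depth: int
    alt_count: int
    vaf: float
    gene: str | None = None
    zygosity: str | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return SNV
    return INSERTION if len(alt) > len(ref) else DELETION


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimonious left-trimmed representation of a ref/alt pair.

    Shared trailing bases are removed first, then shared leading bases
    (advancing ``pos``), keeping at least one base on each side.  Full
    left-alignment against a reference sequence is not attempted; inputs
    produced by this package are emitted already anchored.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError("ref and alt are identical after normalization")
    return pos, ref, alt


def passes_thresholds(depth: int, alt_count: int, params: CallerParams) -> bool:
    return (
        depth >= params.min_depth
        and alt_count >= params.min_alt
        and alt_count / depth >= params.min_vaf
    )


def call_variants(
    columns: Iterable[PileupColumn], params: CallerParams = CallerParams()
) -> list[VariantCall]:
    """Apply the calling thresholds to a stream of pileup columns.

    Multi-allelic columns are handled by evaluating every non-reference
    allele independently; two alleles at one site may both be called.
    Output order follows input order (then allele string), so identical
    input yields an identical call list.
    """
    calls: list[VariantCall] = []
    for col in columns:
        depth = col.filtered_depth
        if depth == 0:
            continue
        for allele in sorted(a for a in col.counts if a != col.ref):
            count = col.counts[allele]
            if count > depth:
                raise ValueError(
                    f"{col.chrom}:{col.pos}: alt count {count} exceeds depth {depth}"
                )
            if not passes_thresholds(depth, count, params):
                continue
            pos, ref, alt = normalize_variant(col.pos, col.ref, allele)
            call = VariantCall(
                chrom=col.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                variant_type=variant_type(ref, alt),
                depth=depth,
                alt_count=count,
                vaf=count / depth,
            )
            if not (
                depth >= params.reportable_min_depth
                and count >= params.reportable_min_alt
            ):
                call.flags.add(FLAG_LOW_CONFIDENCE)
            calls.append(call)
    return calls


def call_variants_table(
    pileup: pd.DataFrame, params: CallerParams = CallerParams()
) -> pd.DataFrame:
    """Vectorized calling over a pileup table.

    ``pileup`` has one row per observed non-reference allele with columns
    ``chrom, pos, ref, allele, count, depth`` where ``depth`` is the total
    quality-filtered depth of the column.  Returns the calls as a DataFrame
    with the same columns plus ``vaf`` and ``low_confidence``; the result is
    row-for-row identical to running :func:`call_variants` on the
    corresponding columns.
    """
    if pileup.empty:
        return pileup.assign(vaf=pd.Series(dtype=float), low_confidence=pd.Series(dtype=bool))
    depth = pileup["depth"].to_numpy()
    count = pileup["count"].to_numpy()
    if (count < 0).any():
        raise ValueError("negative allele count in pileup table")
    if (count > depth).any():
        raise ValueError("allele count exceeds column depth in pileup table")
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, count / np.maximum(depth, 1), 0.0)
    mask = (depth >= params.min_depth) & (count >= params.min_alt) & (vaf >= params.min_vaf)
    out = pileup.loc[mask].copy()
    out["vaf"] = vaf[mask]
    out["low_confidence"] = ~(
        (out["depth"] >= params.reportable_min_depth)
        & (out["count"] >= params.reportable_min_alt)
    )
    return out.reset_index(drop=True)


def mark_reportable(
    calls: Sequence[VariantCall],
    panel,
    params: CallerParams = CallerParams(),
    phenotype_match: Mapping[str, bool] | None = None,
) -> list[VariantCall]:
    """Flag calls meeting the stricter reportability gate.

    Reportable requires depth >= 10, alt reads >= 4, VAF >= 0.1 and a tier-1
    gene -- or a tier-2 gene whose associated phenotype matches the patient
    (``phenotype_match``: gene symbol -> bool, set by triage).  Calls must be
    annotated with their gene; a gene absent from the panel is an error.
    """
    phenotype_match = phenotype_match or {}
    for call in calls:
        if call.gene is None:
            raise ValueError(f"call {call.chrom}:{call.pos} lacks a gene annotation")
        gene = panel[call.gene]  # raises KeyError for off-panel genes
        strict = (
            call.depth >= params.reportable_min_depth
            and call.alt_count >= params.reportable_min_alt
            and call.vaf >= params.min_vaf
        )
        tier_ok = gene.tier == 1 or (gene.tier == 2 and phenotype_match.get(gene.symbol, False))
        if strict and tier_ok:
            call.flags.add(FLAG_REPORTABLE)
        else:
            call.flags.discard(FLAG_REPORTABLE)
    return list(calls)


def genotype_zygosity(
    call: VariantCall,
    sex: str,
    chrom_class: str,
    params: CallerParams = CallerParams(),
) -> str | None:
    """Assign zygosity from VAF, sample sex and chromosome class.

    Diploid loci (autosomes, female X) are homozygous at VAF >= ``hom_vaf``
    (default 0.80, which separates the binomial heterozygous and homozygous
    VAF distributions at depth >= 20) and heterozygous below.  Male X calls
    are hemizygous regardless of VAF.  Mitochondrial variants get no
    zygosity (heteroplasmy is out of scope); ``None`` is returned and the
    call flagged.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    if chrom_class == "MT":
        call.flags.add("mitochondrial_no_zygosity")
        call.zygosity = None
        return None
    if chrom_class == "X" and sex == "male":
        call.zygosity = HEMIZYGOUS
    elif call.vaf >= params.hom_vaf:
        call.zygosity = HOMOZYGOUS
    else:
        call.zygosity = HETEROZYGOUS
    return call.zygosity
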
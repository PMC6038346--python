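"""Analytical-performance accounting and sample-tracking concordance.

Sensitivity/specificity are computed against a truth set over a defined
target space.  Matching is exact on the normalized (locus, ref, alt)
tuple; genotype is not scored.  True-negative accounting is per position:
of all target positions not bearing a truth variant, those without any
emitted call are true negatives, so specificity = TN / (TN + FP) with
TN + FP equal to the truth-variant-free position count.

Sample tracking compares NGS genotypes at a fixed panel of six common SNPs
(population MAF ~ 0.46-0.48) with genotypes from an orthogonal platform;
any discordance indicates a sample swap.  Under Hardy-Weinberg equilibrium
the probability that two *unrelated* samples agree at a SNP with allele
frequency p is (p^2)^2 + (2pq)^2 + (q^2)^2, so the expected probability of
full 6/6 agreement by chance is the product over the panel -- about 1.9e-3
at these MAFs, which is what makes the panel discriminating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import SNV, VariantCall, normalize_variant, variant_type


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float  # truth mixture allele fraction

    def __post_init__(self) -> None:
        if not (0 < self.af <= 1):
            raise ValueError(f"truth AF must be in (0,1], got {self.af}")

    @property
    def vtype(self) -> str:
        return variant_type(self.ref, self.alt)

    @property
    def normalized_key(self) -> tuple[str, int, str, str]:
        pos, ref, alt = normalize_variant(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)


@dataclass(frozen=True)
class TruthSet:
    variants: tuple[TruthVariant, ...]
    target_positions: int  # size of the callable target space, in positions

    def __post_init__(self) -> None:
        if len({(v.chrom, v.pos) for v in self.variants}) > self.target_positions:
            raise ValueError("more truth loci than target positions")

    @property
    def n_snvs(self) -> int:
        return sum(v.vtype == SNV for v in self.variants)

    @property
    def n_indels(self) -> int:
        return len(self.variants) - self.n_snvs


@dataclass(frozen=True)
class BenchmarkResult:
    tp: int
    fn: int
    fp: int
    tn: int
    tp_by_type: Mapping[str, int]
    fn_by_type: Mapping[str, int]
    sensitivity: float | None
    sensitivity_by_type: Mapping[str, float | None]
    specificity: float

    def summary(self) -> str:
        sens = "n/a" if self.sensitivity is None else f"{self.sensitivity:.4f}"
        return (
            f"TP={self.tp} FN={self.fn} FP={self.fp} TN={self.tn} "
            f"sensitivity={sens} specificity={self.specificity:.4f}"
        )


def _norm_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    pos, ref, alt = normalize_variant(pos, ref, alt)
    return (chrom, pos, ref, alt)


def benchmark_calls(
    calls: Iterable[VariantCall] | pd.DataFrame,
    truth: TruthSet,
    target_positions_in_truth_space: set[tuple[str, int]] | None = None,
) -> BenchmarkResult:
    """Score calls against the truth set.

    ``calls`` may be :class:`VariantCall` objects or a call table with
    columns ``chrom, pos, ref, allele`` (the vectorized caller output).
    Both representations are normalized before matching, so equivalent
    indel spellings compare equal and ordering is irrelevant.
    """
    if isinstance(calls, pd.DataFrame):
        call_keys = {
            _norm_key(c, int(p), r, a)
            for c, p, r, a in zip(calls["chrom"], calls["pos"], calls["ref"], calls["allele"])
        }
    else:
        call_keys = {_norm_key(c.chrom, c.pos, c.ref, c.alt) for c in calls}

    truth_keys = {v.normalized_key: v for v in truth.variants}
    truth_positions = {(k[0], k[1]) for k in truth_keys}

    tp_by_type = {"SNV": 0, "indel": 0}
    fn_by_type = {"SNV": 0, "indel": 0}
    for key, variant in truth_keys.items():
        bucket = "SNV" if variant.vtype == SNV else "indel"
        if key in call_keys:
            tp_by_type[bucket] += 1
        else:
            fn_by_type[bucket] += 1
    tp = sum(tp_by_type.values())
    fn = sum(fn_by_type.values())

    fp_keys = {k for k in call_keys if k not in truth_keys}
    fp_positions = {(k[0], k[1]) for k in fp_keys} - truth_positions
    fp = len(fp_positions)

    clean_positions = truth.target_positions - len(truth_positions)
    tn = clean_positions - fp
    if tn < 0:
        raise ValueError("more false-positive positions than truth-free positions")

    def _sens(tp_: int, fn_: int) -> float | None:
        return tp_ / (tp_ + fn_) if (tp_ + fn_) else None

    return BenchmarkResult(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        tp_by_type=tp_by_type,
        fn_by_type=fn_by_type,
        sensitivity=_sens(tp, fn),
        sensitivity_by_type={
            "SNV": _sens(tp_by_type["SNV"], fn_by_type["SNV"]),
            "indel": _sens(tp_by_type["indel"], fn_by_type["indel"]),
        },
        specificity=tn / clean_positions if clean_positions else 1.0,
    )


# ---------------------------------------------------------------------------
# Sample tracking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackingSnp:
    rsid: str
    gene: str
    maf: float

    def __post_init__(self) -> None:
        if not (0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: MAF must be in [0, 0.5], got {self.maf}")


#: Six common SNPs on consistently-reported panel genes used for identity
#: tracking between the NGS pipeline and an orthogonal genotyping platform.
TRACKING_PANEL: tuple[TrackingSnp, ...] = (
    TrackingSnp("rs10864198", "USH2A", 0.4531),
    TrackingSnp("rs7598901", "ALMS1", 0.4736),
    TrackingSnp("rs2228557", "COL4A4", 0.4657),
    TrackingSnp("rs7624750", "OPA1", 0.4683),
    TrackingSnp("rs734312", "WFS1", 0.4633),
    TrackingSnp("rs2438349", "ADGRV1", 0.4830),
)


@dataclass(frozen=True)
class TrackingResult:
    passed: bool
    n_concordant: int
    table: pd.DataFrame  # rsid, gene, ngs, orthogonal, concordant
    message: str


def tracking_concordance(
    ngs_genotypes: Mapping[str, str],
    orthogonal_genotypes: Mapping[str, str],
    panel: Sequence[TrackingSnp] = TRACKING_PANEL,
) -> TrackingResult:
    """Compare genotypes at the tracking panel between two platforms.

    Genotypes are unordered diploid strings like ``"A/G"``.  Pass requires
    concordance at all panel SNPs; any mismatch fails with a sample-swap
    warning.  A SNP missing from either set is an error naming it.
    """
    rows = []
    n_ok = 0
    for snp in panel:
        missing = [
            side
            for side, genotypes in (("NGS", ngs_genotypes), ("orthogonal", orthogonal_genotypes))
            if snp.rsid not in genotypes
        ]
        if missing:
            raise KeyError(f"genotype for {snp.rsid} missing from: {', '.join(missing)}")
        g1 = _canonical_genotype(ngs_genotypes[snp.rsid])
        g2 = _canonical_genotype(orthogonal_genotypes[snp.rsid])
        ok = g1 == g2
        n_ok += ok
        rows.append((snp.rsid, snp.gene, g1, g2, ok))
    table = pd.DataFrame(rows, columns=["rsid", "gene", "ngs", "orthogonal", "concordant"])
    passed = n_ok == len(panel)
    message = (
        "all tracking SNPs concordant"
        if passed
        else f"IDENTITY-SWAP WARNING: {len(panel) - n_ok} discordant tracking SNP(s)"
    )
    return TrackingResult(passed=passed, n_concordant=n_ok, table=table, message=message)


def _canonical_genotype(genotype: str) -> str:
    alleles = sorted(genotype.replace("|", "/").split("/"))
    return "/".join(alleles)


def genotype_match_probability(maf: float) -> float:
    """HWE probability that two unrelated samples share a genotype at a
    biallelic SNP with minor-allele frequency ``maf``."""
    p, q = maf, 1 - maf
    return (p * p) ** 2 + (2 * p * q) ** 2 + (q * q) ** 2


def expected_full_concordance_probability(
    panel: Sequence[TrackingSnp] = TRACKING_PANEL,
) -> float:
    """HWE probability that two unrelated samples agree at every panel SNP
    (the chance of a sample swap going unnoticed)."""
    return float(np.prod([genotype_match_probability(s.maf) for s in panel]))
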
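"""Per-target copy-number detection against a pooled background.

Evidence layers, computed on a shared target set:

1. **Normalized read depth.**  Each sample's per-target counts are divided
   by the sample median (library-size normalization); the test sample's
   normalized profile is divided by the per-target median of the background
   profiles and log2-transformed.  Expected values: 0 for two copies, -1
   for a heterozygous deletion, log2(3/2) = +0.585 for a three-copy gain.
2. **Zero coverage.**  Maximal runs of targets with essentially no reads in
   the test sample but proper coverage in the background flag homozygous
   deletions (copy number 0), which depth ratios alone represent poorly.
3. **Allelic imbalance.**  B-allele fractions of constitutionally
   heterozygous SNPs shift away from 0.5 under copy-number change (to 1/3
   or 2/3 at three copies) and disappear entirely in deleted regions.
   Imbalance is confirmatory: it annotates confidence but never vetoes a
   depth call.

Segmentation is rule-based merging of adjacent same-state targets within a
gene; panel targets are exon-sized and sparse, so no HMM/CBS machinery is
used.  GC-content correction is not implemented (the simulator injects no
GC bias); this is a documented gap for real capture data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CnvParams:
    het_del_log2_max: float = -0.6   # midway between log2(1/2) and log2(2/2)
    dup_log2_min: float = 0.42       # midway between log2(2/2) and log2(3/2)
    hom_del_depth_max: int = 2       # raw reads at or below which a target is "zero"
    proper_coverage_floor: int = 50  # background median needed to trust a zero
    min_targets_per_call: int = 1
    baf_imbalance_alpha: float = 0.01
    background_min_samples: int = 8

    def __post_init__(self) -> None:
        if not (self.het_del_log2_max < 0 < self.dup_log2_min):
            raise ValueError("thresholds must satisfy het_del_log2_max < 0 < dup_log2_min")


@dataclass
class CnvCall:
    gene: str
    first_target: str
    last_target: str
    n_targets: int
    state: int  # copy number in {0, 1, 3}
    mean_log2_ratio: float
    evidence: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.state not in (0, 1, 3):
            raise ValueError(f"state must be 0, 1 or 3, got {self.state}")
        if self.state == 0 and "zero_coverage" not in self.evidence and not (
            self.mean_log2_ratio <= -3
        ):
            raise ValueError("CN=0 requires zero_coverage evidence or mean log2 <= -3")


class BackgroundError(ValueError):
    """The pooled background does not satisfy the preconditions."""


def _check_background(background: pd.DataFrame, params: CnvParams) -> None:
    if background.shape[1] < params.background_min_samples:
        raise BackgroundError(
            f"background has {background.shape[1]} samples; "
            f"at least {params.background_min_samples} required"
        )


def normalize_depth(
    sample: pd.Series, background: pd.DataFrame, params: CnvParams = CnvParams()
) -> pd.Series:
    """Per-target log2 ratio of the sample against the pooled background.

    ``sample`` is indexed by target id; ``background`` is targets x samples
    on the same index.  Targets whose background median (after per-sample
    median normalization) is zero are masked (NaN).  A zero sample count at
    an unmasked target yields ``-inf``.
    """
    _check_background(background, params)
    if not sample.index.equals(background.index):
        raise ValueError("sample and background must share the same target index")
    sample_med = float(sample.median())
    if sample_med <= 0:
        raise ValueError("sample median count is zero; cannot normalize")
    bg_rel = background.div(background.median(axis=0), axis=1)
    bg_profile = bg_rel.median(axis=1)
    rel = (sample / sample_med) / bg_profile
    with np.errstate(divide="ignore"):
        log2r = np.log2(rel.to_numpy(dtype=float))
    log2r[bg_profile.to_numpy() <= 0] = np.nan
    return pd.Series(log2r, index=sample.index, name="log2_ratio")


@dataclass(frozen=True)
class ZeroCoverageCandidate:
    gene: str
    first_target: str
    last_target: str
    targets: tuple[str, ...]


def detect_zero_coverage(
    sample: pd.Series,
    background: pd.DataFrame,
    targets: pd.DataFrame,
    params: CnvParams = CnvParams(),
) -> list[ZeroCoverageCandidate]:
    """Homozygous-deletion candidates: maximal runs of targets (within a
    gene, in target order) where the sample has <= ``hom_del_depth_max``
    raw reads while the raw background median is at or above the
    proper-coverage floor.

    ``targets`` is a DataFrame indexed like ``sample`` with a ``gene``
    column; row order defines target order.
    """
    _check_background(background, params)
    bg_median = background.median(axis=1)
    is_zero = (sample <= params.hom_del_depth_max) & (
        bg_median >= params.proper_coverage_floor
    )
    candidates: list[ZeroCoverageCandidate] = []
    for gene, idx in targets.groupby("gene", sort=False).groups.items():
        run: list[str] = []
        for tid in idx:
            if bool(is_zero.loc[tid]):
                run.append(tid)
            else:
                if run:
                    candidates.append(ZeroCoverageCandidate(gene, run[0], run[-1], tuple(run)))
                run = []
        if run:
            candidates.append(ZeroCoverageCandidate(gene, run[0], run[-1], tuple(run)))
    return candidates


@dataclass(frozen=True)
class ImbalanceVerdict:
    verdict: str  # "balanced" | "imbalanced" | "uninformative" | "supports_deletion"
    p_value: float | None = None
    n_snps: int = 0


def allelic_imbalance(
    bafs: Sequence[float],
    depths: Sequence[int],
    params: CnvParams = CnvParams(),
    n_targets: int | None = None,
    expected_hets_per_target: float | None = None,
) -> ImbalanceVerdict:
    """Test heterozygous-SNP B-allele fractions in a region against 0.5.

    Each SNP gets a two-sided binomial test of its B-allele read count at
    p = 0.5; per-SNP p-values are combined with Fisher's method and the
    region is *imbalanced* when the combined test rejects at
    ``baf_imbalance_alpha``.

    With zero heterozygous SNPs the verdict is *uninformative* -- unless the
    region is long enough that seeing no het SNP is itself unlikely: when
    ``n_targets`` and ``expected_hets_per_target`` (the background het
    density) are given and the Poisson probability of observing zero hets
    falls below alpha, the verdict is *supports_deletion* (loss of
    heterozygosity).
    """
    if len(bafs) != len(depths):
        raise ValueError("bafs and depths must have equal length")
    if len(bafs) == 0:
        if n_targets and expected_hets_per_target:
            p_zero = float(np.exp(-expected_hets_per_target * n_targets))
            if p_zero < params.baf_imbalance_alpha:
                return ImbalanceVerdict("supports_deletion", p_value=p_zero, n_snps=0)
        return ImbalanceVerdict("uninformative", n_snps=0)
    pvals = []
    for baf, depth in zip(bafs, depths):
        b_count = int(round(baf * depth))
        pvals.append(stats.binomtest(b_count, depth, 0.5).pvalue)
    combined = stats.combine_pvalues(pvals, method="fisher").pvalue
    verdict = "imbalanced" if combined < params.baf_imbalance_alpha else "balanced"
    return ImbalanceVerdict(verdict, p_value=float(combined), n_snps=len(bafs))


def call_cnv(
    log2_ratios: pd.Series,
    zero_candidates: Sequence[ZeroCoverageCandidate],
    targets: pd.DataFrame,
    params: CnvParams = CnvParams(),
    imbalance: Mapping[str, ImbalanceVerdict] | None = None,
    expected_cn: pd.Series | None = None,
) -> list[CnvCall]:
    """Integrate the evidence layers into copy-number calls.

    Per-target states: CN=0 from zero-coverage candidates; CN=1 where the
    (baseline-adjusted) log2 ratio <= ``het_del_log2_max``; CN=3 where it
    >= ``dup_log2_min``.  Adjacent same-state targets within a gene merge
    into one call.  ``expected_cn`` (per target, default 2) shifts the
    baseline for loci with a different constitutive copy number, e.g. 1 for
    male X targets against a sex-matched diploid-equivalent background.
    Imbalance verdicts (keyed by gene) only annotate evidence.
    """
    imbalance = imbalance or {}
    adj = log2_ratios.copy().astype(float)
    if expected_cn is not None:
        adj = adj - np.log2(expected_cn.reindex(adj.index).fillna(2) / 2.0)
    zero_targets = {t for cand in zero_candidates for t in cand.targets}

    calls: list[CnvCall] = []
    for gene, idx in targets.groupby("gene", sort=False).groups.items():
        run_state: int | None = None
        run: list[str] = []

        def flush() -> None:
            nonlocal run, run_state
            if run_state in (0, 1, 3) and len(run) >= params.min_targets_per_call:
                values = adj.loc[list(run)].to_numpy(dtype=float)
                mean_l2 = float(np.mean(values)) if len(values) else float("nan")
                evidence = {"zero_coverage"} if run_state == 0 else {"depth"}
                verdict = imbalance.get(gene)
                if verdict is not None and verdict.verdict in ("imbalanced", "supports_deletion"):
                    evidence.add("allelic_imbalance")
                calls.append(
                    CnvCall(
                        gene=gene,
                        first_target=run[0],
                        last_target=run[-1],
                        n_targets=len(run),
                        state=run_state,
                        mean_log2_ratio=mean_l2,
                        evidence=evidence,
                    )
                )
            run, run_state = [], None

        for tid in idx:
            value = adj.loc[tid]
            if tid in zero_targets:
                state = 0
            elif np.isnan(value):
                state = None  # masked target: breaks runs, never calls
            elif value <= params.het_del_log2_max:
                state = 1
            elif value >= params.dup_log2_min:
                state = 3
            else:
                state = 2
            if state != run_state:
                flush()
                run_state = state
            if state in (0, 1, 3):
                run.append(tid)
        flush()

    _check_no_overlap(calls)
    return calls


def _check_no_overlap(calls: Sequence[CnvCall]) -> None:
    seen: dict[tuple[str, str], int] = {}
    for call in calls:
        for tid in (call.first_target, call.last_target):
            key = (call.gene, tid)
            if key in seen and seen[key] != call.state:
                raise RuntimeError(
                    f"contradictory overlapping CNV calls at {key}; this is a bug"
                )
            seen[key] = call.state
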
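"""Homology-aware safeguards for pseudogene-affected panel regions.

Some panel genes (classically STRC with its pSTRC pseudogene, and OTOA)
have near-identical counterparts elsewhere in the genome.  Short reads from
the counterpart misalign into the gene, depressing unique coverage and
injecting counterfeit ("bleed-through") variants.  Three safeguards:

* *Conflictive regions*: target regions whose DP20 callability is below
  100% in strictly more than half the cohort are systematically
  under-covered and flagged.
* Variant calls inside conflictive regions that are annotated as homologous
  (having a high-identity counterpart) are flagged
  ``needs_orthogonal_confirmation``; triage refuses to count them as
  causative until a confirmation record (e.g. long-range PCR + Sanger) is
  supplied.
* A variant recurring in >= 90% of cohort samples inside a homologous
  region is almost certainly the counterpart's reference sequence bleeding
  through, not a real variant, and is marked ``suspected_bleed_through``.

Homology annotation (which intervals have counterparts) is supplied as an
input interval table; genome self-alignment is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import FLAG_BLEED_THROUGH, FLAG_NEEDS_CONFIRMATION, VariantCall


@dataclass(frozen=True)
class HomologyParams:
    dp_threshold: int = 20
    sample_fraction: float = 0.5      # strictly more than this fraction of samples
    bleed_through_fraction: float = 0.9
    min_cohort_for_bleed_through: int = 10

    def __post_init__(self) -> None:
        for name in ("sample_fraction", "bleed_through_fraction"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {value}")


@dataclass(frozen=True)
class ConflictiveRegion:
    region_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    genes: tuple[str, ...]
    homologous: bool = False
    counterpart: str | None = None
    affected_fraction: float = 0.0  # fraction of samples with callability < 1

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based position containment."""
        return chrom == self.chrom and self.start < pos <= self.end


def find_conflictive_regions(
    callability: pd.DataFrame,
    regions: pd.DataFrame,
    params: HomologyParams = HomologyParams(),
) -> list[ConflictiveRegion]:
    """Identify systematically under-covered regions across a cohort.

    ``callability`` is a samples x regions matrix of DP20 callability
    fractions (columns = region ids).  ``regions`` describes each region id
    (columns ``chrom, start, end, gene`` and optionally ``counterpart`` --
    a non-empty counterpart marks the region as homologous), indexed by
    region id.  A region is conflictive iff its callability is < 1.0 in
    strictly more than ``sample_fraction`` of the samples.
    """
    if callability.shape[0] == 0:
        raise ValueError("empty cohort: no samples in callability matrix")
    out: list[ConflictiveRegion] = []
    for region_id in callability.columns:
        frac = float((callability[region_id] < 1.0).mean())
        if frac > params.sample_fraction:
            meta = regions.loc[region_id]
            counterpart = meta.get("counterpart", None)
            if isinstance(counterpart, float) and pd.isna(counterpart):
                counterpart = None
            gene = meta["gene"]
            genes = tuple(gene) if isinstance(gene, (list, tuple)) else (str(gene),)
            out.append(
                ConflictiveRegion(
                    region_id=str(region_id),
                    chrom=str(meta["chrom"]),
                    start=int(meta["start"]),
                    end=int(meta["end"]),
                    genes=genes,
                    homologous=bool(counterpart),
                    counterpart=counterpart or None,
                    affected_fraction=frac,
                )
            )
    return out


def flag_homology_variants(
    calls: Sequence[VariantCall], regions: Sequence[ConflictiveRegion]
) -> list[VariantCall]:
    """Flag calls inside *homologous* conflictive regions for orthogonal
    confirmation; calls in non-homologous conflictive regions only get a
    ``low_callability_region`` annotation."""
    for call in calls:
        for region in regions:
            if not region.contains(call.chrom, call.pos):
                continue
            if region.homologous:
                call.flags.add(FLAG_NEEDS_CONFIRMATION)
            else:
                call.flags.add("low_callability_region")
    return list(calls)


def detect_bleed_through(
    cohort_calls: Mapping[str, Sequence[VariantCall]],
    regions: Sequence[ConflictiveRegion],
    params: HomologyParams = HomologyParams(),
) -> list[tuple[tuple[str, int, str, str], float]]:
    """Find variants inside homologous regions recurring across the cohort.

    ``cohort_calls`` maps sample id -> calls.  A variant present in at
    least ``bleed_through_fraction`` of all samples inside a homologous
    region is marked ``suspected_bleed_through`` on every carrying call.
    Returns the suspected variant keys with their cohort fractions.
    """
    n_samples = len(cohort_calls)
    if n_samples < params.min_cohort_for_bleed_through:
        raise ValueError(
            f"cohort of {n_samples} samples is too small for bleed-through "
            f"screening (need >= {params.min_cohort_for_bleed_through})"
        )
    homologous = [r for r in regions if r.homologous]
    carriers: dict[tuple[str, int, str, str], set[str]] = {}
    for sample, calls in cohort_calls.items():
        for call in calls:
            if any(r.contains(call.chrom, call.pos) for r in homologous):
                carriers.setdefault(call.key, set()).add(sample)
    suspected: list[tuple[tuple[str, int, str, str], float]] = []
    for key, samples in carriers.items():
        fraction = len(samples) / n_samples
        if fraction >= params.bleed_through_fraction:
            suspected.append((key, fraction))
            for calls in cohort_calls.values():
                for call in calls:
                    if call.key == key:
                        call.flags.add(FLAG_BLEED_THROUGH)
    return sorted(suspected)
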
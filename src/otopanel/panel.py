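"""Panel definition, target-region model and coverage/callability QC.

A diagnostic panel is an ordered collection of genes, each assigned to an
evidence tier (tier 1: strong/moderate disease association, routinely
reported; tier 2: weak/preliminary association, reported only on phenotype
match), a reference transcript and one or more inheritance modes.

Coordinate conventions are centralized here: target regions are 0-based,
half-open (BED); per-position records (depth tracks, pileups, variants) are
1-based (VCF).  :func:`target_positions` is the single conversion point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

VALID_TIERS = (1, 2)
VALID_MODES = ("AR", "AD", "XR", "XD", "MT", "de-novo-AD")
VALID_CHROM_CLASSES = ("autosome", "X", "MT")

DEFAULT_CALLABILITY_THRESHOLDS = (10, 20, 50, 100)


class PanelValidationError(ValueError):
    """Raised when a panel configuration violates its invariants."""


@dataclass(frozen=True)
class PanelGene:
    """One gene of the diagnostic panel."""

    symbol: str
    tier: int
    transcript: str
    inheritance_modes: tuple[str, ...]
    phenotypes: tuple[str, ...] = ()
    chrom_class: str = "autosome"

    def __post_init__(self) -> None:
        if self.tier not in VALID_TIERS:
            raise PanelValidationError(
                f"gene {self.symbol}: tier must be one of {VALID_TIERS}, got {self.tier!r}"
            )
        if not self.inheritance_modes:
            raise PanelValidationError(f"gene {self.symbol}: inheritance_modes is empty")
        for mode in self.inheritance_modes:
            if mode not in VALID_MODES:
                raise PanelValidationError(
                    f"gene {self.symbol}: unknown inheritance mode {mode!r}"
                )
        if self.chrom_class not in VALID_CHROM_CLASSES:
            raise PanelValidationError(
                f"gene {self.symbol}: unknown chrom_class {self.chrom_class!r}"
            )

    @property
    def syndromic_phenotypes(self) -> tuple[str, ...]:
        return tuple(p for p in self.phenotypes if _is_syndromic(p))

    @property
    def nonsyndromic_phenotypes(self) -> tuple[str, ...]:
        return tuple(p for p in self.phenotypes if not _is_syndromic(p))


def _is_syndromic(phenotype: str) -> bool:
    low = phenotype.lower()
    return "syndrome" in low and "non-syndromic" not in low


class PanelDefinition:
    """Ordered, validated collection of :class:`PanelGene`."""

    def __init__(self, genes: Iterable[PanelGene], version: str = "v3") -> None:
        self.version = version
        self._genes: dict[str, PanelGene] = {}
        for gene in genes:
            if gene.symbol in self._genes:
                raise PanelValidationError(f"duplicate gene symbol {gene.symbol!r}")
            self._genes[gene.symbol] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[PanelGene]:
        return iter(self._genes.values())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __getitem__(self, symbol: str) -> PanelGene:
        try:
            return self._genes[symbol]
        except KeyError:
            raise KeyError(f"gene {symbol!r} is not on the panel") from None

    def tier_counts(self) -> dict[int, int]:
        counts = {t: 0 for t in VALID_TIERS}
        for gene in self:
            counts[gene.tier] += 1
        return counts

    def symbols(self, tier: int | None = None) -> list[str]:
        return [g.symbol for g in self if tier is None or g.tier == tier]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "genes": [
                {
                    "symbol": g.symbol,
                    "tier": g.tier,
                    "transcript": g.transcript,
                    "inheritance_modes": list(g.inheritance_modes),
                    "phenotypes": list(g.phenotypes),
                    "chrom_class": g.chrom_class,
                }
                for g in self
            ],
        }


def load_panel(source: str | Path | Mapping) -> PanelDefinition:
    """Load and validate a panel from a YAML document or an equivalent mapping.

    The document has a ``version`` tag and a ``genes`` list; each record
    carries ``symbol``, ``tier``, ``transcript``, ``inheritance_modes`` and
    optionally ``phenotypes`` and ``chrom_class``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    doc = doc or {}
    genes = [
        PanelGene(
            symbol=rec["symbol"],
            tier=int(rec["tier"]),
            transcript=rec.get("transcript", ""),
            inheritance_modes=tuple(rec["inheritance_modes"]),
            phenotypes=tuple(rec.get("phenotypes", ())),
            chrom_class=rec.get("chrom_class", "autosome"),
        )
        for rec in doc.get("genes", [])
    ]
    return PanelDefinition(genes, version=doc.get("version", "unversioned"))


def load_builtin_panel() -> PanelDefinition:
    """Load the packaged v3 panel fixture (199 genes)."""
    ref = resources.files("otopanel.data").joinpath("panel_v3.yaml")
    with resources.as_file(ref) as path:
        return load_panel(path)


# ---------------------------------------------------------------------------
# Target regions and callability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetRegion:
    """A captured target interval, 0-based half-open (BED convention)."""

    chrom: str
    start: int
    end: int
    gene: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"target {self.label or self.gene}: start must be < end "
                f"({self.start} >= {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def target_positions(region: TargetRegion) -> range:
    """1-based positions covered by a 0-based half-open target region."""
    return range(region.start + 1, region.end + 1)


def read_targets_bed(path: str | Path) -> list[TargetRegion]:
    """Read targets from a BED file with columns chrom, start, end, gene, label."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene", "label", "strand"],
        usecols=range(5),
        dtype={"chrom": str, "gene": str, "label": str},
    )
    return [
        TargetRegion(r.chrom, int(r.start), int(r.end), r.gene, "" if pd.isna(r.label) else str(r.label))
        for r in df.itertuples()
    ]


def write_targets_bed(targets: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t{t.label}\n")


class DepthTrackError(ValueError):
    """A target base is missing from the depth track."""


def _depth_lookup(depth_track: pd.DataFrame) -> dict[tuple[str, int], int]:
    required = {"chrom", "pos", "depth"}
    missing = required - set(depth_track.columns)
    if missing:
        raise ValueError(f"depth track lacks columns: {sorted(missing)}")
    return {
        (c, int(p)): int(d)
        for c, p, d in zip(depth_track["chrom"], depth_track["pos"], depth_track["depth"])
    }


def _gene_depths(
    targets: Sequence[TargetRegion], lookup: Mapping[tuple[str, int], int]
) -> dict[str, list[int]]:
    by_gene: dict[str, list[int]] = {}
    for region in targets:
        depths = by_gene.setdefault(region.gene, [])
        for pos in target_positions(region):
            key = (region.chrom, pos)
            if key not in lookup:
                raise DepthTrackError(
                    f"no depth for {region.chrom}:{pos} in target "
                    f"{region.gene}/{region.label or '?'} ({region.chrom}:{region.start}-{region.end})"
                )
            depths.append(lookup[key])
    return by_gene


def compute_callability(
    depth_track: pd.DataFrame,
    targets: Sequence[TargetRegion],
    thresholds: Sequence[int] = DEFAULT_CALLABILITY_THRESHOLDS,
) -> pd.DataFrame:
    """Per-gene callability: fraction of target bases with depth >= t.

    ``depth_track`` has columns ``chrom, pos, depth`` (``pos`` 1-based) for a
    single sample.  Returns a DataFrame indexed by gene with one ``dp{t}``
    column per threshold.  Genes whose targets cover zero bases are excluded
    with a warning.
    """
    lookup = _depth_lookup(depth_track)
    by_gene = _gene_depths(targets, lookup)
    rows = {}
    for gene, depths in by_gene.items():
        if not depths:
            warnings.warn(f"gene {gene} has no target bases; excluded from callability")
            continue
        arr = pd.Series(depths)
        rows[gene] = {f"dp{t}": float((arr >= t).mean()) for t in thresholds}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


def region_callability(
    depth_track: pd.DataFrame,
    targets: Sequence[TargetRegion],
    threshold: int = 20,
) -> pd.Series:
    """Per-target-region callability at one depth threshold, indexed by label."""
    lookup = _depth_lookup(depth_track)
    values = {}
    for region in targets:
        depths = []
        for pos in target_positions(region):
            key = (region.chrom, pos)
            if key not in lookup:
                raise DepthTrackError(
                    f"no depth for {region.chrom}:{pos} in target {region.gene}/{region.label or '?'}"
                )
            depths.append(lookup[key])
        values[region.label or f"{region.gene}:{region.start}-{region.end}"] = float(
            pd.Series(depths).ge(threshold).mean()
        )
    return pd.Series(values, name=f"dp{threshold}")


@dataclass(frozen=True)
class LowCoverageRegion:
    gene: str
    label: str
    chrom: str
    positions: tuple[int, ...]  # 1-based positions with depth below threshold


def low_coverage_report(
    depth_track: pd.DataFrame,
    targets: Sequence[TargetRegion],
    threshold: int = 20,
    tiers: Mapping[str, int] | None = None,
    tier: int | None = 1,
) -> list[LowCoverageRegion]:
    """List target regions with callability < 1.0 at ``threshold`` and the
    exact 1-based positions below it.

    When ``tiers`` (gene -> tier) and ``tier`` are given, only genes of that
    tier are screened (per-patient reports list tier-1 shortfalls).
    """
    lookup = _depth_lookup(depth_track)
    report: list[LowCoverageRegion] = []
    for region in targets:
        if tiers is not None and tier is not None and tiers.get(region.gene) != tier:
            continue
        low = []
        for pos in target_positions(region):
            key = (region.chrom, pos)
            if key not in lookup:
                raise DepthTrackError(
                    f"no depth for {region.chrom}:{pos} in target {region.gene}/{region.label or '?'}"
                )
            if lookup[key] < threshold:
                low.append(pos)
        if low:
            report.append(
                LowCoverageRegion(region.gene, region.label, region.chrom, tuple(low))
            )
    return report
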
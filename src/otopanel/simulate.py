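"""Synthetic sequencing-level inputs with recorded seeds and emitted truth.

Three generators:

* :func:`simulate_mixture` -- the analytical-validation specimen: DNA from
  ``n_individuals`` (default 10) genotyped individuals pooled in equimolar
  amounts and sequenced to high depth.  Each truth variant is carried by
  ``k`` of the 2N haplotypes, so its mixture allele fraction is k/2N; the
  emitted truth set holds every variant with AF >= min_carrier/2N.  Depth is
  per-pseudo-target lognormal (capture efficiency) times Poisson (sampling);
  alternate reads at a truth locus are Binomial(depth, AF(1-e) + (1-AF)e/3)
  and sequencing errors elsewhere put Binomial(depth, e/3) reads on each of
  the three non-reference bases.

* :func:`simulate_patient` -- one sample plus a pooled background cohort of
  per-target read counts, with copy-number events injected by scaling the
  event targets' expected counts by CN/2 (0 for CN=0) and shifting the
  B-allele fractions of constitutionally heterozygous SNPs to CN-consistent
  expectations (1/3 or 2/3 at CN=3; het SNPs vanish in deleted regions).

* :func:`build_table_fixtures` -- the curated 50-case cohort fixture
  (packaged YAML) as ready-to-triage :class:`~otopanel.triage.CaseRecord`
  objects.

The same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .caller import PileupColumn
from .qc import TruthSet, TruthVariant
from .triage import AnnotationRecord, CaseRecord, CaseVariant

BASES = np.array(["A", "C", "G", "T"])
CONTIG = "panel"


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults mirror the analytical-validation design: a 10-genome
    equimolar mixture carrying 1624 truth variants (121 of them indels)
    over a ~1.03 M-position target space at mean depth 1000x with a 0.001
    per-base error rate.  ``af_spectrum_beta`` shapes the pool allele
    frequency of truth variants (array-ascertained common polymorphisms);
    ``min_carrier_haplotypes`` enforces the AF >= 0.1 truth-set cut-off."""

    seed: int = 0
    n_individuals: int = 10
    n_truth_variants: int = 1624
    indel_fraction: float = 121 / 1624
    target_space_size: int = 1_034_817
    mean_depth: float = 1000.0
    error_rate: float = 0.001
    depth_dispersion: float = 0.3  # lognormal sigma of per-target capture efficiency
    target_size: int = 120         # bases per pseudo-target
    af_spectrum_beta: tuple[float, float] = (12.0, 12.0)
    min_carrier_haplotypes: int = 2
    het_density_per_kb: float = 0.8

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("mixture needs at least 2 individuals")
        for name in ("indel_fraction", "error_rate"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class MixtureSample:
    """Simulated pooled-specimen pileup plus its emitted truth set."""

    config: SimulationConfig
    truth: TruthSet
    depth: np.ndarray          # per-position filtered depth, index = pos-1
    pileup: pd.DataFrame       # chrom,pos,ref,allele,count,depth (alt rows only)
    ref_codes: np.ndarray      # per-position reference base code 0..3

    def pileup_frame(self) -> pd.DataFrame:
        return self.pileup

    def columns(self, positions: Sequence[int] | None = None) -> Iterator[PileupColumn]:
        """Yield :class:`PileupColumn` objects (small-scale/testing path).

        ``positions`` restricts the stream (1-based); by default every
        position with nonzero depth is yielded, which is only sensible for
        small target spaces.
        """
        by_pos: dict[int, list[tuple[str, str, int]]] = {}
        for pos, ref, allele, count in zip(
            self.pileup["pos"], self.pileup["ref"], self.pileup["allele"], self.pileup["count"]
        ):
            by_pos.setdefault(int(pos), []).append((str(ref), str(allele), int(count)))
        pos_iter = positions if positions is not None else range(1, len(self.depth) + 1)
        for pos in pos_iter:
            depth = int(self.depth[pos - 1])
            if depth == 0:
                continue
            rows = by_pos.get(pos, [])
            # at indel loci the column ref is the anchored multi-base allele
            ref = max((r for r, _, _ in rows), key=len, default=str(BASES[self.ref_codes[pos - 1]]))
            counts = {allele: count for _, allele, count in rows}
            counts[ref] = max(depth - sum(counts.values()), 0)
            yield PileupColumn(CONTIG, pos, ref, counts)


def _draw_carrier_counts(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Carrier haplotype counts k for each truth variant: pool allele
    frequency ~ Beta(af_spectrum_beta), k ~ Binomial(2N, f), redrawn until
    k >= min_carrier_haplotypes (the truth-set AF cut-off)."""
    n_hap = 2 * config.n_individuals
    a, b = config.af_spectrum_beta
    k = np.zeros(config.n_truth_variants, dtype=np.int64)
    todo = np.arange(config.n_truth_variants)
    while todo.size:
        f = rng.beta(a, b, size=todo.size)
        draw = rng.binomial(n_hap, f)
        ok = draw >= config.min_carrier_haplotypes
        k[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return k


def _per_position_depth(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    n = config.target_space_size
    n_targets = (n + config.target_size - 1) // config.target_size
    sigma = config.depth_dispersion
    # capture-efficiency multiplier with mean 1
    mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_targets)
    per_pos_mult = np.repeat(mult, config.target_size)[:n]
    return rng.poisson(config.mean_depth * per_pos_mult).astype(np.int64)


def simulate_mixture(config: SimulationConfig = SimulationConfig()) -> MixtureSample:
    """Simulate the pooled validation specimen and its truth set."""
    rng = np.random.default_rng(config.seed)
    n = config.target_space_size
    n_hap = 2 * config.n_individuals
    e = config.error_rate

    ref_codes = rng.integers(0, 4, size=n, dtype=np.int8)
    depth = _per_position_depth(rng, config)

    loci = np.sort(rng.choice(n, size=config.n_truth_variants, replace=False)) + 1
    k = _draw_carrier_counts(rng, config)
    afs = k / n_hap
    n_indels = int(round(config.indel_fraction * config.n_truth_variants))
    is_indel = np.zeros(config.n_truth_variants, dtype=bool)
    is_indel[rng.choice(config.n_truth_variants, size=n_indels, replace=False)] = True

    # truth alleles
    truth_records: list[TruthVariant] = []
    truth_ref: list[str] = []
    truth_alt: list[str] = []
    for i, pos in enumerate(loci):
        ref_base = str(BASES[ref_codes[pos - 1]])
        if not is_indel[i]:
            others = [b for b in BASES if b != ref_base]
            alt = others[rng.integers(0, 3)]
            ref = ref_base
        else:
            extra = "".join(BASES[rng.integers(0, 4, size=rng.integers(1, 4))])
            if rng.random() < 0.5:  # insertion
                ref, alt = ref_base, ref_base + extra
            else:  # deletion
                ref, alt = ref_base + extra, ref_base
        truth_ref.append(ref)
        truth_alt.append(alt)
        truth_records.append(TruthVariant(CONTIG, int(pos), ref, alt, float(afs[i])))

    # alternate reads at truth loci
    truth_depth = depth[loci - 1]
    p_alt = afs * (1 - e) + (1 - afs) * e / 3
    alt_counts = rng.binomial(truth_depth, p_alt)

    # substitution errors everywhere: three non-reference base slots
    err_counts = rng.binomial(depth[None, :].repeat(3, axis=0), e / 3)

    frames: list[pd.DataFrame] = []
    # error rows (slot j -> j-th non-reference base for the position's ref)
    non_ref = np.array([[b for b in BASES if b != r] for r in BASES])  # 4 x 3
    for j in range(3):
        nz = np.nonzero(err_counts[j])[0]
        if nz.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": CONTIG,
                    "pos": nz + 1,
                    "ref": BASES[ref_codes[nz]],
                    "allele": non_ref[ref_codes[nz], j],
                    "count": err_counts[j, nz],
                    "depth": depth[nz],
                }
            )
        )
    # truth rows (merge with coincident error rows on the same allele)
    nz = np.nonzero(alt_counts)[0]
    frames.append(
        pd.DataFrame(
            {
                "chrom": CONTIG,
                "pos": loci[nz],
                "ref": np.array(truth_ref, dtype=object)[nz],
                "allele": np.array(truth_alt, dtype=object)[nz],
                "count": alt_counts[nz],
                "depth": truth_depth[nz],
            }
        )
    )
    pileup = pd.concat(frames, ignore_index=True)
    pileup = (
        pileup.groupby(["chrom", "pos", "ref", "allele", "depth"], as_index=False, sort=False)[
            "count"
        ]
        .sum()
        .sort_values(["pos", "allele"], kind="mergesort")
        .reset_index(drop=True)
    )[["chrom", "pos", "ref", "allele", "count", "depth"]]
    # an allele's reads can never exceed the column depth
    pileup["count"] = np.minimum(pileup["count"], pileup["depth"])

    truth = TruthSet(tuple(truth_records), target_positions=n)
    return MixtureSample(config=config, truth=truth, depth=depth, pileup=pileup, ref_codes=ref_codes)


# ---------------------------------------------------------------------------
# Patient samples with injected CNV events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvEvent:
    gene: str
    copy_number: int  # 0, 1 or 3
    first_target: int = 0      # 0-based index within the gene's targets
    last_target: int | None = None  # inclusive; None = last

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 3):
            raise ValueError("copy_number must be 0, 1 or 3")


@dataclass
class PatientSample:
    config: SimulationConfig
    targets: pd.DataFrame          # index target_id, column gene
    counts: pd.Series              # test-sample counts per target
    background: pd.DataFrame       # targets x background samples
    het_bafs: Mapping[str, tuple[tuple[float, ...], tuple[int, ...]]]
    truth_events: tuple[CnvEvent, ...]


def simulate_patient(
    config: SimulationConfig = SimulationConfig(),
    events: Sequence[CnvEvent] = (),
    n_genes: int = 50,
    targets_per_gene: int = 10,
    n_background: int = 8,
) -> PatientSample:
    """Simulate per-target read counts for one sample and its background.

    Expected counts at an event target scale by CN/2 (0 at CN=0); elsewhere
    the sample is exchangeable with the background.  Heterozygous-SNP BAFs
    are emitted per gene for the allelic-imbalance check."""
    seen: dict[tuple[str, int], int] = {}
    for event in events:
        last = event.last_target if event.last_target is not None else targets_per_gene - 1
        for t in range(event.first_target, last + 1):
            key = (event.gene, t)
            if key in seen and seen[key] != event.copy_number:
                raise ValueError(f"overlapping contradictory events at {key}")
            seen[key] = event.copy_number

    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    target_ids = [f"{g}_t{t}" for g in genes for t in range(targets_per_gene)]
    targets = pd.DataFrame({"gene": np.repeat(genes, targets_per_gene)}, index=target_ids)

    n_targets = len(target_ids)
    sigma = config.depth_dispersion
    capture = rng.lognormal(-0.5 * sigma**2, sigma, size=n_targets)
    expected = config.mean_depth * capture

    background = pd.DataFrame(
        rng.poisson(expected[:, None], size=(n_targets, n_background)),
        index=target_ids,
        columns=[f"BG{i + 1:02d}" for i in range(n_background)],
    )

    cn = np.full(n_targets, 2, dtype=float)
    gene_cn: dict[str, int] = {}
    for event in events:
        base = genes.index(event.gene) * targets_per_gene if event.gene in genes else None
        if base is None:
            raise ValueError(f"event gene {event.gene} not in simulated target set")
        last = event.last_target if event.last_target is not None else targets_per_gene - 1
        cn[base + event.first_target : base + last + 1] = event.copy_number
        gene_cn[event.gene] = event.copy_number
    counts = pd.Series(
        rng.poisson(expected * cn / 2.0), index=target_ids, name="sample"
    )

    # heterozygous-SNP BAFs per gene
    span_kb = targets_per_gene * config.target_size / 1000.0
    het_bafs: dict[str, tuple[tuple[float, ...], tuple[int, ...]]] = {}
    for gene in genes:
        state = gene_cn.get(gene, 2)
        if state in (0, 1):
            het_bafs[gene] = ((), ())  # hets lost with the allele
            continue
        n_het = rng.poisson(config.het_density_per_kb * span_kb)
        bafs, depths = [], []
        for _ in range(n_het):
            depth = int(rng.poisson(config.mean_depth))
            p = 0.5 if state == 2 else (1 / 3 if rng.random() < 0.5 else 2 / 3)
            bafs.append(rng.binomial(depth, p) / max(depth, 1))
            depths.append(depth)
        het_bafs[gene] = (tuple(bafs), tuple(depths))

    return PatientSample(
        config=config,
        targets=targets,
        counts=counts,
        background=background,
        het_bafs=het_bafs,
        truth_events=tuple(events),
    )


# ---------------------------------------------------------------------------
# Curated cohort fixture
# ---------------------------------------------------------------------------


def build_table_fixtures() -> list[CaseRecord]:
    """The packaged 50-case cohort fixture as CaseRecord objects."""
    ref = resources.files("otopanel.data").joinpath("cohort_cases.yaml")
    with resources.as_file(ref) as path, open(path) as fh:
        doc = yaml.safe_load(fh)
    cases: list[CaseRecord] = []
    for rec in doc["cases"]:
        variants = [
            CaseVariant(
                gene=v["gene"],
                label=v["label"],
                zygosity=v["zygosity"],
                criteria=tuple(v.get("criteria", ())),
                consequence=v.get("consequence", "other"),
                is_cnv=bool(v.get("is_cnv", False)),
                de_novo=bool(v.get("de_novo", False)),
                in_databases=v.get("in_databases"),
                confirmed=v.get("confirmed"),
                needs_confirmation=bool(v.get("needs_confirmation", False)),
                override_class=v.get("override_class"),
                override_justification=v.get("override_justification", ""),
                printed_class=v.get("printed_class"),
            )
            for v in rec.get("variants", ())
        ]
        cases.append(
            CaseRecord(
                case_id=rec["id"],
                sex=rec["sex"],
                phenotype=rec["phenotype"],
                suspected_inheritance=str(rec["suspected_inheritance"]),
                onset=rec.get("onset", "unknown"),
                pre_test_syndromic=bool(rec.get("pre_test_syndromic", False)),
                variants=variants,
                printed_hidden_syndrome=rec.get("printed_hidden_syndrome"),
            )
        )
    if len(cases) != 50:
        raise RuntimeError(f"cohort fixture must hold 50 cases, found {len(cases)}")
    return cases


load_cohort_fixture = build_table_fixtures
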
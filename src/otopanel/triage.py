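"""Interpretation cascade: MAF filtering, inheritance consistency, tiered
reportability and per-case causative-diagnosis assignment.

The cascade mirrors a clinical-panel workflow.  Candidate variants are
first rarity-filtered by class: a 5% population-MAF cut-off for variants
already asserted pathogenic (HGMD-DM or ClinVar P/LP) or predicted to
create a null allele, and a stricter 1% cut-off for all other
protein/RNA-affecting variants; synonymous variants without a splice
consequence are dropped, and a variant with no recorded MAF is treated as
rare (kept).  Variants are then classified with the ACMG combining rules,
checked for consistency with the inheritance mode of the gene they affect
(biallelic for recessive genes, a single allele for dominant genes,
hemizygous male or heterozygous female for X-linked), and routed to the
report: tier-1 class 3-5 reported, tier-1 class 1-2 suppressed (reference
range), tier-2 class 4-5 reported only on phenotype match, and
inheritance-inconsistent class 3-5 variants carried for information only.

A case is *diagnosed* when an inheritance-consistent configuration of
confirmed class 4-5 variants explains the phenotype; a *hidden syndrome* is
flagged when the causative gene's associated phenotypes are exclusively
syndromic while the patient presented as non-syndromic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from . import acmg
from .acmg import AcmgResult, apply_override, classify_tokens
from .panel import PanelDefinition, PanelGene

NULL_CONSEQUENCES = frozenset(
    ["nonsense", "frameshift_ptc", "canonical_splice", "start_loss",
     "exon_deletion", "exon_duplication"]
)
KNOWN_CONSEQUENCES = NULL_CONSEQUENCES | frozenset(
    ["missense", "synonymous", "inframe_indel", "other"]
)

REPORTED = "reported_with_class"
INFORMATIVE_ONLY = "informative_only"
SUPPRESSED = "suppressed"


@dataclass(frozen=True)
class TriageParams:
    maf_cutoff_strict: float = 0.05
    maf_cutoff_default: float = 0.01

    def __post_init__(self) -> None:
        if not self.maf_cutoff_default < self.maf_cutoff_strict:
            raise ValueError("maf_cutoff_default must be < maf_cutoff_strict")


@dataclass(frozen=True)
class AnnotationRecord:
    population_maf: float | None = None  # max MAF across population databases
    hgmd_dm: bool = False
    clinvar_class: str = "none"  # P, LP, VUS, LB, B, none
    consequence: str = "other"
    predictor_scores: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.population_maf is not None and not (0 <= self.population_maf <= 1):
            raise ValueError(f"population_maf out of [0,1]: {self.population_maf}")


def predicted_null(consequence: str) -> bool:
    """True exactly for consequences expected to create a null allele."""
    if consequence in NULL_CONSEQUENCES:
        return True
    if consequence not in KNOWN_CONSEQUENCES:
        warnings.warn(f"unknown consequence {consequence!r}; treated as non-null")
    return False


def maf_filter(annotation: AnnotationRecord, params: TriageParams = TriageParams()) -> bool:
    """Keep/drop decision by population MAF and variant class.

    Returns True to keep.  An absent MAF is treated as 0 (rare).
    """
    if annotation.consequence == "synonymous":
        return False
    maf = annotation.population_maf or 0.0
    strict_class = (
        annotation.hgmd_dm
        or annotation.clinvar_class in ("P", "LP")
        or predicted_null(annotation.consequence)
    )
    cutoff = params.maf_cutoff_strict if strict_class else params.maf_cutoff_default
    return maf < cutoff


# ---------------------------------------------------------------------------
# Case records
# ---------------------------------------------------------------------------


@dataclass
class CaseVariant:
    """A candidate variant of one case, ready for classification."""

    gene: str
    label: str  # HGVS-style description or CNV description
    zygosity: str  # heterozygous | homozygous | hemizygous
    criteria: tuple[str, ...] = ()
    consequence: str = "other"
    is_cnv: bool = False
    de_novo: bool = False
    in_databases: bool | None = None
    confirmed: bool | None = None  # orthogonal confirmation result, None = not attempted
    needs_confirmation: bool = False
    annotation: AnnotationRecord | None = None
    override_class: int | None = None
    override_justification: str = ""
    printed_class: str | None = None  # curated class label carried by fixtures
    acmg: AcmgResult | None = None
    reportability: str | None = None

    def classify(self) -> AcmgResult:
        result = classify_tokens(self.criteria)
        if self.override_class is not None:
            result = apply_override(result, self.override_class, self.override_justification)
        self.acmg = result
        return result

    @property
    def classification(self) -> int:
        if self.acmg is None:
            self.classify()
        return self.acmg.classification

    @property
    def usable_as_causative(self) -> bool:
        """Confirmation gate: a variant flagged for orthogonal confirmation
        may never be cited as causative without a positive record."""
        if self.needs_confirmation:
            return self.confirmed is True
        return self.confirmed is not False


@dataclass(frozen=True)
class Diagnosis:
    genes: tuple[str, ...]
    variant_labels: tuple[str, ...]
    inheritance_pattern: str  # AR | AD | XL
    configuration: str
    hidden_syndrome: str  # yes | potential | no
    includes_cnv: bool
    database_novel: bool


@dataclass
class CaseRecord:
    case_id: str
    sex: str
    phenotype: str
    suspected_inheritance: str
    onset: str = "unknown"
    pre_test_syndromic: bool = False
    variants: list[CaseVariant] = field(default_factory=list)
    diagnosis: Diagnosis | None = None
    printed_hidden_syndrome: str | None = None


# ---------------------------------------------------------------------------
# Inheritance consistency
# ---------------------------------------------------------------------------


def inheritance_consistent(
    gene: PanelGene, variants: Sequence[CaseVariant], sex: str
) -> tuple[bool, str | None]:
    """Check whether the variants in one gene form a configuration
    consistent with the gene's inheritance modes.

    Returns (flag, configuration label).  Compound heterozygotes are
    assumed in trans when phase is unknown.  A heterozygous SNV plus an
    overlapping heterozygous exon/gene deletion (leaving the SNV effectively
    hemizygous) also satisfies a recessive mode.
    """
    if not gene.inheritance_modes:
        raise ValueError(f"gene {gene.symbol} has no inheritance modes")
    if not variants:
        return False, None
    zygs = [v.zygosity for v in variants]
    modes = set(gene.inheritance_modes)

    if gene.chrom_class == "X":
        if "XR" in modes or "XD" in modes:
            if sex == "male" and "hemizygous" in zygs:
                return True, "XL-hemi"
            if "XD" in modes and sex == "female" and any(
                z in ("heterozygous", "homozygous") for z in zygs
            ):
                return True, "XL-het-female"
        return False, None

    if "AR" in modes:
        if "homozygous" in zygs:
            return True, "AR-biallelic"
        # two (assumed trans) non-reference alleles: het SNVs, het CNVs, or a
        # het deletion uncovering a now-hemizygous SNV
        n_alleles = sum(z in ("heterozygous", "hemizygous") for z in zygs)
        if n_alleles >= 2:
            return True, "AR-biallelic"

    if "AD" in modes or "de-novo-AD" in modes:
        if any(z in ("heterozygous", "homozygous") for z in zygs):
            label = "de-novo-AD" if any(v.de_novo for v in variants) else "AD-het"
            return True, label

    return False, None


def assign_reportability(
    variant: CaseVariant,
    gene: PanelGene,
    consistent: bool,
    phenotype_match: bool = False,
) -> str:
    """Route a classified variant to the report.

    Tier 1: class 3-5 reported, class 1-2 suppressed (reference range).
    Tier 2: only class 4-5 with a matching phenotype are reported.
    Class 3-5 variants in an inheritance-inconsistent configuration are
    carried for informative purposes only.
    """
    cls = variant.classification
    if gene.tier == 1:
        if cls <= 2:
            status = SUPPRESSED
        else:
            status = REPORTED if consistent or cls == 3 else INFORMATIVE_ONLY
    else:
        if cls >= 4 and phenotype_match:
            status = REPORTED if consistent else INFORMATIVE_ONLY
        else:
            status = SUPPRESSED
    variant.reportability = status
    return status


# ---------------------------------------------------------------------------
# Diagnosis and cohort summary
# ---------------------------------------------------------------------------


def _hidden_syndrome_status(gene: PanelGene, case: CaseRecord) -> str:
    """yes: gene exclusively syndromic and the patient presented as
    non-syndromic; potential: gene has both syndromic and non-syndromic
    phenotypes; no: otherwise (incl. a pre-test syndromic presentation)."""
    syndromic = gene.syndromic_phenotypes
    nonsyndromic = gene.nonsyndromic_phenotypes
    if case.pre_test_syndromic:
        return "no"
    if syndromic and not nonsyndromic:
        return "yes"
    if syndromic and nonsyndromic:
        return "potential"
    return "no"


def _inheritance_pattern(gene: PanelGene, configuration: str) -> str:
    if gene.chrom_class == "X" or configuration.startswith("XL"):
        return "XL"
    if configuration == "AR-biallelic":
        return "AR"
    return "AD"


def diagnose_case(
    case: CaseRecord,
    panel: PanelDefinition,
    count_vus: bool = False,
) -> CaseRecord:
    """Assign a causative diagnosis when an inheritance-consistent
    configuration of confirmed class 4-5 variants exists.

    ``count_vus`` additionally admits class-3 variants into configurations
    (used for the sensitivity analysis of the diagnostic yield, never for
    reporting).  Variants flagged for orthogonal confirmation qualify only
    with a positive confirmation record.
    """
    min_class = 3 if count_vus else 4
    by_gene: dict[str, list[CaseVariant]] = {}
    for variant in case.variants:
        variant.classify()
        if variant.classification >= min_class and variant.usable_as_causative:
            by_gene.setdefault(variant.gene, []).append(variant)

    causative_genes: list[str] = []
    labels: list[str] = []
    configuration = None
    pattern = None
    hidden = "no"
    includes_cnv = False
    novel = False
    for symbol, variants in by_gene.items():
        gene = panel[symbol]
        ok, config = inheritance_consistent(gene, variants, case.sex)
        if not ok:
            continue
        causative_genes.append(symbol)
        labels.extend(v.label for v in variants)
        if configuration is None:
            configuration = config
            pattern = _inheritance_pattern(gene, config)
            hidden = _hidden_syndrome_status(gene, case)
        includes_cnv = includes_cnv or any(v.is_cnv for v in variants)
        novel = novel or any(v.in_databases is False for v in variants)

    if causative_genes:
        case.diagnosis = Diagnosis(
            genes=tuple(causative_genes),
            variant_labels=tuple(labels),
            inheritance_pattern=pattern,
            configuration=configuration,
            hidden_syndrome=hidden,
            includes_cnv=includes_cnv,
            database_novel=novel,
        )
    else:
        case.diagnosis = None
    return case


@dataclass(frozen=True)
class DiagnosisSummary:
    n_cases: int
    n_diagnosed: int
    yield_percent: float
    n_diagnosed_with_vus: int
    yield_percent_with_vus: float
    inheritance_breakdown: Mapping[str, int]
    inheritance_percent: Mapping[str, float]
    cnv_cases: int
    hidden_syndrome_cases: int
    database_novel_cases: int
    causative_genes: tuple[str, ...]

    @property
    def n_causative_genes(self) -> int:
        return len(self.causative_genes)


def summarize_cohort(cases: Sequence[CaseRecord], panel: PanelDefinition) -> DiagnosisSummary:
    """Cohort-level diagnostic-yield statistics.

    The primary yield counts only class 4-5 diagnoses; a secondary figure
    reports the yield had suspicious VUS configurations been counted.
    Percentage breakdowns are over diagnosed cases.
    """
    if not cases:
        raise ValueError("empty cohort")
    diagnosed: list[CaseRecord] = []
    for case in cases:
        diagnose_case(case, panel, count_vus=False)
        if case.diagnosis is not None:
            diagnosed.append(case)

    n_with_vus = 0
    for case in cases:
        probe = diagnose_case(
            CaseRecord(
                case_id=case.case_id,
                sex=case.sex,
                phenotype=case.phenotype,
                suspected_inheritance=case.suspected_inheritance,
                onset=case.onset,
                pre_test_syndromic=case.pre_test_syndromic,
                variants=list(case.variants),
            ),
            panel,
            count_vus=True,
        )
        if probe.diagnosis is not None:
            n_with_vus += 1
        # re-derive the strict diagnosis clobbered by the probe run
        diagnose_case(case, panel, count_vus=False)

    breakdown = {"AR": 0, "AD": 0, "XL": 0}
    genes: set[str] = set()
    cnv_cases = hidden = novel = 0
    for case in diagnosed:
        d = case.diagnosis
        breakdown[d.inheritance_pattern] += 1
        genes.update(d.genes)
        cnv_cases += d.includes_cnv
        hidden += d.hidden_syndrome == "yes"
        novel += d.database_novel

    n, nd = len(cases), len(diagnosed)
    pct = {k: (100.0 * v / nd if nd else 0.0) for k, v in breakdown.items()}
    return DiagnosisSummary(
        n_cases=n,
        n_diagnosed=nd,
        yield_percent=100.0 * nd / n,
        n_diagnosed_with_vus=n_with_vus,
        yield_percent_with_vus=100.0 * n_with_vus / n,
        inheritance_breakdown=breakdown,
        inheritance_percent=pct,
        cnv_cases=cnv_cases,
        hidden_syndrome_cases=hidden,
        database_novel_cases=novel,
        causative_genes=tuple(sorted(genes)),
    )
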
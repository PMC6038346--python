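# Methods

## Scope and data model

The package implements the computational core of a targeted gene-panel
workflow for hereditary sensorineural hearing loss, starting from
alignment-level evidence (per-position allele counts, per-target read
counts) and ending at cohort-level diagnostic statistics.  Read
generation, alignment and duplicate removal are upstream and out of
scope; annotations (population MAF, database assertions, consequence,
predictor scores) are consumed as inputs, never recomputed.

Coordinate conventions: target regions are 0-based half-open (BED);
per-position records are 1-based (VCF).  Conversion happens in one place
(`panel.target_positions`).

## SNV/indel calling

A pileup column carries only reads passing the base-quality (≥ 20) and
mapping-quality (≥ 30) cutoffs, and the VAF denominator is that filtered
depth — quality filtering gates the evidence, not a post-hoc annotation.
A call is emitted for every non-reference allele with depth ≥ 6,
alternate count ≥ 3 and VAF ≥ 0.1, all comparisons inclusive.
Multi-allelic columns are evaluated per allele; two alleles at one site
may both be called.  Calls passing these permissive thresholds but
failing the stricter reportability gate (depth ≥ 10, alternate reads
≥ 4) keep a `low_confidence` flag rather than being dropped, so manual
review can rescue borderline events (e.g. long indels with
underestimated frequencies).

Indels are represented VCF-anchored and reduced to a parsimonious
left-trimmed form; full left-alignment against a reference sequence is
not attempted because the package's own generators emit anchored
representations.

Zygosity: diploid loci are called homozygous at VAF ≥ 0.80, a threshold
at which the binomial heterozygous (p = 0.5) and homozygous (p ≈ 1)
read-fraction distributions have negligible overlap for depth ≥ 20.
Male X calls are hemizygous regardless of VAF; mitochondrial variants
get no zygosity (heteroplasmy quantification is out of scope).

## CNV calling

Per-target counts are library-size normalized (division by the sample
median), and the test profile is divided by the per-target median of the
normalized background profiles; the log2 of that ratio is ~0 at two
copies, −1 at one copy and log2(3/2) ≈ +0.585 at three.  Decision
thresholds sit midway between those expectations: ≤ −0.6 for a
single-copy loss, ≥ +0.42 for a gain.  Median-of-ratios normalization is
robust to outlier background samples and makes the ratios exactly
invariant to rescaling a sample's counts.  A background needs at least
8 samples; targets whose background median is zero are masked.

Homozygous deletions are detected separately as maximal runs of targets
with ≤ 2 raw reads in the sample but a background median ≥ 50 (depth
ratios represent "no DNA" poorly).  Allelic imbalance — per-SNP two-sided
binomial tests of B-allele counts against 0.5, combined with Fisher's
method at α = 0.01, plus a loss-of-heterozygosity signal when a long
region carries no heterozygous SNP at all — is confirmatory only: it
annotates confidence and never vetoes a depth call, because depth is the
primary, always-available evidence while het-SNP content is incidental.

Segmentation is rule-based merging of adjacent same-state targets within
a gene: panel targets are sparse and exon-sized, and the events of
interest span one exon to one gene, so HMM/CBS machinery would add
parameters without information.  Constitutive copy number can be
supplied per target (`expected_cn`), which shifts the baseline for
male-X loci when the background is not sex-matched.  GC-content
correction is not implemented and the simulator injects no GC bias; on
real capture data this is a known gap that would widen the log2 noise.

## Homology safeguards

Regions with DP20 callability < 100% in strictly more than 50% of
cohort samples are conflictive; the strict inequality follows the
definition of the screening rule.  Homology status (whether a
conflictive region has a high-identity counterpart) is an input interval
table — genome self-alignment is out of scope.  Calls in homologous
conflictive regions are flagged `needs_orthogonal_confirmation` and the
triage layer refuses to cite them as causative without a positive
confirmation record; the gene-restricted-realignment step of the wet
pipeline is represented by this downstream contract (calls are surfaced
and gated, not silently lost).  A variant recurring in ≥ 90% of samples
inside a homologous region is marked `suspected_bleed_through`
(pseudogene reference sequence read through into the gene); the screen
requires a cohort of at least 10 samples.

## ACMG triage

The combining-rules engine is a total, deterministic function of the
criteria multiset, counting applied strengths on the pathogenic side
(very strong / strong / moderate / supporting) and the benign side
(stand-alone / strong / supporting).  The strength-modifier grammar
`STRENGTH(code)` is taken at face value; nesting is rejected.  Two
completions were needed for totality and are package decisions: two
very-strong criteria classify as pathogenic (the guideline enumerates
only single-PVS1 combinations), and a pathogenic criterion applied at
stand-alone counts as very strong while a benign criterion at moderate
or above counts as strong.  Benign rules (BA1, BS, BP) are implemented
even though the shipped fixture contains no benign-classified row;
simultaneous firing of both sides yields class 3 (uncertain), as does an
empty or insufficient criteria set.  A manual override with mandatory
justification can replace the rule class; the rule-derived class and
fired rule are retained so overrides are never silent.

Replaying the 29 curated criteria rows of the cohort fixture reproduces
the curated class in 27; the two deviations are structural, not bugs: a
SOX10 frameshift where the rules yield pathogenic (PVS1 + PM2 + PP3) but
likely pathogenic was curated, and an OTOA whole-gene deletion where the
rules yield likely pathogenic (PVS1 + PM3) and the curators applied an
explicit upgrade to pathogenic — the fixture carries that upgrade as an
override record.

MAF filtering: variants asserted pathogenic (HGMD-DM, ClinVar P/LP) or
predicted null (nonsense, frameshift with premature stop, canonical
splice, start loss, complete exon deletion/duplication) are kept below
5% population MAF; all other protein/RNA-affecting variants below 1%;
synonymous non-splice variants are dropped; an absent MAF means rare and
is never grounds for dropping.

Inheritance consistency: recessive genes need a homozygous variant, two
(assumed in trans) heterozygous/hemizygous alleles, or a heterozygous
SNV uncovered by an overlapping deletion; dominant genes need one
allele; X-linked genes need a hemizygous male (or a heterozygous female
for X-dominant).  Phase is not modeled — compound heterozygotes are
assumed in trans, the standard clinical default when parental data are
unavailable.  Reportability: tier 1 reports class 3–5 and suppresses 1–2
(reference range); tier 2 reports only class 4–5 with a phenotype match;
inheritance-inconsistent class 3–5 variants are carried for information
only.

Hidden-syndrome detection is keyword-based: a gene phenotype entry is
syndromic when it names a syndrome and is not marked non-syndromic; a
diagnosis in an exclusively-syndromic gene for a patient who presented
non-syndromic is a hidden syndrome, a mixed gene gives "potential".
This stands in for clinical-geneticist judgment and agrees with the
curated annotation on every diagnosed fixture case; a manual override
field exists for cases where keywords would misfire.

## Validation accounting

Matching is exact on normalized (locus, ref, alt); zygosity is not
scored.  True negatives are counted per position: the denominator is
the set of target positions bearing no truth variant, a position with
any false-positive call is not a true negative.  Sensitivity is always
reported overall and stratified SNV vs indel.  Sample tracking passes
only at 6/6 genotype concordance; under Hardy–Weinberg equilibrium two
unrelated samples agree at a SNP with allele frequency p with
probability (p²)² + (2pq)² + (q²)², about 0.375 per SNP at the panel's
MAFs, so full-panel agreement by chance is ≈ 2 × 10⁻³.

## Simulation design

The mixture simulator emulates the analytical-validation specimen: DNA
of 10 genotyped individuals pooled equimolar, so every truth variant
sits at a mixture AF of k/20 for k carrier haplotypes, and the truth set
keeps variants with k ≥ 2 (AF ≥ 0.1).  Defaults: 1624 truth variants of
which 121 indels, a 1,034,817-position target space, mean depth 1000×,
per-base error 0.001.  Depth is lognormal-dispersed (σ = 0.3 per
120-base pseudo-target, modeling capture efficiency) Poisson sampling;
alternate reads at a truth locus are Binomial(depth, AF·(1−e) +
(1−AF)·e/3); errors put Binomial(depth, e/3) reads on each non-reference
base.  Indel errors are not separately modeled — substitution noise
suffices to exercise the thresholds, and error-driven calls are
impossible at VAF ≥ 0.1 and depth ~1000 anyway.

The pool-frequency spectrum is a deliberate choice.  Truth sets for
cell-line validations come from array/population-project genotypes,
which are strongly ascertained toward common polymorphisms; the default
therefore draws each variant's pool allele frequency from Beta(12, 12)
(minor AF mostly 0.3–0.5) with k ~ Binomial(20, f) conditioned on
k ≥ 2.  This puts only ~0.3% of truth variants at the k = 2 boundary,
where AF is exactly the 0.1 VAF threshold and detection is a coin flip:
at depth 1000 the observed VAF of a true AF = 0.10 variant exceeds 0.10
with probability ≈ 0.5 by binomial sampling.  No finite-depth simulator
can detect boundary variants with certainty — this is a property of the
inclusive threshold, not of the implementation — so the zero-error
"every variant is called" invariant is asserted for AF strictly above
the threshold (k ≥ 3), and the spectrum knob (`af_spectrum_beta`,
`min_carrier_haplotypes`) lets users study harsher spectra.  Under the
defaults the caller's expected sensitivity is ≈ 0.998 and its
specificity is ~1.0, comfortably above the real-assay figures the
simulation is meant to bound from above, as expected for a simulation
free of alignment artifacts, mapping bias and pseudogene interference.

The patient simulator emits per-target counts for one sample plus a
background cohort (default 8 samples, 50 genes × 10 targets): expected
counts scale by CN/2 at injected event targets, het-SNP BAFs shift to
1/3 or 2/3 at CN = 3 and vanish in deleted regions (het density default
0.8/kb).  It simulates pileups and counts directly — no reads, no
alignment — because calling consumes pileup-level evidence.  What the
generators deliberately do not model: GC bias, mapping bias, read-level
pseudogene bleed (cohort-recurrent bleed-through variants are injected
directly at the variant level), FFPE-style damage, mosaicism.  Passing
tests therefore demonstrate correctness of the calling and triage logic
under idealized evidence, not robustness to real-capture artifacts.

The cohort fixture encodes 50 curated cases (21 with causative variants
and their criteria strings, zygosities, database-presence and validation
status; 29 negatives, 3 of them carrying suspicious homozygous or
hemizygous VUS).  Fields the curation does not state — the sexes of
cases other than the three hemizygous males — are synthetic stand-ins
that preserve the cohort totals (21 male / 29 female) and are marked as
such in the fixture file.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is byte-identical
across runs with the same seed.  The shipped tests run the validation
mixture at full size (~1.03 M positions, seconds when vectorized), the
CNV parameter-recovery study at 100 seeded single-event samples
(recall and precision ≥ 0.95 required at default parameters, mean
per-target depth ≥ 300), and the combining-rules engine against an
independently coded oracle over every criteria count vector of size
≤ 6.  Cohort-scale sequencing metrics of a real laboratory (mean
coverage per gene, per-gene callability tables) are descriptive of real
data and have no synthetic counterpart here.

## Known limitations

* No GC/mappability correction in CNV calling; thresholds assume a
  background processed with the same capture protocol.
* No read-level realignment: homology handling is contract-level
  (flagging and confirmation gating), not sequence-level.
* Phase is assumed, not inferred; de novo status is an input assertion.
* Phenotype matching is keyword overlap with a manual override, not a
  clinical ontology.
* The ACMG engine applies the generic combining rules; disease-specific
  rule specializations (e.g. hearing-loss expert-panel adaptations) are
  not encoded.
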
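# Methods

## Model overview and assumptions

The package estimates birth prevalence and current population prevalence
of *PEX1*-mediated Zellweger spectrum disorder from allele frequencies
observed in large genetic-diversity cohorts. The chain of inference is:

    variant tiers → allele-class frequencies q_c → genotype frequencies
    (expanded Hardy-Weinberg) → phenotype birth frequencies → births per
    year → survival-aged prevalence by age and phenotype.

Assumptions inherited by every downstream number:

* **Hardy-Weinberg equilibrium** within each modelled region: random
  mating, no inbreeding coefficient, no population substructure. Observed
  patient cohorts can violate this (homozygote enrichment from local
  founder effects); the χ² goodness-of-fit stage exists to quantify that
  departure, not to correct it.
* **Disjoint cohorts** within a region. Pooling sums allele counts and
  allele numbers; duplicated cohort names are a hard error.
* **Diagnosis independence**: no correction for ascertainment, fetal
  mortality, or diagnostic rates.

## Variant classification

Precedence: ClinVar benign/likely-benign excludes; ClinVar
pathogenic/likely-pathogenic includes (frequency and homozygote filters do
*not* apply to this tier); essential-LOF consequences (stop_gained,
frameshift_variant, start_lost, splice_donor_variant,
splice_acceptor_variant — configurable) are high-confidence pLOF; all
remaining variants are candidates for prediction and must pass the
frequency filter (pooled AF ≤ 0.002, the threshold separating known
pathogenic from benign alleles in this gene) and the homozygote filter
(no homozygotes observed — a homozygous healthy adult argues against a
severe recessive allele). Survivors are predicted splice at SpliceAI max
delta ≥ 0.8 (high-precision cutoff), else predicted missense by consensus
vote.

**Consensus vote.** Four predictors (SIFT, PolyPhen-2, EVE, AlphaMissense):
deleterious iff ≥3 of 4 vote deleterious; with only 2 or 3 non-missing
calls, unanimity is required; <2 calls never reaches consensus. This is a
strict-majority rule chosen for robustness to missing scores (EVE in
particular does not cover all positions). ClinVar "conflicting" is treated
as VUS and falls through to the prediction rules, which lets a
VUS-but-predicted-deleterious allele (the p.(Arg985His) pattern) enter the
expanded model.

## Allele classes and pooling

Classes: NULL (known-pathogenic LOF + high-confidence pLOF), G843D (the
p.(Gly843Asp) hypomorph, matched on HGVS protein name), MISSENSE_KNOWN
(other known-pathogenic non-LOF), PREDICTED_SPLICE, PREDICTED_MISSENSE.
The core model uses the first three; the expanded model all five.

Real cohorts report per-site allele numbers that vary with call rate. The
class denominator used here (`pooled_an`) is the sum over region cohorts
of each cohort's maximum observed AN, with class numerators summed over
member variants. When per-cohort AN is constant across sites — true of
all synthetic fixtures — this is exact; with variable call rates it
slightly deflates q for poorly called sites, a conservative choice.

## Genotype prevalence and uncertainty

Expanded Hardy-Weinberg: genotype (i, j) has birth frequency `q_i²` if
i = j, else `2 q_i q_j`; summing over all pairs gives `Q = (Σ q_c)²`
exactly (conservation is tested to 1e-12 relative).

The confidence range is a **modified-Wald (Agresti–Coull) interval on the
total pathogenic allele count** X over AN: with z the normal quantile
(1.644854 at the 90% level), p′ = (X + z²/2)/(AN + z²), half-width
z·√(p′(1−p′)/(AN + z²)), clipped to [0, 1]; the interval on Q is
(p_lo², p_hi²). Allele-level uncertainty could instead be propagated per
class; squaring the total keeps the genotype-class ranges internally
consistent (each class frequency is scaled by (p_lo/p̂)² and (p_hi/p̂)²,
so class ranges sum to the total range) and produces the narrow, monotone
ranges appropriate at AN ~ 10⁶. With X = 0 the interval degenerates to
(0, p_hi²). Coverage of the underlying interval is verified empirically:
at AN = 10⁵, p = 2×10⁻³, the 90% interval covers in ≈90% of 10⁴ binomial
replicates.

Rates: per-million = Q·10⁶; the "1 in N" figure is 1/Q rounded to three
significant figures (matching the granularity at which such figures are
quoted); undefined and flagged at Q = 0.

## Phenotype assignment and survival

Default genotype→phenotype map: NULL/NULL → severe, NULL/G843D →
intermediate, G843D/G843D → mild. Every other pair → a combined
intermediate-or-mild bucket, split 0.5/0.5 (configurable). `expected`
mode splits the mass deterministically; `sampled` mode assigns whole
genotype segments by a seeded Bernoulli draw, mirroring how rare-genotype
patient segments would fall one way or the other; both conserve total
frequency exactly.

Survival is piecewise-constant annual survival applied to completed years
of life, with S(0) = 1 and S(a) the product of annual factors for years
1..a:

| phenotype     | years 1–8 | 9–18  | 19–31 |
|---------------|-----------|-------|-------|
| severe        | 0.760     | 0.760 | 0.760 |
| intermediate  | 0.966     | 0.992 | 0.980 |
| mild          | 0.994     | 0.994 | 0.994 |

Band boundaries are read as inclusive integer years ("until age 8" =
years 1–8; "ages 9 to 18" = years 9–18; "from 19" = years 19–31). No
half-year correction is applied — the rates are annual. The model horizon
is 31 years because survival data beyond that age are too sparse; the
headline "under 31" totals sum ages 0–30, and the full 0–31 table is also
reported.

`fit_annual_survival` recovers a constant annual rate from Kaplan-Meier
points by least squares of ln S on t **through the origin** (S(0) = 1 is
exact, and a constant annual rate is an exponential model, hence the
log scale); it returns exp(β̂).

## Births and cohort aging

Each (age, phenotype) prevalence cell is
`births(reference_year − age) · phenotype birth frequency · S(age)`.
Where only a single year's birth count is configured, earlier years are
constant-extrapolated with a logged warning — prevalence totals are
linear in births, so a ±10% drift in historical births moves the 31-year
totals by roughly the same factor. Reference year defaults to 2021. Birth
"best estimates" are rounded half-to-even to whole numbers; confidence
bounds are kept at one decimal.

## Goodness of fit

Observed patient genotype counts are compared with model genotype
proportions (renormalised over affected genotypes) by χ² with
df = k − 1 — expected proportions come from the population model, not the
sample, so no estimated-parameter correction applies. Categories with
expected count < 1 are pooled, smallest first, into an "other" bucket
until every bucket (including the pool) has expected ≥ 1; at a cohort
size of ~60 this keeps the χ² approximation honest (empirical type-I rate
at α = 0.05 stays within 0.04–0.06 under multinomial null simulation).
Unordered pairs are aligned, so (NULL, G843D) and (G843D, NULL) are the
same category.

## Synthetic data: what it emulates, and what it does not

The generator plants variants with known true allele frequencies and
annotation templates for every tier, plus decoys each built to fail
exactly one classification rule (benign assertion, frequency, homozygote,
sub-threshold SpliceAI, split predictor vote, no rule at all). Allele
counts are Binomial(AN, q_true) per cohort; homozygote counts
Binomial(⌊AN/2⌋, q_true²) — an independent-diploid approximation that is
adequate at q ≤ 10⁻²-scale frequencies. Each variant draws from its own
integer-seeded RNG stream, so tables are reproducible per variant and
across platforms.

The US-like preset plants q_NULL = 1.1×10⁻³, q_G843D = 9×10⁻⁴, known
missense 5×10⁻⁵, predicted splice 3×10⁻⁴, predicted missense 6.5×10⁻⁴ —
core total 2.05×10⁻³ (Q_core ≈ 4.2×10⁻⁶, ~1 in 240,000 births) and
expanded total 3.0×10⁻³ (Q ≈ 9×10⁻⁶). These are fixture choices matching
the order of magnitude of a large Western country's variant landscape,
chosen once for realism, and the cohort sizes (10⁶ alleles pooled over
two cohorts) match the scale at which such estimates become stable.

What passing tests on synthetic data do **not** show about real data: no
population substructure or founder enrichment, no linkage between
variants, no per-site call-rate variation, no genotyping error, no large
deletions/CNVs or deep-intronic alleles (which sequencing-based cohort
counts also miss), and annotation columns are internally consistent by
construction, which real VEP/ClinVar exports are not always.

## Problem sizes and numerical choices

Simulation-based checks use 10⁴ replicates for interval coverage and χ²
calibration and 500 end-to-end recovery replicates at AN = 10⁶ — sizes at
which Monte-Carlo error (≈0.3% on coverage, ≈0.13% on mean recovery bias)
is well inside the assertion bands, while a full run stays in seconds.
The recovery preset uses ClinVar-pathogenic variants only, so the
frequency filter cannot randomly exclude a near-threshold variant and
bias the estimate; that exclusion effect is real for predicted variants
near AF 0.002 and is visible instead in classification tests. z is taken
from the normal quantile function (1.6448536… at 90%). Ties and
degenerate inputs: AN = 0 rows are rejected at load; Q = 0 flags the
1-in-N rate as undefined; empty genotype lists produce zero vectors.

## Known limitations

* The expanded model inherits the error rates of in-silico pathogenicity
  prediction; its numbers are upper-bound-flavoured relative to the core
  model.
* Constant-extrapolated birth series bias old-age cohorts in countries
  with strong birth-rate trends.
* The HWE assumption understates homozygote genotypes where founder
  effects exist — exactly the departure the goodness-of-fit stage
  measures.
* Survival schedules are point estimates; no uncertainty is propagated
  through them.
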
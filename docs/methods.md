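# Methods

This note documents the models, statistical procedures, parameter choices,
and known limitations of `lipidheat`.

## Data model and units

An analysis starts from a wide sample × analyte matrix of non-negative
normalized mass-spectral signal per mg anther dry weight (1.0 = signal of
1 nmol internal standard), plus per-sample metadata: genotype, treatment
(AT = ambient, HT = heat), year, block, replicate, and a QC-pool flag.
QC-pool samples are repeated injections of a pooled extract and carry no
genotype/treatment.

Analyte identities are shorthand names. A summed form `CLASS(c:d)` gives
total acyl carbons and total carbon–carbon double bonds; a chain form
`CLASS(c1:d1/c2:d2[/c3:d3])` lists the acyl chains, whose order carries no
*sn*-position information (equality normalizes chains by descending carbons,
then double bonds). Isobaric analytes with different chain sets are kept
distinct with `_A`/`_B` variant tags. Chain counts per class: TAG 3; DAG and
the diacyl phospho/galactolipids (PC, PE, PI, PA, PG, MGDG, SQDG) 2; SE and
the acyl part of ASG 1; SG 0 (no acyl chain, so no unsaturation index).

Some summed compositions have a single plausible chain set among the common
C16/C18 fatty acids; these are shipped as a built-in, caller-overridable
assignment map (e.g. PC 34:3 → 16:0/18:3, PC 36:6 → 18:3/18:3,
PC/PE 34:2 → 16:0/18:2 — the only pair of major fatty acids summing to
34:2). Species without explicit chains or an assignment are excluded from
fatty-acid decompositions and listed in an exclusion log; in particular
TAG(54:5) has no unambiguous assignment.

## QC filtering

An analyte is dropped globally if, **in any year**, (1) its mean signal over
the experimental samples falls below the limit of detection, or (2) its
coefficient of variation over the QC-pool injections exceeds a cutoff.

* `lod` — default 5·10⁻⁵ signal units (nmol equivalents). The threshold is a
  parameter because practice varies by instrument and batch; a 10× stricter
  reading (5·10⁻⁴) can be applied by passing it explicitly.
* `cov_max` — default 0.3. CoV uses the sample (n−1) standard deviation over
  the pool injections; at least two injections per year are required, and the
  default generator provides six per year so that a CoV estimated from a
  handful of injections is not itself the bottleneck.
* The LOD criterion tests the **mean** over experimental samples within each
  year — the weaker and more stable of the plausible readings (vs. requiring
  every sample above LOD).

Filtering is idempotent and preserves analyte order. Exact zeros are legal
values and participate in row totals.

## Composition and unsaturation metrics

`percent_of_total` divides each sample row by its total signal (×100); a
zero-total row is an error naming the sample. All composition metrics
require percent units; ratios (TAG:PC, PC 18:3/18:2) are invariant to the
choice.

The unsaturation index of a molecular species is its double bonds per acyl
chain, d/chains. The class index is the amount-weighted mean of its member
species' indices, computed per grouping cell; a cell with zero class total
yields a flagged missing value (NaN), never a silent zero. The class index
is always bracketed by the member species' indices.

Fatty-acid totals per class sum amount × occurrences of each fatty acid over
the assignable species; fold changes divide the HT mean of that total by the
AT mean (NaN when the AT denominator is zero). Ratios are computed **per
sample and then averaged** (mean of ratios, matching per-observation error
bars), not as a ratio of means; group means in this module are plain
arithmetic means, while design-adjusted means live in the factorial model
below.

The default "structural glycerolipid" set for molecular-species composition
is the diacyl classes {PC, PE, PI, PA, PG, MGDG, SQDG, DAG}; TAG and the
sterol lipids are excluded (TAG pools are storage, not membrane structure).
The set is a parameter.

## Factorial cell means and Fisher's LSD

The trial is a two-factor factorial (treatment × genotype) replicated over
2 years × 2 blocks × 4 replications. `FactorialLSD` fits an ordinary linear
model

    value ~ treatment * genotype + year + year:block

by least squares. This is a deliberate **fixed-effects approximation** of a
mixed model with random year and block effects: with only two years the
variance components are essentially unidentifiable, while fixed blocking
terms absorb the same nuisance variation and leave the treatment and
genotype contrasts intact. Least-squares cell means average the model
prediction over the year × block combinations in which the genotype was
observed (a genotype grown in one year is estimated within that year, and
its smaller n flows into its standard error). On balanced data the LS means
equal raw cell means.

Comparisons use Fisher's least significant difference on the residual mean
square s² with its residual degrees of freedom:
t = (m₁−m₂)/(s·√(1/n₁+1/n₂)), two-sided at α (default 0.05). The compact
letter display uses insert-and-absorb lettering over the pairwise LSD
matrix with levels processed in descending-mean order, so the output is
deterministic and independent of input order. No multiple-testing
correction is applied across analytes (a Benjamini–Hochberg flag exists but
is off by default): per-analyte arrows are descriptive, as is conventional
for this style of lipidome figure. Degenerate zero-residual fits compare
means up to floating-point rounding. A treatment × genotype cell with fewer
than two observations is rejected up front.

## PLS-DA and VIP

Two-class PLS-DA regresses the centered {0,1} treatment code on the
mean-centered analyte matrix. For a single response the NIPALS weight at
each stage is wₐ = Xᵀy/‖Xᵀy‖ with no iteration, so extraction is exact and
deterministic: tₐ = Xwₐ, pₐ = Xᵀtₐ/tₐᵀtₐ, qₐ = yᵀtₐ/tₐᵀtₐ, followed by
deflation of X (and y). Component signs are fixed by forcing the
largest-magnitude weight entry positive. Default components A = 2, matching
a two-axis scores plot; VIP is computed from the same A components.

**No unit-variance scaling is applied by default** — only mean-centering.
Percent-of-total lipidomics tables span orders of magnitude across analytes,
and leaving the scale in place makes VIP reflect absolute compositional
shifts; scaling is available as an option. Wold's VIP,
VIPⱼ = √(p·Σₐ SSₐw²ⱼₐ/Σₐ SSₐ) with SSₐ = qₐ²·tₐᵀtₐ, satisfies
mean(VIP²) = 1 identically, which is verified to 1e-8 in the tests.
Rankings break VIP ties by analyte name. Constant columns get zero weight;
a constant class label is an error.

## Co-occurrence groups

Coordinated lipid metabolism is detected from Spearman correlations over
**all experimental samples pooled** (both treatments, both years): the
co-variation of interest includes the common response to heat. Correlations
are computed on the percent-of-total table; Spearman is rank-based, so any
per-sample monotone renormalization leaves it unchanged. Average ranks
handle ties; zero-variance analytes are flagged, excluded from clustering,
and reported.

The merge tree is single-linkage on distance d = 1 − ρ (scipy's
implementation; deterministic for a fixed input). Lipid groups at threshold
ρ* (default 0.90) are the size-≥2 connected components of the graph with an
edge wherever ρ ≥ ρ* — provably the same partition as cutting the
single-linkage tree at similarity ρ*, an equivalence asserted in the tests.
Every member of a group correlates with at least one other member at
ρ ≥ ρ*. Direction arrows come from the factorial model's pooled AT-vs-HT
contrast per analyte: up/down when significant at α, ns otherwise or when
the analyte is missing from the statistics.

Newick export places leaves at height 0 and each internal node at half its
merge distance (ultrametric convention), so a two-leaf tree merged at
ρ = 0.9 is `(A:0.05,B:0.05);`. Labels containing reserved characters are
quoted; the output round-trips through standard Newick readers.

## ΔΔCT relative expression

Technical replicates are averaged first; ΔCT = CT_target − CT_reference per
biological replicate; ΔΔCT = mean ΔCT(HT) − mean ΔCT(AT); fold = 2^−ΔΔCT
with amplification efficiency fixed at 2 (no Pfaffl correction). Folds are
invariant to plate-wide CT shifts, and swapping calibrator and treatment
inverts them exactly. A fold beyond 1.5× in either direction is called
up/down (`nc` otherwise); the 1.5-fold rule is a reporting convention, not a
statistical test, and the package deliberately does not attach one.

## Synthetic-study generator

The generator emulates the field trial the analyses assume, with every
planted feature recorded as ground truth (`SimTruth`).

**Baseline template.** 89 analytes across the 12 headgroup classes, in
percent of total signal under AT: PC 44, PE 18, TAG 9, PI 3, PA 2, PG 2.5,
MGDG 2, SQDG 1.5, DAG 2, ASG 5, SG 4, SE 7. Within the structural
glycerolipids the pooled 34:3 / 34:2 / 36:6 / 36:5 / 36:4 species make up
26.0 / 25.9 / 11.4 / 15.7 / 12.8 percent of the structural total (jointly
91.8%) — the composition of an ambient-grown peanut anther lipidome
dominated by PC, with five diacyl species carrying most of the signal.

**Design.** Two years × 2 blocks × 4 replications for seven genotypes, two
of which (Sugg, SPT 06-07) are each grown in a single year (8 instead of 16
observations per treatment), plus 6 QC-pool injections per year. Signal
units come from scaling the percent template by a total signal of 2.0 per
mg dry weight.

**Generative model.** Each value is multiplicative:

    signal = baseline × heat multiplier × year shift × block shift
             × latent group factor × lognormal noise

with all lognormal terms mean-one. Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `noise_cv` | 0.20 | replicate CoV of ordinary analytes (positive, right-skewed signal data) |
| `block_noise_cv` | 0.06 | residual CoV of co-occurring group members: most of their variance is the shared factor |
| `block_sigma` | 0.35 | log-sd of the per-sample latent factor shared within a co-occurring group; yields within-group Spearman ≈ 0.93–0.95, the regime in which a ρ ≥ 0.90 grouping is meaningful |
| `year_sigma`, `block_shift_sigma` | 0.05 | mild common-scale shifts per year and block; they cancel under percent-of-total |
| `qc_cv` | 0.10 | QC-pool injection CoV, comfortably below the 0.3 filter |
| depletion per genotype | 0.9 (Bailey) … 0.6 (SPT 06-07) | HT multiplier on 18:3-containing species; heat-tolerant genotypes deplete more |
| TAG gain per genotype | 1.8 … 3.2 | HT multiplier on TAG species, moving TAG from ~9% to ~17–31% of signal |

A species "contains 18:3" if its explicit or assigned chains include 18:3,
or (for unassigned diacyl species) if its totals force one among the common
C16/C18 fatty acids (34:3, 34:4, 36:5, 36:6, 36:7). Four co-occurring groups
are planted: the 18:3 PC trio {PC(34:3), PC(36:5), PC(36:6)}, the five major
PE species, and two six-member TAG sets. Non-18:3 members of the PE group
(PE(34:2), PE(36:4)) deplete at the square root of the genotype factor:
their heat response is coordinated by the shared headgroup rather than by
acyl content, which is what keeps a mixed group co-varying as one unit.
Optional "junk" analytes can be planted below the LOD or with QC CoV ≈ 0.6
to exercise the filter.

Randomness comes from named substreams of a master seed (one stream per
draw family), so enlarging the template does not perturb existing draws and
a fixed seed is bit-reproducible.

The CT-table generator plants true expression folds (default: the FAD
desaturase pattern with FAD2-1 up 2.8–3.9× in three genotypes, FAD2-2 up
3.9× in one, FAD3-2 up 1.8× in one and down 1.7× in another) as CT offsets
of −log₂(fold) under HT, with biological (SD 0.15 cycles) and technical
(SD 0.05) noise around a reference gene at CT 20.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: instrument drift and batch effects beyond a
scalar per year/block, missing values and censoring at the detection limit,
isotope and ionization interference between analytes, compositional
constraints beyond closure (values are generated independently up to the
latent factors), non-lognormal outliers, and any mechanistic link between
expression and lipid phenotypes (CT tables and lipid tables are generated
independently). Recovery results certify the pipeline's statistics, not
biology.

## Problem sizes and runtime choices

The test-suite simulations use the default study size (≈200 samples × 89
analytes) over fixed 20-seed lists; calibration uses 1000 null fits of the
16-observation single-genotype design; oracle comparisons use 200 random
instances of up to 12 analytes. The acceptance script reports
single-study values at the given seed plus 10-study recovery rates and a
500-simulation type-I rate. These sizes put Monte-Carlo error well below
the asserted margins while keeping any single command in the seconds-to-
a-minute range.

Numerical conventions worth knowing: degenerate (zero-residual) factorial
fits compare means at 1e-9 relative tolerance; VIP and letter-display ties
break by name/order deterministically; Spearman matrices set zero-variance
analytes to NaN and drop them from clustering; percent rows must sum to 100
within 1e-6.

## Known limitations

* The fixed-blocking approximation understates the uncertainty a true
  random-year model would attach to cross-year generalization; with two
  years this is the lesser evil, but treatment effects are strictly
  "effects under these two years' conditions".
* Per-genotype unsaturation contrasts at the weakest planted effect
  (depletion 0.9, n = 16) sit near the design's noise floor; they are
  detectable pooled across genotypes, and individually only for strong
  responders. This mirrors the underlying experiment, where the least
  responsive genotype's changes were not statistically significant.
* VIP rankings from unscaled data favor abundant analytes; a low-abundance
  but sharply responding species can rank below a mildly responding major
  species. This matches the intended reading (absolute compositional
  shifts) but is a choice, not a law; use `scale=True` to rank relative
  responses.
* The 1.5-fold expression call carries no error control.
* Exact reproduction of a published VIP top-15 ordering from another
  toolchain is not expected: component count and preprocessing conventions
  differ between implementations; set membership is the robust comparison.
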
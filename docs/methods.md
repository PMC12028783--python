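# Methods

`alleloscreen` implements the statistical layer of a donor-screening
allelopathy bioassay: germination indices computed from Petri-dish counts,
an asymmetric response index against the control, a composite effect index
per donor, an entropy-weighted TOPSIS ranking, and the comparison machinery
(ANOVA + Duncan letters, permutation variable importance, PCA) that
supports the screen. This note records the models, the defaults and the
design choices that were genuinely open.

## The bioassay model

The screening design is a control (distilled water) plus T donor
treatments (root exudates), each applied to `dishes_per_treatment = 4`
Petri dishes of `seeds_per_dish = 30` seeds. Germinated seeds are counted
on day 3 (`n3`) and day 7 (`n7`); per-seedling radicle length, germ length
and seedling height are measured at day 7. Physiological indicators (a
14-indicator panel: O2•−, OH•, H2O2, MDA; SOD, POD, CAT, APX, GR; ASA,
DHA; proline, soluble sugar, soluble protein) are measured on seedlings
with 4 biological × 3 technical replicates.

### Germination indices

With fractions kept internally in [0, 1]:

- germination percentage = `n7 / n_total`
- germination potential = `n3 / n_total` (early vigor)
- SVI (simple vigor index) = germination percentage × seedling height (cm) × 100

The SVI unit convention (fraction × cm × 100) was an open choice because
percent-vs-fraction scaling is a pure constant factor; it cancels in the
response index, which is a ratio, so no downstream quantity depends on it.

Aggregation is dish-level: per-dish indices are averaged with equal dish
weights so the ANOVA layer sees n = 4 replicates per treatment, matching
the replication unit of the design. A dish with `n7 = 0` has no seedlings:
it contributes 0 to SVI and is excluded from morphometric means (avoiding
0/0), a documented convention for an edge case the design makes rare.

### Response index and composite effect

For a treatment value `T` and control value `C`:

    RI = (T − C)/T  if T ≥ C,   RI = (T − C)/C  if T < C

RI is sign-matched to `T − C`, bounded in (−1, 1) for positive inputs
(−1 exactly when T = 0), and invariant to common rescaling of T and C.
SE, the comprehensive effect index of a donor, is the arithmetic mean of
its RI values over the six germination parameters (germination percentage,
germination potential, radicle length, germ length, seedling height, SVI);
the parameter set is configurable with this default. SE > 0 is read as a
net-stimulatory donor.

Open choice: RI can be computed on treatment-level means (default, since
the index is defined on single T and C values) or per dish against the
control mean and then averaged (`basis="per_dish"`); the basis used is
recorded in the output. Cells with T = C = 0 are undefined; they become
missing values excluded from SE, with a warning, rather than aborting a
whole screen for one degenerate cell.

## Entropy-weighted TOPSIS

The donor ranking treats the screen as a multi-criteria decision problem:
alternatives = donors, criteria = the six germination parameters, all
benefit-oriented by default (the screen looks for promotion). Criterion
weights use the entropy weight method on raw column proportions:
`e_j = −(1/ln m) Σ_i p_ij ln p_ij`, divergence `d_j = 1 − e_j`, weights
`w_j = d_j / Σ d_j`, with `0 ln 0 := 0`. A criterion constant across
alternatives has entropy exactly 1 and weight exactly 0 (the
implementation clamps the roundoff so the zero is exact). If every
criterion is constant the weights are undefined and the package raises,
offering an explicit uniform-weights fallback flag rather than silently
choosing one.

TOPSIS then vector-normalizes each column (divide by its Euclidean norm),
applies the weights, takes the per-criterion best/worst as ideal and
anti-ideal points, and scores each alternative by relative closeness
`C_i = D−_i / (D+_i + D−_i)`. Ranking is by descending closeness; ties
keep input order and are reported. Min-max normalization is available
behind a switch because the normalization scheme is a recognized free
choice in TOPSIS variants; both routes are oracle-tested. Nonpositive
cells (possible when ranking RI values rather than raw parameters) are
shifted by |column min| + 1e-6 × column range, with a warning, since the
entropy step requires positivity.

Numerical conventions: an alternative coinciding with both ideal and
anti-ideal (the whole weighted matrix is one point) gets closeness 0.5;
closeness is exactly 1/0 only at ideal/anti-ideal coincidence.

## Comparison statistics

**ANOVA.** Classical one-way fixed-effects ANOVA per indicator, with
technical replicates averaged into biological replicates first so the
replication unit is the biological sample (pooling all 12 values per
treatment would inflate the error degrees of freedom). Zero within-group
variance is a degenerate-input error, not a silent infinity.

**Duncan's multiple range test.** Means sorted descending; the least
significant range for a span of p means is

    LSR_p = q((1 − α)^(p−1); p, df_error) × sqrt(MSE / n_h)

with `q` the studentized range quantile at Duncan's protection level and
`n_h` the harmonic mean group size (the standard treatment of unbalanced
groups, flagged in the output). Two means differ iff their gap exceeds the
LSR for their span and no enclosing non-significant span covers them. The
letter display comes from a step-down procedure (a non-significant span
absorbs everything inside it; a significant one splits into its two
sub-spans), followed by dropping non-maximal spans; it is verified against
an exhaustive span-enumeration oracle. Quantiles are memoized because the
studentized range ppf is expensive.

**Multiple testing across indicators:** none is applied by default — each
indicator is reported marginally; this is deliberate and documented rather
than hidden.

**Percent change** vs control is `(T − C)/C × 100`, defined only for
`C > 0`.

**Variable importance.** Importance of the six germination parameters for
SE uses permutation importance around a random-forest regressor:
out-of-sample increase in squared-error loss when one feature column is
permuted, averaged over ≥ 50 permutation rounds on a held-out split.
Permutation importance was chosen over impurity-based importance because
it is a model-agnostic, reproducible contract that does not depend on
tree-library internals; hyperparameters (500 trees by default) live in
config. Duplicated or strongly collinear predictors split their
importance mass — a documented property of permutation importance, not a
defect. Constant response is a degenerate-input error; at least 8
observations are required (pool simulated screens when ranking only 10
donors is too few).

**PCA.** The physiology panel mixes units (μmol·g⁻¹, U·g⁻¹, mg·g⁻¹), so
PCA is computed on the correlation matrix: indicators standardized to zero
mean and unit variance after technical replicates are averaged, then an
eigendecomposition with a deterministic sign convention (each component's
largest-magnitude loading is made positive). Explained-variance fractions
are nonincreasing and sum to 1; zero-variance indicators are dropped with
a warning. Per-treatment centroids of the scores support the grouping
read-out.

**Radar profiles.** Per indicator, treatment means are min-max scaled to
[0, 1]; min-max is a declared convention (the natural scaling for a radar
axis), and a constant indicator maps to 0.5 with a warning.

## The synthetic generator

No raw measurements are distributed with the assay design, so the package
ships a generator that emulates the design's statistical structure with
planted effects, making every downstream stage testable:

- **Counts.** Each seed germinates by day 7 with probability
  `p_germ_day7`; germinated seeds carry a day-3 label with probability
  `p_germ_day3_given_day7`. The hierarchical construction enforces
  `n3 ≤ n7` structurally rather than by rejection. The operational
  criterion for "germinated at day 3" is modelled as a latent Bernoulli
  label because the assay defines only the two count snapshots.
- **Morphometrics.** Lognormal per seedling, parameterized by arithmetic
  mean and CV (`σ² = ln(1 + cv²)`), guaranteeing positivity; CV defaults
  to 0.25, a typical between-seedling spread for young seedlings.
- **Physiology.** A biological replicate draws a latent value
  `control_mean × multiplier × (1 + ε_bio)`, `ε_bio ~ N(0, physio_cv)`
  (default CV 0.10); technical replicates multiply by `(1 + ε_tech)` with
  half the biological CV, and values are truncated at 0. With zero CV the
  generator is exact, which pins the arithmetic.
- **Reproducibility.** One counter-based RNG substream per (treatment,
  dish) and per (treatment, indicator, biological replicate), derived
  from the single design seed, so output is byte-identical across reruns
  and independent of generation order.

Default planted effects give a strong promoter (T1: +20% germination
probability, +35% morphometrics), a mild germination inhibitor that still
promotes growth (T2), a strong morphometric promoter (T5), a
potential-inhibiting donor (T8) and a near-neutral weakest donor (T10) —
the qualitative structure of a mixed stimulatory/inhibitory donor panel.
The shipped demo (control, strong donor, weak donor) plants the weak
donor at a few percent promotion on every parameter so its net-stimulatory
sign is stable across seeds, and physiology contrasts follow the two
selected donors' distinct mechanisms (ascorbate pool and MDA for the
strong donor; CAT, soluble sugar and proline for the weak one).

What the generator does **not** emulate: dose–response in exudate
concentration (effects are phenomenological multipliers), germination time
courses beyond the two snapshots, correlations between morphometric traits
within a seedling, between-dish position effects, or non-Gaussian assay
noise. Passing tests therefore demonstrate that the analysis machinery is
correct and well-calibrated on data with the assumed structure — not that
the assumed structure captures every feature of a real bioassay.

## Problem sizes used in validation

Validation simulations use sizes chosen to make Monte-Carlo error
negligible relative to the tested tolerances: 10,000 null datasets for
ANOVA calibration (3 Monte-Carlo standard errors ≈ 0.0065 around 0.05),
1,000 random instances for the Duncan oracle comparison, 100 random
matrices for the TOPSIS oracle comparison, 200 simulated screens for
planted-ranking recovery, and 100 seeded runs for importance recovery
(100-tree forests, 50 permutation rounds — enough for a planted exact
dependency, far cheaper than the 500-tree default used for real screens).

## Known limitations

- RI on treatment means ignores dish-level uncertainty in the index
  itself; the per-dish basis is provided but the two give different
  (both defensible) answers when effects are small.
- The entropy/TOPSIS formulation is one canonical variant; published
  screens do not always state their normalization, so numeric closeness
  scores are comparable only within a variant (rankings are more stable
  than scores, which is why the package's contracts are rank-based).
- Duncan's test controls per-comparison error at its protection level,
  not the family-wise rate; it is implemented because it is the standard
  post-hoc in this assay literature, not because it is conservative.
- With only 10 donors, importance ranking operates at the lower edge of
  its observation requirement; orderings on a single screen are
  qualitative.
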
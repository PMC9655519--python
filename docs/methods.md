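# Methods

## Scope and model

`phosphoquant` implements a two-group differential-abundance workflow for
label-free MS1 intensities, applied independently to each pairwise
comparison of a multi-condition design (by default the three comparisons of
a control / stimulated / stimulated+inhibited experiment: DMSO vs Fsk,
Fsk vs Fsk+AICAR, DMSO vs Fsk+AICAR). Features are either protein groups
(global protein analysis) or modification-specific peptides
(phosphopeptide analysis); intensities are nonnegative with an explicit
missing marker. MaxQuant writes `0` for non-detection, so zeros and blank
cells map to missing on read, and missing is never representable as an
observed value internally.

Each comparison is self-contained: normalization, filtering and imputation
are computed on the two conditions involved, so adding or removing a third
condition cannot change a comparison's results (this matches the separate
per-comparison quantified totals such a workflow reports).

## Normalization

Per-sample scaling to the median of per-sample observed medians:
`k_s = M / m_s` with `m_s = median(observed values of sample s)` and
`M = median over s of m_s`. Missing entries are untouched. The phrase
"median of the median intensities of each condition" admits a
condition-level reading; `reference="conditions"` provides it (the
reference becomes the median of per-condition medians of sample medians),
but per-sample scaling is the default because it is the only reading that
equalizes run-level loading, and condition-level medians are recoverable
from it. Normalization is idempotent: re-fitting on normalized data yields
factors of 1 within 1e-9.

## Noise-floor imputation

For condition *c*, the floor `ν_c` is the `level` quantile (default 0.01,
linear interpolation between order statistics; `nearest-rank` available) of
**all** observed normalized values pooled across that condition's samples
and features. Every missing cell in condition *c* receives exactly `ν_c`,
which is why exported tables repeat one constant per condition across
unrelated low-abundance features. The pooled-vector definition (rather than
per-sample quantiles later aggregated) is the one consistent with a single
shared floor per condition. Imputation is a constant-fill detection-limit
model only; model-based MNAR imputation (e.g. sampling a truncated
distribution) is out of scope.

Ordering: the quantifiability decision uses raw (pre-imputation)
missingness; the floor is computed on the full normalized table and fills
survivors and non-survivors alike, after which survivors proceed to
testing.

## Quantifiability filter

A feature is quantifiable for a comparison when it has ≥ `min_values`
(default 3) observed intensities in condition A **or** in condition B.
Protein-group features additionally require `peptide_count ≥ min_peptides`
(default 2); the peptide rule never applies to modification-specific
peptides. `min_values` exceeding both conditions' sample counts is a hard
error rather than a silently empty result.

## Moderated t-test

Statistics run on log2-transformed post-imputation intensities: a t-test on
raw MS1 intensities would be dominated by scale, and the empirical-Bayes
moderation tradition is log-scale. Reported ratios, in contrast, are
computed from untransformed post-imputation condition means
(`ratio = mean_B / mean_A`, `log2fc = log2(ratio)`), mirroring how
intensity tables print fold changes.

Per feature, the pooled two-sample variance `s_g²` has
`d_g = n_A + n_B − 2` degrees of freedom. The prior `(d0, s0²)` is
estimated by moment-matching the log sample variances against the scaled-F
model `s_g² ~ s0²·F(d_g, d0)`:

- `e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`;
- the excess `var(e_g) − ψ′(d_g/2)` identifies `d0/2` through the trigamma
  inverse (Newton iteration from `y = 0.5 + 1/x`, tolerance 1e-10);
- `s0² = exp(mean(e_g) + ψ(d0/2) − log(d0/2))`.

A non-positive excess yields `d0 = +∞` with `s0²` the bias-corrected
geometric mean `exp(mean(e_g))`. Zero sample variances carry no scale
information and are excluded from prior fitting; all-zero variances are a
hard error. The implementation agrees with Bioconductor limma's
`lmFit`/`eBayes` on the non-degenerate branch to ~1e-14 (checked in the
test suite through `Rscript`); in the infinite-`d0` branch limma uses the
arithmetic mean of variances where this package keeps the geometric-mean
form, a deliberate, documented divergence.

The posterior variance is `s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)` and
`t̃_g = (x̄_B − x̄_A)/(s̃_g·√(1/n_A + 1/n_B))`, two-sided p from Student's t
with `d0 + d_g` df (standard normal when `d0 = ∞`). `d0 = 0` reproduces the
classical pooled t exactly; `d0 → ∞` approaches a known-variance z-test —
both are regression-tested as oracle equivalences. Users may fix `(d0, s0²)`
instead of estimating them.

## FDR, z-scores and classification

- **BH**: step-up with a stable sort on (p, position) and monotonicity by
  running minimum; `q ≥ p` elementwise, exact against the brute-force
  definition.
- **z-score**: `z_g = (L_g − mean(L))/sd(L)` over the comparison's log2
  fold changes (population sd); a robust median/1.4826·MAD variant is
  available. Standardized log2FC is the only z definition compatible with
  a symmetric ±1.96 cutoff on effect direction, which is why it is the
  default reading.
- **Variant**: `q < 0.05` and `z ≥ 1.96` (up) or `z ≤ −1.96` (down).
- **Volcano**: `|log2fc| ≥ 1.17` (equivalently ≥ 2.25-fold) and `p < 0.05`.
- **Heatmap**: log10 post-imputation intensities of variant features, rows
  ordered by descending log2FC; an empty variant set yields an empty
  matrix with a warning, not an error.

Whether the original statistics ran on 9 replicate values or 3
experiment-level means is not derivable from the outputs; the design
carries both experiment and replicate indices and the default is no
collapsing.

## Phosphopeptide post-processing

- **Site selection**: the residue with the highest localization
  probability; ties break to the lowest position. Probabilities may only
  sit on S/T/Y. When a table carries no probabilities, the first S/T/Y is
  taken with a warning.
- **Motif**: peptides aligned on the chosen site over offsets −w..+w
  (default w = 7, the de-facto 15-mer standard for phosphosite logos);
  positions beyond a peptide's ends count as a 21st gap category rather
  than renormalizing, so short peptides do not inflate edge frequencies.
  Columns sum to 1 within 1e-9.
- **Unique proteins**: distinct accessions among significant
  phosphopeptides, with multi-site proteins listed and flagged divergent
  when their peptides move in opposite directions.
- **Trajectories**: per condition, mean post-imputation intensity divided
  by the control-condition mean, for a phosphopeptide and its parent
  protein; the SEM is taken across experiment-level fold values (batches
  in the design), so a 3-experiment design yields SEM over 3 values.

## Over-representation analysis

Upper-tail hypergeometric `P(X ≥ k)` per gene set, BH across sets,
identifiers case-normalized. The universe is the quantified features of
the comparison, not a whole annotation database, to avoid background
inflation. Reproducing any specific GO/KEGG term list is a non-goal
(annotation versions dominate such lists).

## Synthetic data generator

`generate_dataset` emulates the statistical structure the analysis
assumes, per feature g and sample s:

- baseline `b_g ~ N(μ, τ²)` on the log2 scale, default μ = 21 (≈ 2×10⁶ ion
  counts, the scale of the repeated noise floors in typical LFQ exports)
  and τ = 2;
- residual variance `σ_g² ~ s0²·d0/χ²(d0)` with defaults (4, 0.05) — the
  same scaled-inverse-chi-square family the moderation prior assumes;
- a fraction (default 0.05) of features carries a log2 effect (default
  N(0, 1.5²), or a fixed value) applied to every non-control condition;
- observed `log2 I_{g,s} = b_g + effect + N(0, σ_g²)`, exponentiated to the
  intensity scale;
- detection is Bernoulli with `p = logistic((log2 I − m)/γ)`, default
  midpoint `m = μ − 4` and scale γ = 1.5, giving ~10% missing cells
  concentrated at low abundance (left-censoring, the regime constant-floor
  imputation targets); an MCAR switch exists for stress tests;
- default design: 3 conditions × 3 experiments × 1 replicate, matching a
  three-independent-experiments layout; the truth table records baseline,
  variance, differential status and effect per feature.

`generate_phospho_metadata` adds tryptic-like peptides (K/R-terminated,
length 7–35, ≥1 S/T/Y) whose intended site residue is serine with
probability `serine_fraction` (default 0.85, with 0.13 threonine and 0.02
tyrosine — the canonical phosphoproteome S/T/Y split), a dominant
localization probability in (0.75, 1), and the remainder spread over other
S/T/Y positions. All generation is driven by one mandatory seed;
identical seeds give identical output.

What the generator does **not** emulate: correlated features (complexes,
shared peptides), batch effects between experiments, intensity-dependent
variance beyond the censoring itself, retention-time or
match-between-runs structure, and spectrum-level noise. Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and its
statistical calibration under the stated model, not performance on any
particular real dataset.

## Numerical choices and degenerate inputs

- Quantile definition: linear interpolation (configurable to
  nearest-rank); the repeated printed floors in real exports are
  insensitive to this choice at table precision.
- BH ties: stable sort on (p, position) makes output permutation-
  equivariant and deterministic.
- z-scores use the population standard deviation; zero spread is a hard
  error pointing at the degenerate input rather than returning ±∞.
- A sample with no observed values, a condition with no observed values,
  non-numeric intensities, and empty results exports are hard errors with
  the offending sample/column named.
- Identical values in both groups give t = 0, p = 1 (moderation keeps the
  posterior variance positive).
- Intensity parsing uses correctly-rounded `float()` so a write/read
  round trip is bit-exact.

## Known limitations

- Constant-floor imputation distorts within-group variance when a group
  mixes observed and imputed cells: simulations with default left-censoring
  show end-to-end recall of strong (8-fold) effects dropping from ~0.99
  (fully observed) to ~0.8, and occasional imputation-driven false
  variants on null data (0–5 per 800 features). This is a property of the
  constant-floor method itself, faithfully implemented; the test suite
  asserts the calibration statements on fully observed simulations and
  this characterization documents the censored regime.
- Two-group comparisons only: no multi-factor linear models, contrasts or
  spline trends.
- The moderated test assumes log-scale normality and exchangeable
  variances across features; gross violations (e.g. heavy batch structure)
  are not detected.
- Dataset-scale result counts from any particular real experiment depend
  on the deposited raw data and search engine settings and are not
  reproduced here; the acceptance machinery instead verifies the
  arithmetic on printed summary values and the statistical properties on
  simulations with known truth.
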
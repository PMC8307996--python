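# Methods

This note documents the models and procedures implemented in `rheumet`,
the defaults chosen where the design was open, and what the synthetic
data generator does and does not emulate.

## Synthetic cohort model

The generator emulates a longitudinal three-disease serum ¹H-NMR study:
RA (n=26), AS (n=29), PsA (n=23) sampled before treatment (BT) and at
two follow-ups (3M, 6M). Baseline is never dropped; each follow-up
sample is independently missing with probability `dropout_prob`
(default 0.15, roughly matching the attrition visible in typical
longitudinal N counts; configurable per disease × timepoint).

Concentrations follow a multiplicative model. For subject *s* with
disease *d*, metabolite *m*, timepoint *t*:

```
c[s,m,t] = B[s,m] · E[m,d,t] · ε ,   B ~ LogNormal(0, σ_subject),
                                     ε ~ LogNormal(0, σ_within)
```

with σ_subject = σ_within = 0.2 by default. Lognormal variation keeps
concentrations strictly positive and gives coefficient-of-variation
levels (~20% within subject, ~28% for an unpaired contrast) typical of
serum metabolite panels; no published per-metabolite variances exist
for this design, so these are stated defaults, not fitted values.
`E` is the planted effect matrix (1 everywhere for null metabolites)
and is recorded, together with per-sample jitter offsets and true
concentrations, in a `GroundTruth` object.

### Spectra

Each spectrum is a sum of **Lorentzian multiplets** on a descending ppm
axis (20 ppm sweep, default 8,192 points; a full-resolution mode emits
exactly 60,474 points). Multiplets use binomial line intensities
(s/d/t/q and a quintet-style "m"), J-coupling converted from Hz at
600 MHz, and are area-normalized so region integrals are analytically
linear in concentration — this is what makes closed-form oracles
possible, and is why a pure Lorentzian (rather than pseudo-Voigt)
lineshape was chosen. A TSP singlet at δ = 0.000 ppm is jitter- and
effect-free and anchors referencing and normalization.

Defaults that matter:

* `linewidth_hz = 2.0`. At the 8,192-point desk scale this puts ≥ 1.4
  grid points under the FWHM, keeping the aliasing error of a sampled
  Lorentzian sum below ~1%; much narrower lines alias visibly at this
  resolution (they are fine in full-resolution mode).
* `jitter_sd_ppm = 0.003`, drawn per sample *and* per metabolite —
  large enough (≈ 1.2 grid points) to corrupt naive fixed-window
  integration, small enough for interval alignment to recover.
* `noise_sd = 0.3`, `baseline_amplitude = 0.05` (three slow sinusoids).
  The small baseline emulates the *residual* after the manual
  phase/baseline correction that precedes this pipeline in practice;
  baseline-correction algorithms are deliberately out of scope.
* Panel positions: the unidentified signals (Unk_3/4/7/8/14/16) sit at
  their reported ppm values; a few amino-acid resonances in the crowded
  0.9–1.5 ppm region are nudged to nearby plausible positions, and the
  weakest amplitudes are kept ≥ 0.12, so that default integration
  regions stay disjoint and Lorentzian tail cross-talk from strong
  neighbours stays well below the biological variation. With these
  defaults the noise-free end-to-end pipeline reproduces true
  concentrations at Pearson r > 0.99 per metabolite.

What the generator does **not** emulate: free-induction decays and
Fourier processing, water suppression artefacts, phase errors,
macromolecule baselines, peak-shape asymmetry, inter-metabolite
correlation structure (each metabolite varies independently), and
instrument drift. Passing tests therefore demonstrate correctness of
the analysis chain under a controlled forward model, not robustness to
every artefact of real spectrometers.

## Preprocessing

* **Referencing**: the tallest peak in a search window (default
  ±0.3 ppm) is taken as TSP if it rises > 5 noise MADs above the window
  median; its apex is located by parabolic interpolation through the
  three points around the discrete maximum and the axis translated so
  it sits at 0.000 ppm. Spectra without a detectable TSP are dropped
  from the batch with a warning rather than aborting.
* **Normalization**: intensities are scaled so the *sum of data points*
  in the TSP window (default ±0.05 ppm) equals a constant. The literal
  "constant sum of the TSP signal" reading is implemented (TSP-window
  sum, not total spectral sum).
* **COW**: segment-wise dynamic programming (default segment 60 points,
  slack 3, cumulative boundary offset capped at 5×slack), maximizing
  the summed per-segment Pearson correlation with the reference,
  endpoints fixed, linear interpolation for segment stretching. Because
  segment-wise correlation does not mathematically guarantee that the
  *global* correlation improves, the identity warp is returned whenever
  the warped spectrum would correlate worse than the input — this makes
  "alignment never hurts" an invariant rather than a tendency.
* **icoshift**: per interval, each sample is rigidly shifted by the
  integer lag (bounded by `max_shift` and by a third of the interval
  length) that maximizes full-length cross-correlation with the
  pointwise mean spectrum; candidate shifts are edge-padded so all lags
  are compared on the same support, and vacated points take the
  interval-edge value. Default intervals are the integration regions
  themselves (merged only if they overlap): aligning each resonance
  independently is what allows per-metabolite jitter to be corrected;
  padding intervals until neighbours merge measurably degrades the
  correction. The TSP region is never aligned.
* **Relative integrals**: sum of data points over the region's
  window(s), minus the third quartile of a signal-free noise region
  (default [9.7, 10.3] ppm — the convention names no region, so it is
  configurable). Two subtraction conventions are provided: `once`
  (Q3 subtracted a single time per integral; the literal reading and
  the default) and `per_point` (Q3 × region size; the physically
  sensible flat-offset correction). Negative corrected integrals are
  retained and flagged, not clipped.

## Univariate statistics

All tests are two-sided at α = 0.05. Routing between the parametric and
nonparametric branch is operationalized as: **parametric iff
Shapiro–Wilk p ≥ 0.05 in every group and Levene (center = mean)
p ≥ 0.05** — the conventional reading of "depending on the data
distribution"; central tendencies are means on the parametric route and
medians otherwise, and the percentage difference
`100·(CT_b − CT_a)/CT_a` uses the route-consistent central tendency on
the *general* dataset (all samples, regardless of pairing).

The two-timepoint comparison is dropout-aware. Dropouts are counted per
pairwise comparison (subjects present at exactly one of the two
timepoints). With < 3 dropouts the unpaired observations are discarded
and a paired *t*-test used; with ≥ 3 (exactly 3 is ambiguous in the
source description; it is assigned to the pooled branch), the paired
*t* on complete pairs and a Welch *t* on the unpaired remainders are
combined with Fisher's method, `p = χ²₂ₖ-survival(−2Σ ln pᵢ)`. The two
sub-tests use disjoint observations, so under the null the pooled p is
exact; type-I error calibration is verified by simulation. When one
side has fewer than two unpaired observations the pooled branch is
infeasible and the complete-pairs test is used with a logged warning —
with a never-dropped baseline this is the *normal* outcome for
BT-vs-follow-up comparisons, and the pooled branch engages for
follow-up-vs-follow-up comparisons where both sides lose subjects.

Benjamini–Hochberg adjustment is applied within one comparison family
(one metabolite panel × one comparison). Multi-group comparisons route
to one-way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn pairwise rank
z-tests (tie-corrected) with Šidák adjustment `1 − (1 − p)^m`.

## Chemometrics

Variables are unit-variance scaled (zero-variance columns dropped with
a warning). PCA is computed by SVD of the centered matrix; R²X per
component is the explained fraction of total centered sum of squares.
The 95% Hotelling T² ellipse on two score vectors has semi-axes
`sᵢ · sqrt(2(n−1)(n+1)/(n(n−2)) · F₀.₉₅;₂,ₙ₋₂)`; empirical coverage is
verified at 0.95 ± 0.01.

PLS-DA is two-class NIPALS on a centered 0/1 dummy response (the
three-disease design is analyzed as three pairwise models, matching the
pairwise tables this schema mirrors). Successive score vectors are
orthogonal by deflation; predictions use `B = W(PᵀW)⁻¹q`. The sklearn
PLS implementation serves as an independent oracle in the tests, never
as the implementation.

Cross-validation is sevenfold, stratified by class, with fold
assignment by seeded within-class shuffle; **unit-variance scaling is
refit inside every training fold**, so Q² = 1 − PRESS/SS carries no
scaling leakage (SS is the total centered dummy-y sum of squares).
CV-ANOVA follows the Eriksson-style F construction

```
F = [(SS − PRESS)/A] / [PRESS/(N − A − 1)],   p = F-survival(A, N−A−1)
```

with A latent variables; PRESS ≥ SS reports p = 1. This convention is
conservative under the null (the p-value distribution has an atom at 1,
so its null rejection rate sits *below* the nominal level rather than
at it); a label-permutation p-value is available as a cross-check mode.
The number of latent variables defaults to Q² maximization (stop when
an added LV improves Q² by < 0.01), and can be fixed to mirror a given
model row.

VIP uses the weight-normalized form with `mean(VIP²) = 1`; biomarkers
are selected by the strict intersection VIP > 1.00 **and** q < 0.05
(values exactly at a threshold are excluded), sorted by VIP descending,
with the direction of change taken from the route-consistent central
tendencies.

## Clinical rules

Activity bands and the EULAR / BASDAI response classifications are
implemented exactly as printed, preserving every ≤/< boundary, and are
verified to partition the (Δ, endpoint) plane exhaustively. "Remission"
has no printed definition in the banding rules; the summarizer uses the
conventional external-guideline thresholds DAS28 < 2.6 and BASDAI < 3
(configurable), and reports exact fractions alongside nearest-integer
percentages because rounded percentages alone are ambiguous at these
denominators. PsA records may use either instrument; PsARC (Likert
joint-count) scoring is not implemented because its inputs (joint
counts) are outside this package's scope.

## Problem sizes and determinism

Simulation-based tests run at desk scale: 1000 replicates for the
type-I and FDR calibrations, 200 for ellipse coverage and null
chemometrics, 50 cohorts for the planted-effect recovery study. The
recovery and null studies run on *feature-level* cohorts (the
concentration model feeding a feature table directly): the spectral
stage is exercised by its own end-to-end tests, and omitting it from
50-replicate statistical studies keeps them fast without changing what
they measure. Every stochastic component takes an explicit seed; the
full-study bundle is byte-reproducible and logs seeds plus config and
table hashes per stage.

## Known limitations

* Alignment is integer-grid (icoshift) or piecewise-linear (COW);
  sub-gridpoint peak registration is not attempted.
* PLS-DA is strictly two-class; no OPLS-DA, no multi-class coding.
* The partially paired construction (paired-t + Welch-t, Fisher-pooled)
  is one documented reading of a test described only by name; other
  decompositions exist.
* CV-ANOVA p-values are conservative under the null (see above), so
  "fraction of significant models" statements inherit that
  conservatism.
* The generator's independence between metabolites means correlation-
  based tools (STOCSY, the Pearson screen) see structure only where it
  is planted.
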
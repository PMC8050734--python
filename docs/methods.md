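# Methods

## Data model and conventions

Inputs are a nonnegative feature-by-sample abundance matrix (TSV) and a
sample design with zeitgeber time `zt` (hours since lights-on, half-open
[0, 24)), feeding condition, replicate index and light regime. Missing
observations are empty TSV cells (NaN), never zero-coded; every
operation drops missing (t, y) pairs and requires at least three
distinct timepoints with data. The default fixture grid is ZT 2, 6, 10,
14, 18, 22 with four replicates per timepoint and two conditions (NRF as
the reference, DRF as the intervention); the exact offsets of a 4-h grid
are not biologically constrained here, so they are parameters everywhere.

## Rhythm detection

Each feature/condition series is fit by the linearized cosinor
`y = M + b1 cos(wt) + b2 sin(wt)`, `w = 2pi/tau`, with replicates as
independent observations (no pre-averaging; fitting on raw series
preserves residual degrees of freedom even though plots typically show
mean +/- sem). Amplitude is `A = sqrt(b1^2 + b2^2)`, acrophase
`phi = atan2(b2, b1)/w` wrapped to [0, tau). A constant series returns
`A = 0`, `p = 1`.

Rhythmicity is assessed by three complementary tests in the spirit of
ensemble rhythm detectors that mix parametric, spectral and
nonparametric components:

1. the cosinor F-test of `b1 = b2 = 0` (2, n-3 df);
2. the classical Lomb-Scargle periodogram at the single test frequency,
   with `p = exp(-z)` for the normalized power `z` (the exponential
   null; slightly conservative at replicated regular grids);
3. a cosine-template Kendall rank-correlation test over a 1-h acrophase
   grid, minimum one-sided p Bonferroni-corrected for the grid size.
   The tie-corrected asymptotic normal null for Kendall's S is used at
   all n because replicated designs always tie on the template side,
   where an exact null is undefined; the implementation is vectorized
   across features and templates and is unit-tested against
   `scipy.stats.kendalltau`.

The three p-values are combined by the Fisher statistic
`X = -2 sum(log p_i)`. On a replicated regular grid the F and
periodogram components are nearly perfectly dependent, so referring X to
a chi-square with 6 df would be anticonservative (analytically about
0.08 actual size at nominal 0.05). X is therefore calibrated by the
moment-matching (Brown) construction: its null mean and variance are
estimated from seeded within-feature timepoint permutations (default
100 permutations on up to 200 features, pooled — under exchangeability
the null law of X is feature-independent), and the p-value is taken from
the matched scaled chi-square `c * chisq(f)`. The permutation seed is an
explicit argument, so detection is deterministic given its inputs.
Under a timepoint-permutation null the achieved size at alpha = 0.05
stays within binomial error of nominal (tested).

BH q-values are computed per detection batch (one tissue, condition and
period at a time), mirroring per-dataset thresholding. Acrophase is
reported for every feature, including near-arrhythmic ones, but carries
a `phase_low_confidence` flag when `q >= threshold`.

Ultradian (12-h) detection is the same machinery with `tau = 12`. For
free-running (constant-light) series the period is scanned over a grid
(default 20-28 h, 0.1-h steps) and the minimum-RSS period is selected;
the reported p is Bonferroni-corrected for selection over the grid and
flagged as such. Note that a single 24-h window with six timepoints
carries weak period information: the RSS surface is shallow in tau, so
period estimates are reliable only at high signal-to-noise.

## Two-condition comparison

Both conditions are fit jointly by nonlinear least squares,

    y = (M_A + dM x) + (A_A + dA x) cos(w (t - phi_A - dphi x)),

with `x` the condition indicator, initialized from the two linearized
per-condition fits. Because the objective is multimodal in the phase,
poor first solutions are restarted over a fixed jitter ladder on `dphi`
(0, +/-3, +/-6, +12 h) and the best kept; non-convergence is flagged,
never dropped. Wald tests for `dM`, `dA`, `dphi` use the asymptotic
covariance `sigma^2 (J'J)^{-1}` with a t reference (n - 6 df);
zero-residual exact fits degenerate to p = 1 for null differences and
p = 0 otherwise. `dphi` is wrapped to (-tau/2, tau/2] with exact
antiphase reported as +tau/2 (deterministic tie rule). Under the
generator's default multiplicative noise, 95% Wald intervals for `dphi`
achieve close to nominal coverage (tested at 93-97%); the plain
(non-robust) covariance is kept because the heteroscedasticity induced
by multiplicative noise across a cosine cycle is mild at sigma = 0.2.

The comparison runs regardless of rhythmicity, but downstream
entrainment classification is gated on the dual-oscillating flag
(q < 0.05 in both conditions) — the stricter of the two possible
gatings, chosen so that phase shifts are only interpreted where a phase
is defined on both sides.

Per-timepoint two-sample t-tests (pooled variance) use a Bonferroni
family of the timepoints within a feature (alpha/m, i.e. 0.00833 for six
timepoints at alpha = 0.05); timepoints with fewer than two replicates
in either group are flagged untestable. Heatmap profiles are timepoint
means standardized per feature and condition to mean 0 and population
(ddof = 0) sd 1; constant profiles become all-zero rows with a flag.

## Folding and entrainment classes

The signed shift comes from the joint fit when it converged, else from
the circular difference of per-condition acrophases (provenance recorded
per feature). Folding maps it to `min(m, tau - m)`, `m = |d| mod tau`,
bounded by tau/2. Classes on the 24-h scale: phase-locked [0, 4],
intermediate (4, 8), phase-inverted [8, 12]; the printed interval
notation is read as closed outer bins, making edge ties deterministic.
Summaries report counts, percentages (two decimals) and a 1-h histogram
with bins [0,1), ..., [11,12], the last closed. Cross-dataset
integration marks a feature phase-shifted when its folded shift is
strictly greater than the threshold (default 4 h) and reports
per-dataset fractions plus pairwise overlaps. Licensed oscillators are
the symmetric difference of the two conditions' 12-h rhythmic sets.

## Phase set enrichment and overrepresentation

Shifts in hours map to angles `theta = 2pi shift/24`. Each set of at
least `min_size` members (after intersection with the shift universe) is
scored by the two-sample Kuiper statistic `V = D+ + D-` against the
non-member background, with a seeded permutation p-value floored at
`(b + 1)/(n_perm + 1)`; a uniform reference with the asymptotic Kuiper
series is available by flag. The permutation null is drawn by
re-labelling membership among the pooled universe, which for continuous
shifts depends only on the two group sizes and is vectorized. The
magnitude of a set is the circular mean resultant length
`R = |mean(exp(i theta))|`, the canonical temporal-cohesiveness measure
on the circle: 1 only when all member shifts coincide, rotation- and
relabelling-invariant. Note that folded shifts live on half the circle,
so even unstructured sets have baseline R near 2/pi; magnitude is a
descriptive companion to the Kuiper p, not itself a test.

Overrepresentation uses the one-sided (greater) Fisher exact test on the
2x2 table of query membership by set membership within the universe,
with the sample odds ratio and the zero-cell rule: 0 for empty overlap,
infinity for a zero denominator with non-empty overlap, no continuity
correction. BH q-values are computed across sets.

## Synthetic data generator

The generator emulates a two-condition restricted-feeding design:
6 timepoints x 4 replicates x 2 conditions, 10-30% rhythmic features by
default (`frac_rhythmic = 0.2`). Rhythmic features get mesor
`M ~ lognormal(log 50, 1)`, relative amplitude
`A/M ~ lognormal(log 0.5, 0.3)` truncated to [0.05, 0.95] (typical of
features that pass q < 0.05 rhythm detection; truncation keeps signals
strictly positive), acrophase uniform on [0, 24), and an amplitude
attenuation of x0.6 under the second condition, echoing the dampening
of oscillations under inverted feeding. The signed phase shift of each
rhythmic feature is drawn by entrainment class — folded magnitude
uniform on [0, 4) for phase-locked, [4, 8) intermediate, [8, 12]
inverted, with random sign — so ground-truth classes are consistent
with the classifier's bins by construction. Tissue archetypes encode
reported class mixtures: VAT (0.1954, 0, 0.8046), liver (0.39, 0, 0.61),
kidney (0.3711, 0.2378, 0.3911), heart (0.5741, 0.2091, 0.2168); where
only the inverted share of a tissue was reported, the locked class
receives the whole remainder. Noise is multiplicative log-normal
(sigma = 0.2, expression-like) or additive Gaussian (metabolite-like,
floored at zero). Ultradian features carry a 12-h cosine in exactly one
condition (default DRF) and are flat in the other — the simplest
generative mechanism for condition-licensed oscillators. Identical
seeds give byte-identical output.

What the generator does *not* emulate: between-feature correlation,
batch effects, count-specific mean-variance structure, non-sinusoidal
waveforms, or partial entrainment dynamics within the week. Passing
recovery tests therefore demonstrates the statistical chain is correct
under its stated model, not that real tissues obey that model.

## Known limitations

- **Class-boundary bleed.** Recovered class percentages are biased
  wherever the generative folded-shift density is positive at a bin
  edge: the phase-shift estimate carries standard error roughly
  `(tau/2pi) (sigma/A) sqrt(2/n)` per condition (about 0.4-1 h under the
  default noise), and features within that distance of the 4-h or 8-h
  boundary cross bins. For mixtures with an empty intermediate class
  (the VAT and liver archetypes) the flow across the 8-h edge is
  one-way, so the recovered inverted fraction falls several points below
  the generative value — visible in the worked example and in the
  archetype-recovery checks, where an exact binomial interval around
  the generative value captures kidney and heart (balanced flows) but
  not VAT or liver at the default noise. Any classifier with hard bins
  shares this property; real-data inverted percentages are biased the
  same way.
- Period scanning from one 24-h window is ill-conditioned (see above).
- The ensemble calibration assumes within-feature exchangeability under
  the null; autocorrelated noise would require block permutations.
- The joint comparison assumes a shared residual variance across
  conditions and homoscedastic errors within a series.

## Problem sizes and runtimes

The statistical acceptance checks use 2,500 features (2,000 rhythmic)
per tissue archetype for mixture recovery, 1,000 features for the
permutation-null size check, 500 features for CI coverage, and 10,000
permutations for phase-set enrichment; the full suite runs in well under
a minute on one CPU. Larger simulations change none of the qualitative
conclusions; these sizes keep exact binomial intervals tight (about
+/- 2.3 points at n = 2,000) while remaining quick to re-run.
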
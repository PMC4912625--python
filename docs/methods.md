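# Methods

## The estimation problem

A sample of `S` cells from a repertoire of `N` cells and `D` clones
observes each clone with probability `1 − e^(−λ)`, where `λ = f·S` is
the clone's expected cell contribution and `f` its overall frequency.
Coverage — sampled cells per overall clone, `S/D` — governs how much of
the repertoire is visible: at 1x coverage roughly half of all clones are
missed in typical clone-size distributions, and below 1x the observed
clone count is hard-bounded by the cell count, so sample richness
undercounts true richness by at least `1/coverage`-fold. The package
estimates the overall clone-size distribution, and hence any Hill
diversity of the overall repertoire, from the sample spectrum alone.

## Sampling model and its assumptions

Per-clone sampling is Poisson, not multinomial: clone contributions are
independent and the realized sample size is random with mean `S`. This
is accurate when (i) the repertoire is well mixed, (ii) it is much
larger than the sample (a warning is emitted when parent cells are less
than 10x sample cells), and (iii) no clone holds a large share (~30%+)
of all cells — dominant clones are better counted directly, which the
large-clone shortcut below does automatically.

## The reconstruction

Observed clones at sizes 1..30 (the large-clone threshold) are modelled
as a zero-truncated Poisson mixture with components `(w_j, m_j)`:
fraction of clones and mean sampled cells. Estimation interleaves two
self-consistent updates until joint convergence (relative
log-likelihood change < 1e-8 and relative missing-count change < 1e-6,
capped at 500 sweeps):

1. one EM sweep of the complete-data Poisson mixture in which the
   current missing-clone count stands in for the unobservable zero
   class (closed-form weight and mean updates);
2. a Horvitz–Thompson refresh of the missing count,
   `missing = n_obs · P(0)/(1 − P(0))`, with pooled detection
   probability `P(0) = Σ_j w_j e^(−m_j)`.

The fixed point of this interleaving is identical to running EM to
convergence inside each missing-count update — the two conditions
characterize the same stationary point — but one joint loop allows all
starting points of a scanning round to be advanced together as a single
batched array computation, which is what makes ensemble-scale validation
affordable in pure numpy.

Component means are floored at `S/N` when `N` is known (no fitted clone
smaller than one cell in the overall repertoire) and the missing count
is capped at `N − n_observed`, so richness estimates can never exceed
the overall cell count.

### Scanning

EM on truncated mixtures is multimodal, so each component count `k` is
fitted from 56 deterministic starts: for `k = 1`, means log-spaced on
[0.05, 30]; for `k > 1`, the incumbent `(k−1)`-fit augmented by one new
component with mean from an 8-point log grid on [0.05, 30] crossed with
weight fractions {0.01, 0.03, 0.05, 0.1, 0.2, 0.3, 0.5}. One extra start
averages the two top-ranked fits component-wise (matched by mean rank).
Fits are ranked by likelihood plus the multinomial coefficient
`ln[n!/Π n_i!]` (the number of ways to assign clones to size classes);
ties within 1e-9 resolve toward fewer components, then smaller fitted
sample mass. Duplicate components (means within max(1e-6, 1e-4·m)) are
merged after convergence.

### Model growth, AICc, and the noise threshold

Starting from `k = 1`, a `(k+1)`-component candidate replaces the
incumbent only if **both** guards pass:

* **AICc improves.** `AICc = −2·lnL + 2p + 2p(p+1)/(n−p−1)` with
  `p = 2k−1` free parameters and `n = 31` observations — the size
  classes 0..30, counting observed absences as observations.
* **The new component rises above sampling noise.** The component's
  expected *corroborated* clones, `E = D·w_new·P(X≥2 | m_new)`, must
  exceed 3 Poisson standard deviations of the observed clone count `B`
  in its own size window (`m_new ± 3√m_new`, never below size 2), and
  must not exceed `B` by more than the same margin. Singletons are
  deliberately excluded from `E`: on singleton evidence alone a
  component's weight and mean trade off freely against the missing-clone
  count (the classic divergence of unseen-species likelihoods), so a
  component corroborated only by singletons is indistinguishable from
  noise no matter how much singleton mass it claims. The symmetric upper
  bound stops fits that "pay" for likelihood with corroborated clones
  the window does not contain. This windowed two-sided form was chosen
  after observing that simpler statistics (the component's own Poisson
  SD, or a whole-spectrum yardstick) either admit degenerate
  small-mean components that inflate the missing class several-fold, or
  veto genuine components whose evidence is locally overwhelming.

Clones above 30 sampled cells bypass the EM entirely and are added to
the estimate directly; their relative sampling error (`1/√30` or
better) is small, and on data without large clones the shortcut is a
no-op by construction.

### Derived outputs

Overall Hill diversities place `D·w_j` clones at relative abundance
`m_j` and each directly-counted clone at its observed size. The minimum
detected clone size is `m_min·N/S`; the upper richness bound
`U = R_max·w_m·m_min·N/S` (with `R_max` the upper error bar) assumes all
cells potentially hiding below the minimum detected size are singleton
clones. The formula as printed measures only the hiding clones; because
it is ambiguous whether detected clones should be added back, the
package also reports `U + R_max`. A resampled spectrum (a Poisson sample
of a parent realization drawn from the fit) is attached for
predicted-versus-observed overlays, including the predicted missing
count at size 0.

## Error bars, calibration, power

An error profile maps coverage to the worst observed |proportional
error| of an ensemble of gold-standard fits, binned by coverage,
regularized to be non-increasing in coverage, interpolated linearly in
(log coverage, log error) with flat extrapolation (flagged). Profiles
are built per gold-standard repertoire — one fit per coverage level —
and pooled ensembles feed calibration. Error bars invert the band: the
upper bar is the largest candidate true diversity whose lower band
reaches the estimate, the lower bar the smallest whose upper band does;
since coverage depends on the candidate (`S/d` at fixed cells `S`), the
inversion is solved on a 3001-point log grid spanning estimate/100 to
estimate·100. Results with |error| > 10x are excluded from profile
construction as outliers and logged.

Calibration partitions the ensemble 70–30 into reference and validation
sets 100 times, measures how often the bars bracket the truth, and
raises the upper bar in 0.1% steps until the mean bracketing rate
reaches 95% (bracketing failures from over-estimation cannot be fixed by
an upper-bar raise; the search then reports the best achievable rate
with a warning).

Power tables invert the bars once more: for overall richness `D` and
fold-difference `f`, the smallest sample `S` whose calibrated intervals
around `D` (at coverage `S/D`) and `f·D` (at `S/(f·D)`) do not overlap —
a conservative surrogate for a two-sample test at α = 0.05 — subject to
a runnability floor: the smallest `S` for which a uniform repertoire of
`D` clones is expected to yield at least 10 doubleton clones (below
that, the singleton/doubleton signal that drives the missing-species
estimate does not exist). The floor is evaluated at the column's
reference richness so columns stay monotone in the fold.

## Gold-standard generator

Three clone-size families, with exactly `D` clones and sizes rescaled to
a budget of `N` cells (default 1e9):

* exponential, `f(x) ∝ e^(−sx)`, `s` from 0.2 (steep: dominated by
  small clones) to 0.02 (nearly flat);
* reciprocal-exponential, `f(x) ∝ e^(−sx)/x`, the stationary shape of a
  simple clone birth–death model;
* bimodal: two equal-count groups of clones whose mean sizes differ by
  `size_ratio` (20–30x typical), emulating expanded clones over a small-
  clone background.

Counts are apportioned by largest remainder, so generated richness is
exact; the cell budget is met to within rounding (~2%). Noise modes
perturb sampled spectra: `per_count` adds zero-mean noise of SD
`1.22·√n` to each count (super-Poissonian quantification error; the
default SD scale is configurable), `baseline` perturbs every size class
with constant SD, `sporadic` multiplies random size classes by a
uniform 2–10x factor (PCR jackpot-like); counts are rounded and floored
at zero. The Chao1 estimator (`S_obs + F1²/2F2`, bias-corrected
`S_obs + F1(F1−1)/2` when `F2 = 0`) is included as the benchmark
baseline.

What the generator does *not* emulate: sequence-level artefacts (read
errors, chimeras, clustering mistakes), non-Poisson cell capture,
amplification bias correlated across sizes, or clone-size families
beyond the three above. Passing validation therefore demonstrates
correct unseen-species inference under the stated sampling model, not
robustness to arbitrary experimental pipelines.

## Problem sizes used in validation

The shipped experiments are desk-scale: accuracy ensembles use 20
exponential parents (s ∈ [0.02, 0.2] × D ∈ [1e3, 1e5], three samples
each); the noisy benchmark uses 8 distributions × 4 coverages
(0.05–0.3x) at D = 1e5 with 10 noise realizations; profile/calibration
sweeps use 24 parents × 7 coverages (0.01x–10x) × 2 samples. These
sizes were chosen so the full acceptance run completes in minutes while
keeping ensemble medians stable to well under the tolerances asserted.

## Known limitations

* Below ~0.3x coverage, and for repertoires whose smallest clones sit
  near or below one expected sampled cell (e.g. bimodal parents at 1x,
  whose small mode contributes λ ≈ 0.1), the truncated-mixture
  likelihood is nearly flat along a ridge trading component weight
  against the missing count: point estimates there carry 20–50%
  error regardless of stopping rule, and only the error bars are
  informative. The noise threshold deliberately prefers under- to
  over-estimation on this ridge.
* Richness error at 1x coverage is dominated by the zero-class mass a
  k≤4-component mixture can represent; medians are ~15–20% on flat
  exponential parents (the likelihood plateaus after k≈3).
* AICc uses 31 size-class observations irrespective of clone counts, so
  very large samples still grow conservatively.
* Error bars assume the test repertoire resembles the calibration
  ensemble's families; profiles extrapolated outside 0.01–10x coverage
  are flagged rather than trusted.
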
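# Methods

This note documents the models, estimators and numerical choices behind
`flyrhythm`, and what the synthetic experiments do and do not establish.

## Feeding-event model

Per-fly meal events are an inhomogeneous Poisson process with rate

    λ_i(t) = b_i · r₀ · max(0, 1 + A(t) · cos(2π (t − φ(t)) / P)),

where `t` is hours since lights-on of day 1, `r₀` is `baseline_rate`
(default 1.5 events/hr), `P` the period (24 h), and `b_i` a per-fly
lognormal multiplier (log-SD `fly_effect_sd` = 0.3) capturing stable
appetite differences between flies. The relative amplitude `A(t)` equals
`rel_amplitude` (default 0.6) during LD entrainment and decays as
`rel_amplitude · exp(−damping_rate · t_free)` during free run. The acrophase
φ defaults to 1 h after lights-on — a truncated raised cosine peaking in the
morning and troughing half a cycle later, the simplest waveform consistent
with the morning-peak/evening-trough phenotype and analyzable in closed
form. The rate is masked to zero during the first 0.5 h of each day (the
capillary-change/re-acclimation gap) and inside any fasting window of a
feeding/fasting schedule. Meal volumes are i.i.d. gamma (mean 0.02 µL,
shape 2); no published meal-size distribution exists, and gamma is the
standard positive, right-skewed choice.

Sampling uses thinning against the bound `b_i · r₀ · (1 + rel_amplitude)`,
so event times follow the continuous-time rate exactly rather than a
per-bin discretization. Every generator is a pure function of its config
(seed included): identical configs give bit-identical tables.

Under constant light, arrhythmia is modelled as a population-level Gaussian
random walk of the acrophase (one step per free-running day, SD
`phase_diffusion_sd_hr`, 2.5 h in the `constant_light` scenario) plus
amplitude damping. The walk is shared by all flies deliberately: the LL
phenotype — destabilized period and collapsing strength of the *population
mean* — would be smoothed into pure damping if each fly diffused
independently. Phase diffusion is the phenomenological stand-in for an
unspecified mechanism; no claim is made about per-fly clocks.

Named scenarios fix the study conditions: `wildtype` (3 d LD + 3 d DD,
amplitude 0.6), `clock_mutant` (residual amplitude 0.02 — an arrhythmic
mutant whose population series is effectively flat; the tiny residual
stands in for non-circadian masking and is far below detectability),
`constant_light`, `damped` (DD damping 0.02/hr), `damped_recovery`
(50 flies, 6 DD days, amplitude 0.9, damping 0.02/hr — a long free run so
the decay spans the usable wavelet window, used for parameter recovery),
and `time_restricted` (8-h feeding from time 0, 16-h fasting).

Population size defaults to 30 flies — a typical single-assay ARC cohort.
What the generator does **not** model: fly death or censoring, meal-bout
autocorrelation (real bouts cluster), inter-day appetite drift, and any
dependence of meal size on time of day. Passing tests therefore demonstrate
the correctness and operating characteristics of the estimators under a
clean Poisson world, not robustness to every feature of real ARC data.

## Binning

Each recording day contributes `24 / bin_width` bins (twelve 2-h bins by
default). The recording span (24 − gap = 23.5 h) is tiled exactly by twelve
equal bins of actual width 23.5/12 ≈ 1.958 h, while reported bin centers
lie on the nominal uniform 2-h grid (`day_start + 0.5 + (j + ½)·2`). This
choice keeps the series regularly spaced across day boundaries — required
by both rhythm analyses — and avoids a truncated final bin, which would
inject a spurious 24-h artifact into every series. Bins are half-open
[start, end); an event exactly at the gap boundary belongs to the first
bin. The population mean divides by *all* flies in the experiment,
including non-feeders: it is a per-capita consumption rate. Summed over
bins, `value × n_flies` equals the total logged volume outside the gaps
(conservation, to float tolerance).

## Rhythmicity test

Templates are cosines `cos(2π(t_k − lag)/period)` evaluated at the series'
timepoints, for periods 20–28 h in bin-width steps (all above the 2×-bin
Nyquist limit) and one lag per sample offset within each period, reduced to
rank order. Cosine values within 1e−9 are treated as ties of sampling
symmetry; duplicate rank patterns are removed, keeping the representative
with the smallest |period − 24|, then the smallest lag.

Kendall's S counts concordant minus discordant pairs over pairs untied in
both vectors (tau-a on comparable pairs). Under a uniformly random ordering
of distinct data against a fixed tied template, S is a shifted
Jonckheere–Terpstra statistic; its exact pmf is the convolution of
Mann–Whitney count distributions over sequentially merged template tie
groups, each factor computed by the classic two-term DP recurrence and
normalized before convolving so the result stays at machine precision for
any series length up to 60 (beyond which a normal approximation with
continuity correction applies; the default design never reaches it). The
test statistic is the maximum S over templates (ties resolved by the search
order above); `p_adj = min(1, n_templates × P(S_null ≥ S_obs))`.

Properties: the verdict is invariant under strictly monotone transforms of
the data; a constant series is reported non-rhythmic (degenerate) rather
than erroring, since simulated clock mutants approach flatness. Data ties
are excluded from S but the null assumes continuous data, as in JTK_CYCLE;
with population-mean volumes, exact data ties essentially never occur.
Because the maximal S is taken over ~60 heavily correlated templates and
then Bonferroni-corrected, the test is conservative: its measured type-I
rate at α = 0.05 is ≈ 0.02–0.03, not 0.05. This is inherent to the
construction (shared with JTK_CYCLE), not a defect of the implementation;
the one-sided guarantee "false-positive rate ≤ α" holds with margin.

## Wavelet analysis

The detrended series (mean-subtraction by default; linear detrend opt-in
for drifting baselines) is zero-padded to the next power of two and
convolved in the frequency domain with analytic Morlet wavelets
(ω₀ = 6, the chronobiology default) at 64 log-spaced scales spanning a
16–32 h period band. Scales carry the unit-energy normalization
√(2πs/Δt); period = 4πs/(ω₀ + √(2 + ω₀²)). With this normalization the
power argmax over scale for a pure sinusoid maps through that period
relation to the true period exactly (the argmax of s·exp(−(sω − ω₀)²)
sits at sω = (ω₀ + √(ω₀² + 2))/2, which is precisely the relation's
inverse) — without the √s factor the ridge would sit ≈ 1.35 % low.
Numerically, recovery of 20/24/28-h sinusoids lands within one scale step
(ratio (32/16)^(1/63) ≈ 1.011).

The cone of influence marks points within √2·s of either edge as
unreliable; for 24-h periods this requires roughly six days of data to
leave a usable interior, which is why the end-to-end pipeline computes the
CWT on the full 6-day series while the rhythmicity test runs on the DD
window. The dominant ridge is the per-timepoint power argmax over the
band, ties broken toward 24 h; timepoints with maximal power below
1e−12 × the global maximum have no dominant rhythm and are flagged
invalid. Rhythm strength is power *along the ridge* (not at fixed 24 h),
jointly normalized across groups by the maximum over groups of the
time-mean of ridge power over valid, edge-reliable points; the max-over-
time reading of the normalizer is available behind the `stat="max"`
switch. The damping summary is the least-squares slope of
log(strength + 1e−9) against time over valid points (≥ 6 required); for
amplitude decay exp(−γt), power decays as exp(−2γt), so γ̂ = −slope/2.
On the `damped_recovery` scenario the median γ̂ over replicates lands
within ~10 % of the true 0.02/hr.

## Tracer assay

The generator draws, per group at each of six evenly spaced Zeitgeber
times (5 groups × 10 flies, matching the assay design), a true intake
equal to the U-shaped quadratic 3000 − 360·x + 15·x² (vertex at ZT 12,
≈ 3.6-fold peak-to-trough range, counts on an arbitrary scintillation
scale) times mean-one lognormal group noise (CV 0.15); absorption
efficiency is truncated-normal on (0, 1] (mean 0.75, SD 0.05), body counts
are efficiency × intake and excreta the remainder — the 2-h excretion
window is treated as complete, as validated for the real assay. Intake is
therefore exactly body + excreta, and efficiency ∈ [0, 1] wherever intake
is positive; zero-intake rows are retained with efficiency flagged
undefined.

The quadratic fit is OLS on the Vandermonde design with classical
homoscedastic standard errors from (XᵀX)⁻¹σ̂², per the study's stated
model. A known consequence of the multiplicative noise: variance grows
with the squared mean, the high-mean extreme timepoints carry the most
leverage for the curvature term β₂, and the 95 % CI for β₂ consequently
covers the truth ≈ 88–90 % of the time rather than 95 %. This is a
property of pairing a homoscedastic estimator with mean-proportional
noise, documented rather than patched (a weighted or sandwich estimator
would restore coverage but departs from the stated model).

Rank statistics: Spearman rho is the Pearson correlation of mid-ranks with
an exact two-sided permutation p for n ≤ 8 (t-approximation above);
Kruskal–Wallis uses the tie-corrected H with Dunn's pairwise z on mean
ranks (pooled tie correction) and Holm adjustment — Holm chosen as the
conservative standard since no correction is named in the study design;
Mann–Whitney is exact by enumeration for n₁+n₂ ≤ 12 without ties and
tie-corrected asymptotic otherwise. All are two-sided and invariant under
strictly monotone transforms.

## Reporter quantification

EC mode: per-cell nuclear intensity is base + amplitude·cos(2π(t −
acrophase)/24) with multiplicative Gaussian noise (CV 0.2); cytoplasmic
intensity is a noisy constant. ΔF = F_nucleus − F_cytoplasm may be
negative. Comparisons between timepoints are Mann–Whitney per region with
the **gut** as the unit (cells averaged within gut) to avoid
pseudo-replication — per-cell testing would inflate significance because
cells within a gut share state. Defaults (15 guts/timepoint, 10
cells/region, base 100, amplitude 40, cytoplasm 60) give essentially
complete separation at ZT0 vs ZT12, matching the strong reported EC
contrast (high at ZT0, low at ZT12; the EEC phase is inverted).

EEC mode: the per-gut count of reporter-positive cells is Poisson with a
cosine mean interpolating trough → peak (defaults 2 → 20 positive cells of
60 per gut). Positivity formalizes the visual "clearly above local
epithelial background" criterion as nuclear intensity strictly above
background mean + k·SD with k = 2 — under a Gaussian background this
admits a 2.3 % false-positive fraction per cell, the calibration behind
the default. The generator places positive cells above and negative cells
below the threshold, so counting recovers the Poisson truth exactly; the
count is monotone nonincreasing in k. Oscillation between two timepoints
is a Mann–Whitney test on per-gut counts (≥ 3 guts each).

## Pipeline and problem sizes

An end-to-end run is deterministic given (scenario, seed) and writes a
manifest (config hash, seed, version) from which it is fully reproducible.
The acceptance script and test suite use the study's own sizes where they
are part of the design (36-bin DD windows, 500 null series, 200-replicate
power/coverage runs, 100–200 reporter seeds, 50 end-to-end runs) and
6-day series wherever the wavelet stage needs a usable post-COI interior;
these sizes keep every check comfortably within a desktop minute or two.

## Known limitations

* The rhythmicity test reports a single population-series verdict; there
  is no multi-feature batch mode or FDR machinery, and no waveform beyond
  the cosine template.
* No red-noise significance contours for the scalogram; the strength
  normalization is relative across the supplied groups only.
* The Poisson feeding model omits bout structure and attrition (above);
  the tracer and reporter generators draw independent noise per
  group/cell, with no batch effects.
* Three-day free-running windows leave almost no edge-reliable wavelet
  interior at 24-h periods; period/strength claims on such windows rest on
  few timepoints and should be read qualitatively.
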
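# Methods

`gammatongue` models human figure–ground segregation in Gabor-annulus
textures as stimulus-driven synchronization of gamma-band oscillators in
early visual cortex, following the theory of weakly coupled oscillators
(TWCO): two oscillators phase-lock when their coupling exceeds their
frequency detuning, carving the triangular "Arnold tongue" in the
(detuning, coupling) plane. The package maps the two stimulus factors of
the psychophysical task onto these axes — contrast heterogeneity ζ drives
detuning, grid coarseness ρ modulates the drive's spatial sparsity — and
reads behavioral performance out of population synchrony.

## Stimuli

Textures are irregular grids of ring-shaped Gabor annuli (diameter 0.7°,
carrier 5.7 cycles/°, mean luminance 60.76 cd/m² on an equiluminant gray
background). Annulus contrasts are drawn from U[0.5 − ζ/2, 0.5 + ζ/2]
(ζ ∈ (0, 1]); the background of the behavioral display always uses ζ = 1,
so figure and background differ only in contrast *heterogeneity*, never in
mean contrast. Annuli start on a square grid of spacing s₀·ρ (s₀ = 0.9° at
ρ = 1, a configurable base value chosen to leave jitter room above the
0.7° diameter) and are displaced in a random direction by a radius drawn
from U[0, (s₀ρ − 0.7°)/2], which guarantees non-overlap by construction.
Because the jitter bound grows with ρ, nearest-neighbor distances grow
linearly but slightly sub-proportionally in ρ; the underlying grid spacing
scales exactly.

The annulus profile is a radial carrier cos(2πf·r + φ₀) under an annular
Gaussian envelope (peak at d/4, σ = d/8, hard cutoff at d/2). φ₀ solves the
zero-mean condition of the 2-D profile; after rasterization each annulus is
re-centered on its discrete support so it is exactly equiluminant with the
background, then normalized to peak modulation 1 so that Michelson contrast
c maps to luminance L̄(1 ± c).

The model's input is a 6.7° × 6.7° patch (area matched to the 9° × 5°
behavioral figure) centered at 7° eccentricity on the lower-right diagonal.
Annuli are placed over a 2°-wide margin beyond the patch: the patch is a
cutout of a larger figure texture, so border receptive fields see the same
element statistics as central ones.

## Oscillator sheet

An n × n grid (n = 20, N = 400) of receptive-field (RF) centers spans the
patch uniformly in visual space. Cortical positions follow the Schwartz
monopole complex-log map w = α ln(z + a) with the generic human values
a = 0.7°, α = 0.9. We read α in centimeters of cortex: the implied foveal
magnification α/a ≈ 13 mm/° and the ≈2.2 cm extent of the mapped central
field match human V1, and map coordinates are converted to millimeters
(×10, `RetinotopyParams.unit_mm`) because the coupling decay constant is
calibrated per millimeter of cortex. With this convention nearest-neighbor
oscillators sit ≈0.7–1 mm apart (coupling ≈ 21) while opposite patch
corners are ≈13 mm apart (coupling ≈ 0.1): coupling is local, as in the
tissue it was measured in. Treating the map unit itself or physical human
magnification (≈17.3 mm/map-unit) as the distance scale makes the network
either synchronize for nearly all ζ or never synchronize within a one-
second trial, respectively; the centimeter reading is the only convention
under which both reported regimes — a session-1 synchronized state
confined to low ζ and growth of the synchronized region with learning —
coexist.

RF sizes follow the threshold-linear rule ∅(e) = max(0.172·e − 0.25, 1)°
evaluated at each RF's own eccentricity; the Gaussian RF standard deviation
is σ = ∅/4 (composition of the Gaussian-beam FWHM relation with the
FWHM-to-σ identity). Session-1 coupling is K¹ᵢⱼ = γ·exp(−λ·dᵢⱼ) with
γ = 24.63 and λ = 0.22/mm, taken as given from macaque recordings.

## Afferent drive

Local contrast converts to intrinsic frequency through ν = 25 + 0.25·C Hz
(C in percent), spanning the gamma range 25–50 Hz. Two pooling
granularities are implemented:

* **Pixel-level** (`weighted_rms_contrast`): the weighted RMS of per-pixel
  luminance deviations from the patch mean, with isotropic Gaussian RF
  weights. Because most pixels under an RF are blank background, each
  annulus's contrast is diluted by its areal coverage; the across-oscillator
  frequency spread reaches only ≈1.6·ζ Hz.
* **Element-level** (`element_rms_contrast`, the model default): each
  annulus contributes its Michelson contrast with the Gaussian RF weight
  evaluated at its center, truncated at 4σ; an RF with no element in reach
  idles at the 25 Hz floor. Neural assemblies thereby extract the (RMS)
  average contrast of the annuli inside their RFs, and the frequency spread
  tracks the full contrast-heterogeneity width (≈7·ζ Hz at ζ = 1 with a
  ≈0.05 Hz geometric floor).

The element-level pathway is the model's default because it is the only
reading under which the observed synchronization boundary emerges: with
pixel-level dilution the ζ-dependent detuning never reaches the critical
spread and the network synchronizes for nearly the whole ζ range. The 4σ
truncation is also what gives grid coarseness its desynchronizing effect:
on sparse grids some RFs fall in gaps and detune to the frequency floor,
and neighboring RFs increasingly share single elements, which correlates
their frequencies.

## Dynamics and readouts

Phases follow the Kuramoto equation
θ̇ᵢ = ωᵢ + (1/N) Σⱼ Kˢᵢⱼ sin(θⱼ − θᵢ), integrated for the one-second
stimulus interval from i.i.d. uniform initial phases with an adaptive
Runge–Kutta method (rtol 10⁻⁶, atol 10⁻⁸) on a 1 ms output grid.
Integration is performed in a frame co-rotating at each trial's mean
intrinsic frequency — an exact change of variables, since the coupling
depends only on phase differences — which enlarges stable step sizes
roughly threefold; phases are rotated back before any readout. A block's
25 condition trials are integrated as one batched system to amortize
step-size control.

Synchrony is the magnitude r of the Kuramoto order parameter, averaged
over the second half of the trial; a condition counts as "synchronized"
when the trial-mean r reaches 0.5 (the threshold is configurable — the
underlying transition is steep enough that nearby choices move the cutoff
by at most one sweep step). Pairwise phase-locking values are computed over
the second half subsampled to 50 timepoints. The instantaneous frequency
θ̇/2π serves as a firing-rate proxy: because the coupling term is
antisymmetric under exchange of oscillator indices, the population-mean
rate stays pinned to the feedforward mean(ν) and is insensitive to
coupling changes, which is why rate readouts cannot carry learning effects.

## Learning

Between sessions, coupling relaxes toward experience:
K^{s+1} = e^{−E}·Kˢ + (1 − e^{−E})·γ·Qˢ, with E = ε·t the effective
learning rate. Qˢ is the weight-normalized mean of per-trial PLV matrices,
each trial weighted by its probability of a correct response
P_c(r) = 1/(1 + exp(−μ₀ − μ₁·r)); normalizing by the weight sum keeps
Q ∈ [0, 1] and hence K ≤ γ for any number of sessions. (μ₀, μ₁) are fit by
binomial maximum likelihood (logistic regression) to first-session
per-condition accuracies against simulated first-session synchrony. E is
estimated by a coarse-to-fine grid search (five nested grids of 25
candidates; the first log-spaced over [10⁻³, 10], each refinement spanning
the interval between the neighbors of the previous optimum; ties break to
the smallest E) maximizing the weighted Jaccard similarity between
min-max-normalized session-2 accuracy and simulated session-2 synchrony.
Candidate evaluations reuse the same stimuli and initial phases (common
random numbers), so the objective is smooth in E.

Growth mechanism: phase-locked pairs acquire Q near 1 regardless of their
cortical distance, so distant pairs — weakly coupled at session 1 — are
pulled up toward γQ, extending synchronization to sparser stimulation over
sessions, while the γ bound keeps the contrast-heterogeneity cutoff in
place. The ninth (transfer) session is never simulated: learning is
retinotopically local and the figure moves to an untrained quadrant.

Identifiability: E is only *set*-identified by the Jaccard objective. The
min-max-normalized behavioral tongue always contains a cell at exactly 1,
which simulated synchrony approaches from below, so the objective rises to
a plateau in E (spread ≈10⁻³ across the plateau) rather than peaking at
the generating value. The recovery tests therefore assert exact agreement
of the nested search with brute-force evaluation and *functional* recovery
— the estimated E reproduces the generating E's session-2 synchrony tongue
— rather than raw-parameter proximity.

## Synthetic behavior

The cohort generator emulates the per-trial structure of the human
experiment: 8 participants × 9 sessions × 30 blocks × 25 conditions, one
2AFC orientation judgment per trial. Per-condition accuracy is
Bernoulli(max(0.5, (1 − lapse)·P_c(r))) with r the model's session tongue;
session 9 reuses session-1 synchrony (transfer reset). Subject
heterogeneity: normal μ₀ offsets (sd 0.3), log-normal μ₁ scales (sd 0.2),
log-normal subject learning rates, lapse rates uniform on [0, 0.04] — all
configurable. What the generator does not emulate: reaction times, fixation
breaks and trial repetition, sequential (block-order) effects, and any
accuracy structure beyond the synchrony-through-logistic link. Passing
tests therefore show that the estimation pipeline recovers the generating
law, not that the law describes real observers.

The chance clip makes the unclipped logistic fit inconsistent at
near-floor synchrony; recovery tests use populations whose P_c stays above
0.5 everywhere (the identifiable regime), while pipeline-level tests use
the clipped default.

## Numerical and statistical choices

* Integrator tolerances as above; trials with identical named random
  streams are bit-reproducible regardless of execution order or batching.
* Randomness: every stimulus draw, initial-phase vector, and synthetic
  subject uses a dedicated stream keyed by (kind, session, block,
  condition) under one workflow seed (default 1709026616).
* Simpson tongue volumes are computed on the native (ζ, ρ) axes; the 5 × 5
  design grid is within 5% of a 31-point grid for smooth tongues.
* Monotonicity and growth assertions on simulated tongues use a 2-SEM
  noise allowance estimated from per-block spread — the calibrated form of
  a monotonicity claim about Monte-Carlo averages.
* Degenerate inputs: constant maps cannot be min-max normalized or
  correlated (errors); two all-zero maps have weighted Jaccard 1; perfect
  separation and degenerate accuracies raise fit errors rather than
  returning runaway estimates.

## Problem sizes used in the shipped analyses

Analytic identities are exact and instantaneous. The session-1 cutoff
sweep uses the full 20 × 20 sheet with 16–32 trials per ζ level; the
tongue-shape and learning analyses use 16 blocks and 8 sessions × 8 blocks
respectively on the full sheet; parameter recovery runs on a 10 × 10 sheet
with 5-block sessions, 8 × 30-block cohorts, and single-block candidate
evaluations in the E search. These sizes give Monte-Carlo standard errors
well below the margins of the corresponding claims (e.g. the nearest
failing ζ level in the cutoff sweep sits ≈4 SEM below the synchronization
threshold).

## Known limitations and deviations

* A small genuine *increase* of incoherent-floor synchrony with grid
  coarseness (≈+0.02 in r at the coarsest grid) arises from shared-element
  frequency correlations; the idealized tongue is weakly non-monotone in ρ
  at heterogeneities far above the cutoff.
* The ρ effect on session-1 synchrony is weak at low ζ (detuning is then
  nearly zero at every coarseness); coarseness differentiates the tongue
  mainly through learning and in the transition zone.
* Background texture is not simulated; the background firing-rate proxy is
  purely feedforward.
* The cortical-distance unit convention is a modeling decision (see
  Oscillator sheet); all downstream quantities depend on it only through
  the coupling profile.
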
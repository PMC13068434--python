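# gammatongue

A weakly-coupled-oscillator model of early visual cortex (V1) that predicts
human figure–ground segregation in texture stimuli from gamma-band
synchronization, together with the full analysis pipeline: stimulus
synthesis, retinotopic oscillator sheet, Kuramoto dynamics, Hebbian
plasticity of lateral coupling across training sessions, Arnold-tongue
comparison metrics, and a synthetic-behavior generator for end-to-end
testing of the estimation code.

**Who it is for.** Computational and visual neuroscientists studying
synchrony-based perceptual grouping, perceptual learning, or
psychophysics–model linking; anyone who needs a reproducible
Kuramoto-on-retinotopy simulation with stimulus-driven detuning.

## The model

A texture of Gabor annuli is viewed by an n × n (n = 20) sheet of phase
oscillators with receptive fields tiling a 6.7° × 6.7° patch at 7°
eccentricity. Each oscillator's intrinsic frequency follows its local
contrast, ν = 25 + 0.25·C Hz, where C is the Gaussian-RF-weighted RMS
contrast (in percent) of the annuli in its receptive field. Phases evolve
by the Kuramoto equation

    θ̇ᵢ = ωᵢ + (1/N) Σⱼ Kˢᵢⱼ sin(θⱼ − θᵢ),     ωᵢ = 2πνᵢ,

with session-1 coupling decaying exponentially with cortical distance,
K¹ᵢⱼ = γ e^(−λ dᵢⱼ) (γ = 24.63, λ = 0.22/mm, macaque-calibrated), distances
from the complex-log retinotopic map w = α ln(z + a) (a = 0.7, α = 0.9).
Stimulus **contrast heterogeneity** ζ (the width of the uniform
distribution annulus contrasts are drawn from) controls frequency
*detuning*; **grid coarseness** ρ (annulus spacing scale) controls how
sparsely the sheet is driven. Synchrony is the Kuramoto order parameter
r = |mean e^{iθ}| averaged over the second half of each 1 s trial; over the
(ζ, ρ) condition grid it forms an **Arnold tongue** that predicts 2AFC
discrimination accuracy through a logistic link P_c = 1/(1+e^{−μ₀−μ₁r}).
Between sessions, coupling learns Hebbianly from correctness-weighted
phase-locking values Q: K^{s+1} = e^{−E}Kˢ + (1−e^{−E})γQˢ, with a single
effective learning rate E fit to second-session behavior.

See `docs/methods.md` for assumptions, parameter conventions, and known
limitations.

## Worked example

```python
import numpy as np
import gammatongue as gt

sheet = gt.build_sheet(n=20)                    # 400 oscillators
K1 = gt.initial_coupling(sheet)                 # K1_ij = 24.63 exp(-0.22 d_ij)
sim = gt.SessionSimulator(sheet=sheet, seed=1)
res = sim.run_session(K1.K, session=1, blocks=4)

np.set_printoptions(precision=2, suppress=True)
print(res.tongue.values)          # rows: zeta levels, cols: rho levels
print(round(gt.tongue_size(res.tongue), 4))
```

prints

```
[[0.82 0.83 0.77 0.76 0.88]
 [0.07 0.1  0.1  0.09 0.1 ]
 [0.06 0.06 0.06 0.06 0.06]
 [0.06 0.05 0.06 0.06 0.07]
 [0.05 0.05 0.05 0.05 0.05]]
0.065
```

Read this as the session-1 Arnold tongue: the network synchronizes
(r ≈ 0.8) only at the lowest contrast heterogeneity (ζ = 0.01, top row) —
annuli there share nearly identical contrast, so the oscillators are barely
detuned — and collapses to the incoherent floor (r ≈ 0.05–0.1, about
1/√N) once heterogeneity exceeds the synchronization cutoff. The scalar
0.065 is the Simpson-rule volume under the tongue, the summary that grows
across training sessions as Hebbian learning strengthens long-range
coupling. Analytic anchors: `gt.rf_diameter(7.0)` → `1.0` (degrees),
`gt.diameter_to_sigma(1.0)` → `0.25`, and the contrast–frequency rule maps
C = 0 → 25 Hz, C = 100 → 50 Hz.

A thin CLI wraps the same library:

```bash
gamma-tongue simulate --session 1 --blocks 4 --seed 1 --out out/
gamma-tongue synth --n 8 --out cohort.csv
gamma-tongue train --cohort cohort.csv --out fit/
gamma-tongue metrics --a fit/synchrony_session1.csv --metric size
```

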
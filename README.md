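# dyadosc

Coupled-oscillator analysis of dyadic interbeat-interval (IBI)
dynamics: a Python pipeline for studying **physiological linkage** —
the statistical interdependence of two interacting people's autonomic
signals — in terms of oscillation frequency, phase, damping or
amplification, and between-partner coupling.

The pipeline is aimed at researchers with dyadic psychophysiology data
(e.g. ECG-derived IBIs from two people doing a joint task) who want to
go beyond cross-correlation: estimate each dyad's dynamics, group dyads
into qualitatively distinct linkage patterns, and relate those patterns
to experimental conditions and questionnaire covariates.

## The model

For each dyad, both partners' detrended IBI series x_A(t), x_B(t)
(2-s window means, linearly detrended) follow a coupled damped linear
oscillator:

```
x_A'' = η_A x_A + ζ_A x_A' + η_AB x_B + ζ_AB x_B'
x_B'' = η_B x_B + ζ_B x_B' + η_BA x_A + ζ_BA x_A'
```

where η (own position) sets the oscillation frequency — oscillatory iff
η < 0, with period 2π/√(−η) sample units — ζ (own velocity) sets
damping (ζ < 0) or amplification (ζ > 0), and the cross terms couple
the partners in frequency and damping. Derivatives are estimated by
generalized Local Linear Approximation (GLLA) over a time-delay
embedding; the 8 coefficients per dyad are fit by stacked OLS, with the
embedding (tau ∈ {3,4}, embed ∈ {3,4,5}) chosen per dyad by maximizing
adjusted R². The per-dyad coefficient vectors feed a latent profile
analysis (diagonal-covariance Gaussian mixture), and profile membership
feeds Bayesian stage-2 models (hierarchical outcome models with
dyad-varying intercepts; multinomial-logit membership models on dyad
average/difference covariates) reported with 90% highest-density
intervals.

A synthetic-data generator produces full studies from known dynamics —
three regimes (slow in-phase damping, fast in-phase damping, fast
anti-phase), a balanced 2×2 condition design, covariates with plantable
effects on regime membership — so every stage is testable with known
ground truth. See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
from dyadosc import co_model, preprocess, synth

# a noise-free dyad from the slow in-phase regime
dyad = synth.make_archetype("slow_inphase_damping", n_steps=150, seed=3, noise_sd=0.0)
a = preprocess.detrend_linear(dyad.series_a)
b = preprocess.detrend_linear(dyad.series_b)

fit = co_model.co_grid_search(a, b)
print(f"tau={fit.tau} embed={fit.embed} adj_r2={fit.adj_r2:.4f}")
print(f"period A = {fit.period_a:.1f} units = {fit.period_a_s:.0f} s")
print(f"own-frequency coefficients: {fit.coefficients['eta_self_a']:.4f}, "
      f"{fit.coefficients['eta_self_b']:.4f}")
```

prints

```
tau=4 embed=5 adj_r2=0.9967
period A = 50.3 units = 101 s
own-frequency coefficients: -0.0156, -0.0176
```

The grid picked (tau=4, embed=5); the fitted own-frequency coefficients
are negative (oscillatory) and imply periods of ~47–50 sample units —
the generating regime oscillates at 45–50 samples, and GLLA attenuates
frequency coefficients slightly toward zero, so fitted periods read a
bit long. The near-1 adjusted R² reflects a noise-free dyad.

The same flow from a shell, end to end on a simulated study:

```sh
dyadosc run --out-dir results/run1 --seed 1
```

writes the cleaned series, the per-dyad 8-coefficient table
(`co_parameters.csv`), the fit summary, the profile-selection report
and assignments, per-profile predicted-trajectory plots, one posterior
summary CSV per stage-2 model, and a `manifest.json` with SHA-256
checksums — re-running with the same seed reproduces every artifact
byte for byte. Individual stages are available as `dyadosc simulate`,
`preprocess`, `fit`, `profiles`, and `models`.

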
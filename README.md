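# swaybayes

Bayesian attribution analysis of visually driven postural sway.

When the entire visual scene moves, the retinal signal is ambiguous: the
perceived relative motion `r = v_e − v_b` could come from the environment
moving (`v_e`) or from the body swaying (`v_b`). Standing observers resolve
this by combining vision with vestibular and kinesthetic cues. This package
implements, as a tested analysis pipeline, a Bayesian observer model of that
attribution and the posturography machinery needed to test it against sway
recordings. It is aimed at researchers in sensorimotor integration and
postural control who want to fit and compare gain models on
visual-perturbation posturography data, or to prototype such analyses on
synthetic cohorts.

## The model

The observer combines

* a zero-mean Gaussian prior over body velocity, merged with the Gaussian
  likelihood of the physical cues signalling upright stance, into one
  Gaussian with variance σ<sub>c</sub>²;
* a sparse prior over environment velocity,
  p(v<sub>e</sub>) ∝ exp(−c·|v<sub>e</sub>/v₀|<sup>α</sup>), with α < 2
  encoding that the visual world usually moves slowly;
* noiseless vision, so hypothesising a body velocity v<sub>b</sub> implies an
  environment velocity r + v<sub>b</sub>.

A first-order expansion of the environment-prior log density around the
percept gives the MAP body-velocity estimate in closed form,

&nbsp;&nbsp;&nbsp;&nbsp;v̂<sub>b</sub> = −sign(r)·σ<sub>c</sub>²·c·α·(|r|/v₀)<sup>α−1</sup>,

so the predicted postural response **gain is a power law of scene velocity
with exponent α − 2**: near-flat for a Gaussian-like prior (α ≈ 2, as fitted
to vestibular-loss patients), steeply falling for a sparse prior (healthy
subjects). A dense-grid posterior argmax serves as the numerical oracle for
this closed form, including the exact Gaussian special case and an optional
finite visual-noise marginalisation.

Around the core model the package provides:

* `posturography` — 4th-order zero-phase Butterworth filtering (6 Hz),
  shoulder-midpoint trunk displacement, closed-form sinusoid fitting at the
  stimulus frequency, response gain, and quiet-stance velocity
  distributions;
* `gain_models` — the attribution power law plus three competitors
  (constant gain; log-growing saturating response amplitude; piecewise
  constant-then-decreasing gain), deterministic least-squares fitting,
  Gaussian BIC (profiled- or known-variance form), paired t-tests and
  log-log slope statistics;
* `synthetic` — seeded cohorts mirroring the study design (10 subjects,
  0.2 Hz scene oscillation at 1–150 cm amplitude, 60 s trials at 120 Hz,
  plus quiet-stance controls with exactly Gaussian stationary velocity);
* `cli` — a thin `swaybayes` command with `simulate`, `extract`, `fit`,
  `compare` and `report` subcommands.

## Worked example

```python
import numpy as np
from swaybayes import (AttributionParams, StimulusSpec, peak_velocity,
                       predicted_gain, loglog_slope, build_comparison)
from swaybayes.synthetic import generate_gain_curves

amps = [1, 3, 25, 100, 150]                      # scene amplitudes, cm
v = np.array([peak_velocity(StimulusSpec(frequency=0.2, amplitude=a))
              for a in amps])
print("peak velocities:", np.round(v, 1))

healthy = AttributionParams(sigma_c2=0.34, alpha=1.32)
print("predicted gains:", np.round(predicted_gain(v, healthy), 3))
print("log-log slope:", round(loglog_slope(v, predicted_gain(v, healthy)), 2))

curves = generate_gain_curves("attribution", {"sigma_c2": 0.34, "alpha": 1.32},
                              noise_sd=0.02, n_subjects=10, seed=1)
report = build_comparison(curves, noise_variance=0.02**2)
for m, b in sorted(report.mean_bic.items(), key=lambda kv: kv[1]):
    print(f"{m:15s} mean BIC {b:8.2f}")
t = report.paired_tests["constant"]
print(f"paired t-test vs constant: t={t.t:.1f}, p={t.p:.2g}")
```

prints

```
peak velocities: [  1.3   3.8  31.4 125.7 188.5]
predicted gains: [0.384 0.182 0.043 0.017 0.013]
log-log slope: -0.68
attribution     mean BIC     4.99
piecewise       mean BIC     6.42
log_saturation  mean BIC     7.27
constant        mean BIC   257.45
paired t-test vs constant: t=31.5, p=1.6e-10
```

The five stimulus amplitudes at 0.2 Hz sweep peak velocities from 1.3 to
188 cm/s. The healthy parameter set (σ<sub>c</sub>² = 0.34, α = 1.32)
predicts near-0.4 gain at the slowest scene and a hundred-fold smaller gain
at the fastest, falling on an exact power law of slope α − 2 = −0.68. On a
ten-subject synthetic cohort generated from that model (gain noise s.d.
0.02), the attribution model attains the lowest mean BIC among the four
candidates — the nesting three-parameter piecewise model pays its extra
parameter penalty — and the constant-gain model is rejected decisively.

The same analysis end to end from the shell, via marker trajectories on
disk:

```sh
swaybayes report --seed 3 --out demo
# ... INFO mean BIC: {...} | slope -0.680 +/- 0.124 s.d.
```

which simulates a cohort (`demo/cohort/*.csv` + manifest), extracts per-trial
gains (`demo/gains.csv`), and writes the model-comparison report
(`demo/comparison.json`) with per-subject fits, BIC table, paired tests and
slope statistics. The recovered slope −0.68 ± 0.12 s.d. matches the
generating exponent.

## Limitations

The analytic power-law estimate is a first-order approximation valid when
scene velocity is large relative to body-sway uncertainty; its agreement
with the grid oracle degrades at slow velocities and for weakly sparse
priors with high physical-cue variance (see `docs/methods.md`). The
synthetic cohorts reproduce the statistical structure the analysis assumes,
not biomechanics; see the methods note for what passing tests do and do not
establish about real recordings.
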
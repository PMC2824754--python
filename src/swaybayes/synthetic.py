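"""Synthetic posturography cohorts.

Emulates the statistical structure of the study design the analysis assumes:
per subject, five 60 s visual-perturbation trials (AP scene oscillation at
0.2 Hz, displacement amplitudes 1, 3, 25, 100, 150 cm, i.e. peak velocities
~1.2-188 cm/s) plus one quiet-stance control, captured at 120 Hz as shoulder
and L5 marker trajectories.

Quiet sway is a stochastically driven damped linear oscillator in trunk
position — its stationary *velocity* marginal is exactly Gaussian (the
empirical feature the analysis relies on) while position stays bounded and
mean-reverting.  Perturbation trials superimpose on that sway a sinusoidal
trunk response whose amplitude follows the subject's gain model evaluated at
the scene's peak velocity.  Every artifact is a pure function of
(parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import linalg

from .gain_models import GainCurve, gain_function
from .posturography import (
    MarkerTrajectories,
    StimulusSpec,
    peak_velocity,
    write_marker_csv,
)

__all__ = [
    "SubjectParams",
    "CohortDataset",
    "STUDY_AMPLITUDES_CM",
    "STUDY_FREQUENCY_HZ",
    "generate_quiet_stance",
    "generate_trial",
    "generate_cohort",
    "generate_gain_curves",
]

#: scene displacement amplitudes of the study design, cm
STUDY_AMPLITUDES_CM = (1.0, 3.0, 25.0, 100.0, 150.0)
STUDY_FREQUENCY_HZ = 0.2
STUDY_DURATION_S = 60.0
STUDY_RATE_HZ = 120.0

#: damping ratio of the quiet-sway oscillator (broad, aperiodic-ish sway spectrum)
_SWAY_DAMPING = 0.7


@dataclass(frozen=True)
class SubjectParams:
    """Generating parameters for one synthetic subject.

    ``sway_relaxation`` is the positional relaxation time of the quiet-sway
    process (s); ``sway_velocity_sd`` the stationary s.d. of body velocity
    (cm/s); ``marker_jitter_sd`` iid measurement noise per marker sample (cm).
    """

    subject_id: str
    gain_model: str = "attribution"  # attribution | constant | log_saturation | piecewise
    gain_params: dict = field(default_factory=lambda: {"sigma_c2": 0.34, "alpha": 1.32})
    phase_lag: float = -0.3
    sway_relaxation: float = 1.6
    sway_velocity_sd: float = 0.8
    marker_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sway_velocity_sd < 0 or self.marker_jitter_sd < 0:
            raise ValueError("noise s.d. must be >= 0")
        if not (-math.pi < self.phase_lag <= math.pi):
            raise ValueError("phase_lag must lie in (-pi, pi]")
        if self.sway_relaxation <= 0:
            raise ValueError("sway_relaxation must be > 0")


def _sway_process(
    rng: np.random.Generator,
    n: int,
    dt: float,
    tau: float,
    sigma_v: float,
) -> np.ndarray:
    """Sample trunk position from the damped stochastic oscillator.

    ``x'' = -w0^2 x - 2*zeta*w0 x' + sqrt(q) xi`` with ``w0 = 1/tau``,
    ``zeta = 0.7`` and ``q = 4*zeta*w0*sigma_v^2``, exactly discretised via
    Van Loan matrix exponentials.  Stationary: ``sd(v) = sigma_v``,
    ``sd(x) = sigma_v * tau``, x and v uncorrelated; both marginals Gaussian.
    """
    if sigma_v == 0.0:
        return np.zeros(n)
    w0 = 1.0 / tau
    zeta = _SWAY_DAMPING
    q = 4.0 * zeta * w0 * sigma_v**2
    F = np.array([[0.0, 1.0], [-(w0**2), -2.0 * zeta * w0]])
    L = np.array([[0.0], [1.0]])
    # Van Loan: exact transition matrix A and process-noise covariance Q over dt
    M = np.zeros((4, 4))
    M[:2, :2] = F
    M[:2, 2:] = L @ L.T * q
    M[2:, 2:] = -F.T
    E = linalg.expm(M * dt)
    A = E[:2, :2]
    Q = E[:2, 2:] @ A.T
    Q = 0.5 * (Q + Q.T)
    chol = np.linalg.cholesky(Q + 1e-18 * np.eye(2))
    # stationary initial state: x ~ N(0, (sigma_v*tau)^2), v ~ N(0, sigma_v^2)
    z = np.array([sigma_v * tau, sigma_v]) * rng.standard_normal(2)
    shocks = rng.standard_normal((n - 1, 2))
    out = np.empty(n)
    out[0] = z[0]
    for i in range(1, n):
        z = A @ z + chol @ shocks[i - 1]
        out[i] = z[0]
    return out


def _markers_from_trunk(
    trunk: np.ndarray,
    time: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    jitter_sd: float,
) -> MarkerTrajectories:
    """Derive shoulder/L5 marker traces from a trunk AP signal.

    Shoulders sit at fixed AP offsets (symmetric, so their midpoint recovers
    the trunk signal exactly when jitter is 0); L5 follows the trunk with an
    attenuation typical of pelvis motion.
    """
    n = len(trunk)
    jit = lambda: rng.normal(0.0, jitter_sd, n) if jitter_sd > 0 else 0.0
    return MarkerTrajectories(
        sample_rate=rate,
        time=time,
        lsho_ap=trunk + 1.5 + jit(),
        rsho_ap=trunk - 1.5 + jit(),
        l5_ap=0.4 * trunk + jit(),
    )


def generate_quiet_stance(
    subject: SubjectParams,
    duration: float = STUDY_DURATION_S,
    rate: float = STUDY_RATE_HZ,
) -> MarkerTrajectories:
    """One stationary-scene control trial for a subject. Deterministic under seed."""
    if duration < 30.0:
        raise ValueError("control trials must last >= 30 s")
    if rate <= 12.0:
        raise ValueError("rate must exceed twice the 6 Hz analysis-filter cutoff")
    rng = np.random.default_rng([int(subject.seed), 0])
    n = int(round(duration * rate)) + 1
    time = np.arange(n) / rate
    trunk = _sway_process(
        rng, n, 1.0 / rate, subject.sway_relaxation, subject.sway_velocity_sd
    )
    return _markers_from_trunk(trunk, time, rate, rng, subject.marker_jitter_sd)


def generate_trial(
    subject: SubjectParams,
    stim: StimulusSpec,
    duration: float | None = None,
    rate: float = STUDY_RATE_HZ,
) -> MarkerTrajectories:
    """One visual-perturbation trial.

    Trunk AP = ``G(peak_velocity) * amplitude * sin(2*pi*f*t + phase_lag)``
    plus the subject's quiet-sway noise, where ``G`` is the subject's gain
    model.  Trial index for seeding is derived from the stimulus amplitude so
    each (subject, stimulus) pair has its own reproducible stream.
    """
    if rate <= 12.0:
        raise ValueError("rate must exceed twice the 6 Hz analysis-filter cutoff")
    duration = stim.duration if duration is None else duration
    n = int(round(duration * rate)) + 1
    time = np.arange(n) / rate
    if stim.is_control:
        response = np.zeros(n)
    else:
        g = gain_function(subject.gain_model, subject.gain_params)(peak_velocity(stim))
        response = (
            g * stim.amplitude
            * np.sin(2.0 * math.pi * stim.frequency * time + subject.phase_lag)
        )
    trial_key = int(round(stim.amplitude * 1000)) + 1
    rng = np.random.default_rng([int(subject.seed), trial_key])
    sway = _sway_process(
        rng, n, 1.0 / rate, subject.sway_relaxation, subject.sway_velocity_sd
    )
    return _markers_from_trunk(
        response + sway, time, rate, rng, subject.marker_jitter_sd
    )


@dataclass
class CohortDataset:
    """A synthetic cohort: per subject, stimulus trials plus one quiet-stance trial.

    ``manifest`` records every generating parameter and seed, sufficient to
    regenerate the dataset bit-for-bit.
    """

    subjects: list[SubjectParams]
    trials: dict[str, list[tuple[StimulusSpec, MarkerTrajectories]]]
    quiet: dict[str, MarkerTrajectories]
    manifest: dict

    def write(self, outdir) -> Path:
        """Write marker CSVs and manifest.json; returns the manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = []
        for subj in self.subjects:
            sid = subj.subject_id
            for stim, traj in self.trials[sid]:
                fname = f"{sid}_amp{stim.amplitude:g}.csv"
                write_marker_csv(traj, outdir / fname)
                files.append(
                    {
                        "file": fname,
                        "subject_id": sid,
                        "frequency_hz": stim.frequency,
                        "amplitude_cm": stim.amplitude,
                        "duration_s": stim.duration,
                    }
                )
            fname = f"{sid}_quiet.csv"
            write_marker_csv(self.quiet[sid], outdir / fname)
            files.append(
                {
                    "file": fname,
                    "subject_id": sid,
                    "frequency_hz": None,
                    "amplitude_cm": 0.0,
                    "duration_s": self.manifest["duration_s"],
                }
            )
        manifest = dict(self.manifest, files=files)
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return mpath


def calibrated_sway_sd(
    gain_noise_sd: float,
    amplitude_cm: float = 1.0,
    frequency: float = STUDY_FREQUENCY_HZ,
    duration: float = STUDY_DURATION_S,
    relaxation: float = 1.6,
) -> float:
    """Sway velocity s.d. that induces a target gain-measurement noise.

    The least-squares amplitude estimate of a ``duration``-long sinusoid fit
    against sway with two-sided position PSD ``S_x`` has standard error
    ``sqrt(2*S_x(w_stim)/duration)``.  For the quiet-sway oscillator
    (``w0 = 1/relaxation``, damping ``zeta``), ``S_x`` scales with
    ``sigma_v^2``, so the sway level delivering gain noise ``gain_noise_sd``
    at a scene amplitude of ``amplitude_cm`` has the closed form below.
    Trials at larger amplitudes then carry proportionally *less* gain noise.
    """
    w0 = 1.0 / relaxation
    zeta = _SWAY_DAMPING
    w = 2.0 * math.pi * frequency
    q_unit = 4.0 * zeta * w0  # process intensity per unit sigma_v^2
    s_unit = q_unit / ((w0**2 - w**2) ** 2 + (2.0 * zeta * w0 * w) ** 2)
    amp_sd_unit = math.sqrt(2.0 * s_unit / duration)
    return gain_noise_sd * amplitude_cm / amp_sd_unit


def make_attribution_sampler(
    sigma_c2: float = 0.34,
    alpha: float = 1.32,
    sigma_c2_spread: float = 0.03,
    alpha_spread: float = 0.05,
    sway_velocity_sd: float = 0.8,
):
    """Population sampler for attribution-truth cohorts.

    Central values follow the healthy fit (sigma_c2 = 0.34, alpha = 1.32)
    with modest inter-subject spread; phase lags are free parameters.
    ``sway_velocity_sd`` sets the quiet-sway level; pass
    :func:`calibrated_sway_sd` output to realise a prescribed
    gain-measurement noise in parameter-recovery experiments.
    """

    def sampler(rng: np.random.Generator) -> dict:
        return {
            "gain_model": "attribution",
            "gain_params": {
                "sigma_c2": float(np.clip(rng.normal(sigma_c2, sigma_c2_spread), 0.05, 1.5)),
                "alpha": float(np.clip(rng.normal(alpha, alpha_spread), 0.2, 2.5)),
            },
            "phase_lag": float(rng.uniform(-0.6, 0.0)),
            "sway_relaxation": 1.6,
            "sway_velocity_sd": sway_velocity_sd,
            "marker_jitter_sd": 0.02,
        }

    return sampler


_default_subject_sampler = make_attribution_sampler()


def generate_cohort(
    n_subjects: int = 10,
    amplitudes: tuple = STUDY_AMPLITUDES_CM,
    frequency: float = STUDY_FREQUENCY_HZ,
    duration: float = STUDY_DURATION_S,
    rate: float = STUDY_RATE_HZ,
    master_seed: int = 0,
    subject_sampler=None,
) -> CohortDataset:
    """Generate a full synthetic cohort mirroring the study design.

    Defaults: 10 subjects x (5 stimulus amplitudes -> peak velocities
    1.2, 3.7, 31, 125, 188 cm/s + 1 quiet-stance control), 60 s at 120 Hz.
    Per-subject seeds derive deterministically from ``master_seed``.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs >= 2 subjects")
    sampler = subject_sampler or _default_subject_sampler
    master_rng = np.random.default_rng(int(master_seed))
    seeds = master_rng.integers(0, 2**31 - 1, size=n_subjects)
    subjects = []
    for i in range(n_subjects):
        draw = sampler(master_rng)
        subjects.append(SubjectParams(subject_id=f"s{i:02d}", seed=int(seeds[i]), **draw))
    if len({s.subject_id for s in subjects}) != n_subjects:
        raise ValueError("duplicate subject ids")
    trials: dict[str, list] = {}
    quiet: dict[str, MarkerTrajectories] = {}
    for subj in subjects:
        rows = []
        for amp in amplitudes:
            stim = StimulusSpec(frequency=frequency, amplitude=float(amp), duration=duration)
            rows.append((stim, generate_trial(subj, stim, duration=duration, rate=rate)))
        trials[subj.subject_id] = rows
        quiet[subj.subject_id] = generate_quiet_stance(subj, duration=duration, rate=rate)
    manifest = {
        "master_seed": int(master_seed),
        "n_subjects": n_subjects,
        "frequency_hz": frequency,
        "amplitudes_cm": list(amplitudes),
        "duration_s": duration,
        "rate_hz": rate,
        "subjects": [asdict(s) for s in subjects],
    }
    return CohortDataset(subjects=subjects, trials=trials, quiet=quiet, manifest=manifest)


def generate_gain_curves(
    model: str,
    params: dict,
    velocities=None,
    noise_sd: float = 0.02,
    n_subjects: int = 10,
    seed: int = 0,
    condition: str = "synthetic",
) -> list[GainCurve]:
    """Fast path: noisy gain curves straight from a gain model, no time series.

    ``gains = model(velocity) + iid N(0, noise_sd)``, floored at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if velocities is None:
        velocities = [
            peak_velocity(StimulusSpec(frequency=STUDY_FREQUENCY_HZ, amplitude=a))
            for a in STUDY_AMPLITUDES_CM
        ]
    v = np.asarray(velocities, dtype=float)
    truth = gain_function(model, params)(v)
    rng = np.random.default_rng(int(seed))
    curves = []
    for i in range(n_subjects):
        g = np.maximum(truth + rng.normal(0.0, noise_sd, len(v)), 0.0)
        curves.append(
            GainCurve(velocities=v, gains=g, subject_id=f"s{i:02d}", condition=condition)
        )
    return curves
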
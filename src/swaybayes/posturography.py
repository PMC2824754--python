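"""Posturography signal processing.

Reduces motion-capture marker trajectories (anterior-posterior positions of
the two shoulder markers and the fifth lumbar vertebra, sampled at 120 Hz) to
a trunk-displacement sway signal, and extracts from it either the sinusoidal
response to a moving visual scene (amplitude, phase, gain) or, for
quiet-stance trials, the distribution of body velocity.

Processing chain: 4th-order zero-phase Butterworth low-pass at 6 Hz →
shoulder-midpoint trunk displacement re-zeroed at trial start → closed-form
least-squares sinusoid fit at the stimulus frequency → gain = fitted
amplitude / scene amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

__all__ = [
    "MarkerTrajectories",
    "SwaySignal",
    "StimulusSpec",
    "SinusoidFit",
    "VelocityDistribution",
    "lowpass_filter",
    "trunk_displacement",
    "fit_sinusoid",
    "response_gain",
    "peak_velocity",
    "velocity_distribution",
    "read_marker_csv",
    "write_marker_csv",
    "FILTER_ORDER",
    "FILTER_CUTOFF_HZ",
]

FILTER_ORDER = 4
FILTER_CUTOFF_HZ = 6.0

#: longest run of missing samples repaired by linear interpolation on ingest
MAX_GAP_SAMPLES = 5


@dataclass(frozen=True)
class MarkerTrajectories:
    """AP marker positions (cm) for left/right shoulder and L5, uniformly sampled."""

    sample_rate: float  # Hz
    time: np.ndarray  # s
    lsho_ap: np.ndarray  # left shoulder AP, cm
    rsho_ap: np.ndarray  # right shoulder AP, cm
    l5_ap: np.ndarray  # fifth lumbar vertebra AP, cm

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        cols = {}
        for name in ("lsho_ap", "rsho_ap", "l5_ap"):
            x = np.asarray(getattr(self, name), dtype=float)
            if x.shape != t.shape:
                raise ValueError(f"{name} length does not match time")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"{name} contains non-finite samples after ingest")
            cols[name] = x
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        dt = np.diff(t)
        if len(t) < 2 or not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
            raise ValueError("time must be uniformly sampled at sample_rate")
        object.__setattr__(self, "time", t)
        for name, x in cols.items():
            object.__setattr__(self, name, x)

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SwaySignal:
    """Trunk AP displacement (cm) relative to trial start."""

    sample_rate: float
    displacement: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.displacement, dtype=float)
        if x.ndim != 1 or len(x) < 2:
            raise ValueError("displacement must be a 1-D array with >= 2 samples")
        if x[0] != 0.0:
            raise ValueError("displacement must be re-zeroed to the first sample")
        object.__setattr__(self, "displacement", x)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.displacement)) / self.sample_rate

    @property
    def duration(self) -> float:
        return (len(self.displacement) - 1) / self.sample_rate


@dataclass(frozen=True)
class StimulusSpec:
    """Sinusoidal AP scene motion: frequency (Hz), displacement amplitude (cm), duration (s).

    ``amplitude = 0`` encodes the stationary-scene (quiet stance) control.
    """

    frequency: float = 0.2
    amplitude: float = 25.0
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def is_control(self) -> bool:
        return self.amplitude == 0.0


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares sinusoid ``A*sin(2*pi*f*t + phase) + offset`` fitted to sway."""

    amplitude: float  # cm, >= 0
    phase: float  # rad, in (-pi, pi]
    offset: float  # cm
    rss: float  # cm^2
    frequency: float  # Hz

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class VelocityDistribution:
    """Histogram and Gaussian fit of quiet-stance body velocity (cm/s)."""

    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    gof_stat: float  # D'Agostino normality statistic on decorrelated samples
    gof_p: float
    n_effective: int  # decorrelated sample count used for the test


# ---------------------------------------------------------------------------
# filtering and reduction
# ---------------------------------------------------------------------------

def _butter_sos(sample_rate: float):
    return sps.butter(FILTER_ORDER, FILTER_CUTOFF_HZ, fs=sample_rate, output="sos")


def lowpass_filter(traj: MarkerTrajectories) -> MarkerTrajectories:
    """Zero-phase 4th-order Butterworth low-pass (6 Hz) on every marker channel.

    Applied forward-backward (``sosfiltfilt``) so the stimulus-frequency phase
    is not biased; DC and the 0.2 Hz passband are preserved to well under 0.1%.
    """
    if traj.sample_rate <= 2 * FILTER_CUTOFF_HZ:
        raise ValueError("sample_rate must exceed twice the filter cutoff")
    sos = _butter_sos(traj.sample_rate)
    warmup = 3 * (2 * sos.shape[0] + 1)  # ~ sosfiltfilt default pad length
    if traj.n_samples < 3 * warmup:
        raise ValueError(
            f"signal too short for stable zero-phase filtering "
            f"(need >= {3 * warmup} samples, got {traj.n_samples})"
        )
    filt = {
        name: sps.sosfiltfilt(sos, getattr(traj, name))
        for name in ("lsho_ap", "rsho_ap", "l5_ap")
    }
    return replace(traj, **filt)


def trunk_displacement(traj: MarkerTrajectories) -> SwaySignal:
    """Trunk AP displacement: shoulder-marker midpoint, re-zeroed to the first sample.

    The L5 marker is ingested and carried along but not used by this default
    reducer.
    """
    mid = 0.5 * (traj.lsho_ap + traj.rsho_ap)
    disp = mid - mid[0]
    disp[0] = 0.0  # exact zero despite float rounding
    return SwaySignal(sample_rate=traj.sample_rate, displacement=disp)


# ---------------------------------------------------------------------------
# sinusoid fitting and gain
# ---------------------------------------------------------------------------

def fit_sinusoid(sway: SwaySignal, frequency: float) -> SinusoidFit:
    """Closed-form least squares of ``a*sin + b*cos + offset`` at one frequency.

    Amplitude is ``hypot(a, b)`` and phase ``atan2(b, a)``, so a signal
    ``A*sin(2*pi*f*t + phi)`` is recovered exactly.  The DC offset regressor
    is included; on detrended data it fits ~0 and the classic two-parameter
    description is nested within.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if frequency >= sway.sample_rate / 2:
        raise ValueError("frequency must be below the Nyquist rate")
    if sway.duration < 2.0 / frequency * (1.0 - 1e-9):
        raise ValueError("need at least 2 stimulus periods of signal")
    t = sway.time
    w = 2.0 * math.pi * frequency
    design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, _, _, _ = np.linalg.lstsq(design, sway.displacement, rcond=None)
    a, b, offset = coef
    resid = sway.displacement - design @ coef
    phase = math.atan2(b, a)
    if phase <= -math.pi:  # wrap to (-pi, pi]
        phase += 2.0 * math.pi
    return SinusoidFit(
        amplitude=float(np.hypot(a, b)),
        phase=float(phase),
        offset=float(offset),
        rss=float(np.dot(resid, resid)),
        frequency=frequency,
    )


def response_gain(fit: SinusoidFit, stim: StimulusSpec) -> float:
    """Response gain: fitted sway amplitude over scene displacement amplitude.

    Dimensionless; identical to the velocity-amplitude ratio at matched
    frequency.  Undefined for the stationary-scene control.
    """
    if stim.amplitude <= 0:
        raise ValueError("gain undefined for control trials (amplitude 0)")
    return fit.amplitude / stim.amplitude


def peak_velocity(stim: StimulusSpec) -> float:
    """Peak velocity of the sinusoidal scene motion, ``2*pi*f*A`` (cm/s)."""
    return 2.0 * math.pi * stim.frequency * stim.amplitude


# ---------------------------------------------------------------------------
# quiet stance
# ---------------------------------------------------------------------------

def velocity_distribution(
    sway: SwaySignal, decorrelation_s: float = 2.0
) -> VelocityDistribution:
    """Body-velocity distribution of a quiet-stance recording.

    Velocity by central differences of the (filtered) displacement at the
    native rate; histogram with Freedman-Diaconis bins; Gaussian fit by sample
    mean and s.d.  Normality (D'Agostino) is assessed on a subsample spaced
    ``decorrelation_s`` apart because consecutive 120 Hz samples are strongly
    autocorrelated and would invalidate the iid test.
    """
    if sway.duration < 30.0 * (1.0 - 1e-9):  # tolerate rate round-trip error
        raise ValueError("quiet-stance analysis needs >= 30 s of signal")
    x = sway.displacement
    if np.ptp(x) == 0.0:
        raise ValueError("constant signal: velocity distribution degenerate")
    v = np.gradient(x, 1.0 / sway.sample_rate)
    edges = np.histogram_bin_edges(v, bins="fd")
    counts, _ = np.histogram(v, bins=edges)
    step = max(1, int(round(decorrelation_s * sway.sample_rate)))
    v_sub = v[::step]
    if len(v_sub) >= 20 and np.ptp(v_sub) > 0:
        stat, p = stats.normaltest(v_sub)
    else:
        stat, p = math.nan, math.nan
    return VelocityDistribution(
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)),
        bin_edges=edges,
        counts=counts,
        gof_stat=float(stat),
        gof_p=float(p),
        n_effective=len(v_sub),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ["time_s", "lsho_ap_cm", "rsho_ap_cm", "l5_ap_cm"]


def _fill_gaps(x: np.ndarray, name: str) -> np.ndarray:
    """Linear interpolation over NaN runs of <= MAX_GAP_SAMPLES; longer runs reject."""
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad[0] or bad[-1]:
        raise ValueError(f"{name}: missing samples at trial boundary")
    # run-length check
    edges = np.diff(bad.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if np.any(ends - starts > MAX_GAP_SAMPLES):
        raise ValueError(
            f"{name}: gap longer than {MAX_GAP_SAMPLES} samples; trial rejected"
        )
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def read_marker_csv(path) -> MarkerTrajectories:
    """Read a marker-trajectory CSV (columns time_s, lsho_ap_cm, rsho_ap_cm, l5_ap_cm).

    Short dropout gaps (<= 5 samples) are repaired by linear interpolation;
    longer gaps reject the trial.
    """
    df = pd.read_csv(path)
    missing = set(_MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) < 2 or np.ptp(dt) > 1e-6 * np.median(dt):
        raise ValueError("marker CSV must be uniformly sampled")
    rate = 1.0 / float(np.median(dt))
    cols = {
        "lsho_ap": _fill_gaps(df["lsho_ap_cm"].to_numpy(dtype=float), "lsho_ap_cm"),
        "rsho_ap": _fill_gaps(df["rsho_ap_cm"].to_numpy(dtype=float), "rsho_ap_cm"),
        "l5_ap": _fill_gaps(df["l5_ap_cm"].to_numpy(dtype=float), "l5_ap_cm"),
    }
    return MarkerTrajectories(sample_rate=rate, time=t, **cols)


def write_marker_csv(traj: MarkerTrajectories, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": traj.time,
            "lsho_ap_cm": traj.lsho_ap,
            "rsho_ap_cm": traj.rsho_ap,
            "l5_ap_cm": traj.l5_ap,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
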
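"""Candidate gain models, least-squares fitting, BIC and model comparison.

Four models of how postural response gain depends on scene peak velocity:

* ``attribution`` — the Bayesian attribution power law
  ``g(s) = sigma_c2 * alpha * s**(alpha-2)`` (2 free parameters);
* ``constant`` — a linear controller's constant gain ``g0`` (1 parameter);
* ``log_saturation`` — response *amplitude* grows as ``m*ln(1 + s/v0)`` up to a
  saturation velocity ``v_sat = 2.8`` cm/s and is constant above it; the gain
  is that amplitude divided by ``s`` (1 parameter);
* ``piecewise`` — gain constant at ``g0`` below a corner velocity ``s_c`` and
  decaying as ``(s/s_c)**(-beta)`` above it (3 parameters).

Models are fit per subject by (deterministic) least squares on the gain scale,
scored with the Gaussian-residual BIC ``n*ln(rss/n) + k*ln(n)``, and compared
across subjects with a two-sided paired t-test on per-subject BIC values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .attribution import AttributionParams, predicted_gain

__all__ = [
    "GainCurve",
    "FitResult",
    "PairedTest",
    "ComparisonReport",
    "MODEL_NAMES",
    "V_SAT",
    "model_constant",
    "model_log_saturation",
    "model_piecewise",
    "model_attribution",
    "fit_model",
    "bic_score",
    "compare_models",
    "build_comparison",
    "loglog_slope",
    "aggregate_slopes",
    "read_gain_curves",
    "write_gain_curves",
]

#: saturation velocity of the log-saturation model, cm/s (fixed, from the
#: posturography literature, not fitted)
V_SAT = 2.8

MODEL_NAMES = ("attribution", "constant", "log_saturation", "piecewise")

RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class GainCurve:
    """Measured response gain versus scene peak velocity for one subject."""

    velocities: np.ndarray  # cm/s, strictly increasing, > 0
    gains: np.ndarray  # dimensionless, >= 0
    subject_id: str = "s00"
    condition: str = "synthetic"  # healthy | patient | synthetic

    def __post_init__(self) -> None:
        v = np.asarray(self.velocities, dtype=float)
        g = np.asarray(self.gains, dtype=float)
        if v.ndim != 1 or v.shape != g.shape:
            raise ValueError("velocities and gains must be equal-length 1-D arrays")
        if len(v) < 2:
            raise ValueError("a gain curve needs at least 2 points")
        if not np.all(np.diff(v) > 0) or not np.all(v > 0):
            raise ValueError("velocities must be positive and strictly increasing")
        if not np.all(g >= 0):
            raise ValueError("gains must be non-negative")
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "gains", g)


@dataclass(frozen=True)
class FitResult:
    """One model fitted to one gain curve."""

    model_name: str
    params: dict
    rss: float
    n: int
    k: int
    bic: float
    at_bounds: bool = False  # best solution pinned to a parameter bound

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if self.k not in (1, 2, 3):
            raise ValueError("k must be 1, 2 or 3")


@dataclass(frozen=True)
class PairedTest:
    """Two-sided paired t-test on per-subject BIC differences (model - reference)."""

    t: float
    p: float
    n: int
    mean_diff: float
    valid: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def model_constant(s, g0: float):
    """Constant gain ``g0`` at every velocity."""
    if g0 < 0:
        raise ValueError("g0 must be >= 0")
    s = np.asarray(s, dtype=float)
    out = np.full_like(s, float(g0))
    return float(out) if out.ndim == 0 else out


def model_log_saturation(s, m: float, v_sat: float = V_SAT, v0: float = 1.0):
    """Gain of a log-growing, saturating response amplitude.

    Response amplitude ``m*ln(1 + s/v0)`` for ``s <= v_sat``, constant
    ``m*ln(1 + v_sat/v0)`` above; the gain divides by ``s``, so at large ``s``
    it falls off as ``1/s`` (log-log slope -> -1).
    """
    if m <= 0:
        raise ValueError("m must be > 0")
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("velocity must be > 0")
    amp = m * np.log1p(np.minimum(s, v_sat) / v0)
    out = amp / s
    return float(out) if out.ndim == 0 else out


def model_piecewise(s, g0: float, s_c: float, beta: float):
    """Gain constant at ``g0`` up to ``s_c``, then ``g0*(s/s_c)**(-beta)``."""
    if g0 < 0 or s_c <= 0 or beta < 0:
        raise ValueError("require g0 >= 0, s_c > 0, beta >= 0")
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("velocity must be > 0")
    out = np.where(s <= s_c, g0, g0 * (np.maximum(s, s_c) / s_c) ** (-beta))
    return float(out) if out.ndim == 0 else out


def model_attribution(s, sigma_c2: float, alpha: float):
    """Attribution power-law gain ``sigma_c2*alpha*s**(alpha-2)`` (c=1, v0=1)."""
    return predicted_gain(s, AttributionParams(sigma_c2=sigma_c2, alpha=alpha))


_MODEL_FUNCS = {
    "constant": model_constant,
    "log_saturation": model_log_saturation,
    "piecewise": model_piecewise,
    "attribution": model_attribution,
}

_MODEL_K = {"constant": 1, "log_saturation": 1, "piecewise": 3, "attribution": 2}


def gain_function(model_name: str, params: dict):
    """Callable ``s -> gain`` for a named model with fixed parameters."""
    func = _MODEL_FUNCS[model_name]
    return lambda s: func(s, **params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def bic_score(n: int, rss: float, k: int, noise_variance: float | None = None) -> float:
    """Gaussian BIC of a least-squares fit (additive constants dropped).

    With ``noise_variance`` unknown (default) the variance is profiled out:
    ``n*ln(rss/n) + k*ln(n)``.  When the measurement-noise variance is known —
    e.g. on synthetic cohorts, where the generator defines it — the
    known-variance form ``rss/noise_variance + k*ln(n)`` is used instead.
    The profiled form over-rewards extra parameters at small ``n`` (it charges
    fitted noise on a log scale), so model *selection* among nested gain
    models should pass the known variance whenever one exists.

    ``rss`` is floored at 1e-12.
    """
    if n <= k:
        raise ValueError(f"unidentifiable fit: n={n} <= k={k}")
    rss = max(float(rss), RSS_FLOOR)
    if noise_variance is None:
        return n * math.log(rss / n) + k * math.log(n)
    if noise_variance <= 0:
        raise ValueError("noise_variance must be > 0")
    return rss / noise_variance + k * math.log(n)


def _rss(curve: GainCurve, model_name: str, params: dict) -> float:
    pred = _MODEL_FUNCS[model_name](curve.velocities, **params)
    return float(np.sum((curve.gains - pred) ** 2))


def _fit_constant(curve: GainCurve):
    g0 = float(np.mean(curve.gains))  # exact LS solution
    return {"g0": g0}, False


def _fit_log_saturation(curve: GainCurve):
    # linear in m: gain = m * basis(s)
    basis = np.log1p(np.minimum(curve.velocities, V_SAT)) / curve.velocities
    m = float(np.dot(basis, curve.gains) / np.dot(basis, basis))
    at_bounds = m <= 1e-9
    return {"m": max(m, 1e-9)}, at_bounds


_ALPHA_LO, _ALPHA_HI = 1e-3, 3.0


def _attribution_profile_rss(alpha: float, curve: GainCurve):
    """RSS minimised over the linear prefactor A = sigma_c2*alpha at fixed alpha."""
    phi = curve.velocities ** (alpha - 2.0)
    a = float(np.dot(phi, curve.gains) / np.dot(phi, phi))
    a = max(a, 1e-12)
    rss = float(np.sum((curve.gains - a * phi) ** 2))
    return rss, a


def _fit_attribution(curve: GainCurve):
    grid = np.linspace(_ALPHA_LO, _ALPHA_HI, 61)
    rss_grid = np.array([_attribution_profile_rss(al, curve)[0] for al in grid])
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda al: _attribution_profile_rss(al, curve)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    alpha = float(res.x) if res.fun <= rss_grid[i] else float(grid[i])
    _, a = _attribution_profile_rss(alpha, curve)
    at_bounds = alpha <= _ALPHA_LO * 1.01 or alpha >= _ALPHA_HI * 0.9999
    return {"sigma_c2": a / alpha, "alpha": alpha}, at_bounds


def _fit_piecewise(curve: GainCurve):
    v, g = curve.velocities, curve.gains
    lb = np.array([0.0, v[0] * 1e-3, 0.0])
    ub = np.array([max(10.0, 10.0 * np.max(g)), v[-1], 6.0])

    def resid(theta):
        return model_piecewise(v, *theta) - g

    s_c_starts = np.geomspace(v[0] * 0.5, v[-1] * 0.9, 5)
    beta_starts = (0.1, 0.7, 1.5)
    g0_start = max(float(np.mean(g[: max(2, len(g) // 2)])), 1e-3)
    best = None
    for s_c0 in s_c_starts:
        for b0 in beta_starts:
            x0 = np.clip([g0_start, s_c0, b0], lb + 1e-12, ub - 1e-12)
            sol = optimize.least_squares(resid, x0, bounds=(lb, ub), method="trf")
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
    theta = best[1]
    tol = 1e-6
    at_bounds = bool(np.any(theta <= lb + tol) or np.any(theta >= ub - tol))
    return {"g0": float(theta[0]), "s_c": float(theta[1]), "beta": float(theta[2])}, at_bounds


_FITTERS = {
    "constant": _fit_constant,
    "log_saturation": _fit_log_saturation,
    "attribution": _fit_attribution,
    "piecewise": _fit_piecewise,
}


def fit_model(
    curve: GainCurve,
    model_name: str,
    options: dict | None = None,
    noise_variance: float | None = None,
) -> FitResult:
    """Least-squares fit of one named model to one gain curve.

    All fitters are deterministic (closed form, profiled 1-D search, or a
    fixed multi-start grid), so the returned ``rss`` is reproducible
    bit-for-bit.  ``at_bounds`` flags a best fit pinned to a parameter bound.
    ``noise_variance``, when known, selects the known-variance BIC form (see
    :func:`bic_score`).
    """
    if model_name not in _FITTERS:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    params, at_bounds = _FITTERS[model_name](curve)
    rss = _rss(curve, model_name, params)
    n, k = len(curve.gains), _MODEL_K[model_name]
    return FitResult(
        model_name=model_name,
        params=params,
        rss=rss,
        n=n,
        k=k,
        bic=bic_score(n, rss, k, noise_variance=noise_variance),
        at_bounds=at_bounds,
    )


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def compare_models(
    fits_model: dict[str, FitResult], fits_reference: dict[str, FitResult]
) -> PairedTest:
    """Paired t-test on BIC differences (model minus reference) across subjects.

    Pairing is by subject id (dict key).  Zero-variance differences make the
    statistic undefined; that is reported explicitly, never as ``p = 0``.
    """
    common = sorted(set(fits_model) & set(fits_reference))
    if len(common) < 2:
        raise ValueError("paired test needs >= 2 paired subjects")
    diffs = np.array([fits_model[s].bic - fits_reference[s].bic for s in common])
    if np.allclose(diffs, diffs[0], rtol=0.0, atol=1e-14):
        return PairedTest(
            t=math.nan, p=math.nan, n=len(common), mean_diff=float(np.mean(diffs)),
            valid=False, note="zero-variance BIC differences: statistic undefined",
        )
    t, p = stats.ttest_rel(
        [fits_model[s].bic for s in common],
        [fits_reference[s].bic for s in common],
    )
    return PairedTest(t=float(t), p=float(p), n=len(common), mean_diff=float(np.mean(diffs)))


@dataclass
class ComparisonReport:
    """BIC table and paired tests for a set of models on a cohort of gain curves."""

    per_subject_bic: dict[str, dict[str, float]]  # model -> subject -> BIC
    mean_bic: dict[str, float]
    sem_bic: dict[str, float]
    paired_tests: dict[str, PairedTest]  # model -> test vs reference
    reference: str
    fits: dict[str, dict[str, FitResult]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "per_subject_bic": self.per_subject_bic,
            "mean_bic": self.mean_bic,
            "sem_bic": self.sem_bic,
            "paired_tests": {
                m: {
                    "t": t.t, "p": t.p, "n": t.n,
                    "mean_diff": t.mean_diff, "valid": t.valid, "note": t.note,
                }
                for m, t in self.paired_tests.items()
            },
            "fitted_params": {
                m: {s: fr.params for s, fr in by_subj.items()}
                for m, by_subj in self.fits.items()
            },
        }


def build_comparison(
    curves: list[GainCurve],
    models: tuple[str, ...] = MODEL_NAMES,
    reference: str = "attribution",
    noise_variance: float | None = None,
) -> ComparisonReport:
    """Fit every model to every subject's curve and compare BICs vs the reference.

    Pass ``noise_variance`` when the gain-measurement noise is known (synthetic
    cohorts): nested-model selection then uses the known-variance BIC, which
    penalises free parameters correctly at the study's small n per curve.
    """
    if reference not in models:
        raise ValueError("reference model must be in the model list")
    ids = [c.subject_id for c in curves]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in curves")
    fits = {
        m: {
            c.subject_id: fit_model(c, m, noise_variance=noise_variance)
            for c in curves
        }
        for m in models
    }
    per_subject = {m: {s: fr.bic for s, fr in fits[m].items()} for m in models}
    mean_bic = {m: float(np.mean(list(per_subject[m].values()))) for m in models}
    sem_bic = {
        m: float(stats.sem(list(per_subject[m].values()))) for m in models
    }
    tests = {
        m: compare_models(fits[m], fits[reference])
        for m in models
        if m != reference
    }
    return ComparisonReport(
        per_subject_bic=per_subject,
        mean_bic=mean_bic,
        sem_bic=sem_bic,
        paired_tests=tests,
        reference=reference,
        fits=fits,
    )


# ---------------------------------------------------------------------------
# slope statistics
# ---------------------------------------------------------------------------

def loglog_slope(velocities, gains) -> float:
    """OLS slope of ``ln(gain)`` on ``ln(velocity)``.

    For a pure attribution power law this equals ``alpha - 2`` exactly.
    """
    v = np.asarray(velocities, dtype=float)
    g = np.asarray(gains, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 points for a slope")
    if np.any(v <= 0) or np.any(g <= 0):
        raise ValueError("velocities and gains must be > 0 for log-log regression")
    slope, _ = np.polyfit(np.log(v), np.log(g), 1)
    return float(slope)


def aggregate_slopes(slopes) -> tuple[float, float]:
    """Sample mean and sample s.d. (n-1 normalisation) of a set of slopes."""
    s = np.asarray(slopes, dtype=float)
    if len(s) < 2:
        raise ValueError("need >= 2 slopes to aggregate")
    return float(np.mean(s)), float(np.std(s, ddof=1))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GAIN_COLUMNS = ["subject_id", "condition", "velocity_cm_s", "gain"]


def write_gain_curves(curves: list[GainCurve], path) -> None:
    rows = [
        (c.subject_id, c.condition, v, g)
        for c in curves
        for v, g in zip(c.velocities, c.gains)
    ]
    df = pd.DataFrame(rows, columns=_GAIN_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_gain_curves(path) -> list[GainCurve]:
    df = pd.read_csv(path)
    missing = set(_GAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gain CSV missing columns: {sorted(missing)}")
    curves = []
    for (sid, cond), grp in df.groupby(["subject_id", "condition"], sort=True):
        grp = grp.sort_values("velocity_cm_s")
        curves.append(
            GainCurve(
                velocities=grp["velocity_cm_s"].to_numpy(),
                gains=grp["gain"].to_numpy(),
                subject_id=str(sid),
                condition=str(cond),
            )
        )
    return curves
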
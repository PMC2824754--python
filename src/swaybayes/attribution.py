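"""Bayesian self- versus environment-motion attribution.

When the whole visual scene moves, the retinal signal only reports *relative*
motion ``r = v_e - v_b`` between environment and body.  The nervous system must
apportion that percept between self-motion and scene motion.  The model here
combines

* a Gaussian prior over body velocity merged with the Gaussian likelihood of
  physical (vestibular / kinesthetic) cues signalling upright stance — a single
  zero-mean Gaussian with variance ``sigma_c2``;
* a sparse prior over environment velocity, ``p(v_e) ∝ exp(-c * |v_e/v0|**alpha)``,
  encoding that the visual world usually moves slowly (``alpha < 2`` gives
  heavier-than-Gaussian tails; ``alpha = 2`` is the Gaussian special case);
* a visual likelihood taken as noiseless by default (``sigma_v2 = 0``), so the
  environment velocity consistent with a hypothesised body velocity ``v_b`` is
  exactly ``r + v_b``.

The maximum a posteriori (MAP) body-velocity estimate is computed two ways:
a dense-grid argmax (:func:`map_estimate_numeric`, the numerical oracle) and
the first-order Taylor closed form (:func:`map_estimate_analytic`), which
yields the model's signature result — a postural response gain that is a power
law in scene velocity with exponent ``alpha - 2``.  The closed forms are
reconstructed from the published prose description of the derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "AttributionParams",
    "PosteriorGrid",
    "log_env_prior",
    "log_posterior_body",
    "map_estimate_numeric",
    "map_estimate_analytic",
    "predicted_gain",
    "posterior_grid_marginal",
]


@dataclass(frozen=True)
class AttributionParams:
    """Parameters of the attribution model.

    Attributes
    ----------
    sigma_c2:
        Variance of the combined body-movement prior and physical-cue
        likelihood, in (velocity-scale units)^2.  Must be positive.
    alpha:
        Exponent of the sparse environment-velocity prior.  ``alpha < 2`` is
        sparse (heavy tails), ``alpha = 2`` Gaussian-like.  Must be positive.
    c:
        Scale coefficient of the environment prior; fixed to 1 by default so
        the model has exactly two free parameters (any rescaling of ``c`` is
        absorbed by ``sigma_c2`` in the gain prefactor).
    v0:
        Velocity normalisation scale in cm/s; velocities are divided by
        ``v0`` before entering the prior.  Fixed to 1 cm/s by default.
    sigma_v2:
        Visual-noise variance; 0 by default (noiseless-vision assumption).
    """

    sigma_c2: float
    alpha: float
    c: float = 1.0
    v0: float = 1.0
    sigma_v2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_c2 > 0 and math.isfinite(self.sigma_c2)):
            raise ValueError(f"sigma_c2 must be finite and > 0, got {self.sigma_c2}")
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")
        if not (self.c > 0 and self.v0 > 0):
            raise ValueError("c and v0 must be > 0")
        if not (self.sigma_v2 >= 0 and math.isfinite(self.sigma_v2)):
            raise ValueError(f"sigma_v2 must be finite and >= 0, got {self.sigma_v2}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AttributionParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class PosteriorGrid:
    """Unnormalised log posterior over body velocity, sampled on a grid."""

    velocities: np.ndarray
    log_density: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.velocities, dtype=float)
        ld = np.asarray(self.log_density, dtype=float)
        if v.ndim != 1 or v.shape != ld.shape:
            raise ValueError("velocities and log_density must be equal-length 1-D arrays")
        if not np.all(np.diff(v) > 0):
            raise ValueError("velocities must be strictly increasing")
        if not np.all(np.isfinite(ld)):
            raise ValueError("log_density must be finite everywhere")
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "log_density", ld)

    def argmax(self) -> float:
        """Location of the posterior maximum, refined by quadratic interpolation."""
        return _refined_argmax(self.velocities, self.log_density)


def log_env_prior(v, params: AttributionParams):
    """Unnormalised log density of the sparse environment-velocity prior.

    ``log p(v_e) = -c * (|v_e| / v0) ** alpha`` — even in ``v``, maximal at 0,
    strictly decreasing in ``|v|``.
    """
    v = np.asarray(v, dtype=float)
    out = -params.c * (np.abs(v) / params.v0) ** params.alpha
    return float(out) if out.ndim == 0 else out


def log_posterior_body(v_b, r: float, params: AttributionParams):
    """Unnormalised log posterior over body velocity given visual percept ``r``.

    With noiseless vision the environment velocity implied by hypothesis
    ``v_b`` is ``r + v_b`` (sign convention ``r = v_e - v_b``), so

    ``log p(v_b | r) = -v_b**2 / (2*sigma_c2) + log_env_prior(r + v_b)``.

    Callers with ``sigma_v2 > 0`` must use :func:`posterior_grid_marginal`.
    """
    if params.sigma_v2 > 0:
        raise ValueError("sigma_v2 > 0: use posterior_grid_marginal instead")
    v_b = np.asarray(v_b, dtype=float)
    if not (np.all(np.isfinite(v_b)) and math.isfinite(r)):
        raise ValueError("non-finite inputs")
    out = -(v_b**2) / (2.0 * params.sigma_c2) + log_env_prior(r + v_b, params)
    return float(out) if out.ndim == 0 else out


def _refined_argmax(x: np.ndarray, y: np.ndarray) -> float:
    """Argmax of sampled ``y(x)`` with local quadratic refinement.

    Grid ties are broken toward the sample nearest zero.  An argmax on the
    boundary raises, signalling an under-sized grid.
    """
    ymax = np.max(y)
    # ties (exact or within one ulp of the max) resolved toward |x| smallest
    tied = np.flatnonzero(y >= np.nextafter(ymax, -np.inf))
    i = tied[np.argmin(np.abs(x[tied]))]
    if i == 0 or i == len(x) - 1:
        raise ValueError("posterior argmax on grid boundary: enlarge the grid")
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # flat neighbourhood; keep the grid point
        return float(x[i])
    h = x[i + 1] - x[i]
    return float(x[i] + 0.5 * h * (y0 - y2) / denom)


def _default_half_width(r: float, params: AttributionParams) -> float:
    """Grid half-width: covers 10 posterior sd plus the analytic MAP scale."""
    half = 10.0 * math.sqrt(params.sigma_c2)
    if params.alpha >= 1:
        scale = params.sigma_c2 * params.c * params.alpha * max(
            abs(r) / params.v0, 1.0
        ) ** (params.alpha - 1.0) / params.v0
        half = max(half, 3.0 * scale)
    return half


def map_estimate_numeric(
    r: float,
    params: AttributionParams,
    n_points: int = 40001,
    half_width: float | None = None,
) -> float:
    """MAP body velocity by dense-grid argmax (the numerical oracle).

    The grid spans at least ``±10*sqrt(sigma_c2)`` (wider when the analytic
    estimate is large) with ``n_points >= 10**4`` samples, and the argmax is
    refined by a local quadratic fit.  Odd in ``r`` by construction.
    """
    if n_points < 10**4:
        raise ValueError("n_points must be >= 10**4")
    if not math.isfinite(r):
        raise ValueError("non-finite r")
    if params.sigma_v2 > 0:
        raise ValueError("sigma_v2 > 0: use posterior_grid_marginal instead")
    if r == 0.0:
        return 0.0
    # evaluate on |r| > 0 side via odd symmetry so refinement behaves identically
    sign = 1.0 if r > 0 else -1.0
    half = half_width if half_width is not None else _default_half_width(r, params)
    v = np.linspace(-half, half, n_points)
    lp = log_posterior_body(v, abs(r), params)
    return sign * _refined_argmax(v, lp)


def map_estimate_analytic(r, params: AttributionParams):
    """Closed-form MAP estimate from the first-order Taylor expansion.

    Expanding the environment-prior log density around the percept ``r`` and
    keeping zero- and first-order terms gives a Gaussian posterior with mean

    ``v_b_hat = sigma_c2 * d/dr log_env_prior(r)
             = -sign(r) * sigma_c2 * c * alpha * (|r|/v0)**(alpha-1) / v0``

    valid when the scene velocity is large compared to the uncertainty about
    body sway.  Odd in ``r``; the implied gain ``|v_b_hat|/|r|`` is a power law
    in ``|r|`` with exponent ``alpha - 2``.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite r")
    if params.alpha < 1 and np.any(r == 0.0):
        raise ValueError("r = 0 with alpha < 1: prior derivative diverges at 0")
    mag = (
        params.sigma_c2
        * params.c
        * params.alpha
        * (np.abs(r) / params.v0) ** (params.alpha - 1.0)
        / params.v0
    )
    out = -np.sign(r) * mag
    return float(out) if out.ndim == 0 else out


def predicted_gain(r, params: AttributionParams):
    """Predicted postural response gain ``|v_b_hat| / r`` at scene velocity ``r > 0``.

    Equals ``sigma_c2 * c * alpha * (r/v0)**(alpha-2) / v0**2``: strictly
    decreasing in ``r`` for ``alpha < 2``, constant for ``alpha = 2``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise ValueError("scene velocity r must be finite and > 0")
    out = np.abs(map_estimate_analytic(r, params)) / r
    return float(out) if np.ndim(out) == 0 else out


def posterior_grid_marginal(
    r: float,
    params: AttributionParams,
    vb_grid: np.ndarray | None = None,
    ve_grid: np.ndarray | None = None,
    edge_mass_tol: float = 1e-8,
) -> PosteriorGrid:
    """Posterior over body velocity with finite visual noise, on a grid.

    For ``sigma_v2 > 0`` the visual likelihood is a Gaussian in
    ``r - (v_e - v_b)`` and is integrated (trapezoid rule) against the
    environment prior for each hypothesised ``v_b``.  For ``sigma_v2 = 0``
    this collapses to :func:`log_posterior_body` evaluated on the grid.

    Raises if the integrand carries non-negligible mass at the ``v_e`` grid
    edges (truncation warning).
    """
    if not math.isfinite(r):
        raise ValueError("non-finite r")
    if vb_grid is None:
        half = _default_half_width(r, params)
        vb_grid = np.linspace(-half, half, 2001)
    vb_grid = np.asarray(vb_grid, dtype=float)

    if params.sigma_v2 == 0.0:
        return PosteriorGrid(vb_grid, log_posterior_body(vb_grid, r, params))

    if ve_grid is None:
        # integrate in the offset u = v_e - (r + v_b): the visual likelihood is
        # then a fixed narrow Gaussian in u, resolved regardless of sigma_v2
        sig_v = math.sqrt(params.sigma_v2)
        u = np.linspace(-8.0 * sig_v, 8.0 * sig_v, 801)
        log_integrand = (
            -(u[None, :] ** 2) / (2.0 * params.sigma_v2)
            + log_env_prior(r + vb_grid[:, None] + u[None, :], params)
        )
        grid_axis = u
    else:
        ve_grid = np.asarray(ve_grid, dtype=float)
        resid = r - (ve_grid[None, :] - vb_grid[:, None])
        log_integrand = (
            -(resid**2) / (2.0 * params.sigma_v2)
            + log_env_prior(ve_grid, params)[None, :]
        )
        grid_axis = ve_grid
    peak = np.max(log_integrand, axis=1, keepdims=True)
    rel = np.exp(log_integrand - peak)
    edge = max(np.max(rel[:, 0]), np.max(rel[:, -1]))
    if edge > edge_mass_tol:
        raise ValueError(
            f"integrand mass {edge:.2e} at integration-grid edge exceeds "
            f"{edge_mass_tol:.0e}; enlarge ve_grid"
        )
    log_marginal = np.log(np.trapezoid(rel, grid_axis, axis=1)) + peak[:, 0]
    log_post = -(vb_grid**2) / (2.0 * params.sigma_c2) + log_marginal
    return PosteriorGrid(vb_grid, log_post)
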
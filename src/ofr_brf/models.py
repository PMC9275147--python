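"""Center-surround summation models and their fitting.

Two descriptive models quantify spatial integration of motion for ocular
following:

* a difference-of-Gaussians (DoG) sensitivity profile whose integral over a
  centered disk of diameter ``D`` gives the predicted response amplitude

  .. math::

     R(D) = g_e \\, \\mathrm{erf}\\!\\left(\\frac{D}{2\\sqrt{2}\\sigma_e}\\right)
          - g_i \\, \\mathrm{erf}\\!\\left(\\frac{D}{2\\sqrt{2}\\sigma_i}\\right)

  with excitatory/inhibitory extents ``sigma_e <= sigma_i`` (deg) and gains
  ``g_e, g_i`` (deg of eye-position change). The curve rises, peaks near the
  excitatory extent, and declines toward the asymptote ``g_e - g_i`` when the
  surround is active;

* an exponential decay of ring-stimulus responses with inner diameter ``x``,
  ``R(x) = g_r e^{-x/tau} + r_0``, whose size constant ``tau`` (deg)
  quantifies how quickly peripheral motion loses its drive.

Fits minimise SE-weighted squared residuals with a bounded trust-region
least-squares solver from a small multi-start grid; goodness of fit is the
normalized chi-square (residual chi-square over residual degrees of freedom).
Integration across the stimulus is one-dimensional (across the diameter),
the convention under which the summation integral is exactly an erf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .defaults import TAU_MAX

__all__ = [
    "DoGParams",
    "ExpDecayParams",
    "dog_profile",
    "dog_summation_response",
    "exp_decay_response",
    "fit_dog",
    "fit_exp_decay",
    "normalized_chi2",
]

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class DoGParams:
    """DoG summation parameters (degrees / response degrees)."""

    sigma_e: float
    sigma_i: float
    g_e: float
    g_i: float
    mu: float = 0.0
    chi2_n: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_e <= 0 or self.sigma_i <= 0:
            raise ValueError("sigma_e and sigma_i must be positive")
        if self.g_e < 0 or self.g_i < 0:
            raise ValueError("gains must be non-negative")

    @property
    def asymptote(self) -> float:
        """Large-stimulus response limit g_e - g_i."""
        return self.g_e - self.g_i


@dataclass(frozen=True)
class ExpDecayParams:
    """Ring-response decay parameters: R(x) = g_r exp(-x/tau) + r_0."""

    g_r: float
    tau: float
    r_0: float
    chi2_n: float | None = None

    def __post_init__(self) -> None:
        if self.g_r < 0 or self.r_0 < 0:
            raise ValueError("g_r and r_0 must be non-negative")
        if not (0 < self.tau <= TAU_MAX):
            raise ValueError(f"tau must lie in (0, {TAU_MAX}]")


def dog_profile(x, p: DoGParams):
    """Pointwise DoG weight density (1/deg) at visual position ``x`` (deg)."""
    x = np.asarray(x, dtype=float)
    ze = (x - p.mu) / p.sigma_e
    zi = (x - p.mu) / p.sigma_i
    return (p.g_e / (p.sigma_e * _SQRT2PI) * np.exp(-0.5 * ze * ze)
            - p.g_i / (p.sigma_i * _SQRT2PI) * np.exp(-0.5 * zi * zi))


def dog_summation_response(D, p: DoGParams):
    """Predicted amplitude for a centered disk of diameter ``D`` (deg).

    Integral of :func:`dog_profile` over [-D/2, D/2] (for mu = 0), which is
    exactly ``g_e erf(D / (2 sqrt(2) sigma_e)) - g_i erf(D / (2 sqrt(2)
    sigma_i))``.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("diameter must be non-negative")
    return (p.g_e * erf(D / (2 * _SQRT2 * p.sigma_e))
            - p.g_i * erf(D / (2 * _SQRT2 * p.sigma_i)))


def exp_decay_response(x, p: ExpDecayParams):
    """Predicted ring amplitude at inner diameter ``x`` (deg)."""
    x = np.asarray(x, dtype=float)
    return p.g_r * np.exp(-x / p.tau) + p.r_0


def normalized_chi2(observed, predicted, se, n_params: int) -> tuple[float, bool]:
    """Residual chi-square over residual degrees of freedom.

    Returns ``(chi2_n, unit_weights_used)``; zero/absent SEs fall back to
    unit weights with a flag.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size <= n_params:
        raise ValueError("need more points than free parameters")
    unit = False
    if se is None:
        unit = True
        w = np.ones_like(observed)
    else:
        w = np.asarray(se, dtype=float)
        if np.any(w <= 0):
            unit = True
            w = np.ones_like(observed)
    chi2 = float(np.sum(((observed - predicted) / w) ** 2))
    return chi2 / (observed.size - n_params), unit


@dataclass
class FitResult:
    """Outcome of a bounded least-squares fit."""

    params: DoGParams | ExpDecayParams
    stderr: dict[str, float]
    chi2_n: float
    success: bool
    unit_weights: bool
    start: tuple[float, ...]
    message: str = ""
    flags: list[str] = field(default_factory=list)


def _weights(amp, se):
    if se is None:
        return None
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        return None
    return se


def _stderr(res, names, chi2_n):
    """Parameter SEs from the least-squares Jacobian (Gauss-Newton covariance,
    scaled by the reduced chi-square)."""
    try:
        _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
        tol = np.finfo(float).eps * max(res.jac.shape) * s[0]
        s = s[s > tol]
        vt = vt[: s.size]
        cov = (vt.T / s**2) @ vt * max(chi2_n, 0.0)
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
        if err.size < len(names):
            err = np.pad(err, (0, len(names) - err.size), constant_values=np.nan)
    except np.linalg.LinAlgError:
        err = np.full(len(names), np.nan)
    return dict(zip(names, err))


def fit_dog(diameters, amp, se=None, *, mu_free: bool = False,
            weighted: bool = True) -> FitResult:
    """Fit the DoG-erf summation law to a disk summation curve.

    The surround is kept at least as broad as the center by parameterising
    ``sigma_i = sigma_e + delta`` with ``delta >= 0``. A multi-start grid over
    ``sigma_e`` in {2, 5, 10} deg (surround initialised at twice the center,
    gains from the curve maximum and asymptote) guards against local minima;
    the start with the lowest residual wins.
    """
    D = np.asarray(diameters, dtype=float)
    y = np.asarray(amp, dtype=float)
    n_free = 5 if mu_free else 4
    if D.size < n_free + 1:
        raise ValueError("need at least one more point than free parameters")
    w = _weights(y, se) if weighted else None

    def predict(theta):
        if mu_free:
            s_e, d, g_e, g_i, mu = theta
        else:
            (s_e, d, g_e, g_i), mu = theta, 0.0
        s_i = s_e + d
        # integral of the (possibly shifted) DoG profile over [-D/2, D/2]
        be, ae = (D / 2 - mu) / (_SQRT2 * s_e), (-D / 2 - mu) / (_SQRT2 * s_e)
        bi, ai = (D / 2 - mu) / (_SQRT2 * s_i), (-D / 2 - mu) / (_SQRT2 * s_i)
        return 0.5 * (g_e * (erf(be) - erf(ae)) - g_i * (erf(bi) - erf(ai)))

    def residuals(theta):
        r = predict(theta) - y
        return r / w if w is not None else r

    g_e0 = max(float(y.max()), 1e-9)
    g_i0 = max(float(y.max() - y[-1]), 1e-9)
    lo = [1e-3, 0.0, 0.0, 0.0]
    hi = [200.0, 400.0, np.inf, np.inf]
    if mu_free:
        lo.append(-60.0)
        hi.append(60.0)
    best = None
    best_start: tuple[float, ...] = ()
    for s_e0 in (2.0, 5.0, 10.0):
        x0 = [s_e0, s_e0, g_e0, g_i0] + ([0.0] if mu_free else [])
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best, best_start = res, tuple(x0)
    if best is None:
        raise RuntimeError("DoG fit failed to converge from every start")

    if mu_free:
        s_e, d, g_e, g_i, mu = best.x
    else:
        (s_e, d, g_e, g_i), mu = best.x, 0.0
    params = DoGParams(sigma_e=float(s_e), sigma_i=float(s_e + d),
                       g_e=float(g_e), g_i=float(g_i), mu=float(mu))
    pred = predict(best.x)
    chi2_n, unit = normalized_chi2(y, pred, se if weighted else None, n_free)
    params = replace(params, chi2_n=chi2_n)
    names = ["sigma_e", "delta", "g_e", "g_i"] + (["mu"] if mu_free else [])
    flags = []
    if g_i <= 1e-6 * max(g_e, 1e-30):
        flags.append("sigma_i_unidentifiable")
    return FitResult(params=params, stderr=_stderr(best, names, chi2_n),
                     chi2_n=chi2_n, success=bool(best.success), unit_weights=unit,
                     start=best_start, message=best.message, flags=flags)


def fit_exp_decay(inner_diameters, amp, se=None, *, weighted: bool = True) -> FitResult:
    """Fit ``g_r exp(-x/tau) + r_0`` to a ring summation curve.

    tau is bounded in (0, 100] deg; multi-start over tau in {10, 30, 80}.
    """
    x = np.asarray(inner_diameters, dtype=float)
    y = np.asarray(amp, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")
    w = _weights(y, se) if weighted else None

    def residuals(theta):
        g_r, tau, r_0 = theta
        r = g_r * np.exp(-x / tau) + r_0 - y
        return r / w if w is not None else r

    g_r0 = max(float(y[0] - y[-1]), 1e-9)
    r_00 = max(float(y[-1]), 0.0)
    best = None
    best_start: tuple[float, ...] = ()
    for tau0 in (10.0, 30.0, 80.0):
        x0 = [g_r0, tau0, r_00]
        try:
            res = least_squares(residuals, x0,
                                bounds=([0.0, 1e-6, 0.0], [np.inf, TAU_MAX, np.inf]),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best, best_start = res, tuple(x0)
    if best is None:
        raise RuntimeError("exponential-decay fit failed from every start")

    g_r, tau, r_0 = best.x
    flags = []
    if tau >= TAU_MAX - 1e-6 or tau <= 1e-5:
        flags.append("tau_at_bound")
    if g_r <= 1e-9:
        flags.append("flat_curve")
    params = ExpDecayParams(g_r=float(g_r), tau=float(tau), r_0=float(r_0))
    pred = exp_decay_response(x, params)
    chi2_n, unit = normalized_chi2(y, pred, se if weighted else None, 3)
    params = replace(params, chi2_n=chi2_n)
    return FitResult(params=params,
                     stderr=_stderr(best, ["g_r", "tau", "r_0"], chi2_n),
                     chi2_n=chi2_n, success=bool(best.success), unit_weights=unit,
                     start=best_start, message=best.message, flags=flags)
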
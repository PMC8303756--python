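"""Separation-of-variables solution family for spheroid formation.

The analytic treatment is quasi-static: on the ball the concentration is
expanded in the Dirichlet eigenfunctions ``sin(lambda_n r)/r`` with
``lambda_n = n*pi/R1(t)`` frozen at the evaluation time, where ``R1(t)``
is the diffusion-only (no-proliferation) reference radius.  A constant
source ``eta*Ci`` makes the auxiliary problem linear with a particular
part per mode, and the exponential-growth transform

    C(r,t) = e^{eta t} C1(r,t) - eta * int_0^t C1(r,tau) e^{eta tau} dtau

lifts its solution ``C1`` to the full concentration-dependent equation.
The boundary flux of C then yields the radius rate dR/dt.  Three levels of
reduction are provided, from most to least faithful:

1. :func:`series_radius_rate` -- the full eigen-series with the shape
   factor F evaluated at the current radius R(t); per-mode time integrals
   are available in closed form, so no quadrature error enters.
2. :func:`simplified_radius_rate` -- the separation-of-timescales
   reduction R_bar = n*pi*R/R1 ~ n*pi (F replaced by its limit value),
   which collapses the mode index out of the spatial factor and leaves a
   history integral over R(tau); exact when proliferation is slow
   compared with diffusive relaxation.
3. :func:`closed_form_radius` -- additionally freezes R(tau) ~ R0 and
   replaces the eigen-sum by its short-time (theta-function) asymptotics,
   giving an elementary formula in the imaginary error function erfi.

All eigen-series are non-uniformly convergent at t = 0 when Ci != C0
(the initial and boundary data disagree at the surface), so rates are
evaluated at t >= t_min = t_min_frac * t_max and take the one-sided limit
for earlier times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import special

from .params import ModelParameters
from .solver import CollapseError, Trajectory


class HistoryError(ValueError):
    """Raised when a radius history does not cover the requested time."""


class DegenerateCollapseWarning(RuntimeWarning):
    """The diffusion-only radius reaches zero inside the requested window:
    the analytic solution family is outside its validity window there."""


class SeriesConvergenceWarning(RuntimeWarning):
    """The eigen-series tail did not reach the requested tolerance."""


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation and tolerance knobs for the eigen-series evaluations.

    ``n_terms`` modes are summed (the reported tail bound is the magnitude
    of the last retained term relative to the sum); ``quad_tol`` controls
    the relative tolerance of the history integral in the simplified rate;
    ``t_min_frac`` sets the early-time clamp t_min = t_min_frac * t_max
    below which the eigen-series is not uniformly convergent;
    ``r1_floor_frac`` freezes the eigenvalues once the diffusion-only
    reference radius drops below this fraction of R0 (beyond the validity
    window of the analytic family); ``n_time_steps`` is the internal
    resolution of :func:`integrate_analytic_trajectory`.
    """

    n_terms: int = 200
    tail_tol: float = 1e-8
    quad_tol: float = 1e-8
    t_min_frac: float = 1e-3
    r1_floor_frac: float = 0.1
    n_time_steps: int = 4000

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError(f"n_terms must be >= 1, got {self.n_terms}")
        for name in ("tail_tol", "quad_tol", "t_min_frac", "r1_floor_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_time_steps < 10:
            raise ValueError("n_time_steps must be >= 10")


@dataclass(frozen=True)
class ClosedFormConstants:
    """Constants of the elementary closed-form radius.

    ``alpha`` is the amplitude (C0 - Ci) * sqrt(K * eta) in cm/h units
    composed from the motility and proliferation scales; ``lambda_n_rule``
    maps (n, reference radius) to the Dirichlet eigenvalue, n*pi/R_ref for
    separation of variables on the ball.
    """

    alpha: float
    lambda_n_rule: Callable[[int, float], float] = lambda n, R_ref: n * math.pi / R_ref

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha}")

    @classmethod
    def from_parameters(cls, params: ModelParameters) -> "ClosedFormConstants":
        return cls(alpha=(params.C0 - params.Ci) * math.sqrt(params.K * params.eta))


def load_series_config(path) -> SeriesConfig:
    """Read the ``analytic:`` block of a parameter YAML/JSON file into a
    :class:`SeriesConfig`; missing keys take the defaults, unknown keys in
    the block are rejected."""
    import json
    from pathlib import Path

    import yaml

    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    block = (data or {}).get("analytic", {}) or {}
    known = {f for f in SeriesConfig.__dataclass_fields__}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in analytic block: {sorted(unknown)}")
    return SeriesConfig(**block)


# -- special functions -------------------------------------------------------


def erfi(x):
    """Imaginary error function erfi(x) = (2/sqrt(pi)) * int_0^x e^{s^2} ds.

    Odd, strictly increasing and entire.  Raises for non-finite input.
    For arguments beyond ~26.6 the value overflows double precision; use
    :func:`log_abs_erfi` there.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("erfi requires finite input")
    out = special.erfi(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def log_abs_erfi(x):
    """Overflow-safe companion to :func:`erfi`: returns
    ``(log|erfi(x)|, sign)`` for finite x of any magnitude.

    For |x| <= 20 the logarithm of the direct value is used; beyond that
    the asymptotic expansion erfi(x) ~ e^{x^2}/(x sqrt(pi)) *
    (1 + 1/(2x^2) + 3/(4x^4) + ...) is accurate to double precision.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("log_abs_erfi requires finite input")
    sign = np.sign(arr)
    ax = np.abs(arr)
    small = ax <= 20.0
    log_mag = np.empty_like(ax)
    with np.errstate(divide="ignore"):
        log_mag[small] = np.log(np.abs(special.erfi(ax[small])))
    big = ~small
    if np.any(big):
        xb = ax[big]
        inv2 = 1.0 / xb**2
        series = np.log1p(0.5 * inv2 + 0.75 * inv2**2 + 1.875 * inv2**3)
        log_mag[big] = xb**2 - np.log(xb * math.sqrt(math.pi)) + series
    if np.isscalar(x) or arr.ndim == 0:
        return float(log_mag), float(sign)
    return log_mag, sign


# -- diffusion-only radius ---------------------------------------------------


def diffusion_only_radius(t, params: ModelParameters, *, warn_collapse: bool = True):
    """Radius of a spheroid whose contraction is not opposed by boundary
    growth: the short-time boundary-layer solution

        R1(t) = R0 + (Ci - C0) * sqrt(K/(eta*Ci)) * erfi(sqrt(eta*Ci*t)),

    reducing for eta = 0 to R0 + 2 (Ci - C0) sqrt(K t / pi).  For Ci < C0
    the spheroid contracts strictly; once R1 reaches zero the formula (and
    the analytic family built on it) is outside its validity window, which
    is flagged with :class:`DegenerateCollapseWarning`.
    """
    params = params.normalized()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    K, b = params.K, params.eta * params.Ci
    amp = params.Ci - params.C0
    x = b * t_arr
    if b == 0.0:
        r1 = params.R0 + 2.0 * amp * np.sqrt(K * t_arr / math.pi)
    else:
        # erfi(sqrt(x))/sqrt(b) -> 2 sqrt(t/pi) * (1 + x/3) as x -> 0
        r1 = np.where(
            x < 1e-12,
            params.R0 + 2.0 * amp * np.sqrt(K * t_arr / math.pi) * (1.0 + x / 3.0),
            params.R0 + amp * math.sqrt(K / b) * special.erfi(np.sqrt(x)),
        )
    if warn_collapse and np.any(r1 <= 0):
        t_bad = t_arr[r1 <= 0].min() if t_arr.ndim else float(t_arr)
        warnings.warn(
            f"diffusion-only radius reaches zero by t = {t_bad:.4g} h; "
            "the analytic family is degenerate beyond that time",
            DegenerateCollapseWarning,
            stacklevel=2,
        )
    return float(r1) if np.isscalar(t) or t_arr.ndim == 0 else r1


def _phi_heat(s: np.ndarray) -> np.ndarray:
    """Running integral of the unit-ball heat trace,
    Phi(s) = sum_n (1 - e^{-n^2 pi^2 s}) / (n^2 pi^2)  ->  1/6 as s -> inf.

    Evaluated as 1/6 minus the fast-converging exponential sum; for small s
    the theta-function asymptotics Phi = sqrt(s/pi) - s/2 hold to machine
    precision (the dropped correction is O(e^{-1/(4s)}))."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    small = (s > 0) & (s < 0.02)
    out[small] = np.sqrt(s[small] / np.pi) - s[small] / 2.0
    large = s >= 0.02
    if np.any(large):
        n = np.arange(1.0, 61.0)
        w = n**2 * np.pi**2
        out[large] = 1.0 / 6.0 - np.sum(
            np.exp(-np.outer(s[large], w)) / w, axis=1
        )
    return out


def diffusion_only_radius_exact(t, params: ModelParameters, n_quad: int = 6001):
    """Exact radius of the eta = 0 moving-boundary system (as discretized,
    i.e. without the mesh-advection term).

    Without proliferation the mapped equation reduces, in the rescaled
    diffusion time s(t) with ds/dt = K/R(t)^2, to fixed-domain diffusion on
    the unit ball, giving in closed form

        R(s) = R0 * exp(-2 (C0 - Ci) Phi(s)),
        t(s) = (1/K) * int_0^s R(s')^2 ds',

    with Phi the integrated heat trace of :func:`_phi_heat`.  As s -> inf
    the radius plateaus at R0 * exp(-(C0 - Ci)/3); the short-time limit is
    R0 - 2 (C0 - Ci) sqrt(K t / pi), the eta -> 0 limit of
    :func:`diffusion_only_radius`.  ``t(s)`` is inverted by quadrature on
    a sqrt-stretched grid, accurate to ~1e-8 relative with the default
    ``n_quad``.
    """
    if params.eta != 0.0:
        raise ValueError("diffusion_only_radius_exact requires eta = 0")
    params = params.normalized()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    a = 2.0 * (params.C0 - params.Ci)
    # s grid via u = sqrt(s): resolves the sqrt(s) start; extend u_max until
    # the horizon is covered (R^2 >= R_inf^2 bounds the needed range)
    r_min = params.R0 * math.exp(-max(a, 0.0) / 6.0)
    t_target = float(t_arr.max())
    u_max = math.sqrt(max(params.K * t_target / r_min**2, 1e-12)) * 1.1 + 0.1
    u = np.linspace(0.0, u_max, n_quad)
    s = u**2
    R = params.R0 * np.exp(-a * _phi_heat(s))
    integrand = R**2 * 2.0 * u / params.K
    t_of_s = np.concatenate(
        [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(u))]
    )
    out = np.interp(t_arr, t_of_s, R)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def shape_factor(R, R1, n):
    """Boundary shape factor of eigenmode n evaluated at radius R:

        F(R, n) = (R_bar cos R_bar - sin R_bar) / R^2,  R_bar = n pi R / R1.

    This is the radial derivative of sin(lambda_n r)/r at r = R with
    lambda_n = n pi / R1.  Evaluated through an expansion for small R_bar
    where the direct form loses precision (F ~ -R_bar^3 / (3 R^2)).
    """
    R = np.asarray(R, dtype=float)
    R1 = np.asarray(R1, dtype=float)
    n_arr = np.asarray(n)
    if np.any(R <= 0) or np.any(R1 <= 0) or np.any(n_arr < 1):
        raise ValueError("shape_factor requires R > 0, R1 > 0, n >= 1")
    r_bar = n_arr * np.pi * R / R1
    small = r_bar < 1e-4
    direct = (r_bar * np.cos(r_bar) - np.sin(r_bar)) / R**2
    series = -(r_bar**3) / (3.0 * R**2) * (1.0 - r_bar**2 / 10.0)
    out = np.where(small, series, direct)
    return float(out) if out.ndim == 0 else out


# -- eigen-series machinery ---------------------------------------------------


def _r1_reference(t: float, params: ModelParameters, cfg: SeriesConfig) -> float:
    """Diffusion-only reference radius, floored once the analytic family
    leaves its validity window."""
    r1 = diffusion_only_radius(float(t), params, warn_collapse=False)
    return max(r1, cfg.r1_floor_frac * params.R0)


def _clamp_time(t: float, params: ModelParameters, cfg: SeriesConfig) -> float:
    """Early-time clamp, applied only when the initial and boundary data
    disagree (Ci != C0): that surface discontinuity makes the eigen-series
    non-uniformly convergent at t = 0.  With compatible data the series is
    exact down to t = 0."""
    if params.C0 == params.Ci:
        return float(t)
    return max(float(t), cfg.t_min_frac * params.t_max)


# Alternating Fourier-Bernoulli sums, 2*pi-periodic in theta; closed forms
# valid on [-pi, pi] and extended by wrapping.  Used to sum the algebraic
# (1/n^2, 1/n^4) tails of the eigen-series in closed form.


def _wrap_pi(theta: float) -> float:
    return theta - 2.0 * math.pi * round(theta / (2.0 * math.pi))


def _alt_cos_n2(theta: float) -> float:
    """sum_n (-1)^(n+1) cos(n theta) / n^2 = pi^2/12 - theta^2/4."""
    th = _wrap_pi(theta)
    return math.pi**2 / 12.0 - th**2 / 4.0


def _alt_sin_n3(theta: float) -> float:
    """sum_n (-1)^(n+1) sin(n theta) / n^3 = theta (pi^2 - theta^2) / 12."""
    th = _wrap_pi(theta)
    return th * (math.pi**2 - th**2) / 12.0


def _alt_cos_n4(theta: float) -> float:
    """sum_n (-1)^(n+1) cos(n theta) / n^4 =
    7 pi^4/720 - pi^2 theta^2/24 + theta^4/48."""
    th = _wrap_pi(theta)
    return 7.0 * math.pi**4 / 720.0 - math.pi**2 * th**2 / 24.0 + th**4 / 48.0


def _alt_sin_n5(theta: float) -> float:
    """sum_n (-1)^(n+1) sin(n theta) / n^5 =
    7 pi^4 theta/720 - pi^2 theta^3/72 + theta^5/240."""
    th = _wrap_pi(theta)
    return (
        7.0 * math.pi**4 * th / 720.0
        - math.pi**2 * th**3 / 72.0
        + th**5 / 240.0
    )


def _series_flux(
    t: float, R: float, params: ModelParameters, cfg: SeriesConfig
) -> float:
    """Boundary concentration gradient dC/dr at r = R(t) from the
    transformed eigen-series, with the algebraic tail summed in closed
    form.

    The first ``n_terms`` modes are evaluated exactly through the combined
    kernel psi (robust at the eigenvalue crossing eta = mu_n).  Beyond the
    truncation the exponentials are dead and the per-mode constant reduces
    to -B_n eta C0 F_n / (eta - mu_n); expanding 1/(eta - mu_n) in
    1/mu_n, its 1/n^2 and 1/n^4 parts are alternating Fourier-Bernoulli
    sums with elementary closed forms, leaving an O(1/n^6) remainder below
    double precision at the default truncation."""
    tc = _clamp_time(t, params, cfg)
    r1 = _r1_reference(tc, params, cfg)
    n, mu, c, p = _mode_arrays(params, cfg, r1)
    F = shape_factor(R, r1, n)
    head = float(np.sum(F * ((c - p) * _psi(mu, params.eta, tc) + p)))

    # closed-form tail of the constant part for n > n_terms, valid once the
    # truncated modes' exponentials are dead (mu_N t >> 1); below that the
    # omitted tail is itself negligible (it has not built up yet)
    eta = params.eta
    if eta == 0.0 or mu[-1] * tc < 35.0:
        return head
    beta = r1**2 / (params.K * math.pi**2)  # 1/mu_n = beta / n^2
    x = R / r1
    theta = math.pi * x
    amp = 2.0 * params.R0 * eta * params.C0 / R**2
    # full alternating sums over all n
    full = beta * (x * _alt_cos_n2(theta) - _alt_sin_n3(theta) / math.pi) + (
        eta * beta**2
    ) * (x * _alt_cos_n4(theta) - _alt_sin_n5(theta) / math.pi)
    # numeric head of the same asymptotic expression (n <= n_terms)
    n_f = n.astype(float)
    spatial = x * np.cos(theta * n_f) - np.sin(theta * n_f) / (n_f * math.pi)
    sgn = np.where(n % 2 == 1, 1.0, -1.0)
    head_asym = float(
        np.sum(sgn * spatial * (beta / n_f**2 + eta * beta**2 / n_f**4))
    )
    return head + amp * (full - head_asym)


def _mode_arrays(params: ModelParameters, cfg: SeriesConfig, r1: float):
    """Per-mode eigenvalues and expansion coefficients on the initial ball.

    c_n: Fourier coefficients of the initial deviation (Ci - C0),
    p_n: particular (constant-source eta*Ci) part, both for the expansion
    of r*U in sin(lambda_n r); mu_n = K lambda_n^2 are the modal decay
    rates.
    """
    n = np.arange(1, cfg.n_terms + 1)
    lam = n * np.pi / r1
    mu = params.K * lam**2
    sgn = np.where(n % 2 == 1, 1.0, -1.0)  # (-1)^(n+1)
    base = 2.0 * params.R0 * sgn / (n * np.pi)
    c = base * (params.Ci - params.C0)
    b = params.eta * params.Ci
    p = base * b / mu
    return n, mu, c, p


def _psi(mu: np.ndarray, eta: float, t: float) -> np.ndarray:
    """Exact time kernel of the growth transform applied to a decaying
    mode:  e^{eta t} e^{-mu t} - eta * int_0^t e^{eta s} e^{-mu s} ds
    = (eta - mu e^{(eta-mu) t}) / (eta - mu),  -> 1 - eta*t as mu -> eta."""
    d = eta - mu
    expo = np.exp(np.clip(d * t, -700.0, 700.0))
    near = np.abs(d) * max(t, 1.0) < 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (eta - mu * expo) / d
    return np.where(near, 1.0 - eta * t, out)


def _coerce_history(R_history) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(R_history, Trajectory):
        return np.asarray(R_history.times, float), np.asarray(R_history.radii, float)
    times, radii = R_history
    return np.asarray(times, dtype=float), np.asarray(radii, dtype=float)


def _require_history(times: np.ndarray, t: float) -> None:
    if times.size < 1 or times[0] > 1e-12 or times[-1] < t - 1e-9:
        raise HistoryError(
            f"radius history must cover [0, {t:g}] h; got "
            f"[{times[0] if times.size else 'empty'}, {times[-1] if times.size else ''}]"
        )


def series_radius_rate(
    t: float,
    R: float,
    R_history,
    params: ModelParameters,
    cfg: Optional[SeriesConfig] = None,
) -> float:
    """Full eigen-series radius rate dR/dt (cm/h) at time t.

    Evaluates the boundary flux of the transformed modal solution: the
    shape factor F(R(t), n) is spatial and constant in the integration
    variable, so each mode's time integral is taken in closed form (the
    exponentials are combined in a single exponent, which is the log-space
    evaluation that keeps large eta*tau safe).  ``R_history`` must cover
    [0, t]; within the quasi-static approximation the rate depends on the
    history only through the current radius.
    """
    cfg = cfg or SeriesConfig()
    params = params.normalized()
    times, _ = _coerce_history(R_history)
    _require_history(times, t)
    if R <= 0:
        raise CollapseError(f"radius must be positive, got {R}")
    total = _series_flux(t, R, params, cfg)

    # true bound on the dropped remainder (the O(1/n^6) part beyond the
    # closed-form tail): |1/(eta-mu) + 1/mu + eta/mu^2| <= 2 eta^2/mu^3
    # once mu >= 2 eta, which holds beyond the default truncation
    tc = _clamp_time(t, params, cfg)
    r1 = _r1_reference(tc, params, cfg)
    beta = r1**2 / (params.K * math.pi**2)
    x = R / r1
    amp = 2.0 * params.R0 * params.eta * params.C0 / R**2
    rem_bound = amp * 2.0 * params.eta**2 * beta**3 * (x + 1.0) / (
        4.0 * cfg.n_terms**4
    )
    scale = abs(total) + amp * beta  # flux scale incl. the constant part
    if rem_bound > cfg.tail_tol * max(scale, 1e-300):
        warnings.warn(
            f"eigen-series remainder bound {rem_bound:.2e} exceeds tail_tol "
            f"relative to the flux scale {scale:.2e}; achieved relative tail "
            f"{rem_bound / max(scale, 1e-300):.2e}",
            SeriesConvergenceWarning,
            stacklevel=2,
        )
    return -params.K * total


def _collapsed_sum(tau: float, params: ModelParameters, cfg: SeriesConfig) -> tuple[float, float]:
    """Mode-collapsed boundary sums of the simplified rate at time tau.

    Under R_bar ~ n pi the spatial factor of every mode is n pi (-1)^n/R^2;
    the n-dependence then sits only in the decay rates.  Returns the pair
    (S_h, S_p) with

        S_h = sum_n (c_n - p_n) * n pi (-1)^n * e^{-mu_n tau}
        S_p = sum_n p_n * n pi (-1)^n

    so that the flux sum is (S_h(tau) + S_p)/R(tau)^2.
    """
    r1 = _r1_reference(tau, params, cfg)
    _, mu, c, p = _mode_arrays(params, cfg, r1)
    n = np.arange(1, cfg.n_terms + 1)
    w = n * np.pi * np.where(n % 2 == 1, -1.0, 1.0)  # n pi (-1)^n
    decay = np.exp(np.clip(-mu * tau, -700.0, 0.0))
    s_h = float(np.sum((c - p) * w * decay))
    # sum_n p_n n pi (-1)^n = -2 R0 b sum 1/mu_n = -R0 b R1^2 / (3 K), exact
    s_p = -params.R0 * (params.eta * params.Ci) * r1**2 / (3.0 * params.K)
    return s_h, s_p


def simplified_radius_rate(
    t: float,
    R: float,
    params: ModelParameters,
    cfg: Optional[SeriesConfig] = None,
    *,
    R_history=None,
) -> float:
    """Separation-of-timescales radius rate dR/dt (cm/h) at time t.

    The shape factor is replaced by its R_bar = n pi limit, exact when
    proliferation is slow relative to diffusive relaxation.  The history
    integral over tau uses R(tau) interpolated from ``R_history`` when
    given; otherwise R(tau) is approximated by the diffusion-only radius,
    consistent with the same timescale separation.
    """
    cfg = cfg or SeriesConfig()
    params = params.normalized()
    if R <= 0:
        raise CollapseError(f"radius must be positive, got {R}")
    eta = params.eta
    tc = _clamp_time(t, params, cfg)

    if R_history is not None:
        times, radii = _coerce_history(R_history)
        _require_history(times, tc)

        def radius_at(tau):
            return np.interp(tau, times, radii)

    else:

        def radius_at(tau):
            r = diffusion_only_radius(float(tau), params, warn_collapse=False)
            return max(r, cfg.r1_floor_frac * params.R0)

    def integrand(tau: float) -> float:
        s_h, s_p = _collapsed_sum(tau, params, cfg)
        r_tau = float(radius_at(tau))
        return math.exp(min(eta * tau, 700.0)) * (s_h + s_p) / r_tau**2

    from scipy.integrate import quad

    hist_int, _ = quad(
        integrand, 0.0, tc, epsrel=cfg.quad_tol, epsabs=0.0, limit=200
    )
    s_h, s_p = _collapsed_sum(tc, params, cfg)
    inst = math.exp(min(eta * tc, 700.0)) * (s_h + s_p) / R**2
    return -params.K * (inst - eta * hist_int)


def closed_form_radius(
    t,
    params: ModelParameters,
    consts: Optional[ClosedFormConstants] = None,
):
    """Elementary closed-form radius

        R(t) = R0 + alpha * [ (t - 1/(2 eta)) erfi(sqrt(eta t))
                              - sqrt(t/(pi eta)) e^{eta t} ],
        alpha = (C0 - Ci) sqrt(K eta),

    the exact integral of the simplified rate after freezing R(tau) ~ R0
    and replacing the eigen-sum by its short-time asymptotics
    sum_n e^{-K lambda_n^2 tau} ~ R0 / (2 sqrt(pi K tau)).  Continuous,
    equal to R0 at t = 0, and showing the contraction-then-growth shape
    for Ci < C0.  Valid while K pi^2 t / R0^2 is at most order one.

    Raises a redirect error for eta = 0 (use
    :func:`diffusion_only_radius`, whose eta = 0 limit is this same
    planar reduction).
    """
    if params.eta == 0.0:
        raise ValueError(
            "closed_form_radius requires eta > 0; for eta = 0 use "
            "diffusion_only_radius, its proliferation-free limit"
        )
    params = params.normalized()
    consts = consts or ClosedFormConstants.from_parameters(params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    eta = params.eta
    x = np.sqrt(eta * t_arr)
    bracket = (t_arr - 0.5 / eta) * special.erfi(x) - np.sqrt(
        t_arr / (math.pi * eta)
    ) * np.exp(eta * t_arr)
    out = params.R0 + consts.alpha * bracket
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def integrate_analytic_trajectory(
    params: ModelParameters,
    cfg: Optional[SeriesConfig] = None,
    times: Optional[Sequence[float]] = None,
    *,
    rate: str = "simplified",
) -> Trajectory:
    """Integrate the chosen analytic rate equation forward from R(0) = R0.

    ``rate`` selects :func:`simplified_radius_rate` (default, the curve
    plotted in the model-analysis comparisons) or the full
    :func:`series_radius_rate`.  A Heun (trapezoidal) predictor-corrector
    on a uniform internal grid of ``cfg.n_time_steps`` steps advances the
    radius; for the simplified rate the history integral is accumulated
    incrementally alongside the radius, so the cost is linear in the
    number of steps.  Requested ``times`` (must start at 0) are filled by
    interpolation of the internal grid.
    """
    cfg = cfg or SeriesConfig()
    params = params.check().normalized()
    if rate not in ("simplified", "series"):
        raise ValueError(f"rate must be 'simplified' or 'series', got {rate!r}")
    if times is None:
        times = np.linspace(0.0, params.t_max, 211)
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        raise ValueError("requested times must start at 0")
    t_end = float(times[-1])
    n_steps = cfg.n_time_steps
    h = t_end / n_steps
    eta = params.eta

    grid_t = np.linspace(0.0, t_end, n_steps + 1)
    grid_r = np.empty(n_steps + 1)
    grid_r[0] = params.R0

    if rate == "series":

        def rate_fn(tk: float, Rk: float) -> float:
            return -params.K * _series_flux(tk, Rk, params, cfg)

        for k in range(n_steps):
            tk, Rk = grid_t[k], grid_r[k]
            f1 = rate_fn(tk, Rk)
            R_pred = Rk + h * f1
            if R_pred <= 0:
                raise CollapseError(f"analytic radius collapsed at t = {tk + h:.4g} h")
            f2 = rate_fn(tk + h, R_pred)
            R_next = Rk + 0.5 * h * (f1 + f2)
            if R_next <= 0:
                raise CollapseError(f"analytic radius collapsed at t = {tk + h:.4g} h")
            grid_r[k + 1] = R_next
    else:
        # incremental history integral I(t) = int_0^t e^{eta tau} *
        # (S_h + S_p)(tau) / R(tau)^2 dtau
        def f_integrand(tk: float, Rk: float) -> float:
            tc = _clamp_time(tk, params, cfg)
            s_h, s_p = _collapsed_sum(tc, params, cfg)
            return math.exp(min(eta * tk, 700.0)) * (s_h + s_p) / Rk**2

        def rate_from(tk: float, Rk: float, Ik: float) -> float:
            tc = _clamp_time(tk, params, cfg)
            s_h, s_p = _collapsed_sum(tc, params, cfg)
            inst = math.exp(min(eta * tk, 700.0)) * (s_h + s_p) / Rk**2
            return -params.K * (inst - eta * Ik)

        I = 0.0
        for k in range(n_steps):
            tk, Rk = grid_t[k], grid_r[k]
            g1 = f_integrand(tk, Rk)
            f1 = rate_from(tk, Rk, I)
            R_pred = Rk + h * f1
            if R_pred <= 0:
                raise CollapseError(f"analytic radius collapsed at t = {tk + h:.4g} h")
            g2 = f_integrand(tk + h, R_pred)
            I_pred = I + 0.5 * h * (g1 + g2)
            f2 = rate_from(tk + h, R_pred, I_pred)
            R_next = Rk + 0.5 * h * (f1 + f2)
            if R_next <= 0:
                raise CollapseError(f"analytic radius collapsed at t = {tk + h:.4g} h")
            grid_r[k + 1] = R_next
            I = I + 0.5 * h * (g1 + f_integrand(tk + h, R_next))

    radii = np.interp(times, grid_t, grid_r)
    radii[0] = params.R0
    return Trajectory(
        times=times.copy(),
        radii=radii,
        metadata={
            "parameters": params.to_dict(),
            "config": {
                "rate": rate,
                "n_terms": cfg.n_terms,
                "n_time_steps": cfg.n_time_steps,
            },
        },
    )
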
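"""Two-Gaussian hemodynamic block-response model and joint constrained fit.

The averaged BOLD response of one visual area to one 15 s stimulation /
15 s rest block, sampled at t_n = 0, 2.5, ..., 30 s (13 points, % signal
change), is modelled as the windowed integral of two Gaussian pulses — a
positive activation pulse (T1, alpha1) and a negative undershoot pulse
(T2, alpha2) — plus a linear drift:

    ModelR(t_n) = a1 * I(T1, a1; t_n) + a2 * I(T2, a2; t_n) + b*t_n + d
    I(T, alpha; t) = integral over [max(t-15, 0), t] of
                     exp(-(tau - T)^2 / (2 alpha^2)) dtau

The Heaviside gate clamps the lower integration limit at stimulus onset.
The four temporal parameters are shared across the four Chroma conditions
of one (subject, area); the per-condition amplitudes (a1 > 0, a2 < 0) and
drift (b, d) are free.  The fit minimises the summed squared *relative*
residual ("error value", EV) over all conditions and time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import erf

__all__ = [
    "TimeGrid",
    "HRFTemporalParams",
    "ConditionParams",
    "BlockTimeCourse",
    "JointHRFFit",
    "FitConfig",
    "pulse_window_integral",
    "model_response",
    "error_value",
    "error_value_detailed",
    "fit_joint_hrf",
    "peak_response",
    "normalize_peaks",
]

CONDITIONS = ("/0", "/2", "/4", "/6")

#: Stimulation-phase duration in seconds; the integration window is
#: [t - STIM_DURATION, t], gated at 0.
STIM_DURATION = 15.0


@dataclass(frozen=True)
class TimeGrid:
    """The 13-point sampling grid t_n = 0, 2.5, ..., 30 s."""

    times: tuple = tuple(np.arange(13) * 2.5)

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if t.size != 13:
            raise ValueError(f"time grid must have exactly 13 samples, got {t.size}")
        dt = np.diff(t)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError("time grid must be strictly increasing with fixed spacing")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, float)


@dataclass(frozen=True)
class HRFTemporalParams:
    """Shared pulse timing: centers T1 < T2 (s), widths alpha1, alpha2 (s)."""

    T1: float
    T2: float
    alpha1: float
    alpha2: float

    def __post_init__(self):
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("pulse widths alpha1, alpha2 must be positive")
        if not self.T1 < self.T2:
            raise ValueError(f"activation pulse must precede undershoot (T1 < T2), "
                             f"got T1={self.T1}, T2={self.T2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.T1, self.T2, self.alpha1, self.alpha2])


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition pulse intensities and drift.

    a1 is the (positive) activation intensity, a2 the (negative)
    undershoot intensity; b*t + d is the linear component in % signal
    change.
    """

    a1: float
    a2: float
    b: float
    d: float
    condition: str = "/0"

    def __post_init__(self):
        if not self.a1 > 0:
            raise ValueError(f"a1 must be positive, got {self.a1}")
        if not self.a2 < 0:
            raise ValueError(f"a2 must be negative, got {self.a2}")


@dataclass(frozen=True)
class BlockTimeCourse:
    """One condition's block-averaged BOLD response on the standard grid."""

    condition: str
    responses: np.ndarray
    n_blocks_averaged: int = 54
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self):
        r = np.asarray(self.responses, float)
        object.__setattr__(self, "responses", r)
        if r.shape != (len(self.grid.times),):
            raise ValueError(
                f"responses must match the {len(self.grid.times)}-point grid, "
                f"got shape {r.shape}"
            )


@dataclass
class JointHRFFit:
    """Result of the joint four-condition fit."""

    temporal: HRFTemporalParams
    per_condition: dict
    ev: float
    peaks: dict
    curves: dict
    diagnostics: dict


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_joint_hrf`.

    The outer search over the shared temporal parameters is a bounded
    derivative-free simplex with multiple starts; the first start is a
    canonical HRF (T1=6, T2=16, alpha1=2.5, alpha2=4), the rest are drawn
    inside the bounds from the seed.  The inner problem (a1, a2, b, d per
    condition) is solved by bounded least squares on the relative
    residuals with an analytic Jacobian.
    """

    n_starts: int = 5
    seed: int = 0
    eps: float = 1e-3           # |ModelR| clamp in the EV denominator
    t1_bounds: tuple = (2.0, 12.0)
    t2_bounds: tuple = (8.0, 25.0)
    alpha_bounds: tuple = (0.5, 8.0)
    outer_maxiter: int = 250
    outer_xatol: float = 1e-3
    outer_fatol: float = 1e-9
    polish: bool = True         # joint gradient polish of all 20 parameters
    include_drift_in_peak: bool = True
    peak_dt: float = 0.01

    _A1_MIN = 1e-6
    _A2_MAX = -1e-6


def pulse_window_integral(T, alpha, lower, upper):
    """Integral of exp(-(tau-T)^2 / (2 alpha^2)) over [max(lower, 0), upper].

    Closed form via the error function; vectorised over `lower`/`upper`.
    Returns 0 where the gated window is empty (upper <= max(lower, 0)).
    """
    if np.any(np.asarray(alpha) <= 0):
        raise ValueError("alpha must be positive")
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if np.any(upper < lower):
        raise ValueError("window requires lower <= upper")
    lo = np.maximum(lower, 0.0)
    hi = np.maximum(upper, lo)
    s = alpha * math.sqrt(2.0)
    out = alpha * math.sqrt(math.pi / 2.0) * (erf((hi - T) / s) - erf((lo - T) / s))
    return out if out.ndim else float(out)


def _pulse_bases(temporal: HRFTemporalParams, t: np.ndarray) -> tuple:
    """Window integrals of the two unit pulses at each grid time."""
    lo = t - STIM_DURATION
    g1 = pulse_window_integral(temporal.T1, temporal.alpha1, lo, t)
    g2 = pulse_window_integral(temporal.T2, temporal.alpha2, lo, t)
    return np.atleast_1d(g1), np.atleast_1d(g2)


def model_response(
    temporal: HRFTemporalParams,
    cond: ConditionParams,
    grid: TimeGrid = TimeGrid(),
) -> np.ndarray:
    """Model curve ModelR(t_n) on the grid, in % signal change."""
    t = grid.as_array()
    g1, g2 = _pulse_bases(temporal, t)
    return cond.a1 * g1 + cond.a2 * g2 + cond.b * t + cond.d


def _clamped(model: np.ndarray, eps: float) -> tuple:
    """Denominator-guarded model values and the number of clamped points."""
    sign = np.where(model >= 0, 1.0, -1.0)
    clamped = np.abs(model) < eps
    return np.where(clamped, sign * eps, model), int(clamped.sum())


def error_value_detailed(data, curves, eps: float = 1e-3) -> tuple:
    """EV plus the count of denominator-clamped points.

    `data` and `curves` are equal-length sequences of 13-point arrays (or
    :class:`BlockTimeCourse` on the data side), one per condition.
    """
    ev = 0.0
    n_clamped = 0
    if len(data) != len(curves):
        raise ValueError("data and curves must pair up condition-wise")
    for r, m in zip(data, curves):
        r = r.responses if isinstance(r, BlockTimeCourse) else np.asarray(r, float)
        m = np.asarray(m, float)
        if r.shape != m.shape:
            raise ValueError("data and model curves must share the time grid")
        denom, nc = _clamped(m, eps)
        n_clamped += nc
        ev += float(np.sum(((r - m) / denom) ** 2))
    return ev, n_clamped


def error_value(data, curves, eps: float = 1e-3) -> float:
    """Error value: sum over conditions and times of ((R - ModelR)/ModelR)^2.

    Model values with magnitude below `eps` (% signal change) are clamped
    to +/- eps in the denominator.
    """
    return error_value_detailed(data, curves, eps)[0]


def _fit_condition(r, g1, g2, t, eps, a1_min, a2_max, p0=None, tol=1e-12):
    """Best (a1, a2, b, d) for one condition at fixed temporal parameters.

    Bounded least squares on the relative residuals (R - M)/M with an
    analytic Jacobian; warm-started from the sign-clipped ordinary linear
    solve of M ~ R (or a caller-provided previous solution).
    """
    B = np.column_stack([g1, g2, t, np.ones_like(t)])
    if p0 is None:
        p0, *_ = np.linalg.lstsq(B, r, rcond=None)
    else:
        p0 = np.array(p0, float)
    p0[0] = max(p0[0], 10 * a1_min)
    p0[1] = min(p0[1], 10 * a2_max)

    def residuals(p):
        m = B @ p
        denom, _ = _clamped(m, eps)
        return (r - m) / denom

    def jac(p):
        m = B @ p
        denom, _ = _clamped(m, eps)
        # d/dp [(r - m)/m] = -B * r / m^2 (clamp treated as locally constant)
        return -B * (r / denom**2)[:, None]

    sol = least_squares(
        residuals, p0, jac=jac,
        bounds=([a1_min, -np.inf, -np.inf, -np.inf],
                [np.inf, a2_max, np.inf, np.inf]),
        method="trf", xtol=tol, ftol=tol, gtol=tol,
    )
    return sol.x, 2.0 * sol.cost  # least_squares cost is half the sum of squares


_EYE4 = np.eye(4)


def _fit_condition_fast(r, g1, g2, t, eps, a1_min, a2_max, p0=None,
                        max_iter=40, tol=1e-10):
    """Damped Gauss-Newton variant of :func:`_fit_condition`.

    Used inside the outer temporal search, where the inner problem is
    re-solved thousands of times from warm starts; the sign bounds are
    enforced by projection after each step.
    """
    B = np.column_stack([g1, g2, t, np.ones_like(t)])
    if p0 is None:
        p0, *_ = np.linalg.lstsq(B, r, rcond=None)
    p = np.array(p0, float)
    p[0] = max(p[0], 10 * a1_min)
    p[1] = min(p[1], 10 * a2_max)

    def cost_res(p):
        m = B @ p
        denom, _ = _clamped(m, eps)
        res = (r - m) / denom
        return float(res @ res), res, denom

    cost, res, denom = cost_res(p)
    lam = 1e-10
    for _ in range(max_iter):
        J = -B * (r / denom**2)[:, None]
        g = J.T @ res
        H = J.T @ J
        step_ok = False
        for _ in range(8):
            try:
                step = np.linalg.solve(H + lam * _EYE4, -g)
            except np.linalg.LinAlgError:
                lam = max(lam * 10, 1e-8)
                continue
            cand = p + step
            cand[0] = max(cand[0], a1_min)
            cand[1] = min(cand[1], a2_max)
            new_cost, new_res, new_denom = cost_res(cand)
            if new_cost <= cost:
                step_ok = True
                lam = max(lam / 10, 1e-12)
                break
            lam = max(lam * 10, 1e-8)
        if not step_ok:
            break
        improved = cost - new_cost
        p, cost, res, denom = cand, new_cost, new_res, new_denom
        if improved < tol * (1.0 + cost):
            break
    return p, cost


def fit_joint_hrf(data, config: FitConfig = FitConfig()) -> JointHRFFit:
    """Jointly fit the four Chroma conditions of one (subject, area).

    Parameters
    ----------
    data
        Sequence or mapping of four :class:`BlockTimeCourse`, one per
        condition, on a common grid.
    config
        Optimizer settings; the fit is deterministic for fixed
        (data, config).

    Returns
    -------
    JointHRFFit
        Shared temporal parameters, per-condition amplitudes/drift, EV,
        per-condition peak responses and fitted curves, and optimizer
        diagnostics (starts, convergence flag, clamp warnings).  A
        non-converged outer search still returns the best-so-far
        parameters, flagged in ``diagnostics['converged']``.
    """
    if isinstance(data, dict):
        data = [data[c] for c in sorted(data, key=CONDITIONS.index)]
    data = list(data)
    if len(data) != 4:
        raise ValueError(f"joint fit requires the four Chroma conditions, got {len(data)}")
    grid = data[0].grid
    t = grid.as_array()
    responses = [tc.responses for tc in data]
    labels = [tc.condition for tc in data]

    lb = np.array([config.t1_bounds[0], config.t2_bounds[0],
                   config.alpha_bounds[0], config.alpha_bounds[0]])
    ub = np.array([config.t1_bounds[1], config.t2_bounds[1],
                   config.alpha_bounds[1], config.alpha_bounds[1]])

    warm = [None] * 4  # last inner solution per condition, reused as p0

    def outer_objective(theta):
        T1, T2, a1w, a2w = theta
        if T1 >= T2:  # ordering constraint, enforced by penalty
            return 1e9 * (1.0 + T1 - T2)
        temporal = HRFTemporalParams(T1, T2, a1w, a2w)
        g1, g2 = _pulse_bases(temporal, t)
        total = 0.0
        for i, r in enumerate(responses):
            p, cost = _fit_condition_fast(r, g1, g2, t, config.eps,
                                          config._A1_MIN, config._A2_MAX,
                                          p0=warm[i])
            warm[i] = p
            total += cost
        return total

    rng = np.random.default_rng(config.seed)
    starts = [np.array([6.0, 16.0, 2.5, 4.0])]
    while len(starts) < config.n_starts:
        cand = lb + (ub - lb) * rng.random(4)
        if cand[0] < cand[1]:
            starts.append(cand)

    best = None
    n_converged = 0
    for x0 in starts:
        res = minimize(
            outer_objective, x0, method="Nelder-Mead",
            bounds=list(zip(lb, ub)),
            options={"maxiter": config.outer_maxiter,
                     "xatol": config.outer_xatol, "fatol": config.outer_fatol},
        )
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    converged = n_converged > 0

    # joint gradient polish of all 20 parameters (temporal + 4 x (a1,a2,b,d))
    if config.polish:
        def full_objective(z):
            T1, T2, a1w, a2w = z[:4]
            if T1 >= T2:
                return 1e9 * (1.0 + T1 - T2)
            temporal = HRFTemporalParams(T1, T2, a1w, a2w)
            g1, g2 = _pulse_bases(temporal, t)
            B = np.column_stack([g1, g2, t, np.ones_like(t)])
            ev = 0.0
            for i, r in enumerate(responses):
                m = B @ z[4 + 4 * i: 8 + 4 * i]
                denom, _ = _clamped(m, config.eps)
                ev += float(np.sum(((r - m) / denom) ** 2))
            return ev

        temporal = HRFTemporalParams(*theta)
        g1, g2 = _pulse_bases(temporal, t)
        z0 = np.concatenate(
            [theta] + [_fit_condition(r, g1, g2, t, config.eps,
                                      config._A1_MIN, config._A2_MAX)[0]
                       for r in responses]
        )
        zbounds = list(zip(lb, ub)) + [
            (config._A1_MIN, None), (None, config._A2_MAX), (None, None), (None, None)
        ] * 4
        polish = minimize(full_objective, z0, method="L-BFGS-B", bounds=zbounds,
                          options={"maxiter": 500})
        if polish.fun <= best.fun:
            theta = polish.x[:4]

    temporal = HRFTemporalParams(*theta)
    g1, g2 = _pulse_bases(temporal, t)
    per_condition = {}
    curves = {}
    for label, r in zip(labels, responses):
        p, _ = _fit_condition(r, g1, g2, t, config.eps,
                              config._A1_MIN, config._A2_MAX)
        cp = ConditionParams(a1=p[0], a2=p[1], b=p[2], d=p[3], condition=label)
        per_condition[label] = cp
        curves[label] = model_response(temporal, cp, grid)

    ev, n_clamped = error_value_detailed(
        responses, [curves[c] for c in labels], config.eps
    )
    fit = JointHRFFit(
        temporal=temporal,
        per_condition=per_condition,
        ev=ev,
        peaks={},
        curves=curves,
        diagnostics={
            "converged": converged,
            "n_starts": len(starts),
            "n_starts_converged": n_converged,
            "outer_fun": float(best.fun),
            "n_denominator_clamps": n_clamped,
            "seed": config.seed,
            "conditions": labels,
        },
    )
    fit.peaks = {
        c: peak_response(fit, c, include_drift=config.include_drift_in_peak,
                         dt=config.peak_dt, grid=grid)
        for c in labels
    }
    return fit


def peak_response(
    fit: JointHRFFit,
    condition: str,
    include_drift: bool = True,
    dt: float = 0.01,
    grid: TimeGrid = TimeGrid(),
) -> float:
    """Peak of the fitted curve on a dense grid over [0, 30] s.

    The peak of the fitted model curve is the response measure in % signal
    change.  With ``include_drift=False`` only the two-pulse component is
    maximised.
    """
    cp = fit.per_condition[condition]
    t = grid.as_array()
    tt = np.arange(t[0], t[-1] + dt / 2, dt)
    g1 = pulse_window_integral(fit.temporal.T1, fit.temporal.alpha1,
                               tt - STIM_DURATION, tt)
    g2 = pulse_window_integral(fit.temporal.T2, fit.temporal.alpha2,
                               tt - STIM_DURATION, tt)
    curve = cp.a1 * g1 + cp.a2 * g2
    if include_drift:
        curve = curve + cp.b * tt + cp.d
    return float(curve.max())


def normalize_peaks(peaks, mode: str = "subtract"):
    """Normalise the four condition peaks across conditions.

    ``subtract`` (default) removes the four-condition mean, so the values
    sum to zero; ``ratio`` divides by the mean.
    """
    if isinstance(peaks, dict):
        keys = list(peaks)
        vals = np.array([peaks[k] for k in keys], float)
    else:
        keys = None
        vals = np.asarray(peaks, float)
    if vals.size != 4 or not np.all(np.isfinite(vals)):
        raise ValueError("normalization expects four finite condition peaks")
    mean = vals.mean()
    if mode == "subtract":
        out = vals - mean
    elif mode == "ratio":
        out = vals / mean
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if keys is not None:
        return dict(zip(keys, out))
    return out
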
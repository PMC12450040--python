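"""Saturation-limited dispersion kinetics: the Hill model and its statistics.

The dispersed amount f(t) (turbidity in NTU or mass in g) follows the Hill
saturation law

    f(t) = a * t^c / (b^c + t^c) = a * (1 - 1 / (1 + (t/b)^c))

with saturation level ``a`` (response units), half-saturation time ``b``
(minutes, f(b) = a/2 for every c) and dimensionless shape ``c`` (> 0).
At c = 1 this is the rectangular hyperbola a*t/(b + t) (Michaelis–Menten
form) and solves the quadratic-deficit rate law

    df/dt = (a/b) * (1 - f/a)^2,

i.e. the rate falls with the *square* of the remaining capacity, in contrast
to the first-order Noyes–Whitney law df/dt = K (1 - f/a).  For general c the
rate law is

    df/dt = (a/k) * (f/a)^(1-1/c) * (1 - f/a)^(1+1/c),   k = b/c,

whose f^(1-1/c) factor encodes autocatalytic (sigmoidal) behaviour for
c > 1 and which tends to the logistic equation as c -> infinity.

Fitting is unweighted nonlinear least squares, log-parameterised to keep
all parameters positive, with a deterministic initialiser.  The statistics
panel (R^2, adjusted R^2, SE, F, p, AIC, BIC, AICc) uses the Gaussian
log-likelihood form AIC = n*ln(RSS/n) + 2k with k counting only the curve
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "KineticSeries",
    "HillParams",
    "FitStats",
    "LinearMap",
    "FitError",
    "hill_eval",
    "hill_rate",
    "noyes_whitney_rate",
    "integrate_ode",
    "HillRegressor",
    "fit_hill",
    "fit_stats",
    "prediction_interval",
    "relative_error",
    "linear_correlation",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


@dataclass(frozen=True)
class KineticSeries:
    """A dispersion time course: strictly increasing times (min), responses >= 0."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "mass"  # {"turbidity", "mass"}

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if times.size < 3:
            raise ValueError(f"need at least 3 points, got {times.size}")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(values < 0):
            raise ValueError("responses must be non-negative")
        if self.kind not in ("turbidity", "mass"):
            raise ValueError(f"kind must be 'turbidity' or 'mass', got {self.kind!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class HillParams:
    """Hill parameters; the rate constant k = b/c is derived."""

    a: float
    b: float
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c <= 0:
            raise ValueError(f"a, b, c must all be > 0, got {(self.a, self.b, self.c)}")

    @property
    def k(self) -> float:
        return self.b / self.c


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit panel for a least-squares regression."""

    R2: float
    aR2: float
    SE: float
    p_value: float
    AIC: float
    BIC: float
    AICc: float
    F: float
    DoF: int
    n: int
    k_params: int


@dataclass(frozen=True)
class LinearMap:
    """Affine turbidity–mass relation: NTU = slope * g + intercept."""

    slope: float
    intercept: float
    R2: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.slope, self.intercept, self.R2)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"linear map must be finite, got {vals}")

    def __call__(self, mass):
        return self.slope * np.asarray(mass, dtype=float) + self.intercept


def hill_eval(params: HillParams, t):
    """Evaluate f(t) = a * t^c / (b^c + t^c); f(0) = 0, f(b) = a/2.

    Computed as a * expit(c * (ln t - ln b)), the overflow-free equivalent.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.zeros(t.shape)
    pos = t > 0
    out[pos] = params.a * special.expit(params.c * (np.log(t[pos]) - np.log(params.b)))
    return out if out.ndim else float(out)

def hill_rate(params: HillParams, f):
    """Dispersion rate df/dt expressed in the dispersed amount f.

    c = 1: (a/b) * (1 - f/a)^2.  General c: (a/k) * (f/a)^(1-1/c) *
    (1 - f/a)^(1+1/c) with k = b/c, which reduces to the former at c = 1.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f >= params.a):
        raise ValueError(f"f must satisfy 0 <= f < a = {params.a}")
    deficit = 1.0 - f / params.a
    if params.c == 1.0:
        out = (params.a / params.b) * deficit**2
    else:
        out = (
            (params.a / params.k)
            * (f / params.a) ** (1.0 - 1.0 / params.c)
            * deficit ** (1.0 + 1.0 / params.c)
        )
    return out if out.ndim else float(out)


def noyes_whitney_rate(K: float, a: float, f):
    """First-order dissolution rate K * (1 - f/a), for model comparison.

    At the matched constant K = a/b, the ratio of the quadratic-deficit rate
    to this one is exactly (1 - f/a): the saturation slowdown the first-order
    law misses.
    """
    f = np.asarray(f, dtype=float)
    out = K * (1.0 - f / a)
    return out if out.ndim else float(out)


def integrate_ode(
    params: HillParams, t_grid, rtol: float = 1e-10, atol: float = 1e-12
) -> KineticSeries:
    """Numerically integrate the rate law over ``t_grid`` (must start at 0).

    For c = 1 the rate law is smooth at the origin and integration starts
    from (0, 0).  For c != 1, f = 0 is a degenerate point (the rate is zero
    or infinite there and the forward problem is non-Lipschitz), so the
    trajectory is anchored at the regular half-saturation point (t = b,
    f = a/2) and integrated backward and forward from it; f(0) = 0 is set
    exactly.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0")

    def rhs(_t, y):
        f = min(max(y[0], 0.0), params.a * (1.0 - 1e-15))
        return [hill_rate(params, f)]

    opts = dict(rtol=rtol, atol=atol * max(params.a, 1.0))

    def run(t_span, f0, t_eval):
        sol = solve_ivp(
            rhs, t_span, [f0], t_eval=t_eval,
            method="LSODA" if params.c == 1.0 else "DOP853", **opts,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return sol.y[0]

    if params.c == 1.0:
        values = run((0.0, t_grid[-1]), 0.0, t_grid)
    else:
        anchor = params.b
        half = params.a / 2.0
        out = {0.0: 0.0}
        interior = t_grid[t_grid > 0]
        back = interior[interior < anchor][::-1]
        fwd = interior[interior > anchor]
        if np.any(interior == anchor):
            out[anchor] = half
        if back.size:
            for t, v in zip(back, run((anchor, back[-1]), half, back)):
                out[t] = v
        if fwd.size:
            for t, v in zip(fwd, run((anchor, fwd[-1]), half, fwd)):
                out[t] = v
        values = np.array([out[t] for t in t_grid])
    return KineticSeries(t_grid, np.clip(values, 0.0, None), kind="mass")


def _initial_guess(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Deterministic initialiser: a0 = 1.1*max, b0 = first half-max crossing."""
    vmax = float(values.max())
    if vmax <= 0:
        raise FitError("all responses are zero; nothing to fit")
    a0 = 1.1 * vmax
    half = vmax / 2.0
    idx = int(np.argmax(values >= half))
    if idx == 0:
        b0 = times[0] if times[0] > 0 else float(times[1]) / 2.0
    else:
        t_lo, t_hi = times[idx - 1], times[idx]
        v_lo, v_hi = values[idx - 1], values[idx]
        b0 = t_lo + (half - v_lo) / (v_hi - v_lo) * (t_hi - t_lo) if v_hi > v_lo else t_hi
    return a0, max(float(b0), 1e-3)


class HillRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the Hill saturation curve.

    Parameters
    ----------
    fix_c : bool, default True
        Fit the two-parameter (a, b) model with c = 1; otherwise c is a
        third free parameter.

    Attributes
    ----------
    a_, b_, c_ : float
        Fitted saturation level, half-saturation time and shape.
    params_ : HillParams
    cov_ : ndarray
        Covariance of the fitted (natural-scale) parameters, from the
        Jacobian at the optimum scaled by RSS/DoF.
    stats_ : FitStats
        Full goodness-of-fit panel.

    Notes
    -----
    The optimiser works on log-parameters, which enforces positivity
    without constraints; the initialiser is deterministic, so repeated
    fits of the same data are identical.
    """

    def __init__(self, fix_c: bool = True):
        self.fix_c = fix_c

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have the same length")
        k_params = 2 if self.fix_c else 3
        if t.size < k_params + 1:
            raise ValueError(
                f"need at least {k_params + 1} points for {k_params} parameters"
            )
        a0, b0 = _initial_guess(t, y)
        theta0 = np.log([a0, b0] if self.fix_c else [a0, b0, 1.0])

        def residuals(theta):
            p = np.exp(theta)
            params = HillParams(p[0], p[1], 1.0 if self.fix_c else p[2])
            return hill_eval(params, t) - y

        res = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        if not res.success:
            raise FitError(
                f"Hill fit did not converge: {res.message}; final residuals "
                f"{np.round(res.fun, 6).tolist()}"
            )
        p = np.exp(res.x)
        self.a_, self.b_ = float(p[0]), float(p[1])
        self.c_ = 1.0 if self.fix_c else float(p[2])
        self.params_ = HillParams(self.a_, self.b_, self.c_)
        self.n_features_in_ = 1

        # delta method: J w.r.t. natural params = J_log / p
        rss = float(res.fun @ res.fun)
        dof = t.size - k_params
        J = res.jac / p  # chain rule d(res)/d(param) = d(res)/d(log param) / param
        JTJ = J.T @ J
        try:
            self.cov_ = np.linalg.inv(JTJ) * (rss / dof if dof > 0 else np.nan)
        except np.linalg.LinAlgError:
            self.cov_ = np.full((k_params, k_params), np.nan)
        self.stats_ = fit_stats(y, hill_eval(self.params_, t), k_params=k_params)
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return hill_eval(self.params_, t)


def fit_hill(series: KineticSeries, fix_c: bool = True) -> tuple[HillParams, FitStats]:
    """Fit the Hill curve to a kinetic series; see :class:`HillRegressor`."""
    reg = HillRegressor(fix_c=fix_c).fit(series.times, series.values)
    return reg.params_, reg.stats_


def fit_stats(observed, predicted, k_params: int, n: int | None = None) -> FitStats:
    """Regression statistics panel.

    RSS = sum (obs - pred)^2, TSS about the mean of the observations;
    R^2 = 1 - RSS/TSS; adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-k);
    SE = sqrt(RSS/(n-k)); AIC = n ln(RSS/n) + 2k; BIC = n ln(RSS/n) + k ln n;
    AICc = AIC + 2k(k+1)/(n-k-1); F = ((TSS-RSS)/(k-1)) / (RSS/(n-k)) with
    p the upper tail of F(k-1, n-k).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if n is None:
        n = observed.size
    k = int(k_params)
    if n <= k:
        raise ValueError(f"need n > k_params, got n={n}, k={k}")
    rss = float(np.sum((observed - predicted) ** 2))
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0:
        raise ValueError("degenerate data: zero total sum of squares")
    r2 = 1.0 - rss / tss
    ar2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    se = math.sqrt(rss / (n - k))
    # Gaussian-likelihood information criteria; guard log(0) for exact fits
    rss_ = max(rss, np.finfo(float).tiny)
    aic = n * math.log(rss_ / n) + 2 * k
    bic = n * math.log(rss_ / n) + k * math.log(n)
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n > k + 1 else math.inf
    if k > 1:
        f_stat = ((tss - rss) / (k - 1)) / (rss / (n - k)) if rss > 0 else math.inf
        p_value = float(stats.f.sf(f_stat, k - 1, n - k)) if math.isfinite(f_stat) else 0.0
    else:
        f_stat, p_value = math.nan, math.nan
    return FitStats(
        R2=r2, aR2=ar2, SE=se, p_value=p_value, AIC=aic, BIC=bic, AICc=aicc,
        F=f_stat, DoF=n - k, n=n, k_params=k,
    )


def prediction_interval(SE: float) -> float:
    """Approximate prediction-interval width: 2 * SE (response units)."""
    if SE < 0:
        raise ValueError("SE must be >= 0")
    return 2.0 * SE


def relative_error(SE: float, value: float) -> float:
    """Relative error in percent: 100 * (2*SE) / value."""
    if value <= 0:
        raise ValueError(f"reference value must be > 0, got {value}")
    return 100.0 * prediction_interval(SE) / value


def linear_correlation(turbidity: KineticSeries, mass: KineticSeries) -> LinearMap:
    """OLS regression of turbidity (NTU) on dispersed mass (g).

    Both series must share the same time grid; a constant mass channel has
    no defined slope and raises.
    """
    if turbidity.n != mass.n or not np.allclose(turbidity.times, mass.times):
        raise ValueError("turbidity and mass series must share the same time grid")
    x = mass.values
    y = turbidity.values
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: mass channel is constant")
    res = stats.linregress(x, y)
    return LinearMap(float(res.slope), float(res.intercept), float(res.rvalue**2))
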
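"""Solvent–solute compatibility scoring in Hansen space.

The distance between two substances is

    Ra = sqrt(4*(dd1 - dd2)^2 + (dp1 - dp2)^2 + (dh1 - dh2)^2)

(the dispersive axis carries the conventional factor 4), and the relative
energy difference RED = Ra / R0 compares it with the solute's interaction
radius R0: RED < 1 predicts compatibility.

When a solute's Hansen center and radius are not tabulated but RED values
against a panel of solvents are, :class:`SoluteCalibrator` inverts them:
it finds the (center, R0) whose predicted REDs best match the panel in the
least-squares sense, using multi-start bounded optimisation (the 4-parameter
problem is nonconvex).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .hsp import HansenTriplet

__all__ = [
    "SoluteReference",
    "CompatibilityScore",
    "CalibrationError",
    "ra_distance",
    "red_value",
    "score_mixture",
    "rank_by_red",
    "SoluteCalibrator",
    "calibrate_solute",
    "default_beeswax_reference",
]

#: Search box for calibration: delta_d in [12, 18], delta_p in [0, 6],
#: delta_h in [0, 10], R0 in [2, 20] (all MPa^0.5) — generous bounds around
#: aliphatic/low-polarity solutes such as waxes.
DEFAULT_BOUNDS = ((12.0, 0.0, 0.0, 2.0), (18.0, 6.0, 10.0, 20.0))


class CalibrationError(RuntimeError):
    """The solute calibration failed to converge from any start."""


@dataclass(frozen=True)
class SoluteReference:
    """A solute's Hansen center plus interaction radius R0 (MPa^0.5)."""

    center: HansenTriplet
    R0: float

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError(f"R0 must be > 0, got {self.R0}")


@dataclass(frozen=True)
class CompatibilityScore:
    des_name: str
    Ra: float
    RED: float
    compatible: bool


def ra_distance(a: HansenTriplet, b: HansenTriplet) -> float:
    """Hansen-space distance Ra between two substances (symmetric)."""
    d = a.as_array() - b.as_array()
    return float(np.sqrt(4.0 * d[0] ** 2 + d[1] ** 2 + d[2] ** 2))


def red_value(Ra: float, ref: SoluteReference) -> float:
    """Relative energy difference Ra / R0."""
    if ref.R0 <= 0:
        raise ValueError(f"R0 must be > 0, got {ref.R0}")
    return Ra / ref.R0


def score_mixture(
    des_name: str, hsp: HansenTriplet, ref: SoluteReference, threshold: float = 1.0
) -> CompatibilityScore:
    ra = ra_distance(hsp, ref.center)
    red = red_value(ra, ref)
    return CompatibilityScore(des_name, ra, red, bool(red < threshold))


def rank_by_red(scores) -> list[CompatibilityScore]:
    """Ascending by RED; ties broken lexicographically by name."""
    scores = list(scores)
    if not scores:
        raise ValueError("cannot rank an empty score list")
    return sorted(scores, key=lambda s: (s.RED, s.des_name))


class SoluteCalibrator(BaseEstimator):
    """Recover a solute's Hansen center and radius from RED observations.

    Fit minimises ``sum_i (Ra(X_i, center)/R0 - y_i)^2`` over a bounded box
    by local least squares started from ``n_starts`` quasi-random (Sobol)
    points; the best converged run wins.  Deterministic for a fixed
    ``random_state``.

    Parameters
    ----------
    bounds : pair of 4-tuples
        (lower, upper) for (delta_d, delta_p, delta_h, R0).
    n_starts : int
        Number of multi-start points.
    random_state : int
        Seed of the Sobol start generator.

    Attributes
    ----------
    center_ : HansenTriplet
        Calibrated solute center.
    radius_ : float
        Calibrated interaction radius R0.
    reference_ : SoluteReference
        ``(center_, radius_)`` bundled.
    rms_residual_ : float
        Root-mean-square RED residual at the optimum.
    n_features_in_ : int
        Always 3.
    """

    def __init__(self, bounds=DEFAULT_BOUNDS, n_starts: int = 32, random_state: int = 0):
        self.bounds = bounds
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(f"X must have shape (n, 3), got {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("y must be one RED value per row of X")
        if X.shape[0] < 5:
            raise ValueError(
                "under-determined calibration: need >= 5 (triplet, RED) pairs "
                f"for 4 free parameters, got {X.shape[0]}"
            )
        lo = np.asarray(self.bounds[0], dtype=float)
        hi = np.asarray(self.bounds[1], dtype=float)

        def residuals(p):
            dd, dp, dh, r0 = p
            ra = np.sqrt(
                4.0 * (X[:, 0] - dd) ** 2 + (X[:, 1] - dp) ** 2 + (X[:, 2] - dh) ** 2
            )
            return ra / r0 - y

        sobol = qmc.Sobol(d=4, seed=self.random_state)
        starts = lo + sobol.random(self.n_starts) * (hi - lo)
        best = None
        failures = []
        for x0 in starts:
            try:
                res = least_squares(residuals, x0, bounds=(lo, hi))
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if not res.success:
                failures.append(res.message)
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise CalibrationError(
                f"no start converged out of {self.n_starts}; messages: {failures[:3]}"
            )
        dd, dp, dh, r0 = best.x
        self.center_ = HansenTriplet(dd, dp, dh)
        self.radius_ = float(r0)
        self.reference_ = SoluteReference(self.center_, self.radius_)
        self.rms_residual_ = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        """RED values of new Hansen triplets against the calibrated solute."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float)
        c = self.center_.as_array()
        d = X - c
        ra = np.sqrt(4.0 * d[:, 0] ** 2 + d[:, 1] ** 2 + d[:, 2] ** 2)
        return ra / self.radius_


def calibrate_solute(
    triplets,
    target_reds,
    bounds=DEFAULT_BOUNDS,
    n_starts: int = 32,
    random_state: int = 0,
) -> tuple[SoluteReference, float]:
    """Invert printed RED values to a solute reference.

    ``triplets`` is a list of ``(name, HansenTriplet)`` pairs (names are
    carried for the caller's bookkeeping only).  Returns the calibrated
    :class:`SoluteReference` and the RMS RED residual.
    """
    X = np.stack([t.as_array() for _, t in triplets])
    cal = SoluteCalibrator(bounds=bounds, n_starts=n_starts, random_state=random_state)
    cal.fit(X, np.asarray(target_reds, dtype=float))
    return cal.reference_, cal.rms_residual_


def default_beeswax_reference() -> SoluteReference:
    """The shipped beeswax reference.

    Calibrated (not measured): it is the output of :func:`calibrate_solute`
    over the packaged screening panel of twelve solvent formulations and
    their reported RED values, stored as a fixture together with its RMS
    residual.
    """
    with resources.as_file(
        resources.files("deswax.data").joinpath("beeswax_reference_calibrated.csv")
    ) as p:
        row = pd.read_csv(p, comment="#").iloc[0]
    return SoluteReference(
        HansenTriplet(row["delta_d"], row["delta_p"], row["delta_h"]), row["R0"]
    )
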
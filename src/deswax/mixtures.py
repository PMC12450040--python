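"""Mixture Hansen parameters and Teas fractions for eutectic solvents.

A deep eutectic solvent is treated as an ideal mixture of its constituents:
each partial parameter of the mixture is the volume-fraction-weighted mean
of the pure-component parameters,

    delta_xM = sum_i s_i * phi_i * delta_x,i      (x in {d, p, h})

with phi_i = x_i v_i / sum_j x_j v_j (x_i mole fraction, v_i molar volume)
and optional per-component scaling factors s_i defaulting to 1.  Binary
mixtures are the common case but any number of components is accepted.

Teas fractions normalise a Hansen triplet to percentages summing to 100,
the coordinate system of the ternary solubility chart used in conservation
practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsp import ComponentSpec, GroupTable, HansenTriplet, component_hansen, molar_volume

__all__ = [
    "DESMixture",
    "TeasTriplet",
    "volume_fractions",
    "mixture_hansen",
    "teas_fractions",
    "teas_integers",
    "ternary_coordinates",
    "hansen_report",
]


@dataclass(frozen=True)
class DESMixture:
    """An n-component eutectic at a fixed molar ratio.

    ``ratio`` holds the molar proportions (e.g. ``(1, 2)`` for 1:2); only
    proportions matter, not absolute amounts.  ``scaling`` holds the
    dimensionless correction factors s_i, all 1 by default.
    """

    name: str
    components: tuple[ComponentSpec, ...]
    ratio: tuple[float, ...]
    scaling: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError(f"mixture {self.name!r}: needs at least one component")
        if len(self.ratio) != len(self.components):
            raise ValueError(
                f"mixture {self.name!r}: ratio length {len(self.ratio)} does not "
                f"match {len(self.components)} components"
            )
        if any(r <= 0 for r in self.ratio):
            raise ValueError(f"mixture {self.name!r}: molar ratio entries must be > 0")
        scaling = self.scaling
        if scaling is None:
            scaling = tuple(1.0 for _ in self.components)
        if len(scaling) != len(self.components) or any(s <= 0 for s in scaling):
            raise ValueError(f"mixture {self.name!r}: scaling factors must be > 0")
        object.__setattr__(self, "scaling", tuple(float(s) for s in scaling))
        object.__setattr__(self, "ratio", tuple(float(r) for r in self.ratio))

    @classmethod
    def binary(
        cls,
        name: str,
        component1: ComponentSpec,
        component2: ComponentSpec,
        n1: float,
        n2: float,
        s1: float = 1.0,
        s2: float = 1.0,
    ) -> "DESMixture":
        return cls(name, (component1, component2), (n1, n2), (s1, s2))


@dataclass(frozen=True)
class TeasTriplet:
    """Fractional (percent) contributions F_d, F_p, F_h; they sum to 100."""

    F_d: float
    F_p: float
    F_h: float

    def __post_init__(self) -> None:
        if any(not (0 <= v <= 100) for v in (self.F_d, self.F_p, self.F_h)):
            raise ValueError("Teas fractions must lie in [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.F_d, self.F_p, self.F_h], dtype=float)


def volume_fractions(mix: DESMixture) -> np.ndarray:
    """Volume fractions phi_i from molar ratio and molar volumes."""
    v = np.array([molar_volume(c) for c in mix.components])
    if np.any(v <= 0):
        raise ValueError(f"mixture {mix.name!r}: molar volumes must be > 0")
    x = np.asarray(mix.ratio) / sum(mix.ratio)
    xv = x * v
    return xv / xv.sum()


def mixture_hansen(mix: DESMixture, table: GroupTable) -> HansenTriplet:
    """phi-weighted (optionally s-scaled) mixture Hansen triplet."""
    phi = volume_fractions(mix)
    s = np.asarray(mix.scaling)
    triplets = np.stack([component_hansen(c, table).as_array() for c in mix.components])
    mixed = (s * phi) @ triplets
    return HansenTriplet(*map(float, mixed))


def teas_fractions(hsp: HansenTriplet) -> TeasTriplet:
    """Teas percentages F_x = 100 * delta_x / (delta_d + delta_p + delta_h).

    The unrounded fractions sum to exactly 100 by construction.
    """
    total = hsp.delta_d + hsp.delta_p + hsp.delta_h
    if total <= 0:
        raise ValueError("Teas fractions undefined for an all-zero Hansen triplet")
    return TeasTriplet(
        100.0 * hsp.delta_d / total,
        100.0 * hsp.delta_p / total,
        100.0 * hsp.delta_h / total,
    )


def teas_integers(
    teas: TeasTriplet, method: str = "nearest"
) -> tuple[int, int, int]:
    """Integer Teas triplet for reporting.

    ``method="nearest"`` rounds each axis independently (half away from
    zero), the convention of published Teas tables; the rounded triplet may
    sum to 99-101.  ``method="largest_remainder"`` apportions so the
    integers sum to exactly 100.
    """
    raw = teas.as_array()
    if method == "nearest":
        return tuple(int(math.floor(v + 0.5)) for v in raw)
    if method == "largest_remainder":
        floors = np.floor(raw).astype(int)
        short = 100 - int(floors.sum())
        # hand out the shortfall to the largest fractional remainders;
        # ties go to the earlier axis (d, then p, then h) for determinism
        order = np.argsort(-(raw - floors), kind="stable")
        for i in order[:short]:
            floors[i] += 1
        return tuple(int(v) for v in floors)
    raise ValueError(f"unknown rounding method {method!r}")


def ternary_coordinates(teas: TeasTriplet) -> tuple[float, float]:
    """Cartesian projection of a Teas triplet: x = F_p + F_h/2, y = sqrt(3)/2 * F_h."""
    return (teas.F_p + teas.F_h / 2.0, math.sqrt(3.0) / 2.0 * teas.F_h)


def hansen_report(
    mixtures, table: GroupTable, rounding: str = "nearest"
) -> pd.DataFrame:
    """Hansen + Teas table for a collection of mixtures.

    Columns: ``des_name, delta_d, delta_p, delta_h, F_d, F_p, F_h`` with
    Hansen values to one decimal and Teas fractions as integers, plus the
    ternary-chart coordinates ``x, y`` (full precision).  Rounding happens
    only here; pass the unrounded values around for further computation.
    """
    rows = []
    for mix in mixtures:
        hsp = mixture_hansen(mix, table)
        teas = teas_fractions(hsp)
        fd, fp, fh = teas_integers(teas, method=rounding)
        x, y = ternary_coordinates(teas)
        rows.append(
            {
                "des_name": mix.name,
                "delta_d": round(hsp.delta_d, 1),
                "delta_p": round(hsp.delta_p, 1),
                "delta_h": round(hsp.delta_h, 1),
                "F_d": fd,
                "F_p": fp,
                "F_h": fh,
                "x": x,
                "y": y,
            }
        )
    return pd.DataFrame(rows)
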
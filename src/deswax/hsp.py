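"""Hoftyzer–Van Krevelen group-contribution Hansen solubility parameters.

A molecule is described as a bag of functional groups, each contributing a
dispersive molar attraction constant ``F_d`` (MPa^0.5·cm^3·mol^-1), a polar
molar attraction constant ``F_p`` (same units) and a hydrogen-bonding
cohesion energy ``E_h`` (J·mol^-1).  The three partial solubility
parameters of a pure component with molar volume ``V`` (cm^3·mol^-1) are

    delta_d = (sum_i n_i F_d,i) / V
    delta_p = sqrt(sum_i n_i F_p,i^2) / V
    delta_h = sqrt((sum_i n_i E_h,i) / V)

all in MPa^0.5, where ``n_i`` is the multiplicity of group ``i``.  Note the
polar term sums the *squares* of the per-occurrence constants, so a group
appearing ``n`` times contributes ``n * F_p^2`` inside the square root.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroupContributionEntry",
    "GroupTable",
    "ComponentSpec",
    "HansenTriplet",
    "MissingGroupError",
    "ComponentConfigurationError",
    "molar_volume",
    "component_hansen",
    "load_group_table",
    "default_group_table",
]


class MissingGroupError(LookupError):
    """A component references functional groups absent from the group table."""


class ComponentConfigurationError(ValueError):
    """A component specification is internally inconsistent or incomplete."""


@dataclass(frozen=True)
class GroupContributionEntry:
    """Contribution constants for one functional group.

    Parameters
    ----------
    group_label : str
        Identifier, unique within a table (e.g. ``"CH2"``, ``"COOH"``).
    F_d : float
        Dispersive molar attraction constant, MPa^0.5·cm^3·mol^-1.
    F_p : float
        Polar molar attraction constant, MPa^0.5·cm^3·mol^-1.
    E_h : float
        Hydrogen-bonding energy, J·mol^-1.  Must be non-negative.
    """

    group_label: str
    F_d: float
    F_p: float
    E_h: float

    def __post_init__(self) -> None:
        if not self.group_label:
            raise ValueError("group_label must be a non-empty string")
        if self.E_h < 0:
            raise ValueError(
                f"group {self.group_label!r}: E_h must be >= 0, got {self.E_h}"
            )


class GroupTable(Mapping):
    """Immutable label -> :class:`GroupContributionEntry` lookup table."""

    def __init__(self, entries):
        table = {}
        for e in entries:
            if e.group_label in table:
                raise ValueError(f"duplicate group label {e.group_label!r}")
            table[e.group_label] = e
        self._table = table

    def __getitem__(self, label: str) -> GroupContributionEntry:
        return self._table[label]

    def __iter__(self):
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    @classmethod
    def from_csv(cls, path) -> "GroupTable":
        return load_group_table(path)


def load_group_table(path) -> GroupTable:
    """Read a group-contribution table from delimited text.

    Expected columns: ``group,F_d,F_p,E_h`` (header mandatory, UTF-8,
    dot decimal separator).
    """
    df = pd.read_csv(path, comment="#")
    required = {"group", "F_d", "F_p", "E_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"group table {path}: missing columns {sorted(missing)}")
    return GroupTable(
        GroupContributionEntry(str(r.group), float(r.F_d), float(r.F_p), float(r.E_h))
        for r in df.itertuples(index=False)
    )


def default_group_table() -> GroupTable:
    """The packaged Hoftyzer–Van Krevelen first-order group table."""
    with resources.as_file(
        resources.files("deswax.data").joinpath("hvk_groups.csv")
    ) as p:
        return load_group_table(p)


@dataclass(frozen=True)
class ComponentSpec:
    """A molecule as a bag of functional groups.

    At least one of ``density`` (g·cm^-3) or ``molar_volume`` (cm^3·mol^-1)
    must be given; an explicit molar volume takes precedence.
    """

    name: str
    groups: Mapping[str, int]
    molar_mass: float
    density: float | None = None
    molar_volume: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ComponentConfigurationError(
                f"component {self.name!r}: molar_mass must be > 0"
            )
        if self.density is not None and self.density <= 0:
            raise ComponentConfigurationError(
                f"component {self.name!r}: density must be > 0"
            )
        if self.molar_volume is not None and self.molar_volume <= 0:
            raise ComponentConfigurationError(
                f"component {self.name!r}: molar_volume must be > 0"
            )
        counts = dict(self.groups)
        if not counts or all(c == 0 for c in counts.values()):
            raise ComponentConfigurationError(
                f"component {self.name!r}: needs at least one group with count > 0"
            )
        for label, count in counts.items():
            if count < 0 or int(count) != count:
                raise ComponentConfigurationError(
                    f"component {self.name!r}: count for {label!r} must be a "
                    f"non-negative integer, got {count}"
                )
        object.__setattr__(self, "groups", counts)


@dataclass(frozen=True)
class HansenTriplet:
    """Partial solubility parameters (delta_d, delta_p, delta_h), MPa^0.5."""

    delta_d: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        vals = (self.delta_d, self.delta_p, self.delta_h)
        if not all(np.isfinite(vals)):
            raise ValueError(f"Hansen parameters must be finite, got {vals}")
        if any(v < 0 for v in vals):
            raise ValueError(f"Hansen parameters must be non-negative, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_d, self.delta_p, self.delta_h], dtype=float)

    @property
    def total(self) -> float:
        """Hildebrand-style total parameter sqrt(d^2 + p^2 + h^2)."""
        return float(np.sqrt(self.as_array() @ self.as_array()))


def molar_volume(component: ComponentSpec) -> float:
    """Molar volume in cm^3·mol^-1: stated value, else molar_mass/density."""
    if component.molar_volume is not None:
        return float(component.molar_volume)
    if component.density is not None:
        return float(component.molar_mass / component.density)
    raise ComponentConfigurationError(
        f"component {component.name!r}: neither density nor molar_volume given"
    )


def component_hansen(
    component: ComponentSpec, table: GroupTable | Mapping[str, GroupContributionEntry]
) -> HansenTriplet:
    """Hansen triplet of a pure component from its group decomposition.

    Raises
    ------
    MissingGroupError
        If any group label is absent from ``table`` (all offenders listed).
    """
    missing = sorted(g for g in component.groups if g not in table)
    if missing:
        raise MissingGroupError(
            f"component {component.name!r}: groups not in table: {missing}"
        )
    V = molar_volume(component)
    if V <= 0:
        raise ComponentConfigurationError(
            f"component {component.name!r}: molar volume must be > 0, got {V}"
        )
    sum_fd = 0.0
    sum_fp2 = 0.0
    sum_eh = 0.0
    for label, count in component.groups.items():
        entry = table[label]
        sum_fd += count * entry.F_d
        sum_fp2 += count * entry.F_p**2
        sum_eh += count * entry.E_h
    return HansenTriplet(
        delta_d=sum_fd / V,
        delta_p=float(np.sqrt(sum_fp2)) / V,
        delta_h=float(np.sqrt(sum_eh / V)),
    )
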
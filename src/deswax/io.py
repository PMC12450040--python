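"""Delimited-text readers and writers for the pipeline's table formats.

All tables are header-bearing UTF-8 CSV with dot decimal separators.
Component group decompositions live in a ``groups`` column of
``label:count`` pairs joined by ``;`` (e.g. ``CH3:1;CH2:10;COOH:1``) so the
assignments stay reviewable in plain text.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .hsp import ComponentSpec
from .kinetics import KineticSeries
from .mixtures import DESMixture

__all__ = [
    "parse_groups_field",
    "read_component_table",
    "read_mixture_table",
    "read_timeseries",
    "read_solute_reference",
    "packaged_path",
    "load_packaged_components",
    "load_packaged_mixtures",
    "load_reported_screen",
]


def parse_groups_field(text: str) -> dict[str, int]:
    """Parse ``"CH3:1;CH2:10;COOH:1"`` into a label -> count mapping."""
    groups: dict[str, int] = {}
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        label, _, count = token.partition(":")
        if not _:
            raise ValueError(f"malformed group token {token!r} (expected label:count)")
        groups[label.strip()] = groups.get(label.strip(), 0) + int(count)
    if not groups:
        raise ValueError(f"empty groups field: {text!r}")
    return groups


def read_component_table(path) -> dict[str, ComponentSpec]:
    """Columns: ``name,molar_mass,density,molar_volume,groups``.

    Empty density/molar_volume cells are allowed (at least one required).
    """
    df = pd.read_csv(path, comment="#")
    required = {"name", "molar_mass", "groups"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"component table {path}: missing columns {sorted(missing)}")
    components = {}
    for r in df.itertuples(index=False):
        density = getattr(r, "density", None)
        mv = getattr(r, "molar_volume", None)
        components[str(r.name)] = ComponentSpec(
            name=str(r.name),
            groups=parse_groups_field(r.groups),
            molar_mass=float(r.molar_mass),
            density=None if pd.isna(density) else float(density),
            molar_volume=None if pd.isna(mv) else float(mv),
        )
    return components


def read_mixture_table(path, components: dict[str, ComponentSpec]) -> list[DESMixture]:
    """Columns: ``des_name,component1,component2,n1,n2``."""
    df = pd.read_csv(path, comment="#")
    required = {"des_name", "component1", "component2", "n1", "n2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mixture table {path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"mixture table {path}: no rows")
    mixtures = []
    for r in df.itertuples(index=False):
        for comp in (r.component1, r.component2):
            if comp not in components:
                raise KeyError(
                    f"mixture {r.des_name!r}: component {comp!r} not in component table"
                )
        mixtures.append(
            DESMixture.binary(
                str(r.des_name),
                components[r.component1],
                components[r.component2],
                float(r.n1),
                float(r.n2),
            )
        )
    return mixtures


def read_timeseries(path) -> dict[tuple[str, int], KineticSeries]:
    """Columns: ``time_min,value,kind,replicate`` -> {(kind, replicate): series}."""
    df = pd.read_csv(path, comment="#")
    required = {"time_min", "value", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time series {path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"time series {path}: no rows")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    out = {}
    for (kind, rep), grp in df.groupby(["kind", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out[(str(kind), int(rep))] = KineticSeries(
            grp["time_min"].to_numpy(float), grp["value"].to_numpy(float), kind=str(kind)
        )
    return out


def average_replicates(series_map, kind: str) -> tuple[KineticSeries, np.ndarray]:
    """Mean series across replicates of one kind, plus per-time SD."""
    reps = [s for (k, _), s in sorted(series_map.items()) if k == kind]
    if not reps:
        raise ValueError(f"no series of kind {kind!r}")
    grid = reps[0].times
    for s in reps[1:]:
        if not np.array_equal(s.times, grid):
            raise ValueError(f"replicates of kind {kind!r} have mismatched time grids")
    stack = np.stack([s.values for s in reps])
    return (
        KineticSeries(grid, stack.mean(axis=0), kind=kind),
        stack.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(grid.size),
    )


def read_solute_reference(path):
    """Columns: ``delta_d,delta_p,delta_h,R0`` (single row)."""
    from .compatibility import SoluteReference
    from .hsp import HansenTriplet

    row = pd.read_csv(path, comment="#").iloc[0]
    return SoluteReference(
        HansenTriplet(float(row["delta_d"]), float(row["delta_p"]), float(row["delta_h"])),
        float(row["R0"]),
    )


def packaged_path(filename: str):
    """Context manager yielding a real path to a packaged data file."""
    return resources.as_file(resources.files("deswax.data").joinpath(filename))


def load_packaged_components() -> dict[str, ComponentSpec]:
    with packaged_path("components.csv") as p:
        return read_component_table(p)


def load_packaged_mixtures() -> list[DESMixture]:
    components = load_packaged_components()
    with packaged_path("mixtures.csv") as p:
        return read_mixture_table(p, components)


def load_reported_screen() -> pd.DataFrame:
    """Published Hansen/Teas parameters and screening RED values for the
    twelve solvent formulations, merged on ``des_name``."""
    with packaged_path("reported_hansen.csv") as p:
        hansen = pd.read_csv(p, comment="#")
    with packaged_path("reported_red.csv") as p:
        red = pd.read_csv(p, comment="#")
    return hansen.merge(red, on="des_name", validate="one_to_one")
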
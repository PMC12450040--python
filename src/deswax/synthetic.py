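"""Synthetic paired turbidimetric/gravimetric dispersion curves.

The generator emulates the measurement design of the dispersion experiments:
a mass channel following the Hill saturation law with additive, homoscedastic
Gaussian noise, and a turbidity channel obtained from the *noise-free* mass
through an affine map (default slope 280.26 NTU/g, intercept -209.14 NTU,
the reported turbidity–mass regression for the best-performing solvent)
plus its own Gaussian noise.  Negative model turbidity at small masses is
clamped to zero before noise is added — turbidity is physically
non-negative and the affine map is only meaningful over the observed mass
range.  Both channels are floored at zero after noise.

Three archetypes summarise the observed behaviours; their saturation levels
match the reported endpoint masses, while the half-saturation times are
free choices of this generator (the underlying fitted values were never
published) and must not be read as measured quantities:

=============  ===========  ==========  =======================
archetype      a (g)        b (min)     endpoint at 720 min
=============  ===========  ==========  =======================
high           5.0          80          4.50 g
moderate       1.72         130         1.457 g
negligible     0.02         100         0.0176 g
=============  ===========  ==========  =======================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import HillParams, KineticSeries, LinearMap, hill_eval

__all__ = ["ARCHETYPES", "DEFAULT_TURBIDITY_MAP", "SyntheticSpec", "generate", "write_dataset"]

ARCHETYPES: dict[str, HillParams] = {
    "high": HillParams(a=5.0, b=80.0, c=1.0),
    "moderate": HillParams(a=1.72, b=130.0, c=1.0),
    "negligible": HillParams(a=0.02, b=100.0, c=1.0),
}

DEFAULT_TURBIDITY_MAP = LinearMap(slope=280.26, intercept=-209.14, R2=1.0)

#: Sampling grid (min): the six protocol times plus t = 0 and t = 240.
DEFAULT_TIME_GRID = (0.0, 30.0, 60.0, 120.0, 240.0, 360.0, 480.0, 720.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dispersion experiment.

    ``archetype`` is one of ``"high"``, ``"moderate"``, ``"negligible"`` or
    an explicit :class:`~deswax.kinetics.HillParams`.  Noise standard
    deviations are per channel (g and NTU).  The same seed always yields
    bit-identical output.
    """

    archetype: str | HillParams = "high"
    noise_sd_mass: float = 0.1
    noise_sd_turbidity: float = 25.0
    turbidity_map: LinearMap = DEFAULT_TURBIDITY_MAP
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_mass < 0 or self.noise_sd_turbidity < 0:
            raise ValueError("noise standard deviations must be >= 0")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be strictly increasing from 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.archetype, str) and self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; "
                f"choose from {sorted(ARCHETYPES)} or pass HillParams"
            )

    @property
    def params(self) -> HillParams:
        if isinstance(self.archetype, HillParams):
            return self.archetype
        return ARCHETYPES[self.archetype]


def generate(spec: SyntheticSpec) -> list[tuple[KineticSeries, KineticSeries]]:
    """Generate ``spec.replicates`` pairs of (mass, turbidity) series."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.time_grid, dtype=float)
    mass_true = hill_eval(spec.params, t)
    turb_true = np.clip(spec.turbidity_map(mass_true), 0.0, None)
    out = []
    for _ in range(spec.replicates):
        mass = np.clip(mass_true + rng.normal(0.0, spec.noise_sd_mass, t.size), 0.0, None)
        turb = np.clip(turb_true + rng.normal(0.0, spec.noise_sd_turbidity, t.size), 0.0, None)
        out.append(
            (KineticSeries(t, mass, kind="mass"), KineticSeries(t, turb, kind="turbidity"))
        )
    return out


def write_dataset(spec: SyntheticSpec, outdir) -> tuple[Path, Path]:
    """Write the dataset in the long time-series format plus a manifest.

    The series file has columns ``time_min,value,kind,replicate``; the
    manifest records the full spec and seed for provenance.  Returns the
    two paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep, (mass, turb) in enumerate(generate(spec), start=1):
        for series in (mass, turb):
            for t, v in zip(series.times, series.values):
                rows.append(
                    {"time_min": t, "value": v, "kind": series.kind, "replicate": rep}
                )
    series_path = outdir / "timeseries.csv"
    pd.DataFrame(rows).to_csv(series_path, index=False)
    p = spec.params
    manifest = {
        "archetype": spec.archetype if isinstance(spec.archetype, str) else "custom",
        "hill_params": {"a": p.a, "b": p.b, "c": p.c},
        "noise_sd_mass": spec.noise_sd_mass,
        "noise_sd_turbidity": spec.noise_sd_turbidity,
        "turbidity_map": {
            "slope": spec.turbidity_map.slope,
            "intercept": spec.turbidity_map.intercept,
        },
        "time_grid": list(spec.time_grid),
        "replicates": spec.replicates,
        "seed": spec.seed,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return series_path, manifest_path
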
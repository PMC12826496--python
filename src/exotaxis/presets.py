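"""Preset reduced-scale scenarios mirroring the headline parameter sweeps.

Every preset resolves to explicit configs with the standard parameter set
(a = 10 um, nu = 350 molecules/min, v0 = 3.4 um/hr, D = 250 um^2/min,
tau = 5 min, K = 25 molecules, no degradation, dt_exo = 0.1 min,
dt_cell = 40 min, l0 = 10 um) except where the preset varies a parameter.
Run counts are reduced-scale defaults (hundreds of runs rather than the
thousands a publication-quality curve uses); pass ``n_runs`` to override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import ScenarioConfig

__all__ = ["Preset", "SweepSpec", "resolve_preset", "available_presets"]


@dataclass(frozen=True)
class SweepSpec:
    """One labelled sweep: a base config, the swept parameter, its grid."""

    label: str
    config: ScenarioConfig
    parameter: str
    values: tuple


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    sweeps: tuple[SweepSpec, ...] = field(default_factory=tuple)
    theory_grid: dict | None = None


_CARGO_GRID = (1, 5, 25, 125, 625)
_D_GRID = (0.0, 25.0, 50.0, 100.0, 150.0, 250.0, 500.0, 1000.0)


def _base(**overrides) -> ScenarioConfig:
    defaults = dict(n_runs=200, base_seed=0, total_time=1440.0)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def _cargo_preset(name: str, hill: float, description: str) -> Preset:
    sweeps = tuple(
        SweepSpec(
            label=f"T_deg={t_deg}",
            config=_base(hill=hill, mean_cargo=25.0, degradation_time=t_deg),
            parameter="mean_cargo",
            values=_CARGO_GRID,
        )
        for t_deg in (0.5, 5.0, 60.0)
    )
    return Preset(name=name, description=description, sweeps=sweeps)


def _build_presets() -> dict[str, Preset]:
    presets: dict[str, Preset] = {}

    presets["cargo_sweep_h1"] = _cargo_preset(
        "cargo_sweep_h1",
        hill=1.0,
        description="velocity vs mean cargo, H=1, degradation times 0.5/5/60 min",
    )
    presets["cargo_sweep_h3"] = _cargo_preset(
        "cargo_sweep_h3",
        hill=3.0,
        description="velocity vs mean cargo, H=3, degradation times 0.5/5/60 min",
    )
    presets["secretion_sweep"] = Preset(
        name="secretion_sweep",
        description="velocity vs molecular secretion rate nu (H=3, nbar=K=25)",
        sweeps=(
            SweepSpec(
                label="nu sweep",
                config=_base(hill=3.0, mean_cargo=25.0, n_runs=100),
                parameter="molecular_rate",
                values=(87.5, 175.0, 350.0, 700.0),
            ),
        ),
    )
    presets["memory_sweep"] = Preset(
        name="memory_sweep",
        description="velocity vs memory time tau (H=3, nbar=K=25)",
        sweeps=(
            SweepSpec(
                label="tau sweep",
                config=_base(hill=3.0, mean_cargo=25.0, n_runs=100),
                parameter="memory_time",
                values=(1.25, 2.5, 5.0, 10.0),
            ),
        ),
    )
    presets["diffusivity_sweep"] = Preset(
        name="diffusivity_sweep",
        description="velocity vs exosome diffusivity D (nbar=25, H=3, T=1 day)",
        sweeps=(
            SweepSpec(
                label="D sweep",
                config=_base(hill=3.0, mean_cargo=25.0, n_runs=100),
                parameter="diffusivity",
                values=_D_GRID,
            ),
        ),
    )
    presets["separation_sweep"] = Preset(
        name="separation_sweep",
        description="optimal D vs initial separation l0 (nbar=25, H=3)",
        sweeps=tuple(
            SweepSpec(
                label=f"l0={l0}",
                config=_base(
                    hill=3.0, mean_cargo=25.0, n_runs=100, initial_separation=l0
                ),
                parameter="diffusivity",
                values=_D_GRID,
            )
            for l0 in (10.0, 20.0, 40.0, 80.0)
        ),
    )
    presets["confined_diffusivity_sweep"] = Preset(
        name="confined_diffusivity_sweep",
        description="D sweep with reflective walls at y=+/-L (L in cell radii)",
        sweeps=tuple(
            SweepSpec(
                label=f"L={L}",
                config=_base(
                    hill=3.0, mean_cargo=25.0, n_runs=50, wall_half_width=L,
                    total_time=720.0,
                ),
                parameter="diffusivity",
                values=_D_GRID,
            )
            for L in (100.0, 200.0, 400.0)
        ),
    )
    presets["cargo_scaled_diffusivity"] = Preset(
        name="cargo_scaled_diffusivity",
        description="velocity vs cargo with constant vs cargo-scaled D "
        "(D0=300 um^2/min at nbar0=50)",
        sweeps=(
            SweepSpec(
                label="constant D",
                config=_base(hill=3.0, diffusivity=300.0),
                parameter="mean_cargo",
                values=_CARGO_GRID,
            ),
            SweepSpec(
                label="cargo-scaled D",
                config=_base(
                    hill=3.0,
                    diffusivity_mode="cargo_scaled",
                    D0=300.0,
                    mean_cargo_ref=50.0,
                ),
                parameter="mean_cargo",
                values=_CARGO_GRID,
            ),
        ),
    )
    presets["theory_grid"] = Preset(
        name="theory_grid",
        description="closed-form 1D velocity grids: v/v0 over x for "
        "H in {1,2,3,5} and beta in {0.02,0.05,0.1,0.2}",
        theory_grid={
            "x": tuple(float(x) for x in _logspace(0.05, 20.0, 41)),
            "beta": (0.02, 0.05, 0.1, 0.2),
            "hill": (1.0, 2.0, 3.0, 5.0),
        },
    )
    return presets


def _logspace(lo: float, hi: float, n: int) -> list[float]:
    step = (math.log(hi) - math.log(lo)) / (n - 1)
    return [math.exp(math.log(lo) + i * step) for i in range(n)]


_PRESETS = _build_presets()


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def resolve_preset(name: str, n_runs: int | None = None, base_seed: int | None = None) -> Preset:
    """Return a fully resolved preset; unknown names list the alternatives."""
    try:
        preset = _PRESETS[name]
    except KeyError as exc:
        raise ValueError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from exc
    if n_runs is None and base_seed is None:
        return preset
    updates = {}
    if n_runs is not None:
        updates["n_runs"] = n_runs
    if base_seed is not None:
        updates["base_seed"] = base_seed
    sweeps = tuple(
        SweepSpec(
            label=s.label,
            config=ScenarioConfig.model_validate(
                {**s.config.model_dump(), **updates}
            ),
            parameter=s.parameter,
            values=s.values,
        )
        for s in preset.sweeps
    )
    return Preset(
        name=preset.name,
        description=preset.description,
        sweeps=sweeps,
        theory_grid=preset.theory_grid,
    )
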
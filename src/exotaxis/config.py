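"""Scenario configuration: one validated record for a full simulation.

All internal arithmetic is in micrometres and minutes; the leader/follower
speed v0 is stored in um/min (the literature often quotes um/hr; convert
with :func:`exotaxis.physics.convert_speed`).  ``ScenarioConfig`` is a
pydantic model, so a JSON schema for scenario files is published via
``ScenarioConfig.json_schema()`` and configs round-trip through JSON
(infinite degradation time is encoded as ``null``).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .field import FieldParams, SecretionParams
from .memory import ResponseParams

__all__ = ["ScenarioConfig"]


class ScenarioConfig(BaseModel):
    """Full parameter set of one leader-follower scenario."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    # geometry and motion
    capture_radius: float = Field(10.0, gt=0, description="capture radius a, um")
    v0: float = Field(3.4 / 60.0, gt=0, description="leader/follower speed, um/min")
    initial_separation: float = Field(10.0, gt=0, description="l0, um")
    wall_half_width: Optional[float] = Field(
        None, description="half-width L of reflective slab, um (None = open)"
    )
    # secretion
    molecular_rate: float = Field(
        350.0, ge=0, description="nu, molecules/min (0 = silent leader)"
    )
    mean_cargo: float = Field(50.0, gt=0, description="nbar, molecules/exosome")
    # transport
    diffusivity: float = Field(250.0, ge=0, description="D, um^2/min")
    degradation_time: Optional[float] = Field(
        None, description="T, min (None = no degradation)"
    )
    diffusivity_mode: Literal["constant", "cargo_scaled"] = "constant"
    D0: float = Field(300.0, gt=0, description="reference D for cargo_scaled mode")
    mean_cargo_ref: float = Field(
        50.0, gt=0, description="reference cargo nbar0 for cargo_scaled mode"
    )
    per_exosome_diffusivity: bool = Field(
        False,
        description="scale D per exosome with its realized cargo (variant; the "
        "default applies the cargo-scaled D at the scenario level via nbar)",
    )
    # response
    threshold: float = Field(25.0, gt=0, description="K, molecules")
    hill: float = Field(3.0, ge=1, description="Hill coefficient H")
    memory_time: float = Field(5.0, gt=0, description="tau, min")
    # discretization
    dt_exo: float = Field(0.1, gt=0, description="exosome substep, min")
    dt_cell: float = Field(40.0, gt=0, description="cell step, min")
    total_time: float = Field(1440.0, gt=0, description="T_total, min")
    # ensemble
    n_runs: int = Field(100, ge=1)
    base_seed: int = Field(0, ge=0)
    # efficiency switches (must stay off for headline runs)
    drop_zero_cargo: bool = False
    cull_distance: Optional[float] = Field(
        None, description="drop exosomes beyond this distance from the follower"
    )

    @field_validator("degradation_time")
    @classmethod
    def _degradation_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not math.isinf(v) and v <= 0:
            raise ValueError("degradation time must be positive, inf or None")
        if v is not None and math.isinf(v):
            return None
        return v

    @model_validator(mode="after")
    def _check_consistency(self) -> "ScenarioConfig":
        ratio = self.dt_cell / self.dt_exo
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError("dt_exo must divide dt_cell evenly")
        if self.dt_cell > self.total_time:
            raise ValueError("dt_cell must not exceed total_time")
        n_win = self.total_time / self.dt_cell
        if abs(n_win - round(n_win)) > 1e-9 * n_win:
            raise ValueError("dt_cell must divide total_time evenly")
        if self.degradation_time is not None and self.dt_exo >= self.degradation_time:
            raise ValueError("dt_exo must be smaller than the degradation time")
        if (
            self.wall_half_width is not None
            and self.wall_half_width <= self.capture_radius
        ):
            raise ValueError("wall half-width L must exceed the capture radius a")
        D = self.effective_diffusivity()
        if D > 0 and self.dt_exo > self.capture_radius**2 / D:
            warnings.warn(
                "dt_exo exceeds a^2/D: detection may be undercounted at this "
                "step size",
                stacklevel=2,
            )
        if self.dt_cell > self.capture_radius / self.v0:
            warnings.warn(
                "dt_cell exceeds a/v0: the follower moves more than a capture "
                "radius per cell step",
                stacklevel=2,
            )
        return self

    # -- derived quantities -------------------------------------------------

    def effective_diffusivity(self) -> float:
        """Scenario-level D, honouring the cargo-scaled mode."""
        if self.diffusivity_mode == "cargo_scaled":
            return self.D0 * (self.mean_cargo_ref / self.mean_cargo) ** (1.0 / 3.0)
        return self.diffusivity

    @property
    def substeps_per_cell_step(self) -> int:
        return round(self.dt_cell / self.dt_exo)

    @property
    def n_cell_steps(self) -> int:
        return round(self.total_time / self.dt_cell)

    @property
    def degradation_time_or_inf(self) -> float:
        return math.inf if self.degradation_time is None else self.degradation_time

    # -- parameter-group views ----------------------------------------------

    def field_params(self) -> FieldParams:
        return FieldParams(
            diffusivity=self.effective_diffusivity(),
            degradation_time=self.degradation_time_or_inf,
            dt_exo=self.dt_exo,
            wall_half_width=self.wall_half_width,
            capture_radius=self.capture_radius,
        )

    def secretion_params(self) -> SecretionParams:
        return SecretionParams(
            molecular_rate=self.molecular_rate, mean_cargo=self.mean_cargo
        )

    def response_params(self) -> ResponseParams:
        return ResponseParams(
            threshold=self.threshold, hill=self.hill, memory_time=self.memory_time
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        return cls.model_validate(json.loads(text))

    @classmethod
    def json_schema(cls) -> dict[str, Any]:
        return cls.model_json_schema()

    def config_hash(self) -> str:
        """Stable sha256 of the resolved configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()
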
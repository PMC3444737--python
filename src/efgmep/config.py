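"""Structured run configuration: YAML-backed, schema-validated.

A :class:`RunConfig` fully describes one simulation: geometry source, model
choice with its parameters, MLS settings, quadrature, integrator, stimulus
and outputs. Validation is strict — unknown keys are rejected, each error
names the offending key — and defaults are the packaged parameter sets of the
two membrane models.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from efgmep.errors import InvalidArgumentError

__all__ = ["RunConfig", "load_config", "save_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_StrictModel):
    generator: Optional[Literal["regular_grid", "irregular_cloud", "ventricle_shell"]] = None
    node_file: Optional[str] = None
    bounds: Optional[list[list[float]]] = None          # per-axis [lo, hi], mm
    counts: Optional[list[int]] = None                  # regular grid
    n: Optional[int] = None                             # irregular / shell
    min_spacing: Optional[float] = None                 # mm
    epi_semi_axes: Optional[list[float]] = None
    endo_semi_axes: Optional[list[float]] = None
    base_height: Optional[float] = None
    helix_angle_range: Optional[list[float]] = None     # degrees endo -> epi
    fiber_direction: Optional[list[float]] = None       # uniform fibers


class MLSConfig(_StrictModel):
    d_max: float = 2.0
    weight_kind: Literal["cubic", "quartic"] = "cubic"
    basis: Literal["linear", "quadratic"] = "linear"

    @field_validator("d_max")
    @classmethod
    def _d_max_positive(cls, v):
        if v <= 0:
            raise ValueError("d_max must be > 0")
        return v


class QuadratureConfig(_StrictModel):
    cells_per_axis: Optional[list[int]] = None
    points_per_axis: int = 2

    @field_validator("points_per_axis")
    @classmethod
    def _order(cls, v):
        if v not in (1, 2, 3, 4):
            raise ValueError("points_per_axis must be in {1, 2, 3, 4}")
        return v


class DiffusionConfig(_StrictModel):
    sigma_f: float = 4.0
    sigma_cf: float = 1.0
    isotropic: bool = False


class CubicModelConfig(_StrictModel):
    g: float = 0.004            # mS/mm^2
    v_th: float = 10.0          # mV deviation from rest
    v_p: float = 100.0          # mV deviation from rest
    C_m: float = 0.01           # uF/mm^2
    A_m: float = 200.0          # 1/mm
    v_rest: float = -85.0       # mV absolute


class FHNModelConfig(_StrictModel):
    a: float = 0.13
    b: float = 0.013
    c1: float = 0.26
    c2: float = 0.1
    d: float = 1.0


class IntegratorConfig(_StrictModel):
    method: Literal["euler", "rk4_adaptive"] = "rk4_adaptive"
    t_end: float = 400.0        # ms
    n_steps: Optional[int] = None
    rtol: float = 1e-5
    atol: float = 1e-7
    lumped_mass: bool = False


class StimulusConfig(_StrictModel):
    mode: Literal["initial_value", "current"] = "initial_value"
    amplitude: float = 0.5
    onset: float = 0.0
    duration: float = 0.0
    node_indices: Optional[list[int]] = None
    face_axis: Optional[int] = 0       # stimulate one box face if no indices
    face_depth: Optional[float] = None


class OutputConfig(_StrictModel):
    directory: str = "out"
    snapshot_times: Optional[list[float]] = None
    write_vtk: bool = True
    write_activation_csv: bool = True


class RunConfig(_StrictModel):
    model: Literal["heat", "cubic_cable", "fhn"] = "fhn"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    diffusion: DiffusionConfig = Field(default_factory=DiffusionConfig)
    cubic: CubicModelConfig = Field(default_factory=CubicModelConfig)
    fhn: FHNModelConfig = Field(default_factory=FHNModelConfig)
    mls: MLSConfig = Field(default_factory=MLSConfig)
    quadrature: QuadratureConfig = Field(default_factory=QuadratureConfig)
    integrator: IntegratorConfig = Field(default_factory=IntegratorConfig)
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries the key path
        raise InvalidArgumentError(f"invalid configuration {path}: {exc}") from exc


def save_config(cfg: RunConfig, path):
    """Write a configuration back to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
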
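"""Run configuration: one validated schema drives every pipeline stage."""

from __future__ import annotations

import pathlib

import yaml
from pydantic import BaseModel, Field, field_validator

from . import beam, image, mechanostat, synthetic


class GeometryConfig(BaseModel):
    outer_base_radius: float = 600.0
    inner_base_radius: float = 400.0
    ridge_amplitude: float = 90.0
    pixel_size: float = image.DEFAULT_PIXEL_SIZE_UM

    def build(self) -> synthetic.GeometrySpec:
        return synthetic.GeometrySpec(
            outer_base_radius=self.outer_base_radius,
            inner_base_radius=self.inner_base_radius,
            ridge_amplitude=self.ridge_amplitude,
            pixel_size=self.pixel_size,
        )


class ScheduleConfig(BaseModel):
    sn_lead_days: int = 5
    loading_days: int = 14
    sn_tail_days: int = 2
    dt: float = 1.0

    def build(self) -> mechanostat.SimulationSchedule:
        return mechanostat.SimulationSchedule(
            sn_lead_days=self.sn_lead_days,
            loading_days=self.loading_days,
            sn_tail_days=self.sn_tail_days,
            dt=self.dt,
        )


class MechanostatConfig(BaseModel):
    model_id: str = "M4"
    eps_hom_p: float = mechanostat.EPS_HOM_PERIOSTEAL
    eps_hom_e: float = mechanostat.EPS_HOM_ENDOSTEAL
    k_pt: float = 2.148
    k_pc: float = 0.981
    k_et: float = 7.055
    k_ec: float = 0.794
    k_sn: float = mechanostat.K_SN_DEFAULT

    def build(self) -> mechanostat.MechanostatParams:
        return mechanostat.MechanostatParams(
            model_id=self.model_id,
            eps_hom_p=self.eps_hom_p,
            eps_hom_e=self.eps_hom_e,
            k_pt=self.k_pt,
            k_pc=self.k_pc,
            k_et=self.k_et,
            k_ec=self.k_ec,
            k_sn=self.k_sn,
        )


class CohortConfig(BaseModel):
    n_mice: int = Field(default=6, ge=2)
    load_levels: list[float] = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
    shape_jitter_sd: float = Field(default=20.0, ge=0)
    contour_noise_sd: float = Field(default=3.0, ge=0)
    rotation_jitter_sd: float = Field(default=2.0, ge=0)


class RunConfig(BaseModel):
    """Top-level configuration; CLI flags override individual keys."""

    seed: int = 0
    n_points: int = Field(default=500, ge=8)
    surface_band_um: float = 9.56
    thickness_band_um: float = 19.12
    load_n: float = 10.0
    load_point: tuple[float, float] = synthetic.DEFAULT_LOAD_POINT_UM
    budget: bool = False
    log_level: str = "INFO"
    geometry: GeometryConfig = GeometryConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    mechanostat: MechanostatConfig = MechanostatConfig()
    cohort: CohortConfig = CohortConfig()

    @field_validator("log_level")
    @classmethod
    def _check_level(cls, v: str) -> str:
        if v.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {v!r}")
        return v.upper()

    def load_case(self) -> beam.LoadCase:
        return beam.LoadCase(F=self.load_n, p_F=tuple(self.load_point))

    def cohort_spec(self) -> synthetic.CohortSpec:
        return synthetic.CohortSpec(
            n_mice=self.cohort.n_mice,
            load_levels=tuple(self.cohort.load_levels),
            shape_jitter_sd=self.cohort.shape_jitter_sd,
            contour_noise_sd=self.cohort.contour_noise_sd,
            rotation_jitter_sd=self.cohort.rotation_jitter_sd,
            seed=self.seed,
            truth_params=self.mechanostat.build(),
            schedule=self.schedule.build(),
            geometry=self.geometry.build(),
            load_point=tuple(self.load_point),
            n_points=self.n_points,
        )


def load_config(path: str | pathlib.Path | None, **overrides) -> RunConfig:
    """Read a YAML/JSON config file and apply keyword overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | pathlib.Path) -> None:
    """Write the resolved configuration beside a run's outputs."""
    pathlib.Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json")))
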
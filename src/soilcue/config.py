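"""Pipeline configuration: TOML file -> validated pydantic models.

Unknown keys are rejected so typos fail loudly.  Every random stage draws
from the single top-level ``seed``.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .design import DesignConfig
from .simulate import SimulationParams

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignSection(_Strict):
    """Per-cell replicate counts; keys are "warming,co2" strings."""

    analysed: dict[str, int] | None = None
    drought: dict[str, int] | None = None
    unused: dict[str, int] | None = None

    @staticmethod
    def _parse_cell(key: str) -> tuple[float, float]:
        w, c = key.split(",")
        return (float(w), float(c))

    def to_design_config(self) -> DesignConfig:
        cfg = DesignConfig()
        if self.analysed is not None:
            cfg.analysed = {self._parse_cell(k): v for k, v in self.analysed.items()}
        if self.drought is not None:
            cfg.drought = {self._parse_cell(k): v for k, v in self.drought.items()}
        if self.unused is not None:
            cfg.unused = {self._parse_cell(k): v for k, v in self.unused.items()}
        cfg.validate()
        return cfg


class SimulationSection(_Strict):
    sigma_may: float = 0.45
    sigma_july: float = 0.12
    sigma_october: float = 0.10
    rho: float = 0.3
    irms_at_sd: float = 0.005
    gc_rel_sd: float = 0.01
    eoc_rel_sd: float = 0.05
    dna_rel_sd: float = 0.05

    def to_params(self, seed: int) -> SimulationParams:
        return SimulationParams(
            sigma={"May": self.sigma_may, "July": self.sigma_july,
                   "October": self.sigma_october},
            rho=self.rho,
            irms_at_sd=self.irms_at_sd,
            gc_rel_sd=self.gc_rel_sd,
            eoc_rel_sd=self.eoc_rel_sd,
            dna_rel_sd=self.dna_rel_sd,
            seed=seed,
        )


class QcSection(_Strict):
    #: Exclude QC-flagged rows from the statistical fits.
    drop_flagged: bool = True


class StatsSection(_Strict):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    #: Predictor coding: design units {-1,0,1} or raw physical offsets.
    coding: str = "design_units"
    anova_log: bool = True
    correlation_candidates: list[str] = ["none", "CS", "AR1"]

    @field_validator("coding")
    @classmethod
    def _check_coding(cls, v: str) -> str:
        if v not in ("design_units", "physical_units"):
            raise ValueError("coding must be 'design_units' or 'physical_units'")
        return v


class PipelineConfig(_Strict):
    seed: int = 0
    design: DesignSection = DesignSection()
    simulation: SimulationSection = SimulationSection()
    qc: QcSection = QcSection()
    stats: StatsSection = StatsSection()


def load_config(path: str | Path | None = None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = tomllib.loads(Path(path).read_text())
    return PipelineConfig(**data)
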
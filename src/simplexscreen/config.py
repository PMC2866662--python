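"""Screen configuration: every protocol constant in one validated object.

Each field's default is either a constant of the published protocol (marked
``protocol``) or a package default filling a gap the protocol leaves open
(marked ``default``); the provenance tag is carried in the field description
so that config echoes are self-documenting.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ScreenConfig(BaseModel):
    """Constants of the oxygen-tolerance screening protocol.

    The defaults describe the operating point of the screen: genes deposited
    at a Poisson mean of 2.3 molecules/well, hydrogenase deactivated with
    15 µL of air-equilibrated buffer (~0.25 mM dissolved O2), activity read
    as the A578 slope of a 2 mM methyl viologen solution over two minutes,
    post-exposure assays using 5x the CFPS product of pre-exposure assays,
    and hits called two standard deviations above the wild-type mean.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    lambda_: float = Field(
        2.3, alias="lambda", gt=0,
        description="[protocol] mean template molecules per well")
    sd_multiplier: float = Field(
        2.0, gt=0, description="[protocol] hit threshold in wild-type SDs above the mean")
    volume_factor_post_over_pre: float = Field(
        5.0, gt=0,
        description="[protocol] CFPS volume assayed post-exposure / pre-exposure")
    min_pre_activity_fraction_of_wt: float = Field(
        0.25, ge=0,
        description="[default] QC cutoff as a fraction of plate wild-type mean pre-activity")
    exposure_volume_ul: float = Field(
        15.0, ge=0, description="[protocol] air-equilibrated buffer volume, µL")
    target_residual_low: float = Field(
        0.15, gt=0, lt=1, description="[protocol] lower edge of residual-activity target band")
    target_residual_high: float = Field(
        0.20, gt=0, lt=1, description="[protocol] upper edge of residual-activity target band")
    conversion_coefficient: float = Field(
        9.78, gt=0,
        description="[protocol] methyl viologen A578 conversion, AU per mM reduced MV")
    mv_concentration_mM: float = Field(
        2.0, gt=0, description="[protocol] methyl viologen concentration, mM")
    o2_concentration_mM: float = Field(
        0.25, gt=0, description="[protocol] dissolved O2 in air-equilibrated buffer, mM")
    assay_volume_ul: float = Field(
        200.0, gt=0, description="[protocol] methyl viologen assay volume, µL")
    electrons_per_h2: int = Field(
        2, gt=0, description="[protocol] single-electron MV reductions per H2")
    decay_rate_per_ul: float = Field(
        0.12, gt=0,
        description="[default] exponential deactivation constant k, per µL exposure buffer")
    cv: float = Field(
        0.20, ge=0,
        description="[protocol band] wild-type replicate CV of the tolerance score")
    wt_specific_activity: float = Field(
        150.0, gt=0, description="[protocol] wild-type specific activity, pmol H2/min/ng")
    wt_cfps_yield_ng_per_ul: float = Field(
        40.0, gt=0, description="[protocol] CFPS hydrogenase synthesis yield, ng/µL")
    pre_cfps_volume_ul: float = Field(
        1.0, gt=0, description="[protocol] CFPS product assayed pre-exposure, µL")
    seed: int = Field(0, ge=0, description="[default] base seed for all randomness")

    @model_validator(mode="after")
    def _band_ordered(self) -> "ScreenConfig":
        if self.target_residual_low > self.target_residual_high:
            raise ValueError("target residual band is inverted")
        return self

    @property
    def post_cfps_volume_ul(self) -> float:
        return self.pre_cfps_volume_ul * self.volume_factor_post_over_pre

    @property
    def wt_activity_per_ul(self) -> float:
        """Wild-type activity per µL CFPS product, pmol H2/min/µL."""
        return self.wt_specific_activity * self.wt_cfps_yield_ng_per_ul


class RunConfig(BaseModel):
    """A full pipeline run: screen constants plus geometry, paths and seeds."""

    model_config = ConfigDict(extra="forbid")

    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    plate_size: int = Field(96, description="wells per plate, 96 or 384")
    n_plates: int = Field(1, gt=0)
    n_mutants: int = Field(1000, gt=0)
    n_wildtype_controls: int = Field(8, gt=0)
    n_no_template_controls: int = Field(2, ge=0)
    n_cat_controls: int = Field(2, ge=0)
    out_dir: str = "screen_run"

    @model_validator(mode="after")
    def _plate_ok(self) -> "RunConfig":
        if self.plate_size not in (96, 384):
            raise ValueError("plate_size must be 96 or 384")
        n_ctrl = (self.n_wildtype_controls + self.n_no_template_controls
                  + self.n_cat_controls)
        if n_ctrl >= self.plate_size:
            raise ValueError("controls fill the whole plate")
        return self


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw: Any = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config_json(cfg: BaseModel) -> str:
    return cfg.model_dump_json(indent=2, by_alias=True)
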
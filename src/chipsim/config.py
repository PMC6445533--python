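"""Validated simulation configuration with field defaults.

Every parameter of the read-count simulation lives in one record.  The
defaults describe the reference experiment: n = 1000 loci, energies from a
truncated power law (alpha = 0.5, E_max = 10 kBT), chemical potential
mu = 3 kBT, unbound energy eps_u = 1.59 kBT, background energy
eps_bg = 1 kBT, C = 1e5 ChIP cells (input uses 10%), extraction efficiency
~ TruncNormal(0.5, 0.05) on [0, 1], amplification ratio A = 1000 over
n_cy = 15 PCR cycles, sequencing depth c = 100.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .energy import (
    BindingConfig,
    TruncatedPowerLaw,
    false_positive_params,
    solve_fp_scaling,
)

__all__ = ["SimulationConfig", "load_config"]


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # genome-wide binding model
    n_loci: int = Field(1000, ge=1)
    mu: float = 3.0
    eps_u: float = 1.59
    eps_bg: float = 1.0
    energy_alpha: float = 0.5
    energy_max: float = 10.0
    energies: Optional[Sequence[float]] = None  # overrides the energy law

    # binding mode
    binding_mode: Literal["direct", "indirect", "cooperative", "false_positive"] = "direct"
    indirect_fraction: float = Field(0.0, ge=0.0, le=1.0)
    cooperative_fraction: float = Field(0.0, ge=0.0, le=1.0)
    delta: float = 0.0  # interaction energy, kBT; negative = cooperative
    mu_b: float = 3.0
    b_energy_alpha: float = 0.5
    b_energy_max: float = 10.0

    # false-positive scenario: law given directly, via the mean-scaling
    # factor f, or via a target mean-occupancy ratio (solved by quadrature)
    n_false_loci: int = Field(1000, ge=0)
    fp_f: Optional[float] = None
    fp_alpha: Optional[float] = None
    fp_e_max: Optional[float] = None
    fp_mean_occupancy_ratio: Optional[float] = None

    # chromatin accessibility (None = chromatin ignored)
    accessibility_beta: Optional[float] = None
    accessibility_density: Optional[Sequence[float]] = None
    density_scale: float = 1.0

    # cells and extraction
    n_cells: int = Field(100_000, ge=1)
    input_cell_fraction: float = Field(0.1, gt=0.0, le=1.0)
    extraction_dist: Literal["truncnorm", "powerlaw"] = "truncnorm"
    extraction_mean: float = Field(0.5, gt=0.0, le=1.0)
    extraction_sd: Optional[float] = 0.05
    extraction_cv: Optional[float] = None  # overrides extraction_sd if set
    extraction_alpha: Optional[float] = None  # for the power-law option

    # PCR
    n_cycles: int = Field(15, ge=0, le=15)
    amplification_ratio: Optional[float] = 1000.0
    p_amp: Optional[float] = None
    amplification_cv: float = Field(0.0, ge=0.0)
    pcr_grid: bool = True

    # sequencing
    depth: int = Field(100, ge=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check_cross_fields(self) -> "SimulationConfig":
        if self.p_amp is not None and "amplification_ratio" in self.model_fields_set:
            raise ValueError("specify amplification_ratio or p_amp, not both")
        if self.p_amp is not None and not 0 < self.p_amp < 1:
            raise ValueError("p_amp must be in (0, 1)")
        if self.p_amp is None and self.amplification_ratio is None:
            raise ValueError("one of amplification_ratio or p_amp is required")
        n_fp_opts = sum(
            x is not None
            for x in (self.fp_f, self.fp_alpha, self.fp_mean_occupancy_ratio)
        )
        if n_fp_opts > 1:
            raise ValueError(
                "specify at most one of fp_f, fp_alpha(+fp_e_max), fp_mean_occupancy_ratio"
            )
        if (self.fp_alpha is None) != (self.fp_e_max is None):
            raise ValueError("fp_alpha and fp_e_max must be given together")
        return self

    # ------------------------------------------------------------------
    def binding_config(self) -> BindingConfig:
        return BindingConfig(mu=self.mu, eps_u=self.eps_u)

    def energy_law(self) -> TruncatedPowerLaw:
        return TruncatedPowerLaw(self.energy_alpha, self.energy_max)

    def mean_amplification_ratio(self) -> float:
        if self.p_amp is not None:
            return (1.0 + self.p_amp) ** self.n_cycles
        return float(self.amplification_ratio)

    def extraction_law(self):
        from .protocol import TruncatedNormalLaw

        if self.extraction_dist == "powerlaw":
            # power law on [0, 1]; alpha either given or implied by the mean
            alpha = (
                self.extraction_alpha
                if self.extraction_alpha is not None
                else 2.0 - 1.0 / self.extraction_mean
            )
            return TruncatedPowerLaw(alpha, 1.0)
        sd = (
            self.extraction_cv * self.extraction_mean
            if self.extraction_cv is not None
            else (self.extraction_sd if self.extraction_sd is not None else 0.05)
        )
        return TruncatedNormalLaw(self.extraction_mean, sd, 0.0, 1.0)

    def amplification_law(self):
        from .protocol import TruncatedNormalLaw

        mean_a = self.mean_amplification_ratio()
        sd = self.amplification_cv * mean_a
        return TruncatedNormalLaw(mean_a, sd, 1.0, float(2**self.n_cycles))

    def false_positive_law(self) -> TruncatedPowerLaw:
        if self.fp_alpha is not None:
            return TruncatedPowerLaw(self.fp_alpha, self.fp_e_max)
        if self.fp_mean_occupancy_ratio is not None:
            fp = solve_fp_scaling(
                self.fp_mean_occupancy_ratio, self.energy_law(), self.binding_config()
            )
            return fp.law
        from .energy import F_FALSE_POSITIVE_DEFAULT

        f = self.fp_f if self.fp_f is not None else F_FALSE_POSITIVE_DEFAULT
        return false_positive_params(self.energy_alpha, self.energy_max, f).law


def load_config(source=None, **overrides) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file, a mapping, and/or kwargs.

    Unknown keys are rejected; all validation errors are reported together.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {source} must contain a mapping")
            data.update(loaded)
        elif isinstance(source, dict):
            data.update(source)
        else:
            raise TypeError("source must be a path or a mapping")
    data.update(overrides)
    return SimulationConfig.model_validate(data)
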
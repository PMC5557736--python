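"""Experiment configuration types.

Units follow bench conventions for conventional Ussing chambers: volumes in
mL, areas in cm² (tissue) or mm² (morphometry), concentrations in μmol·L⁻¹,
times in minutes at the interface.  All conversions to coherent units happen
inside the computational routines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Raised when a chamber/geometry configuration violates its invariants."""


@dataclass(frozen=True)
class ChamberConfig:
    """Geometry and sampling protocol of a single Ussing-chamber flux run.

    Defaults encode a conventional chamber run with a 100 μmol·L⁻¹ apical
    fluorescein dose on 0.95 cm² of exposed tissue, basolateral samples at
    t = 0 (post-preincubation baseline), 30, and 60 min, with the withdrawn
    volume replaced by fresh buffer.

    Parameters
    ----------
    chamber_volume : float
        Volume of one half-chamber (mL).
    exposed_area : float
        Exposed tissue area (cm²).
    apical_concentration : float
        Tracer dose held on the apical side (μmol·L⁻¹).
    sample_volume : float
        Volume withdrawn per basolateral sample and replaced by buffer (mL).
    sampling_interval : float
        Time between basolateral samples (min).
    preincubation : float
        Equilibration time before t = 0 (min); metadata only.
    n_samples : int
        Number of basolateral samples, including the t = 0 baseline.
    """

    chamber_volume: float = 10.0
    exposed_area: float = 0.95
    apical_concentration: float = 100.0
    sample_volume: float = 0.5
    sampling_interval: float = 30.0
    preincubation: float = 45.0
    n_samples: int = 3

    def __post_init__(self) -> None:
        for name in ("chamber_volume", "exposed_area", "apical_concentration",
                     "sampling_interval"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.sample_volume < 0:
            raise ConfigurationError("sample_volume must be non-negative")
        if self.preincubation < 0:
            raise ConfigurationError("preincubation must be non-negative")
        if self.sample_volume >= self.chamber_volume:
            raise ConfigurationError(
                f"sample_volume ({self.sample_volume} mL) must be smaller than "
                f"chamber_volume ({self.chamber_volume} mL)")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth and numerics for a simulated chamber run.

    Parameters
    ----------
    true_papp : float
        Ground-truth apparent permeability (cm·s⁻¹).
    noise_sd : float
        SD of additive Gaussian plate-reader noise on each measured
        concentration (μmol·L⁻¹); noisy readings are truncated at 0.
    dt_internal : float
        Explicit integration step (s); must be at most 1/100 of the
        sampling interval.
    seed : int
        Seed of the per-run random stream.
    """

    true_papp: float
    noise_sd: float = 0.0
    dt_internal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_papp < 0:
            raise ConfigurationError("true_papp must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not self.dt_internal > 0:
            raise ConfigurationError("dt_internal must be strictly positive")

    def validate_against(self, config: ChamberConfig) -> None:
        """Check the integration step against the sampling interval."""
        if self.dt_internal > config.sampling_interval * 60.0 / 100.0:
            raise ConfigurationError(
                f"dt_internal = {self.dt_internal} s is too coarse; must be "
                f"<= sampling_interval/100 = "
                f"{config.sampling_interval * 60.0 / 100.0:g} s")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TissueGeometry:
    """Follicle geometry and linear cell densities driving surface correction.

    Defaults are the morphometric parameters of Peyer's patches in 2-month-old
    piglets: follicles 0.71 × 0.86 mm, 0.11 mm apart, analyzed over a 95 mm²
    chamber aperture; the follicle-associated epithelium (FAE) counts 34 cells
    per 100 length-units against 120 for the villous epithelium (VE).  Cell
    densities enter only as a ratio, so their length unit cancels.
    """

    pp_width: float = 0.71
    pp_length: float = 0.86
    inter_pp_distance: float = 0.11
    test_area: float = 95.0
    fae_cell_density: float = 34.0
    ve_cell_density: float = 120.0

    def __post_init__(self) -> None:
        for name in ("pp_width", "pp_length", "test_area",
                     "fae_cell_density", "ve_cell_density"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.inter_pp_distance < 0:
            raise ConfigurationError("inter_pp_distance must be non-negative")
        if self.ve_cell_density < self.fae_cell_density:
            warnings.warn(
                "ve_cell_density < fae_cell_density: the dome epithelium is "
                "normally sparser than villous epithelium; check inputs",
                UserWarning, stacklevel=2)

    def to_dict(self) -> dict:
        return asdict(self)
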
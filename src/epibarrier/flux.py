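"""Dilution correction, paracellular flux, apparent permeability, and TER.

The measurement chain for a serial-sampling Ussing-chamber flux experiment:

1. Basolateral tracer concentrations are measured at each sampling time; each
   sample withdraws ``V_s`` mL that is replaced with fresh buffer, diluting
   the receiver compartment.
2. Measured concentrations are corrected for that dilution:
   ``c = (c_{t-1}·V_s + c_t·V_K)/V_K``.
3. Per-interval flux ``J = Δc·V_K/(Δt·A)`` (reported in μmol·h⁻¹·cm⁻²).
4. Apparent permeability ``P_app = J̄ / c_a`` (reported in cm·s⁻¹), with
   ``c_a`` the apical donor concentration.

Transepithelial resistance (TER) traces are summarized as the mean over a
recording window; resistances are accepted already area-normalized (Ω·cm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .config import ChamberConfig, ConfigurationError

__all__ = [
    "ConcentrationSeries", "FluxResult", "TerSummary",
    "correct_concentrations", "interval_flux", "apparent_permeability",
    "papp_pipeline", "summarize_ter",
]

#: seconds per hour / (mL per L) — J[μmol·h⁻¹·cm⁻²] → P_app[cm·s⁻¹] at c_a[μmol·L⁻¹]
_J_TO_PAPP = 1000.0 / 3600.0


class InputError(ValueError):
    """Raised for malformed measurement tables (negative values, short series)."""


@dataclass
class ConcentrationSeries:
    """Ordered basolateral tracer concentrations of one chamber.

    ``times`` are sampling times in minutes, strictly increasing; the first
    entry is the post-preincubation baseline.  ``measured`` holds raw
    plate-reader concentrations (μmol·L⁻¹); ``corrected`` is filled by
    :func:`correct_concentrations`.
    """

    chamber_id: str
    group: str
    times: np.ndarray
    measured: np.ndarray
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        if self.times.shape != self.measured.shape:
            raise InputError(
                f"chamber {self.chamber_id}: times and measured lengths differ "
                f"({self.times.size} vs {self.measured.size})")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InputError(
                f"chamber {self.chamber_id}: sampling times must be strictly increasing")
        neg = np.flatnonzero(self.measured < 0)
        if neg.size:
            raise InputError(
                f"chamber {self.chamber_id}: negative measured concentration "
                f"at row {neg[0]} (t = {self.times[neg[0]]:g} min)")
        if self.corrected is not None:
            self.corrected = np.asarray(self.corrected, dtype=float)


@dataclass
class FluxResult:
    """Per-interval flux and apparent permeability of one chamber.

    ``interval_flux`` is in μmol·h⁻¹·cm⁻² per sampling interval;
    ``papp`` in cm·s⁻¹ (filled by :func:`apparent_permeability`).
    """

    chamber_id: str
    group: str
    interval_flux: np.ndarray
    mean_flux: float
    papp: float | None = None
    papp_from: str = "mean of all intervals"


@dataclass
class TerSummary:
    """Windowed mean transepithelial resistance of one chamber (Ω·cm²)."""

    chamber_id: str
    group: str
    mean_ter: float
    window: tuple[float, float]
    n_points: int


def correct_concentrations(series: ConcentrationSeries, config: ChamberConfig,
                           mode: str = "verbatim") -> ConcentrationSeries:
    """Correct measured receiver concentrations for sampling dilution.

    ``corrected[0] = measured[0]`` and, for t >= 1,
    ``corrected[t] = (prev[t-1]·V_s + measured[t]·V_K)/V_K``.

    ``mode="verbatim"`` takes ``prev`` as the previous *measured* value, the
    form in which the correction is conventionally stated.  ``mode="recursive"``
    takes the previous *corrected* value, which compounds earlier withdrawals
    and is the better mass-consistent reconstruction for runs with three or
    more intervals.

    Returns a new series; the input is not mutated.
    """
    if mode not in ("verbatim", "recursive"):
        raise ValueError(f"unknown correction mode {mode!r}")
    if config.sample_volume >= config.chamber_volume:
        raise ConfigurationError("sample_volume must be smaller than chamber_volume")
    if series.measured.size < 2:
        raise InputError(
            f"chamber {series.chamber_id}: need >= 2 time points to correct "
            f"(got {series.measured.size})")

    vs, vk = config.sample_volume, config.chamber_volume
    measured = series.measured
    corrected = np.empty_like(measured)
    corrected[0] = measured[0]
    for t in range(1, measured.size):
        prev = corrected[t - 1] if mode == "recursive" else measured[t - 1]
        corrected[t] = (prev * vs + measured[t] * vk) / vk
    return replace(series, corrected=corrected)


def interval_flux(series: ConcentrationSeries, config: ChamberConfig) -> FluxResult:
    """Per-interval tracer flux ``J = Δc·V_K/(Δt·A)`` from corrected concentrations.

    Concentration differences use the dilution-corrected series; the result is
    converted to μmol·h⁻¹·cm⁻².  The mean flux is the arithmetic mean over all
    intervals.
    """
    if series.corrected is None:
        raise InputError(
            f"chamber {series.chamber_id}: corrected concentrations missing; "
            "run correct_concentrations first")
    if series.corrected.size < 2:
        raise InputError(f"chamber {series.chamber_id}: need >= 2 time points")
    dt_min = np.diff(series.times)
    if np.any(dt_min == 0):
        raise InputError(f"chamber {series.chamber_id}: zero-length interval")

    dc = np.diff(series.corrected)                     # μmol·L⁻¹
    moles = dc * config.chamber_volume / 1000.0        # μmol
    j = moles / ((dt_min / 60.0) * config.exposed_area)  # μmol·h⁻¹·cm⁻²
    return FluxResult(chamber_id=series.chamber_id, group=series.group,
                      interval_flux=j, mean_flux=float(np.mean(j)))


def apparent_permeability(flux: FluxResult, config: ChamberConfig) -> FluxResult:
    """Apparent permeability ``P_app = J̄/c_a`` in cm·s⁻¹.

    J̄ (μmol·h⁻¹·cm⁻²) is divided by the apical donor concentration
    (μmol·L⁻¹); the unit conversion factor 1000/3600 yields cm·s⁻¹.
    """
    if config.apical_concentration <= 0:
        raise ConfigurationError("apical_concentration must be strictly positive")
    papp = flux.mean_flux / config.apical_concentration * _J_TO_PAPP
    return replace(flux, papp=float(papp))


def papp_pipeline(series: ConcentrationSeries, config: ChamberConfig,
                  mode: str = "verbatim") -> FluxResult:
    """Full chain: dilution correction → interval flux → apparent permeability."""
    corrected = correct_concentrations(series, config, mode=mode)
    return apparent_permeability(interval_flux(corrected, config), config)


def summarize_ter(times: Sequence[float], resistance: Sequence[float],
                  window: tuple[float, float] = (0.0, 60.0),
                  chamber_id: str = "", group: str = "") -> TerSummary:
    """Mean TER over a recording window.

    ``times`` in minutes, ``resistance`` in Ω·cm² (already area-normalized).
    Points with ``window[0] <= t <= window[1]`` enter the mean; an empty
    overlap is an error.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(resistance, dtype=float)
    if t.size == 0:
        raise InputError("empty TER trace")
    if t.shape != r.shape:
        raise InputError("times and resistance lengths differ")
    lo, hi = window
    if hi < lo:
        raise InputError(f"invalid window ({lo}, {hi})")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise InputError(
            f"window ({lo}, {hi}) min does not overlap the recorded trace "
            f"[{t.min():g}, {t.max():g}] min")
    return TerSummary(chamber_id=chamber_id, group=group,
                      mean_ter=float(np.mean(r[mask])), window=(lo, hi),
                      n_points=int(mask.sum()))
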
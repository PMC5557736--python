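"""Synthetic Ussing-chamber, TER, densitometry, and qPCR data with known truth.

The chamber simulator integrates a two-compartment model with a clamped
apical source:

    dC_b/dt = P_app · A · (C_a − C_b) / V_K

At every sampling time the basolateral concentration is read out (plus
additive Gaussian plate-reader noise, truncated at 0) and the compartment is
diluted by the withdrawal-and-replacement factor (V_K − V_s)/V_K.  The apical
side is treated as a constant source: at P_app ~ 10⁻⁵ cm·s⁻¹ over one hour
the donor depletes by well under 1%, matching the sink-condition assumption
implicit in P_app = J/c_a.

The downstream generators produce group-structured TER samples and
expression tables (band intensities, Ct values) in which the whole-tissue
signal scales with epithelial cell content, so that the surface-correction
analysis has an exact known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ChamberConfig, SimulationTruth
from .flux import ConcentrationSeries

__all__ = [
    "SimulatedExperiment", "SimulationError",
    "simulate_chamber", "simulate_chamber_group",
    "generate_ter_groups", "generate_expression_data",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulatedExperiment:
    """One simulated chamber run: configuration, ground truth, and output.

    ``true_masses`` holds the tracer mass (μmol) that crossed the tissue in
    each sampling interval, from the integrator's own bookkeeping.
    """

    config: ChamberConfig
    truth: SimulationTruth
    measured: ConcentrationSeries
    true_masses: np.ndarray


def simulate_chamber(config: ChamberConfig, truth: SimulationTruth,
                     chamber_id: str = "sim", group: str = "sim") -> SimulatedExperiment:
    """Simulate a serial-sampling tracer flux run.

    The basolateral concentration starts at 0 at t = 0 (the baseline sample
    taken at the end of preincubation) and is integrated by explicit stepping
    at ``truth.dt_internal`` seconds.  Identical (config, truth) always yields
    an identical experiment.
    """
    truth.validate_against(config)
    rng = np.random.default_rng(truth.seed)

    v = config.chamber_volume            # mL == cm³
    rate = truth.true_papp * config.exposed_area / v   # s⁻¹
    c_a = config.apical_concentration
    dilution = (v - config.sample_volume) / v
    interval_s = config.sampling_interval * 60.0
    n_steps = int(round(interval_s / truth.dt_internal))
    dt = interval_s / n_steps

    c_b = 0.0
    times = np.empty(config.n_samples)
    measured = np.empty(config.n_samples)
    true_masses = np.zeros(max(config.n_samples - 1, 0))

    for i in range(config.n_samples):
        if i > 0:
            transferred = 0.0
            for step in range(n_steps):
                dc = rate * (c_a - c_b) * dt
                c_b += dc
                transferred += dc
                if not math.isfinite(c_b):
                    raise SimulationError(
                        f"non-finite basolateral concentration at interval {i}, "
                        f"step {step} (dt_internal = {truth.dt_internal} s)")
            true_masses[i - 1] = transferred * v / 1000.0   # μmol
        times[i] = i * config.sampling_interval
        reading = c_b
        if truth.noise_sd > 0:
            reading = max(0.0, reading + rng.normal(0.0, truth.noise_sd))
        measured[i] = reading
        c_b *= dilution    # withdrawal + replacement with fresh buffer

    series = ConcentrationSeries(chamber_id=chamber_id, group=group,
                                 times=times, measured=measured)
    return SimulatedExperiment(config=config, truth=truth, measured=series,
                               true_masses=true_masses)


def simulate_chamber_group(config: ChamberConfig, truth: SimulationTruth,
                           n_chambers: int, group: str = "sim",
                           id_prefix: str | None = None) -> list[SimulatedExperiment]:
    """Simulate ``n_chambers`` independent replicate runs of one tissue group.

    Chamber i uses an independent seed spawned from ``truth.seed``.
    """
    prefix = id_prefix if id_prefix is not None else group
    seeds = np.random.SeedSequence(truth.seed).generate_state(n_chambers) % (2**31)
    out = []
    for i in range(n_chambers):
        truth_i = SimulationTruth(true_papp=truth.true_papp, noise_sd=truth.noise_sd,
                                  dt_internal=truth.dt_internal, seed=int(seeds[i]))
        out.append(simulate_chamber(config, truth_i,
                                    chamber_id=f"{prefix}{i + 1}", group=group))
    return out


def generate_ter_groups(mean_a: float, mean_b: float, sem_a: float, sem_b: float,
                        n: int, seed: int = 0,
                        labels: tuple[str, str] = ("VE", "PP")) -> pd.DataFrame:
    """Draw two labelled TER samples whose sample SEM matches the target SEM.

    Values are drawn from Normal(mean, sem·√n) per group, so the standard
    error of each simulated group of ``n`` animals is ``sem`` in expectation.

    Returns a tidy frame with columns ``chamber_id``, ``group``,
    ``ter_ohm_cm2``.
    """
    if n < 2:
        raise ValueError("n must be >= 2 (SEM is undefined for a single animal)")
    if sem_a < 0 or sem_b < 0:
        raise ValueError("SEMs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sem in ((labels[0], mean_a, sem_a), (labels[1], mean_b, sem_b)):
        values = rng.normal(mean, sem * math.sqrt(n), size=n)
        for i, val in enumerate(values):
            rows.append({"chamber_id": f"{label}{i + 1}", "group": label,
                         "ter_ohm_cm2": val})
    return pd.DataFrame(rows)


def generate_expression_data(true_per_cell_ratio: float, density_ratio: float,
                             n: int, noise_cv: float = 0.0, seed: int = 0,
                             target_id: str = "CLDN4",
                             groups: tuple[str, str] = ("PP", "VE"),
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate matched densitometry and qPCR tables with known ground truth.

    The test-group whole-tissue signal is the per-cell expression ratio
    divided by the cell-density ratio: a tissue whose epithelium holds
    ``density_ratio``-fold fewer cell contacts delivers proportionally less
    protein and mRNA per unit area, so its raw normalized ratio is
    ``true_per_cell_ratio / density_ratio`` times the reference group's.
    With ``true_per_cell_ratio == density_ratio`` the raw ratios cancel to
    equality and only surface correction reveals the per-cell difference.

    ``noise_cv`` is the coefficient of variation of multiplicative lognormal
    noise on band intensities; Ct values receive the additive-noise equivalent
    (σ/ln 2 cycles), so fold-change noise matches the densitometry noise.

    Returns ``(densitometry, qpcr)`` frames in the common expression-table
    schema: sample_id, group, target_id, target_signal, control_signal, assay.
    """
    if true_per_cell_ratio <= 0 or density_ratio <= 0:
        raise ValueError("expression and density ratios must be strictly positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv ** 2))

    def lognoise(size: int) -> np.ndarray:
        if sigma == 0:
            return np.ones(size)
        return np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=size))

    test_group, ref_group = groups
    tissue_signal = {ref_group: 1.0,
                     test_group: true_per_cell_ratio / density_ratio}
    control_base, target_base = 1000.0, 800.0

    dens_rows = []
    for group in (test_group, ref_group):
        control = control_base * lognoise(n)
        target = control * (target_base / control_base) * tissue_signal[group] * lognoise(n)
        for i in range(n):
            dens_rows.append({"sample_id": f"{group}{i + 1}", "group": group,
                              "target_id": target_id,
                              "target_signal": target[i],
                              "control_signal": control[i],
                              "assay": "densitometry"})

    ct_sigma = sigma / math.log(2)
    ref_ct, base_dct = 20.0, 5.0
    qpcr_rows = []
    for group in (test_group, ref_group):
        dct = base_dct - math.log2(tissue_signal[group])
        noise = rng.normal(0.0, ct_sigma, size=n) if ct_sigma else np.zeros(n)
        target_ct = ref_ct + dct + noise
        for i in range(n):
            qpcr_rows.append({"sample_id": f"{group}{i + 1}", "group": group,
                              "target_id": target_id,
                              "target_signal": float(target_ct[i]),
                              "control_signal": ref_ct,
                              "assay": "qpcr"})

    return pd.DataFrame(dens_rows), pd.DataFrame(qpcr_rows)
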
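"""Validated tabular I/O and pipeline configuration.

All tables are comma-separated UTF-8 with a header row and "." decimals.

Chamber schema (one row per sample):
    chamber_id, group, time_min, concentration_umol_per_L
TER schema:
    chamber_id, group, ter_ohm_cm2          (summaries)
    chamber_id, group, time_min, ter_ohm_cm2 (traces)
Expression schema:
    sample_id, group, target_id, target_signal, control_signal, assay

A simulation's sidecar file is YAML holding the chamber configuration, the
ground truth, and the seed, so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .config import ChamberConfig, ConfigurationError, SimulationTruth, TissueGeometry
from .expression import EXPRESSION_COLUMNS
from .flux import ConcentrationSeries, FluxResult, InputError, TerSummary

CHAMBER_COLUMNS = ["chamber_id", "group", "time_min", "concentration_umol_per_L"]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{what} file {path}: missing columns {missing}")
    if len(df) == 0:
        raise InputError(f"{what} file {path}: no data rows")


def write_chambers_csv(path: str | Path, series_list: list[ConcentrationSeries]) -> None:
    rows = []
    for s in series_list:
        for t, c in zip(s.times, s.measured):
            rows.append({"chamber_id": s.chamber_id, "group": s.group,
                         "time_min": t, "concentration_umol_per_L": c})
    pd.DataFrame(rows, columns=CHAMBER_COLUMNS).to_csv(path, index=False)


def read_chambers_csv(path: str | Path) -> list[ConcentrationSeries]:
    df = pd.read_csv(path)
    _require_columns(df, CHAMBER_COLUMNS, "chamber", path)
    out = []
    for (chamber_id, group), sub in df.groupby(["chamber_id", "group"], sort=False):
        sub = sub.sort_values("time_min")
        out.append(ConcentrationSeries(
            chamber_id=str(chamber_id), group=str(group),
            times=sub["time_min"].to_numpy(),
            measured=sub["concentration_umol_per_L"].to_numpy()))
    return out


def write_sidecar(path: str | Path, config: ChamberConfig,
                  truth: SimulationTruth | None = None,
                  extra: dict | None = None) -> None:
    doc: dict = {"chamber": config.to_dict()}
    if truth is not None:
        doc["truth"] = truth.to_dict()
    if extra:
        doc["meta"] = extra
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_sidecar(path: str | Path) -> tuple[ChamberConfig, SimulationTruth | None, dict]:
    doc = yaml.safe_load(Path(path).read_text())
    config = _build(ChamberConfig, doc.get("chamber", {}), f"{path}:chamber")
    truth = None
    if "truth" in doc:
        truth = _build(SimulationTruth, doc["truth"], f"{path}:truth")
    return config, truth, doc.get("meta", {})


def write_flux_csv(path: str | Path, results: list[FluxResult]) -> None:
    rows = [{"chamber_id": r.chamber_id, "group": r.group,
             "mean_J_umol_per_h_cm2": r.mean_flux,
             "Papp_cm_per_s": r.papp, "papp_from": r.papp_from}
            for r in results]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ter_csv(path: str | Path, summaries: list[TerSummary]) -> None:
    rows = [{"chamber_id": s.chamber_id, "group": s.group,
             "ter_ohm_cm2": s.mean_ter,
             "window_start_min": s.window[0], "window_end_min": s.window[1],
             "n_points": s.n_points}
            for s in summaries]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ter_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["chamber_id", "group", "ter_ohm_cm2"], "TER", path)
    return df


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EXPRESSION_COLUMNS, "expression", path)
    return df


def _build(cls, block: dict, where: str):
    if not isinstance(block, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(block) - names)
    if unknown:
        raise ConfigurationError(f"{where}: unknown keys {unknown}")
    return cls(**block)


@dataclass(frozen=True)
class AnalysisOptions:
    """Pipeline-wide analysis modes (all default to the conventional forms)."""

    dilution_mode: str = "verbatim"      # verbatim | recursive
    rounding: str = "verbatim"           # verbatim | full (morphometry chain)
    ve_sem_mode: str = "zero"            # zero | propagate
    paired: bool = False

    def __post_init__(self) -> None:
        if self.dilution_mode not in ("verbatim", "recursive"):
            raise ConfigurationError(f"unknown dilution_mode {self.dilution_mode!r}")
        if self.rounding not in ("verbatim", "full"):
            raise ConfigurationError(f"unknown rounding {self.rounding!r}")
        if self.ve_sem_mode not in ("zero", "propagate"):
            raise ConfigurationError(f"unknown ve_sem_mode {self.ve_sem_mode!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """One config file driving the whole analysis chain."""

    chamber: ChamberConfig = field(default_factory=ChamberConfig)
    geometry: TissueGeometry = field(default_factory=TissueGeometry)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    outdir: str = "results"
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        known = {"chamber", "geometry", "analysis", "outdir", "seed", "verbosity"}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys {unknown}")
        return cls(
            chamber=_build(ChamberConfig, doc.get("chamber", {}), f"{path}:chamber"),
            geometry=_build(TissueGeometry, doc.get("geometry", {}), f"{path}:geometry"),
            analysis=_build(AnalysisOptions, doc.get("analysis", {}), f"{path}:analysis"),
            outdir=str(doc.get("outdir", "results")),
            seed=int(doc.get("seed", 0)),
            verbosity=int(doc.get("verbosity", 0)))

    def to_yaml(self, path: str | Path) -> None:
        doc = {"chamber": self.chamber.to_dict(),
               "geometry": self.geometry.to_dict(),
               "analysis": dataclasses.asdict(self.analysis),
               "outdir": self.outdir, "seed": self.seed,
               "verbosity": self.verbosity}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
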
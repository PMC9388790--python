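"""CSV / JSON / YAML input-output for the analysis pipeline.

OGTT data travel as long-format CSV with one row per (participant, time):
``participant_id, time_min, glucose_mg_dl, insulin_uU_ml, glycerol_umol_l``.
Missing cells are allowed (per-analyte NaN); basal fields are recomputed from
the -20/-10/0 min samples on read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcing import compute_basal
from .glycerol import GlycerolFitConfig
from .omm import OMMFitConfig
from .preprocess import OGTTRecord
from .synthetic import PopulationConfig

REQUIRED_COLUMNS = ("participant_id", "time_min", "glucose_mg_dl",
                    "insulin_uU_ml", "glycerol_umol_l")


def read_ogtt_csv(path) -> list[OGTTRecord]:
    """Parse a long-format OGTT CSV into validated per-participant records."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    records = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            rows = grp.index[np.flatnonzero(np.diff(t) == 0)].tolist()
            raise ValueError(f"duplicated (participant, time) rows for {pid!r} near rows {rows}")
        records.append(
            OGTTRecord(
                participant_id=str(pid),
                times=t,
                glucose=grp["glucose_mg_dl"].to_numpy(dtype=float),
                insulin=grp["insulin_uU_ml"].to_numpy(dtype=float),
                glycerol=grp["glycerol_umol_l"].to_numpy(dtype=float),
                Gb=compute_basal(t, grp["glucose_mg_dl"].to_numpy(dtype=float)),
                Ib=compute_basal(t, grp["insulin_uU_ml"].to_numpy(dtype=float)),
                gb=compute_basal(t, grp["glycerol_umol_l"].to_numpy(dtype=float)),
            )
        )
    return records


def write_ogtt_csv(records: list[OGTTRecord], path) -> None:
    rows = []
    for rec in records:
        for i, t in enumerate(rec.times):
            rows.append({
                "participant_id": rec.participant_id,
                "time_min": t,
                "glucose_mg_dl": rec.glucose[i],
                "insulin_uU_ml": rec.insulin[i],
                "glycerol_umol_l": rec.glycerol[i],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs, serialisable to YAML."""

    input_csv: str | None = None
    output_dir: str = "results"
    master_seed: int = 0
    n_synthetic: int = 0                  # if > 0, generate instead of reading input_csv
    make_figures: bool = False
    omm: OMMFitConfig = field(default_factory=OMMFitConfig)
    glycerol: GlycerolFitConfig = field(default_factory=GlycerolFitConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    grid_step: float = 1.0                # dense grid for action profiles, min

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            **{k: v for k, v in raw.items() if k not in ("omm", "glycerol", "population")},
            omm=_from_plain(OMMFitConfig, raw.get("omm", {})),
            glycerol=_from_plain(GlycerolFitConfig, raw.get("glycerol", {})),
            population=_from_plain(PopulationConfig, raw.get("population", {})),
        )


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return ".inf"
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    return obj


def _revive(value):
    if value == ".inf":
        return np.inf
    if isinstance(value, list):
        return tuple(_revive(v) for v in value)
    return value


def _from_plain(cls, raw: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in raw:
            v = _revive(raw[f.name])
            if f.name in ("ra_breakpoints",):
                v = np.asarray(v, dtype=float)
            if f.name == "noise_cv" and isinstance(v, tuple):
                v = dict(raw[f.name])
            kwargs[f.name] = v
    return cls(**kwargs)


def fit_result_json(result, participant_id: str, model: str) -> dict:
    """Serialisable summary of a FitResult (schema shared by both models)."""
    return {
        "participant_id": participant_id,
        "model": model,
        "params": result.params_dict(),
        "objective": result.best_objective,
        "n_restarts": len(result.restarts),
        "rng_seed": result.rng_seed,
        "window": list(result.window) if result.window else None,
        "extra": {k: _jsonable(v) for k, v in result.extra.items()
                  if k in ("SI", "g0", "ra_heights")},
    }


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")
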
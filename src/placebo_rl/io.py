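"""CSV schemas, configuration files and run manifests.

Study data travel as three long-format CSVs (trials, subjective reports,
arousal ratings); simulation and fitting settings live in a single
YAML/JSON config; a manifest records the seeds and content checksums that
make every run re-derivable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (AccuracyCoefs, ArousalCoefs, GroupTruth, RTCoefs,
                     SUBJECTIVE_PROFILES, TRIAL_COLUMNS)
from .task import TaskConfig

__all__ = [
    "write_trials", "read_trials",
    "write_table", "read_subjective", "read_arousal",
    "PipelineConfig", "load_config",
    "write_manifest",
]

TRIAL_DTYPES = {"subject_id": "int64", "condition": "string", "phase": "string",
                "block": "int64", "trial_index": "int64", "pair": "string",
                "choice": "string", "correct": "int64", "reward": "int64",
                "rt": "float64", "missed": "int64"}

SUBJECTIVE_COLUMNS = ["subject_id", "condition", "question", "response"]
AROUSAL_COLUMNS = ["subject_id", "condition", "time", "rating"]


def require_columns(df: pd.DataFrame, columns, what: str = "table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def write_trials(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the trial table; an optional header comment records the top-level seed."""
    require_columns(df, TRIAL_COLUMNS, "trial table")
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df[TRIAL_COLUMNS].to_csv(fh, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"choice": "string"})
    require_columns(df, TRIAL_COLUMNS, "trial table")
    df["choice"] = df["choice"].fillna("")
    for col, dt in TRIAL_DTYPES.items():
        if col != "rt":
            df[col] = df[col].astype(dt)
    df["condition"] = df["condition"].astype(object)
    for col in ("phase", "pair", "choice"):
        df[col] = df[col].astype(object)
    return df[TRIAL_COLUMNS]


def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_subjective(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    require_columns(df, SUBJECTIVE_COLUMNS, "subjective table")
    return df[SUBJECTIVE_COLUMNS]


def read_arousal(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    require_columns(df, AROUSAL_COLUMNS, "arousal table")
    return df[AROUSAL_COLUMNS]


@dataclass
class PipelineConfig:
    """Top-level settings for the simulate -> fit -> report pipeline."""

    n_subjects: int = 29
    seed: int = 0
    profile: str = "reduced"  # "reduced" or "full" MCMC profile
    miss_rate: float = 0.0
    truth: GroupTruth = field(default_factory=GroupTruth)
    rt: RTCoefs = field(default_factory=RTCoefs)
    accuracy: AccuracyCoefs = field(default_factory=AccuracyCoefs)
    arousal: ArousalCoefs = field(default_factory=ArousalCoefs)
    subjective_profiles: dict = field(default_factory=lambda: dict(SUBJECTIVE_PROFILES))
    task: TaskConfig = field(default_factory=TaskConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth"]["delta"] = {f"{p}:{c}": v for (p, c), v in self.truth.delta.items()}
        d["subjective_profiles"] = {f"{c}:{q}": list(v)
                                    for (c, q), v in self.subjective_profiles.items()}
        d["task"]["symbols"] = list(self.task.symbols)
        d["task"]["trained_pairs"] = ["".join(p) for p in self.task.trained_pairs]
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("n_subjects", "seed", "profile", "miss_rate"):
        if key in raw:
            kwargs[key] = raw[key]
    if "truth" in raw:
        t = dict(raw["truth"])
        if "delta" in t:
            t["delta"] = {tuple(k.split(":")): float(v) for k, v in t["delta"].items()}
        kwargs["truth"] = GroupTruth(**t)
    for key, cls in (("rt", RTCoefs), ("accuracy", AccuracyCoefs), ("arousal", ArousalCoefs)):
        if key in raw:
            kwargs[key] = cls(**raw[key])
    if "subjective_profiles" in raw:
        kwargs["subjective_profiles"] = {tuple(k.split(":")): tuple(v)
                                         for k, v in raw["subjective_profiles"].items()}
    if "task" in raw:
        t = dict(raw["task"])
        if "symbols" in t:
            t["symbols"] = tuple(t["symbols"])
        if "trained_pairs" in t:
            t["trained_pairs"] = [tuple(p) for p in t["trained_pairs"]]
        kwargs["task"] = TaskConfig(**t)
    return PipelineConfig(**kwargs)


def write_loglik_matrix(matrix: np.ndarray, path) -> None:
    """Per-trial log-likelihood matrix as CSV (rows = posterior draws, columns = trials)."""
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=",",
               header="rows=posterior draws, columns=trials", comments="# ")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, seed: int, files, extra: dict | None = None) -> Path:
    """Record seeds and content checksums of a run's artifacts."""
    out_dir = Path(out_dir)
    manifest = {"seed": int(seed),
                "files": {Path(f).name: _sha256(f) for f in files}}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return path
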
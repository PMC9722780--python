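"""Reading and writing of tables, parameter profiles, and sessions.

Tables are comma-separated text with ``# key=value`` header comments
carrying provenance (config hash, seed); parameter profiles are YAML;
session stimuli go into a compressed ``.npz`` array container with a
JSON metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .ci import ClassificationImage, ImpactCurves
from .observer import ModelParams, Session
from .stimgen import StimulusParams

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "save_params",
    "load_stimulus_params",
    "load_model_params",
    "save_session",
    "load_session",
    "ci_to_frame",
    "impact_to_frame",
]

TRIAL_COLUMNS = [
    "trial_id",
    "seed",
    "target_side",
    "target_onset_ms",
    "cue_present",
    "cue_side",
    "cue_onset_ms",
    "condition",
    "choice",
    "rt_ms",
    "correct",
    "lapsed",
]


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping or dataclass."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """CSV with ``# key=value`` provenance comments above the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_params(params, path) -> None:
    """Write a StimulusParams or ModelParams profile as YAML."""
    d = dataclasses.asdict(params)
    d["_kind"] = type(params).__name__
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def _load_params(path, cls):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d.pop("_kind", None)
    for k, v in list(d.items()):
        if isinstance(v, list):
            d[k] = tuple(v)
    return cls(**d)


def load_stimulus_params(path) -> StimulusParams:
    return _load_params(path, StimulusParams)


def load_model_params(path) -> ModelParams:
    return _load_params(path, ModelParams)


def save_session(session: Session, outdir, meta: Optional[dict] = None) -> None:
    """Persist a session: trials.csv + stimuli.npz + meta.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(session.trials, out / "trials.csv", meta)
    np.savez_compressed(
        out / "stimuli.npz",
        noise=session.noise.astype(np.float32),
        contrast=session.contrast.astype(np.float32),
        eps_z=session.eps_z if session.eps_z is not None else np.empty(0),
    )
    info = {
        "seed": session.seed,
        "n_trials": session.n_trials,
        "stim_params": dataclasses.asdict(session.stim_params),
        "model_params": dataclasses.asdict(session.model_params),
    }
    if meta:
        info.update(meta)
    with open(out / "meta.json", "w") as fh:
        json.dump(info, fh, indent=2, default=str)


def load_session(outdir) -> Session:
    out = Path(outdir)
    with open(out / "meta.json") as fh:
        info = json.load(fh)
    sp_d = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in info["stim_params"].items()
    }
    arrays = np.load(out / "stimuli.npz")
    eps_z = arrays["eps_z"]
    return Session(
        trials=read_table(out / "trials.csv"),
        noise=arrays["noise"].astype(np.float64),
        contrast=arrays["contrast"].astype(np.float64),
        stim_params=StimulusParams(**sp_d),
        model_params=ModelParams(**info["model_params"]),
        seed=info.get("seed"),
        eps_z=eps_z if eps_z.size else None,
    )


def ci_to_frame(ci: ClassificationImage) -> pd.DataFrame:
    """Long-format (bar, lag_ms, weight, n) view of a CI."""
    n_bars, n_lags = ci.weights.shape
    bars, lags = np.meshgrid(np.arange(1, n_bars + 1), np.arange(n_lags), indexing="ij")
    return pd.DataFrame(
        {
            "bar": bars.ravel(),
            "lag_ms": (lags * ci.frame_duration_ms).ravel(),
            "weight": ci.weights.ravel(),
            "n": ci.counts.ravel(),
        }
    )


def impact_to_frame(curves: ImpactCurves) -> pd.DataFrame:
    d = {
        "lag_ms": curves.lag_ms,
        "center": curves.center,
        "surround": curves.surround,
    }
    if curves.center_sem is not None:
        d["center_sem"] = curves.center_sem
        d["surround_sem"] = curves.surround_sem
    return pd.DataFrame(d)
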
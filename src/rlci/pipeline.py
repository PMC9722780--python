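"""End-to-end orchestration: simulate observers, analyse RT and CIs, fit.

``run_pipeline`` chains the whole analysis for a cohort of synthetic
observers: session simulation, condition labelling, RT epoch tables,
per-observer and grand-average classification images and impact curves,
epoch-resolved peak-impact tables, and (optionally) per-observer gain
refits.  Every table carries the config hash and seed that produced it;
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import io
from .behavior import assign_conditions, rt_by_cue_onset
from .ci import (
    DEFAULT_EPOCHS_MS,
    aggregate_impact,
    epoch_cis,
    impact_curves,
    peak_impact,
    response_locked_ci,
)
from .fitting import FitSpec, fit
from .observer import ModelParams, invalid_profile, simulate_session, valid_profile
from .stimgen import StimulusParams

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully determines a pipeline run (and hence every output byte)."""

    seed: int = 0
    n_observers: int = 10
    n_trials: int = 2000
    profile: str = "valid"  # model parameter profile: valid | invalid
    cue_mode: str = "schedule"
    max_lag: int = 45
    estimator: str = "mean"  # CI estimator variant
    leak_noise: bool = False  # accumulator noise-leak variant
    fit_gain: bool = False  # refit the attentional gain per observer
    stim_params: StimulusParams = field(default_factory=StimulusParams)

    def model_params(self) -> ModelParams:
        base = valid_profile() if self.profile == "valid" else invalid_profile()
        return dataclasses.replace(base, leak_noise=self.leak_noise)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sp = d.pop("stim_params", None)
        cfg = cls(**d)
        if sp:
            cfg.stim_params = StimulusParams(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sp.items()}
            )
        return cfg


def _observer_seed(cfg: RunConfig, i: int) -> int:
    return (cfg.seed * 1_000_003 + 7919 * i + 17) % 2**31


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full chain and write the artifact bundle to ``outdir``.

    Returns a small manifest dict (also written as manifest.json).
    Failures abort with the stage name; each stage's outputs are written
    only after the stage completes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config)
    meta = {"config_hash": chash, "seed": config.seed}
    mp = config.model_params()
    sp = config.stim_params

    stage = "simulate"
    try:
        sessions = []
        for i in range(config.n_observers):
            s = simulate_session(
                config.n_trials, sp, mp, seed=_observer_seed(config, i),
                cue_mode=config.cue_mode,
            )
            s.trials["condition"] = assign_conditions(s.trials)
            s.trials["observer_id"] = i
            io.write_table(
                s.trials, out / f"trials_obs{i:02d}.csv", {**meta, "observer": i}
            )
            sessions.append(s)
        all_trials = pd.concat([s.trials for s in sessions], ignore_index=True)

        stage = "analyze-rt"
        for lock in ("stimulus", "response"):
            tab = rt_by_cue_onset(all_trials, lock=lock)
            io.write_table(tab, out / f"rt_{lock}_locked.csv", meta)

        stage = "analyze-ci"
        grand = {}
        rows = []
        for cond in ("valid", "invalid"):
            per_obs = []
            for i, s in enumerate(sessions):
                ci = response_locked_ci(
                    s.trials,
                    s.noise,
                    "target",
                    max_lag=config.max_lag,
                    stim_params=sp,
                    estimator=config.estimator,
                    include=(s.trials["condition"] == cond).to_numpy(),
                    observer_id=i,
                )
                io.write_table(
                    io.ci_to_frame(ci),
                    out / f"ci_obs{i:02d}_{cond}.csv",
                    {**meta, "observer": i, "condition": cond},
                )
                per_obs.append(impact_curves(ci))
            grand[cond] = aggregate_impact(per_obs)
            io.write_table(
                io.impact_to_frame(grand[cond]),
                out / f"impact_grand_{cond}.csv",
                {**meta, "condition": cond},
            )
            # epoch-resolved peak impact (per observer, then averaged)
            for lo, hi in DEFAULT_EPOCHS_MS:
                per_obs_peaks = []
                for i, s in enumerate(sessions):
                    eci = epoch_cis(
                        s.trials,
                        s.noise,
                        epochs_ms=[(lo, hi)],
                        max_lag=config.max_lag,
                        stim_params=sp,
                        estimator=config.estimator,
                    )[(cond, (lo, hi))]
                    cur = impact_curves(eci)
                    try:
                        per_obs_peaks.append(peak_impact(cur))
                    except ValueError:
                        pass
                c = np.array(
                    [p["center"] for p in per_obs_peaks if np.isfinite(p["center"])]
                )
                su = np.array(
                    [p["surround"] for p in per_obs_peaks if np.isfinite(p["surround"])]
                )
                if c.size:
                    rows.append(
                        {
                            "condition": cond,
                            "epoch_start_ms": lo,
                            "epoch_end_ms": hi,
                            "peak_center": c.mean(),
                            "peak_center_sem": (
                                c.std(ddof=1) / np.sqrt(c.size) if c.size > 1 else 0.0
                            ),
                            "peak_surround": su.mean() if su.size else np.nan,
                            "n_observers": int(c.size),
                        }
                    )
        io.write_table(pd.DataFrame(rows), out / "peak_impact_epochs.csv", meta)

        fits = []
        if config.fit_gain:
            stage = "fit"
            for i, s in enumerate(sessions):
                obs = impact_curves(
                    response_locked_ci(
                        s.trials, s.noise, "target", max_lag=30, stim_params=sp
                    )
                )
                res = fit(
                    obs,
                    FitSpec(
                        free_params=["gain"],
                        fixed_params=mp,
                        stim_params=sp,
                        session=s,
                        max_lag=30,
                    ),
                )
                fits.append({"observer": i, "gain": res.estimates["gain"], "rms": res.rms})
            io.write_table(pd.DataFrame(fits), out / "gain_fits.csv", meta)

        stage = "manifest"
        manifest = {
            "config_hash": chash,
            "config": dataclasses.asdict(config),
            "observer_seeds": [_observer_seed(config, i) for i in range(config.n_observers)],
            "outputs": sorted(p.name for p in out.iterdir() if p.suffix == ".csv"),
        }
        import json

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
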
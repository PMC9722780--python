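"""Reaction-time analysis: condition labels, harmonic means, cue-onset epochs.

Trials are labelled valid / invalid / no-cue.  A trial belongs to the
no-cue condition if no cue was shown *or* if the response came no later
than the cue onset (the cue cannot have influenced a decision already
made).  RT central tendency is the harmonic mean, which down-weights the
long right tail of RT distributions; epoch tables aggregate per-observer
harmonic means into across-observer mean and SEM.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "assign_condition",
    "assign_conditions",
    "harmonic_mean_rt",
    "rt_by_cue_onset",
]

CONDITIONS = ("valid", "invalid", "no_cue")


def assign_condition(trial) -> str:
    """Condition label for one trial (mapping or Series with cue fields).

    no cue, or rt <= cue onset -> ``no_cue``; otherwise ``valid`` when
    the cue was on the target side, else ``invalid``.  Ties (rt exactly
    at cue onset) count as no-cue: the decision preceded the cue.
    """
    if not trial["cue_present"]:
        return "no_cue"
    rt = trial["rt_ms"]
    if bool(trial.get("lapsed", False)):
        # lapsed trials never responded; the cue was on screen regardless
        return "valid" if trial["cue_side"] == trial["target_side"] else "invalid"
    if rt is None or (isinstance(rt, float) and np.isnan(rt)):
        raise ValueError("non-lapsed trial without an RT")
    if rt <= trial["cue_onset_ms"]:
        return "no_cue"
    return "valid" if trial["cue_side"] == trial["target_side"] else "invalid"


def assign_conditions(trials: pd.DataFrame) -> pd.Series:
    """Vectorised condition labels for a trial table."""
    responded = ~trials["lapsed"].astype(bool)
    if responded.any() and trials.loc[responded, "rt_ms"].isna().any():
        raise ValueError("non-lapsed trial without an RT")
    cued = trials["cue_present"].astype(bool)
    before_cue = responded & (trials["rt_ms"] <= trials["cue_onset_ms"])
    valid = trials["cue_side"] == trials["target_side"]
    out = np.where(
        ~cued | (cued & before_cue),
        "no_cue",
        np.where(valid, "valid", "invalid"),
    )
    return pd.Series(out, index=trials.index, name="condition")


def harmonic_mean_rt(rts: Iterable[float]) -> float:
    """Harmonic mean n / sum(1/rt) of positive reaction times."""
    rts = np.asarray(list(rts), dtype=float)
    if rts.size == 0:
        raise ValueError("harmonic mean of an empty set is undefined")
    if np.any(rts <= 0) or np.any(~np.isfinite(rts)):
        raise ValueError("reaction times must be positive and finite")
    return float(rts.size / np.sum(1.0 / rts))


def _analyzable(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop lapsed and error trials, mirroring the experiment's exclusions."""
    keep = (~trials["lapsed"].astype(bool)) & trials["correct"].astype(bool)
    return trials.loc[keep]


def rt_by_cue_onset(
    trials: pd.DataFrame,
    lock: str = "response",
    epoch_ms: float = 100.0,
    epoch_range_ms: tuple[float, float] = (0.0, 1500.0),
    observer_col: str = "observer_id",
) -> pd.DataFrame:
    """Harmonic-mean RT per cue-onset epoch, per condition.

    ``lock='stimulus'`` bins cued trials by cue onset time; ``'response'``
    bins by (rt - cue onset), i.e. how long before the response the cue
    appeared (bin k covers cues k..k+epoch_ms ms before the response).
    Per-observer harmonic means are computed first, then averaged across
    observers (SEM with n-1).  No-cue trials have no cue time and are
    reported as a single unbinned row per the figure's flat reference.

    Returns columns: condition, epoch_start_ms, epoch_end_ms, mean_rt_ms,
    sem_ms, n (total trials contributing).
    """
    if lock not in ("stimulus", "response"):
        raise ValueError("lock must be 'stimulus' or 'response'")
    t = _analyzable(trials).copy()
    if "condition" not in t.columns:
        t["condition"] = assign_conditions(t)
    if observer_col not in t.columns:
        t = t.assign(**{observer_col: 0})
    edges = np.arange(epoch_range_ms[0], epoch_range_ms[1] + epoch_ms / 2, epoch_ms)
    rows = []

    def summarize(cond, lo, hi, sub):
        per_obs = (
            sub.groupby(observer_col)["rt_ms"].apply(harmonic_mean_rt).to_numpy()
        )
        mean = float(per_obs.mean())
        sem = float(per_obs.std(ddof=1) / np.sqrt(per_obs.size)) if per_obs.size > 1 else 0.0
        rows.append(
            {
                "condition": cond,
                "epoch_start_ms": lo,
                "epoch_end_ms": hi,
                "mean_rt_ms": mean,
                "sem_ms": sem,
                "n": len(sub),
            }
        )

    cued = t[t["condition"].isin(("valid", "invalid"))]
    key = (
        cued["cue_onset_ms"]
        if lock == "stimulus"
        else cued["rt_ms"] - cued["cue_onset_ms"]
    )
    for cond in ("valid", "invalid"):
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = cued[(cued["condition"] == cond) & (key >= lo) & (key < hi)]
            if len(sub):
                summarize(cond, float(lo), float(hi), sub)
    nc = t[t["condition"] == "no_cue"]
    if len(nc):
        summarize("no_cue", np.nan, np.nan, nc)
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "epoch_start_ms",
            "epoch_end_ms",
            "mean_rt_ms",
            "sem_ms",
            "n",
        ],
    )
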
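"""Response-locked classification images and impact curves.

The classification image (CI) is a reverse-correlation estimate of how
strongly the stimulus noise at each bar and each time *before the
response* pushed the observer's choice.  Only correct, non-lapsed trials
enter; left-target trials are mirrored so that the target field and its
bar order coincide with right-target trials, giving one canonical
(bar x backward-lag) map per field (target / non-target).

The CI weight at a cell is the mean raw noise contrast over contributing
trials (with zero-mean i.i.d. noise this equals the noise-choice
correlation up to a constant scale; a normalised estimator is available
as an option).  "Impact curves" collapse the CI over the two central
bars (center) and the two flanking bars (surround).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stimgen import CENTER_BARS, FLANK_BARS, LEFT, StimulusParams

__all__ = [
    "ClassificationImage",
    "ImpactCurves",
    "response_locked_ci",
    "impact_curves",
    "aggregate_impact",
    "epoch_cis",
    "peak_impact",
    "DEFAULT_EPOCHS_MS",
]

#: Sliding 500-ms epochs of (rt - cue onset), shifted by 250 ms.
DEFAULT_EPOCHS_MS: tuple[tuple[float, float], ...] = (
    (0.0, 500.0),
    (250.0, 750.0),
    (500.0, 1000.0),
    (750.0, 1250.0),
    (1000.0, 1500.0),
)


@dataclass
class ClassificationImage:
    """Response-locked weight map, shape (n_bars, n_lags).

    ``weights[b, l]`` is the mean (mirrored) noise contrast on bar ``b``
    at ``l`` frames before the response frame; cells that no trial
    reached are NaN, with per-cell trial counts in ``counts``.
    """

    weights: np.ndarray
    counts: np.ndarray
    field: str  # "target" or "non_target"
    frame_duration_ms: float = 1000.0 / 30.0
    observer_id: Optional[int] = None

    @property
    def n_lags(self) -> int:
        return self.weights.shape[1]

    @property
    def lag_ms(self) -> np.ndarray:
        return np.arange(self.n_lags) * self.frame_duration_ms


@dataclass
class ImpactCurves:
    """Center / surround traces of a CI versus time before the response."""

    lag_ms: np.ndarray
    center: np.ndarray
    surround: np.ndarray
    center_sem: Optional[np.ndarray] = None
    surround_sem: Optional[np.ndarray] = None


def _mirrored_noise(noise: np.ndarray, target_side: np.ndarray, which: str) -> np.ndarray:
    """Select one field per trial in the canonical orientation.

    ``noise``: (n, 2, n_bars, F).  For left-target trials the bar axis is
    reversed so bars map onto their mirror positions (the central pair
    maps onto itself, flank onto flank).
    """
    if which == "target":
        sel = noise[np.arange(len(target_side)), target_side]
    elif which == "non_target":
        sel = noise[np.arange(len(target_side)), 1 - target_side]
    else:
        raise ValueError("field_selector must be 'target' or 'non_target'")
    out = sel.copy()
    left = target_side == LEFT
    out[left] = out[left, ::-1, :]
    return out


def response_locked_ci(
    trials: pd.DataFrame,
    noise: np.ndarray,
    field_selector: str = "target",
    max_lag: int = 45,
    stim_params: Optional[StimulusParams] = None,
    estimator: str = "mean",
    include: Optional[np.ndarray] = None,
    observer_id: Optional[int] = None,
) -> ClassificationImage:
    """Reverse-correlate noise with the response, backward from the RT.

    For each correct, non-lapsed trial the response frame is the frame
    containing ``rt_ms``; the cell (bar, lag) accumulates the noise
    sample ``lag`` frames earlier.  Lags reaching before the first frame
    (or a response frame beyond the movie, which can happen because the
    motor delay extends past the display) simply contribute nothing.

    estimator ``"mean"`` (default) returns mean noise contrast per cell;
    ``"correlation"`` divides by the per-cell sample SD, giving a
    dimensionless correlation-style weight.
    """
    fd = (stim_params or StimulusParams()).frame_duration_ms
    n_frames = noise.shape[-1]
    keep = (
        trials["correct"].astype(bool) & ~trials["lapsed"].astype(bool)
    ).to_numpy()
    if include is not None:
        keep &= np.asarray(include, dtype=bool)
    t = trials.loc[keep]
    nz = _mirrored_noise(noise[keep], t["target_side"].to_numpy(), field_selector)
    n_bars = nz.shape[1]
    # frame containing rt; the epsilon keeps exact frame-boundary RTs
    # (rt = k * frame_duration) in frame k despite float division
    resp_frame = np.floor(t["rt_ms"].to_numpy() / fd + 1e-9).astype(int)
    lags = np.arange(max_lag + 1)
    frame_idx = resp_frame[:, None] - lags[None, :]  # (n, L)
    ok = (frame_idx >= 0) & (frame_idx < n_frames)
    idx = np.clip(frame_idx, 0, n_frames - 1)
    # gather: (n, n_bars, L)
    samples = np.take_along_axis(nz, idx[:, None, :].repeat(n_bars, axis=1), axis=2)
    w = np.where(ok[:, None, :], samples, 0.0)
    counts = ok.sum(axis=0)  # (L,), same for every bar
    counts_full = np.broadcast_to(counts, (n_bars, max_lag + 1)).copy()
    with np.errstate(invalid="ignore"):
        weights = w.sum(axis=0) / np.where(counts > 0, counts, np.nan)
    if estimator == "correlation":
        sq = np.where(ok[:, None, :], samples**2, 0.0)
        with np.errstate(invalid="ignore"):
            var = sq.sum(axis=0) / np.where(counts > 1, counts, np.nan) - weights**2
        weights = weights / np.sqrt(np.maximum(var, 1e-30))
    elif estimator != "mean":
        raise ValueError("estimator must be 'mean' or 'correlation'")
    return ClassificationImage(
        weights=weights,
        counts=counts_full,
        field=field_selector,
        frame_duration_ms=fd,
        observer_id=observer_id,
    )


def impact_curves(ci: ClassificationImage) -> ImpactCurves:
    """Collapse a CI to center (bars 8, 9) and surround (bars 7, 10) traces."""
    if ci.weights.shape[0] <= max(FLANK_BARS):
        raise ValueError("CI does not span the central and flanking bars")
    center = ci.weights[list(CENTER_BARS)].mean(axis=0)
    surround = ci.weights[list(FLANK_BARS)].mean(axis=0)
    return ImpactCurves(lag_ms=ci.lag_ms.copy(), center=center, surround=surround)


def aggregate_impact(curves: Sequence[ImpactCurves]) -> ImpactCurves:
    """Across-observer mean and SEM of per-observer impact curves."""
    if not curves:
        raise ValueError("no curves to aggregate")
    lag = curves[0].lag_ms
    for c in curves:
        if not np.array_equal(c.lag_ms, lag):
            raise ValueError("impact curves are on different lag grids")
    C = np.stack([c.center for c in curves])
    S = np.stack([c.surround for c in curves])
    n = len(curves)
    sem = lambda a: (np.nanstd(a, axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros(a.shape[1])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        return ImpactCurves(
            lag_ms=lag.copy(),
            center=np.nanmean(C, axis=0),
            surround=np.nanmean(S, axis=0),
            center_sem=sem(C),
            surround_sem=sem(S),
        )


def epoch_cis(
    trials: pd.DataFrame,
    noise: np.ndarray,
    epochs_ms: Sequence[tuple[float, float]] = DEFAULT_EPOCHS_MS,
    by_condition: bool = True,
    **ci_kwargs,
) -> dict:
    """CIs for sliding epochs of the cue-to-response interval.

    Trials are keyed by (rt - cue onset); each trial enters every
    half-open epoch [lo, hi) containing its value (epochs overlap by
    design).  Uncued trials never enter.  Returns a dict keyed by
    ``(condition, (lo, hi))`` — or ``(lo, hi)`` when ``by_condition`` is
    False — mapping to ClassificationImages.
    """
    from .behavior import assign_conditions

    t = trials
    key = (t["rt_ms"] - t["cue_onset_ms"]).to_numpy()
    cued = t["cue_present"].to_numpy().astype(bool)
    cond = (
        assign_conditions(t).to_numpy()
        if by_condition and "condition" not in t.columns
        else (t["condition"].to_numpy() if by_condition else None)
    )
    out = {}
    for lo, hi in epochs_ms:
        in_epoch = cued & (key >= lo) & (key < hi)
        if by_condition:
            for c in ("valid", "invalid"):
                mask = in_epoch & (cond == c)
                out[(c, (lo, hi))] = response_locked_ci(
                    t, noise, include=mask, **ci_kwargs
                )
        else:
            out[(lo, hi)] = response_locked_ci(t, noise, include=in_epoch, **ci_kwargs)
    return out


def peak_impact(
    curve: ImpactCurves, window_ms: tuple[float, float] = (300.0, 400.0)
) -> dict:
    """Mean impact in the pre-response window (default 300-400 ms, inclusive).

    Returns {'center': value, 'surround': value} averaged over the curve
    samples whose lags fall in the window.
    """
    lo, hi = window_ms
    sel = (curve.lag_ms >= lo - 1e-9) & (curve.lag_ms <= hi + 1e-9)
    if not sel.any():
        raise ValueError("no curve samples inside the peak window")

    def _mean(a):
        a = a[np.isfinite(a)]
        return float(a.mean()) if a.size else float("nan")

    return {"center": _mean(curve.center[sel]), "surround": _mean(curve.surround[sel])}
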
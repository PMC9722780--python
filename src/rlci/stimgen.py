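"""Stimulus generation for the cued dynamic-noise contrast-detection task.

The display consists of two one-dimensional dynamic Gaussian noise fields
(16 vertical bars each, refreshed at 30 Hz for 4500 ms) placed left and
right of fixation.  A low-contrast target — an exponential contrast ramp —
is added to the two central bars of one field, starting at a random frame
within the first 500 ms.  On most trials a brief spatial cue is flashed,
usually (but not always) on the target side, at a random time 500–2000 ms
after the ramp begins.

All event times are stored in frames; one frame lasts 1000/30 ms.
Conversion to milliseconds happens only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LEFT",
    "RIGHT",
    "SIDES",
    "CENTER_BARS",
    "FLANK_BARS",
    "StimulusParams",
    "CueSpec",
    "StimulusMovie",
    "target_contrast",
    "make_noise_movie",
    "add_target",
    "schedule_cue",
    "make_trial_movie",
    "luminance_image",
]

LEFT, RIGHT = 0, 1
SIDES = ("left", "right")

# Bars are numbered 1..16 in the lab convention; the target occupies the
# central pair (8, 9) and the flanking pair is (7, 10).  Zero-based:
CENTER_BARS = (7, 8)
FLANK_BARS = (6, 9)


@dataclass(frozen=True)
class StimulusParams:
    """Geometry, timing and statistics of the noise/target/cue display.

    Contrast is dimensionless (Michelson-style, relative to the mean
    luminance); spatial quantities are in degrees of visual angle and
    converted to pixels at 0.018 deg/px.
    """

    n_bars: int = 16
    bar_width_deg: float = 0.29
    field_size_deg: float = 4.6
    frame_rate_hz: float = 30.0
    duration_ms: float = 4500.0
    noise_sd: float = 0.1
    ramp_slope: float = 0.05  # log10-contrast per frame
    ramp_offset: float = -3.0  # log10-contrast at ramp onset
    target_onset_range_ms: tuple[float, float] = (0.0, 500.0)
    cue_probability: float = 0.94
    cue_validity: float = 0.75
    cue_onset_range_ms: tuple[float, float] = (500.0, 2000.0)  # after target onset
    cue_duration_ms: float = 100.0
    pixel_size_deg: float = 0.018
    clip_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("cue_probability", "cue_validity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        frames = self.duration_ms / self.frame_duration_ms
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError(
                f"duration_ms={self.duration_ms} is not a whole number of frames"
            )
        # Field geometry must be consistent with an integer pixel grid.
        if abs(self.n_pixels * self.pixel_size_deg - self.field_size_deg) > (
            0.02 * self.field_size_deg
        ):
            raise ValueError("field_size_deg inconsistent with bar geometry")

    @property
    def frame_duration_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def n_frames(self) -> int:
        return round(self.duration_ms / self.frame_duration_ms)

    @property
    def pixels_per_bar(self) -> int:
        return round(self.bar_width_deg / self.pixel_size_deg)

    @property
    def n_pixels(self) -> int:
        return self.n_bars * self.pixels_per_bar

    def frames_to_ms(self, frames) -> np.ndarray | float:
        return np.asarray(frames) * self.frame_duration_ms


@dataclass(frozen=True)
class CueSpec:
    """A flashed spatial cue: which field, and its on/off frames."""

    side: int
    onset_frame: int
    offset_frame: int

    @property
    def side_name(self) -> str:
        return SIDES[self.side]


@dataclass
class StimulusMovie:
    """One trial's stimulus.

    ``noise`` holds the raw (pre-clipping) Gaussian contrast samples,
    shape (2 fields, n_bars, n_frames); ``contrast`` the displayed values
    after target addition and clipping.  The raw noise is kept because the
    reverse-correlation analysis uses it directly.
    """

    noise: np.ndarray
    contrast: np.ndarray
    target_side: Optional[int] = None
    target_onset_frame: Optional[int] = None
    cue: Optional[CueSpec] = None
    seed: Optional[int] = None
    params: StimulusParams = field(default_factory=StimulusParams)

    @property
    def n_frames(self) -> int:
        return self.noise.shape[-1]


def target_contrast(t, params: StimulusParams = StimulusParams()):
    """Target contrast ``10**min(slope*t + offset, 0)`` at frame(s) ``t``.

    ``t`` counts frames since the onset of target addition.  The ramp
    starts at 10**offset (0.001 with defaults) and saturates at 1.
    """
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("t must be non-negative (frames since target onset)")
    c = 10.0 ** np.minimum(params.ramp_slope * t + params.ramp_offset, 0.0)
    return c if c.ndim else float(c)


def make_noise_movie(
    params: StimulusParams, seed=None, rng: Optional[np.random.Generator] = None
) -> StimulusMovie:
    """Draw a fresh two-field dynamic noise movie (no target, no cue).

    Every bar x frame contrast is i.i.d. Normal(0, noise_sd) in both
    fields; the stored ``contrast`` is the clipped copy.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.noise_sd, size=(2, params.n_bars, params.n_frames))
    contrast = np.clip(noise, *params.clip_range)
    return StimulusMovie(noise=noise, contrast=contrast, seed=seed, params=params)


def _ramp_signal(onset_frame: int, params: StimulusParams) -> np.ndarray:
    """Additive target signal on one bar, length n_frames."""
    sig = np.zeros(params.n_frames)
    t = np.arange(params.n_frames - onset_frame)
    sig[onset_frame:] = target_contrast(t, params)
    return sig


def add_target(
    movie: StimulusMovie, side: int, onset_frame: int, params: Optional[StimulusParams] = None
) -> StimulusMovie:
    """Add the contrast ramp to the two central bars of one field.

    Returns a new movie whose ``contrast`` equals clip(noise + signal);
    ``noise`` is shared, not copied.
    """
    if side not in (LEFT, RIGHT):
        raise ValueError(f"side must be {LEFT} (left) or {RIGHT} (right)")
    params = params or movie.params
    max_onset = int(params.target_onset_range_ms[1] / params.frame_duration_ms)
    if not 0 <= onset_frame <= max_onset:
        raise ValueError(f"onset_frame must lie in [0, {max_onset}]")
    signal = _ramp_signal(onset_frame, params)
    total = movie.noise.copy()
    for b in CENTER_BARS:
        total[side, b, :] += signal
    contrast = np.clip(total, *params.clip_range)
    return StimulusMovie(
        noise=movie.noise,
        contrast=contrast,
        target_side=side,
        target_onset_frame=onset_frame,
        cue=movie.cue,
        seed=movie.seed,
        params=params,
    )


def _cue_frame_bounds(params: StimulusParams) -> tuple[int, int]:
    fd = params.frame_duration_ms
    lo = math.ceil(params.cue_onset_range_ms[0] / fd - 1e-9)
    hi = math.floor(params.cue_onset_range_ms[1] / fd + 1e-9)
    return lo, hi


def schedule_cue(
    rng: np.random.Generator,
    target_side: int,
    target_onset_frame: int,
    params: StimulusParams,
    mode: str = "schedule",
) -> Optional[CueSpec]:
    """Draw the cue for one trial.

    ``mode='schedule'`` follows the experiment's probabilities: a cue on
    94% of trials, on the target side in 75% of those, onset uniform in
    [500, 2000] ms after target onset (quantised to frames), 100 ms long.
    Modes ``'valid'``, ``'invalid'`` and ``'none'`` force the condition
    (cue timing stays randomised).
    """
    if mode == "none":
        return None
    if mode == "schedule":
        if rng.random() >= params.cue_probability:
            return None
        valid = rng.random() < params.cue_validity
    elif mode == "valid":
        valid = True
    elif mode == "invalid":
        valid = False
    else:
        raise ValueError(f"unknown cue mode {mode!r}")
    side = target_side if valid else 1 - target_side
    lo, hi = _cue_frame_bounds(params)
    onset = target_onset_frame + int(rng.integers(lo, hi + 1))
    dur = round(params.cue_duration_ms / params.frame_duration_ms)
    return CueSpec(side=side, onset_frame=onset, offset_frame=onset + dur)


def make_trial_movie(
    params: StimulusParams,
    rng: np.random.Generator | int | None = None,
    cue_mode: str = "schedule",
    target_side: Optional[int] = None,
    seed: Optional[int] = None,
) -> StimulusMovie:
    """Draw a complete trial: side, target onset, cue schedule, noise.

    The draw order (side, onset, cue, noise) is fixed so a trial is fully
    reproducible from its seed.
    """
    if not isinstance(rng, np.random.Generator):
        seed = rng if rng is not None else seed
        rng = np.random.default_rng(seed)
    if target_side is None:
        target_side = int(rng.integers(2))
    max_onset = int(params.target_onset_range_ms[1] / params.frame_duration_ms)
    onset = int(rng.integers(0, max_onset + 1))
    cue = schedule_cue(rng, target_side, onset, params, mode=cue_mode)
    movie = make_noise_movie(params, rng=rng)
    movie = add_target(movie, target_side, onset, params)
    movie.cue = cue
    movie.seed = seed
    return movie


def luminance_image(contrast: np.ndarray, mean_luminance: float) -> np.ndarray:
    """Optional rendering to luminance: L = L_mean * (1 + C)."""
    return mean_luminance * (1.0 + contrast)
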
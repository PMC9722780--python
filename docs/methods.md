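# Methods

## The task being emulated

A two-alternative contrast-detection task with spatial cueing.  The
display is a pair of one-dimensional dynamic noise fields left and right
of fixation, each made of 16 vertical bars (0.29 deg wide, 0.018 deg per
screen pixel, so 16 px per bar and 256 px per field).  Bar contrasts are
redrawn at 30 Hz from a zero-mean Gaussian with SD 0.1 (contrast units)
and clipped to [-1, +1]; a movie lasts 4500 ms (135 frames).  A target —
a contrast ramp

    C_target(t) = 10^min(0.05 t - 3, 0),   t in frames since ramp onset

— is added to the two central bars (bars 8 and 9) of one field, starting
at a uniformly random frame in the first 500 ms.  The ramp starts
invisible (10^-3) and saturates at contrast 1 after 60 frames (2 s).  A
100-ms cue is flashed on 94% of trials, on the target side in 75% of
those, at a uniform time 500–2000 ms after ramp onset.  The observer
reports the target side as fast as possible; the response deadline is
the movie's end.

One printed-geometry inconsistency: a 4.6-deg field at 0.018 deg/px is
255.6 px, while 16 bars x 0.29 deg gives 257.8 px.  We derive geometry
from the bars (16 px/bar, 256 px/field) and accept the ~0.2% mismatch
with the nominal field size.

Times are stored in frames internally (one frame = 1000/30 ms exactly)
and converted to ms only at I/O.  The ramp's clock starts at the onset
of target addition, not at movie onset: the ramp must begin at its
minimum when the addition begins, which is the only reading consistent
with a randomised onset.

## The model observer

Each field is passed through a space–time separable linear filter.  The
spatial profile is a difference of Gaussians,

    F_s(x) = exp(-x²/2σc²) − (σc²/σs²) exp(-x²/2σs²),

evaluated on the pixel grid and truncated at ±4σs (zero padding at the
field edges); the temporal profile is a biphasic gamma-cascade,

    F_t(t) = (1/n! − B (t/τ)²/(n+2)!) (t/τ)ⁿ e^(−t/τ),

sampled on the frame grid and truncated where |F_t| falls below 0.1% of
its peak (≈50 frames at the default τ).  n is fixed at 5 throughout.
The filtered response of the cued field is multiplied by a gain A ≥ 1
from the first frame starting at or after cue onset + 50 ms until the
end of the trial (sustained attention; the cue's own 100-ms duration is
irrelevant to the gain).  Momentary evidence compares the two fields'
rectified, spatially summed responses,

    ΔR(t) = Σx |R_left(x,t)| − Σx |R_right(x,t)|,

and the decision variable is the literal discrete sum

    S(T) = Σ_{t=1..T} ( γ^(T−t) ΔR(t) + ε_t ),  ε_t ~ N(0, σ_ε),

i.e. the leak applies to the evidence only while the internal noise
accumulates as an unleaked random walk.  That is what the printed
formula says, although the verbal description ("noisy leaky integral")
suggests the noise might decay too; a `leak_noise` switch implements the
alternative.  The first frame with S ≥ +b answers "left", S ≤ −b
"right"; the recorded RT adds a constant 250-ms motor delay.  No
crossing by the deadline is a lapse.  Lapsed and error trials are
excluded from every analysis, as the experiment excluded deadline and
error trials.

The filters carry no normalisation beyond their closed forms, so b and
σ_ε are in the evidence units that convention implies.  The shipped
profiles are the fitted parameter vectors: valid cue
[σc 2.94 px, σs 16.9 px, B 0.505, τ 2.38 frames, γ 0.207, b 356.0,
σ_ε 10.6, A 1.20] and invalid cue
[2.92, 15.7, 0.490, 2.41, 0.212, 353.5, 9.80, A ≡ 1].

### What this regime looks like

Under these units the steady-state evidence at full target contrast is
≈290 against a bound of 356: the drive alone never crosses, and the
internal random walk (σ_ε √T ≈ 120 late in the trial) supplies the rest.
Consequences, all measured by the test suite rather than assumed:

- the model's lapse rate is ~23% at the valid profile (forced valid
  cues) and larger without gain; errors (wrong side) are essentially
  absent because the negative bound is far away;
- the valid cue shortens the harmonic-mean RT by ~150 ms relative to
  invalid, and the effect is concentrated in the 500–1000 ms
  response-locked cue epochs;
- the response-locked center impact curve is biphasic — positive peak
  ≈0.003 contrast at ~500 ms before the response, negative lobe beyond
  ~700 ms — and the flanking bars carry the opposite signature;
- raising the gain monotonically shortens RT and removes lapses, but
  *lowers* the CI amplitude: with a weaker drive the crossing depends
  more on favourable stimulus noise, so noise has more impact per
  correct trial.  In a regime where the drive comfortably exceeds the
  bound the amplification of noise through the cued filter would win
  instead; which regime the original fits occupied cannot be determined
  from the printed values alone.

## Analyses

**Condition labels.**  A trial is `no_cue` if no cue appeared or the
response came at or before cue onset (a decision already made cannot
have used the cue; ties go to `no_cue`); otherwise `valid`/`invalid` by
cue-target agreement.

**RT tables.**  Central tendency is the harmonic mean n/Σ(1/RT), robust
to the long right tail.  Epoch tables bin cued trials by cue onset
(stimulus lock) or by rt − cue_onset (response lock) in 100-ms bins over
0–1500 ms, compute per-observer harmonic means first, then the
across-observer mean and SEM (n−1).  The per-epoch value is the mean of
per-observer harmonic means, not a pooled harmonic mean.

**Classification images.**  Only correct, non-lapsed trials enter.  The
response frame is the frame containing rt (lag 0); the CI cell
(bar, lag) is the mean raw pre-clipping noise sample lag frames earlier,
after mirroring left-target trials so both target sides share one
canonical orientation (the central pair maps onto itself).  Mean noise
contrast is used rather than a correlation coefficient: with i.i.d.
zero-mean noise the two differ by a constant scale, and contrast units
match the impact plots; a normalised estimator and a post-clipping
residual source are options.  Lags that reach before the movie's first
frame, or response frames past the movie (possible because the motor
delay extends beyond the display), contribute nothing; empty cells are
NaN, never zero.  Impact curves average bars 8–9 (center) and 7–10
(surround); grand averages weight observers equally.  Epoch CIs slide a
500-ms window in 250-ms steps over rt − cue_onset, half-open [lo, hi),
five epochs over 0–1500 ms; a trial enters every window containing its
value.  Peak impact is the mean of curve samples whose lags fall in
[300, 400] ms inclusive (frame lags 9–12).

**Fitting.**  The objective is the RMS difference between observed and
simulated center+surround impact curves over 0–1000 ms of backward lag.
Each objective evaluation re-simulates the decision stage on the
*observed session's own stimuli* — as in the original procedure, which
fitted each observer with the stimuli actually shown — and with a fixed
accumulator-noise draw reused across evaluations (common random
numbers), so the objective is a deterministic function of the
parameters.  By default the noise draw is the very one that generated
the session, which makes the objective exactly zero at the generating
parameters; an independent stream is available via `sync_noise=False`.

The objective's geometry forced one design choice.  Any parameter change
shifts every trial's RT slightly, which re-aligns the response-locked
sampling and re-randomises the CI estimate: the RMS objective is a
narrow (~±2%) funnel at the optimum sitting on a flat sampling-noise
floor (~2.4e-3 contrast at 2000 trials) with spurious shallow dips.
Plain simplex or coarse grids land in the floor.  One-parameter fits
therefore run in two stages: a smooth trial-level RT-discrepancy
surrogate (mean |ΔRT| plus a lapse-mismatch penalty — zero at the
optimum and monotone in drive-scaling parameters under common random
numbers) localises the basin by successive grid refinement, then the
impact-curve RMS is minimised on a fine grid inside it.  The reported
objective is always the impact-curve RMS.  Multi-parameter fits use
multi-start Nelder–Mead in log space for scale parameters (σc, σs, τ, b)
within documented bounds (σc ∈ [0.5, 20] px < σs ∈ [2, 60] px,
B ∈ [0, 1], τ ∈ [0.5, 10], γ ∈ [0, 0.95], A ∈ [0.5, 3]).  n stays fixed
at 5; invalid-condition fits pin A = 1.

With this machinery, one-parameter recoveries on a 2000-trial synthetic
valid-cue session return A, τ and σc within 0.1% of their generating
values; the identifiability limit is the search resolution, not the
sample size.  With an independent noise stream instead of the
synchronised one, the CI sampling floor at 2000 trials exceeds the
systematic effect of ±20% parameter changes, and single-session point
recovery is not statistically possible — a property of response-locked
reverse correlation at this trial count, documented here so that the
recovery results are read as an internal-consistency validation, not as
a statement about experimental identifiability.

## Problem sizes and seeds

Simulated sessions are vectorised (the per-trial spatial filtering runs
as small in-cache single-precision matrix products, keeping ~1e-7
relative accuracy on an O(10³) evidence scale; everything else is double
precision): 5000 trials simulate in ~4 s on one core.  The test suite
uses 15000 pooled trials for the CI-shape checks, 8000 scheduled trials
for the RT contrasts, and 2000-trial sessions for recovery, matching the
experiment's per-observer trial counts (3200–4960) in spirit while
keeping the default suite fast.  Every random quantity descends from an
explicit integer seed: sessions spawn one child seed per trial, and any
trial regenerates bit-identically from its stored seed (same draw
order: side, onset, cue, stimulus noise, accumulator noise).

## Limitations

- The synthetic observer *is* the model; passing tests show the
  analysis chain is correct and internally consistent, not that the
  model describes any human.  Real data would add sequential effects,
  RT-dependent motor variability, eye movements and learning, none of
  which are generated.
- The evidence units depend on unstated filter normalisation; the
  printed b and σ_ε are interpreted in the units of the bare closed
  forms.  The resulting near-threshold regime (high lapse rate,
  CI amplitude falling with gain) follows from that interpretation.
- The cue rectangles are event metadata only; they are never rendered
  into the contrast movies (they lie outside the noise fields and enter
  no analysis).  Luminance rendering L = L_mean(1 + C) is provided only
  as a utility.
- Human-subject statistics (ANOVAs, t tests, error rates) and figure-
  only quantities are out of scope.
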
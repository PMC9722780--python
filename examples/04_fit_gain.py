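"""Parameter recovery: refit the attentional gain from synthetic data.

A 2000-trial valid-cue session is generated at the fitted parameter
profile (gain A = 1.20).  The gain is then re-estimated by minimising
the RMS difference between the session's impact curves and re-simulated
ones, reusing the same stimuli and accumulator-noise draws across
evaluations (common random numbers).  The search first localises the
basin with a smooth trial-level RT discrepancy, then refines on the
impact-curve RMS.
"""

from rlci import StimulusParams, simulate_session, valid_profile
from rlci.ci import impact_curves, response_locked_ci
from rlci.fitting import FitSpec, fit

params = StimulusParams()
truth = valid_profile()
sess = simulate_session(2000, params, truth, seed=101, cue_mode="valid")
observed = impact_curves(
    response_locked_ci(sess.trials, sess.noise, "target", max_lag=30,
                       stim_params=params)
)

res = fit(
    observed,
    FitSpec(free_params=["gain"], fixed_params=truth, session=sess),
)
est = res.estimates["gain"]
print(f"generating gain: {truth.gain:.3f}")
print(f"recovered gain:  {est:.4f}  ({100 * (est / truth.gain - 1):+.2f}%)")
print(f"objective (impact-curve RMS): {res.rms:.2e} after "
      f"{res.n_evaluations} evaluations")
print("An estimate within a few percent of 1.20 shows the whole chain -")
print("stimulus, filtering, gain, accumulation, CI - is internally consistent.")
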
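"""Shared fixtures: parameter profiles and cached simulated sessions."""

from __future__ import annotations

import numpy as np
import pytest

from rlci import (
    StimulusParams,
    simulate_session,
    valid_profile,
)
from rlci.behavior import assign_conditions
from rlci.ci import impact_curves, response_locked_ci


@pytest.fixture(scope="session")
def stim_params() -> StimulusParams:
    return StimulusParams()


@pytest.fixture(scope="session")
def short_params() -> StimulusParams:
    """A 1.5-s variant of the display for cheap unit tests."""
    return StimulusParams(duration_ms=1500.0, cue_onset_range_ms=(100.0, 400.0))


@pytest.fixture(scope="session")
def model_params():
    return valid_profile()


@pytest.fixture(scope="session")
def valid_session_2000(stim_params, model_params):
    """2000 forced-valid-cue trials at the fitted valid-cue profile."""
    return simulate_session(2000, stim_params, model_params, seed=314159, cue_mode="valid")


@pytest.fixture(scope="session")
def valid_observed_impact(valid_session_2000, stim_params):
    ci = response_locked_ci(
        valid_session_2000.trials,
        valid_session_2000.noise,
        "target",
        max_lag=30,
        stim_params=stim_params,
    )
    return impact_curves(ci)


@pytest.fixture(scope="session")
def pooled_valid_ci(stim_params, model_params):
    """Target-field CI pooled over 15000 forced-valid trials (3 batches),
    plus the per-side subsets used by the mirroring check."""
    W_sum = C_sum = None
    Wl = Cl = Wr = Cr = None
    for seed in (271828, 662607, 141421):
        s = simulate_session(5000, stim_params, model_params, seed=seed, cue_mode="valid")
        for subset, tag in ((None, "all"), (0, "left"), (1, "right")):
            include = (
                None
                if subset is None
                else (s.trials["target_side"] == subset).to_numpy()
            )
            ci = response_locked_ci(
                s.trials, s.noise, "target", max_lag=45,
                stim_params=stim_params, include=include,
            )
            w = np.nan_to_num(ci.weights) * ci.counts
            if tag == "all":
                W_sum = w if W_sum is None else W_sum + w
                C_sum = ci.counts if C_sum is None else C_sum + ci.counts
            elif tag == "left":
                Wl = w if Wl is None else Wl + w
                Cl = ci.counts if Cl is None else Cl + ci.counts
            else:
                Wr = w if Wr is None else Wr + w
                Cr = ci.counts if Cr is None else Cr + ci.counts
    out = {
        "weights": W_sum / np.maximum(C_sum, 1),
        "counts": C_sum,
        "left": Wl / np.maximum(Cl, 1),
        "left_counts": Cl,
        "right": Wr / np.maximum(Cr, 1),
        "right_counts": Cr,
        "frame_duration_ms": stim_params.frame_duration_ms,
    }
    return out


@pytest.fixture(scope="session")
def recovery_fits(valid_session_2000, valid_observed_impact):
    """One-parameter refits of gain, tau and sigma_c on the synthetic
    valid-cue session, with common random numbers."""
    from rlci.fitting import FitSpec, fit

    results = {}
    for name in ("gain", "tau", "sigma_c"):
        results[name] = fit(
            valid_observed_impact,
            FitSpec(
                free_params=[name],
                fixed_params=valid_session_2000.model_params,
                session=valid_session_2000,
            ),
        )
    return results


@pytest.fixture(scope="session")
def scheduled_trials_8000(stim_params, model_params):
    """Trial table (no stimuli) from a big scheduled-cue session."""
    s = simulate_session(8000, stim_params, model_params, seed=977, cue_mode="schedule")
    t = s.trials.copy()
    t["condition"] = assign_conditions(t)
    return t
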
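"""Shared fixtures: one small synthetic session and one fitted model.

The session-scoped model fit is reused by every test that needs a fitted
two-area factor model but does not test fitting accuracy itself.
"""

import numpy as np
import pytest

from crossarea import dlag, preprocess, synth


@pytest.fixture(scope="session")
def small_session():
    cfg = synth.SyntheticSessionConfig(
        n_trials=40, n_channels_A=20, n_channels_B=20, seed=3)
    return synth.generate_session(cfg)


def _prep(session, spikes, smooth_sd=None, bin_width=20.0):
    binned = preprocess.bin_spikes(spikes, session.trial_table,
                                   bin_width=bin_width)
    return preprocess.normalize_activity(preprocess.filter_channels(binned),
                                         smooth_sd=smooth_sd)


@pytest.fixture(scope="session")
def small_prepped(small_session):
    za = _prep(small_session, small_session.spike_times["A"])
    zb = _prep(small_session, small_session.spike_times["B"])
    return za, zb


@pytest.fixture(scope="session")
def small_model(small_prepped):
    za, zb = small_prepped
    return dlag.fit_dlag(za, zb, dims=(5, 5, 5), max_iter=15, tol=1e-8)


@pytest.fixture(scope="session")
def small_latents(small_model, small_prepped):
    za, zb = small_prepped
    return dlag.infer_latents(small_model, za, zb, return_cov=True)
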
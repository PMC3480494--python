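"""Shared fixtures: small synthetic sessions processed once per test run."""

from __future__ import annotations

import numpy as np
import pytest

import ecodec as ec


@pytest.fixture(scope="session")
def small_spec() -> ec.SyntheticSpec:
    """Compact subject-B-shaped study: same geometry, fewer trials."""
    spec = ec.make_subject_spec("B", seed=11)
    spec.n_trials = 30
    return spec


@pytest.fixture(scope="session")
def small_session(small_spec):
    session, gt = ec.generate_session(small_spec, seed=11)
    return session, gt


@pytest.fixture(scope="session")
def small_pipeline(small_session):
    """Sources, design matrix, EMG envelopes and trials for the small session."""
    session, gt = small_session
    cfg = ec.default_config().replace(fit_row_decimation=5, k_folds=5)
    sources = ec.extract_band_sources(session, cfg)
    design = ec.build_design_matrix(sources, cfg)
    emg = ec.emg_envelope(session.emg, session.rate_emg, cfg, session.muscle_names)
    trials = ec.extract_trials(session.events, design, cfg.trial_window)
    return {"session": session, "gt": gt, "cfg": cfg, "sources": sources,
            "design": design, "emg": emg, "trials": trials}


@pytest.fixture(scope="session")
def small_cv(small_pipeline):
    p = small_pipeline
    report = ec.cross_validate(p["design"], p["emg"], p["trials"], p["cfg"], seed=3)
    return report


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
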
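"""Shared fixtures: small synthetic sessions generated once per run."""

import warnings

import pytest

import curvesprint as cs

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def session2():
    """Two-subject session with default (noisy) study conditions."""
    return cs.generate_session(cs.SynthConfig(n_subjects=2, seed=1))


@pytest.fixture(scope="session")
def results2(session2):
    trials, _ = session2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.process_session(trials)


@pytest.fixture(scope="session")
def noiseless2():
    """Two-subject noise-free session (tight recovery tolerances apply)."""
    cfg = cs.SynthConfig(
        n_subjects=2, seed=3, noise_force=0.0, noise_marker=0.0, noise_radar=0.0
    )
    trials, gt = cs.generate_session(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = cs.process_session(trials)
    return trials, gt, results


def match_stance(gt_stances, trial_id, t_hs):
    """Ground-truth stance record nearest in heel-strike time."""
    cand = gt_stances[gt_stances.trial_id == trial_id]
    return cand.loc[(cand.t_hs - t_hs).abs().idxmin()]
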
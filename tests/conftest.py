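"""Shared fixtures: reduced montages and cached synthetic sessions.

Feature extraction on the full 30-channel montage is expensive, so most
statistical tests run on reduced montages drawn from the standard channel
list (the paradigm itself -- 20 trials x 73 s at 250 Hz -- is never
scaled down). Session-scoped fixtures cache generated cohorts.
"""

from __future__ import annotations

import numpy as np
import pytest

from attnfuse.fusion_classify import build_design_matrix
from attnfuse.io_preprocess import bandpass_fir, reject_artifacts, segment_epochs
from attnfuse.synthetic import EffectSpec, ParadigmSpec, generate_subject

#: 10-channel montage: 8 effect-affected (prefrontal + occipital) plus two
#: unaffected midline controls.
MONTAGE10 = ("Fp1", "Fp2", "F3", "F4", "Fz", "O1", "Oz", "O2", "Cz", "Pz")
#: 6-channel montage for the cheapest cohort-level simulations.
MONTAGE6 = ("Fp1", "Fp2", "F3", "O1", "Oz", "Cz")

NULL_EFFECT = EffectSpec(band_gain={"theta": 1.0, "alpha": 1.0, "beta": 1.0})
STRONG_EFFECT = EffectSpec(band_gain={"theta": 0.5, "alpha": 0.5, "beta": 0.5})


def session_to_epochs(session, low=0.5, high=50.0, amp=100.0):
    rec = bandpass_fir(session.recording, low, high)
    es = segment_epochs(rec, subject_id=session.subject_id)
    return reject_artifacts(es, amp_threshold=amp)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_session():
    """One default-spec 30-channel session (seed 7)."""
    return generate_subject(seed=7)


@pytest.fixture(scope="session")
def small_epochset():
    """Clean epoch set from a 6-channel strong-effect session."""
    session = generate_subject(ParadigmSpec(channels=MONTAGE6),
                               STRONG_EFFECT, seed=11)
    return session_to_epochs(session)


@pytest.fixture(scope="session")
def small_design(small_epochset):
    """Full 123-feature design matrix on the 6-channel montage."""
    return build_design_matrix(small_epochset, fs=250.0,
                               channel_names=MONTAGE6)
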
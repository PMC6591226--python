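"""Shared fixtures: small synthetic cohorts and regime shortcuts.

Everything is generated at test time from seeds; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppgmiles.io import load_regime
from ppgmiles.segment import PPGRecording
from ppgmiles.synth import CohortParams, synth_recording


def clean_cohort_params(**over) -> CohortParams:
    """A deterministic, noise-free single-subject regime for oracle tests."""
    defaults = dict(
        n_subjects=1, hr_mean=72.0, hr_sd=0.0, recording_duration=60.0,
        noise_sd=0.0, beat_to_beat_cv=0.0, between_subject_cv=0.0,
        ibi_cv=0.0, resp_amplitude_mod=0.0, resp_baseline_mod=0.0,
        irregular_beat_prob=0.0)
    defaults.update(over)
    return CohortParams(**defaults)


@pytest.fixture(scope="session")
def paper_regime():
    healthy, ohcm, seed = load_regime("paper_regime")
    return healthy, ohcm, seed


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free 60 s healthy recording at HR 72 with its ground truth."""
    srec, gt = synth_recording(clean_cohort_params(), 1)
    return PPGRecording.from_synth(srec), gt


@pytest.fixture(scope="session")
def noisy_recording():
    """A default (noisy, modulated) 60 s healthy recording."""
    srec, gt = synth_recording(CohortParams(recording_duration=60.0), 42)
    return PPGRecording.from_synth(srec), gt


def match_onsets(beats, gt, fs):
    """Pair detected beats with ground-truth beats by nearest onset.

    Returns (gt_index, beat) pairs whose onsets agree within 2 samples.
    """
    det = np.array([b.onset_index for b in beats]) / fs
    pairs = []
    for i, t0 in enumerate(gt.beat_onset_times):
        j = int(np.argmin(np.abs(det - t0)))
        if abs(det[j] - t0) * fs <= 2:
            pairs.append((i, beats[j]))
    return pairs
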
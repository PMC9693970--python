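import dataclasses

import numpy as np
import pytest

from gaitmark import (
    GaitProfile,
    default_hs_profile,
    default_pd_profile,
    extract_cycles,
    simulate_subject,
)


@pytest.fixture
def hs_profile():
    return default_hs_profile()


@pytest.fixture
def pd_profile():
    return default_pd_profile()


@pytest.fixture
def clean_profile():
    """Noise-free, low-variability profile for exact-recovery tests."""
    return GaitProfile(
        stride_time_mean=1.0,
        stride_time_cv=0.0,
        stance_fraction_mean=0.6,
        stance_fraction_sd=0.0,
        double_support_fraction_mean=0.1,
        double_support_fraction_sd=0.0,
        sensor_noise_sd=0.0,
    )


@pytest.fixture
def quick_subject(hs_profile):
    """A short simulated trial plus its ground truth and metadata."""
    return simulate_subject(hs_profile, duration=20.0, sampling_rate=100.0, seed=7)


@pytest.fixture
def quick_cycleset(quick_subject):
    rec, _, _ = quick_subject
    return extract_cycles(rec)


def gt_boundary_indices(truth, sampling_rate):
    """Expected boundary sample indices of one ground-truth cycle."""
    return [int(np.ceil(b * sampling_rate - 1e-9)) for b in truth.phase_bounds()]


def max_boundary_error(cycleset, truths, sampling_rate):
    """Worst |detected - truth| over all phase boundaries, in samples.

    Cycles are matched by nearest start; unmatched ground-truth cycles
    count as an infinite error.
    """
    worst = 0
    for t in truths:
        gt = gt_boundary_indices(t, sampling_rate)
        if not cycleset.accepted:
            return np.inf
        best = min(cycleset.accepted, key=lambda c: abs(c.start - gt[0]))
        if abs(best.start - gt[0]) > sampling_rate:  # no plausible match
            return np.inf
        det = [ph[1] for ph in best.phases] + [best.end]
        worst = max(worst, max(abs(a - b) for a, b in zip(det, gt)))
    return worst
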
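import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gaitmark import (
    GaitProfile,
    Phase,
    cycle_parameters,
    detect_contact,
    differential_grf,
    extract_cycles,
    label_phases,
    reject_outlier_cycles,
    segment_cycles,
    simulate_subject,
)
from gaitmark.core import InsoleRecording
from gaitmark.segmentation import (
    ContactSeries,
    GaitCycle,
    InsufficientGaitError,
    NoGaitError,
    _merge_short_runs,
    _rle,
)
from conftest import max_boundary_error


def _recording_from_totals(left_total, right_total, fs=100.0):
    n = len(left_total)
    left = np.zeros((n, 8))
    right = np.zeros((n, 8))
    left[:, 0] = left_total
    right[:, 0] = right_total
    return InsoleRecording(
        subject_id="T",
        time=np.arange(n) / fs,
        left_sensors=left,
        right_sensors=right,
        left_total=np.asarray(left_total, float),
        right_total=np.asarray(right_total, float),
        sampling_rate=fs,
    )


# --- differential GRF -------------------------------------------------------


def test_delta_zero_when_symmetric(quick_subject):
    rec, _, _ = quick_subject
    rec2 = _recording_from_totals(rec.left_total, rec.left_total)
    assert np.all(differential_grf(rec2).delta == 0.0)


def test_delta_constant_offset():
    rec = _recording_from_totals(np.zeros(10), np.full(10, 700.0))
    assert np.all(differential_grf(rec).delta == 700.0)


def test_delta_antisymmetric_under_foot_swap(quick_subject):
    rec, _, _ = quick_subject
    np.testing.assert_array_equal(
        differential_grf(rec.swapped_feet()).delta, -differential_grf(rec).delta
    )


# --- contact detection ------------------------------------------------------


def test_square_wave_contact():
    left = np.tile([0.0] * 50 + [500.0] * 50, 4)
    right = np.tile([500.0] * 50 + [0.0] * 50, 4)
    rec = _recording_from_totals(left, right)
    contact = detect_contact(rec, contact_threshold=20.0)
    np.testing.assert_array_equal(contact.left, left > 0)
    np.testing.assert_array_equal(contact.right, right > 0)


def test_single_sample_spike_debounced():
    left = np.zeros(200)
    left[:80] = 500.0
    left[120] = 500.0  # 1-sample chatter during swing
    right = np.full(200, 500.0)
    rec = _recording_from_totals(left, right)
    contact = detect_contact(rec, contact_threshold=20.0, min_phase_duration=0.05)
    assert not contact.left[120]


def test_no_gait_error():
    rec = _recording_from_totals(np.full(50, 5.0), np.full(50, 500.0))
    with pytest.raises(NoGaitError):
        detect_contact(rec, contact_threshold=20.0)


@given(
    mask=hst.lists(hst.booleans(), min_size=1, max_size=120),
    min_len=hst.integers(min_value=1, max_value=6),
)
@settings(max_examples=200, deadline=None)
def test_debounce_removes_all_short_interior_runs(mask, min_len):
    out = _merge_short_runs(np.array(mask, dtype=bool), min_len)
    starts, lengths, _ = _rle(out)
    assert len(lengths) == 1 or np.all(lengths >= min_len)


# --- phase labelling --------------------------------------------------------


def test_all_dls_when_both_loaded():
    cs = ContactSeries(np.ones(10, bool), np.ones(10, bool), 20.0, 0.05, 100.0)
    assert np.all(label_phases(cs) == Phase.DLS)


@given(
    left=hst.lists(hst.booleans(), min_size=1, max_size=80),
    right=hst.integers(min_value=0, max_value=2**80 - 1),
)
@settings(max_examples=200, deadline=None)
def test_label_truth_table_oracle(left, right):
    n = len(left)
    left = np.array(left, bool)
    right = np.array([(right >> i) & 1 for i in range(n)], bool)
    cs = ContactSeries(left, right, 20.0, 0.0, 100.0)
    labels = label_phases(cs)
    for i in range(n):
        if left[i] and right[i]:
            expected = Phase.DLS
        elif left[i]:
            expected = Phase.SLS_L
        elif right[i]:
            expected = Phase.SLS_R
        else:
            expected = Phase.AIRBORNE
        assert labels[i] == expected


# --- cycle segmentation -----------------------------------------------------


def _labels_from_pattern(pattern, reps=1):
    out = []
    for phase, n in pattern * reps:
        out.extend([int(phase)] * n)
    return np.array(out, dtype=np.int8)


CANON = [(Phase.DLS, 10), (Phase.SLS_R, 40), (Phase.DLS, 10), (Phase.SLS_L, 40)]


def test_periodic_signal_equal_durations():
    labels = _labels_from_pattern(CANON, reps=6)
    cycles, dropped = segment_cycles(labels, 100.0)
    assert len(cycles) == 5  # last cycle lacks its closing DLS onset
    assert not dropped
    durations = {c.stride_duration for c in cycles}
    assert durations == {1.0}


def test_incomplete_pattern_no_cycles():
    # right foot never leaves the ground: DLS <-> SLS-L only
    labels = _labels_from_pattern([(Phase.DLS, 20), (Phase.SLS_L, 30)], reps=5)
    with pytest.raises(InsufficientGaitError):
        segment_cycles(labels, 100.0)


def test_airborne_cycle_dropped():
    broken = [(Phase.DLS, 10), (Phase.SLS_R, 20), (Phase.AIRBORNE, 5),
              (Phase.SLS_R, 15), (Phase.DLS, 10), (Phase.SLS_L, 40)]
    labels = np.concatenate(
        [_labels_from_pattern(CANON), _labels_from_pattern(broken),
         _labels_from_pattern(CANON, reps=2)]
    )
    cycles, dropped = segment_cycles(labels, 100.0)
    assert len(dropped) == 1
    assert dropped[0].reason == "airborne gap"
    assert len(cycles) == 2


def test_noise_free_synthetic_recovery(clean_profile):
    rec, truths, _ = simulate_subject(clean_profile, duration=25, seed=11)
    cs = extract_cycles(rec)
    assert len(cs.accepted) == len(truths)
    assert max_boundary_error(cs, truths, rec.sampling_rate) <= 1


def test_feet_swap_mirrors_everything(hs_profile):
    rec, _, _ = simulate_subject(hs_profile, duration=20, seed=13)
    cs_r = extract_cycles(rec, anchor="right")
    cs_l = extract_cycles(rec.swapped_feet(), anchor="left")
    assert len(cs_l.accepted) == len(cs_r.accepted)
    for a, b in zip(cs_r.accepted, cs_l.accepted):
        assert (a.start, a.end) == (b.start, b.end)
        pa, pb = cycle_parameters(a), cycle_parameters(b)
        assert pa["left_stance_s"] == pytest.approx(pb["right_stance_s"])
        assert pa["sls_l_s"] == pytest.approx(pb["sls_r_s"])
        assert pa["left_step_s"] == pytest.approx(pb["right_step_s"])
        assert pa["double_support_s"] == pytest.approx(pb["double_support_s"])


# --- cycle parameters -------------------------------------------------------


def test_hand_computed_parameters():
    labels = _labels_from_pattern(CANON, reps=2)
    cycles, _ = segment_cycles(labels, 100.0)
    p = cycle_parameters(cycles[0])
    assert p["stride_s"] == pytest.approx(1.0)
    assert p["left_stance_s"] == pytest.approx(0.6)
    assert p["left_stance_pct"] == pytest.approx(60.0)
    assert p["left_swing_s"] == pytest.approx(0.4)
    assert p["left_swing_pct"] == pytest.approx(40.0)
    assert p["double_support_s"] == pytest.approx(0.2)
    assert p["double_support_pct"] == pytest.approx(20.0)
    assert p["sls_r_s"] == pytest.approx(0.4)
    # brute-force per-sample counting oracle
    span = labels[:100]
    left_loaded = np.isin(span, [Phase.DLS, Phase.SLS_L])
    assert p["left_stance_s"] == pytest.approx(left_loaded.sum() / 100.0)
    right_loaded = np.isin(span, [Phase.DLS, Phase.SLS_R])
    assert p["right_stance_s"] == pytest.approx(right_loaded.sum() / 100.0)
    # step durations: right IC at cycle start, left IC at DLS2 onset
    assert p["left_step_s"] == pytest.approx(0.5)
    assert p["right_step_s"] == pytest.approx(0.5)


def test_stance_swing_complement(quick_cycleset):
    for c in quick_cycleset.accepted:
        p = cycle_parameters(c)
        assert p["left_stance_pct"] + p["left_swing_pct"] == pytest.approx(100.0)
        assert p["right_stance_pct"] + p["right_swing_pct"] == pytest.approx(100.0)


def test_symmetric_cycle_equal_sides():
    labels = _labels_from_pattern(CANON, reps=2)
    cycles, _ = segment_cycles(labels, 100.0)
    p = cycle_parameters(cycles[0])
    assert p["left_stance_s"] == pytest.approx(p["right_stance_s"])
    assert p["left_swing_s"] == pytest.approx(p["right_swing_s"])


# --- outlier rejection ------------------------------------------------------


def _cycle_of_duration(d, fs=1000.0):
    n = int(round(d * fs))
    return GaitCycle(start=0, end=n, phases=[(Phase.DLS, 0, n)], sampling_rate=fs)


def test_outlier_rule_arithmetic():
    cycles = [_cycle_of_duration(1.0) for _ in range(9)] + [_cycle_of_duration(2.0)]
    cs = reject_outlier_cycles(cycles)
    assert len(cs.rejected) == 1
    assert cs.rejected[0].cycle.stride_duration == pytest.approx(2.0)
    assert len(cs.accepted) == 9
    assert cs.sl_mean == pytest.approx(1.1)
    assert cs.sl_sd == pytest.approx(0.31622776, abs=1e-6)
    assert cs.sl_mean + 2 * cs.sl_sd == pytest.approx(1.73245553, abs=1e-6)


def test_no_rejection_when_all_equal():
    cycles = [_cycle_of_duration(1.0) for _ in range(5)]
    cs = reject_outlier_cycles(cycles)
    assert not cs.rejected


def test_rule_is_one_sided():
    cycles = [_cycle_of_duration(1.0) for _ in range(9)] + [_cycle_of_duration(0.2)]
    cs = reject_outlier_cycles(cycles)
    assert not cs.rejected  # short cycles never rejected


def test_single_cycle_passes_through():
    cs = reject_outlier_cycles([_cycle_of_duration(1.0)])
    assert len(cs.accepted) == 1 and not cs.rejected


def test_extreme_cycle_rejected_under_recomputed_bound():
    base = [_cycle_of_duration(1.0 + 0.01 * i) for i in range(10)]
    durations = np.array([c.stride_duration for c in base + [_cycle_of_duration(5.0)]])
    bound = durations.mean() + 2 * durations.std(ddof=1)
    cs = reject_outlier_cycles(base + [_cycle_of_duration(5.0)])
    assert (5.0 > bound) == any(
        r.cycle.stride_duration == pytest.approx(5.0) for r in cs.rejected
    )
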
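"""Preprocessing-chain checks: filter, reference, rejection, floor, averaging,
spherical-spline interpolation (with an independent oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpfield.dataset import EpochSet
from erpfield.headmodel import dipole_gain
from erpfield.preprocess import (
    average_subjects,
    average_trials,
    bandpass,
    enforce_trial_floor,
    preprocess_subject,
    reject_amplitude,
    rereference_average,
)
from erpfield.spline import interpolation_matrix, spherical_spline_interpolate


# -- band-pass filter -------------------------------------------------------

def _sine(freq, fs=500.0, seconds=4.0):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t)


def test_bandpass_preserves_passband_and_rejects_stopband():
    fs = 500.0
    inband = bandpass(_sine(10.0), fs)
    mid = slice(500, -500)  # avoid edge transients
    assert np.abs(inband[mid]).max() == pytest.approx(1.0, rel=0.05)
    hum = bandpass(_sine(50.0), fs)
    assert np.abs(hum[mid]).max() < 0.1  # >= 90% attenuation
    dc = bandpass(np.ones(2000), fs)
    assert np.abs(dc[mid]).mean() < 1e-3


def test_bandpass_zero_phase():
    """Forward-backward filtering leaves a mid-band burst's peak in place."""
    fs = 500.0
    t = np.arange(2000) / fs
    burst = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2) * np.sin(2 * np.pi * 10 * t)
    out = bandpass(burst, fs)
    assert abs(np.argmax(np.abs(out)) - np.argmax(np.abs(burst))) <= 2


def test_bandpass_nyquist_guard():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(np.zeros(100), sampling_rate=50.0, high_hz=30.0)


# -- average reference ------------------------------------------------------

def test_average_reference_examples_and_idempotence(rng):
    assert np.allclose(rereference_average(np.array([5.0, 5.0, 5.0])), 0.0)
    assert np.allclose(
        rereference_average(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0]
    )
    x = rng.normal(size=(16, 40))
    once = rereference_average(x)
    assert np.allclose(rereference_average(once), once)
    # inter-channel differences unchanged
    assert np.allclose(once[3] - once[7], x[3] - x[7])
    with pytest.raises(ValueError):
        rereference_average(np.array([1.0]))


# -- amplitude rejection ----------------------------------------------------

def _epochs_from(trials):
    """trials: list of (channels, samples) arrays."""
    data = np.stack(trials, axis=2)
    return EpochSet(
        data=data, sampling_rate=500.0, epoch_window=(-20.0, (data.shape[1] - 10) * 2)
    )


def test_rejection_threshold_semantics():
    quiet = np.full((4, 30), 10.0)
    near = np.full((4, 30), 64.9)
    spike = np.full((4, 30), 10.0)
    spike[2, 17] = 70.0
    es = reject_amplitude(_epochs_from([quiet, near, spike, np.zeros((4, 30))]))
    assert list(es.trial_flags) == [
        "accepted", "accepted", "amplitude_rejected", "accepted",
    ]


def test_rejection_preserves_prior_exclusions():
    loud = np.full((4, 30), 100.0)
    es = _epochs_from([loud, loud])
    es.trial_flags[0] = "emg_excluded"
    out = reject_amplitude(es)
    assert list(out.trial_flags) == ["emg_excluded", "amplitude_rejected"]


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_rejection_monotone_in_threshold(seed):
    """Raising the threshold never rejects more trials."""
    data = np.random.default_rng(seed).normal(scale=40.0, size=(6, 20, 12))
    es = EpochSet(data=data, sampling_rate=500.0, epoch_window=(-10.0, 30.0))
    n_lo = (reject_amplitude(es, 40.0).trial_flags == "accepted").sum()
    n_hi = (reject_amplitude(es, 65.0).trial_flags == "accepted").sum()
    assert n_hi >= n_lo


# -- trial floor ------------------------------------------------------------

@pytest.mark.parametrize("n_accepted,usable", [(79, False), (80, True)])
def test_trial_floor_boundary(n_accepted, usable):
    data = np.zeros((4, 30, 100))
    es = EpochSet(data=data, sampling_rate=500.0, epoch_window=(-20.0, 40.0))
    es.trial_flags[n_accepted:] = "error_trial"
    report = enforce_trial_floor(es, 80)
    assert report.n_accepted == n_accepted
    assert report.usable is usable


# -- averaging --------------------------------------------------------------

def test_trial_and_subject_averaging(rng):
    x = rng.normal(size=(6, 30))
    es = _epochs_from([x, x])
    erp = average_trials(es)
    assert np.allclose(erp.data, x)
    assert erp.n_trials == 2
    es2 = _epochs_from([x, -x])
    assert np.allclose(average_trials(es2).data, 0.0)
    # excluded trials do not enter the average
    es3 = _epochs_from([x, 100.0 * x])
    es3.trial_flags[1] = "amplitude_rejected"
    assert np.allclose(average_trials(es3).data, x)
    with pytest.raises(ValueError):
        es4 = _epochs_from([x])
        es4.trial_flags[0] = "error_trial"
        average_trials(es4)


def test_group_average_matches_summation_oracle(rng):
    erps = [average_trials(_epochs_from([rng.normal(size=(6, 30))])) for _ in range(7)]
    group = average_subjects(erps)
    brute = sum(e.data for e in erps) / 7.0  # independent summation oracle
    assert np.allclose(group.data, brute, atol=1e-12)
    assert group.level == "group"


# -- spherical-spline interpolation -----------------------------------------

def test_spline_reproduces_constant_map(montage110):
    data = np.full((110, 5), 3.25)
    out = spherical_spline_interpolate(data, [17], montage110)
    assert np.allclose(out[17], 3.25, atol=1e-6)
    # untouched channels exactly preserved
    assert np.array_equal(out[:17], data[:17])


def test_spline_empty_bads_is_identity(montage110, rng):
    data = rng.normal(size=(110, 7))
    assert np.array_equal(
        spherical_spline_interpolate(data, [], montage110), data
    )


def test_spline_needs_enough_good_channels(montage32):
    with pytest.raises(ValueError, match="good channels"):
        spherical_spline_interpolate(
            np.zeros((32, 3)), list(range(28)), montage32
        )


def test_spline_recovers_dipole_map_within_ten_percent(head, montage110, rng):
    """Forward-modeled maps are the oracle: deleting one channel and
    reconstructing it lands within 10% (median over sources)."""
    errors = []
    for _ in range(25):
        direction = rng.normal(size=3)
        direction[2] = abs(direction[2])
        direction /= np.linalg.norm(direction)
        g = dipole_gain(head, 0.7 * direction, montage110.positions)[0]
        true_map = direction @ g
        ch = int(rng.integers(110))
        rec = spherical_spline_interpolate(true_map[:, None], [ch], montage110)
        scale = np.abs(true_map).max()
        errors.append(abs(rec[ch, 0] - true_map[ch]) / scale)
    assert np.median(errors) <= 0.10


def test_spline_matches_mne_interpolation_matrix(montage110):
    """Independent oracle: MNE's spherical-spline operator produces the same
    reconstruction on smooth maps."""
    pytest.importorskip("mne")
    from mne.channels.interpolation import _make_interpolation_matrix

    bad = [5, 60]
    good = [i for i in range(110) if i not in bad]
    ours = interpolation_matrix(
        montage110.positions[good], montage110.positions[bad]
    )
    theirs = _make_interpolation_matrix(
        montage110.positions[good], montage110.positions[bad], alpha=1e-5
    )
    rng = np.random.default_rng(3)
    # smooth test maps: random superficial dipole projections
    head = None
    from erpfield.headmodel import HeadModel

    head = HeadModel()
    for _ in range(5):
        d = rng.normal(size=3)
        d[2] = abs(d[2])
        d /= np.linalg.norm(d)
        v = d @ dipole_gain(head, 0.6 * d, montage110.positions)[0]
        mine = ours @ v[good]
        ref = theirs @ v[good]
        assert np.allclose(mine, ref, atol=0.02 * np.abs(v).max())


# -- full chain --------------------------------------------------------------

def test_preprocess_subject_order_and_reference(montage32, rng):
    data = rng.normal(scale=8.0, size=(32, 100, 30)) + 5.0
    es = EpochSet(data=data, sampling_rate=500.0, epoch_window=(-40.0, 160.0))
    res = preprocess_subject(es, montage32, min_trials=10, bad_channels=[3])
    steps = " | ".join(res.steps)
    assert steps.index("bandpass") < steps.index("average reference")
    assert steps.index("average reference") < steps.index("rejection")
    assert steps.index("rejection") < steps.index("interpolation")
    assert steps.index("interpolation") < steps.index("averaged")
    assert res.usable
    # group-level invariant: ERP is average-referenced
    assert np.abs(res.erp.data.mean(axis=0)).max() < 1e-9
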
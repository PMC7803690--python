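"""Filtering, epoching, rejection, spline interpolation, averaging."""

import numpy as np
import pandas as pd
import pytest

from erpstates import (
    EpochSet,
    Evoked,
    TimeAxis,
    average_by,
    bandpass_notch,
    extract_response_locked,
    grand_average,
    interpolate_bad_channels,
    make_fibonacci_montage,
    make_templates,
    reject_artifacts,
    spatial_correlation,
)
from erpstates.preprocessing import (
    CapacityError,
    MissingCellError,
    PreprocConfig,
    interpolation_matrix,
    run_pipeline,
)
from erpstates.simulate import GeneratorConfig, simulate_epochs


def _sine(freq, sfreq=512.0, seconds=4.0):
    t = np.arange(int(seconds * sfreq)) / sfreq
    return np.sin(2 * np.pi * freq * t)


def _amplitude_at(y, freq, sfreq=512.0):
    """Amplitude of the ``freq`` component by quadrature projection."""
    t = np.arange(y.size) / sfreq
    s, c = np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)
    return 2 * np.hypot(y @ s, y @ c) / y.size


def test_filter_removes_dc():
    x = np.full((2, 2048), 7.5)
    y = bandpass_notch(x, 512.0)
    # > 40 dB attenuation of a constant
    assert np.abs(y).max() < 7.5 * 0.01


def test_filter_passband_preserves_10hz_amplitude():
    y = bandpass_notch(_sine(10.0), 512.0)
    assert _amplitude_at(y, 10.0) == pytest.approx(1.0, abs=0.05)


def test_filter_notch_suppresses_50hz():
    y = bandpass_notch(_sine(50.0), 512.0)
    assert _amplitude_at(y, 50.0) < 0.1


def test_filter_rejects_too_short_segments():
    with pytest.raises(ValueError):
        bandpass_notch(np.zeros((2, 4)), 512.0)


def _meta(n):
    return pd.DataFrame(
        {
            "subject": ["s01"] * n,
            "condition": ["stop"] * n,
            "phoneme": ["p"] * n,
            "rt_ms": [600.0] * n,
            "accepted": [True] * n,
        }
    )


def test_extract_response_locked_indexing(montage16):
    cont = np.arange(16 * 600, dtype=float).reshape(16, 600)
    epochs = extract_response_locked(
        [cont], [500], epoch_tf=150, sfreq=512.0, montage=montage16, metadata=_meta(1)
    )
    assert np.array_equal(epochs.data[0], cont[:, 350:500])
    assert epochs.time.t0_index == 149


def test_extract_response_locked_drops_short_trials(montage16):
    cont = np.zeros((16, 600))
    epochs = extract_response_locked(
        [cont, cont],
        [100, 400],
        epoch_tf=150,
        sfreq=512.0,
        montage=montage16,
        metadata=_meta(2),
    )
    assert epochs.n_trials == 1


def _epochset(data, montage):
    n = data.shape[0]
    return EpochSet(
        data=data,
        montage=montage,
        time=TimeAxis(sfreq=512.0, n_tf=data.shape[2], t0_index=data.shape[2] - 1),
        metadata=_meta(n),
    )


def test_reject_artifacts_threshold(montage16):
    data = np.zeros((10, 16, 50))
    data[3, 5, 10] = 500.0  # one spike trial
    out = reject_artifacts(_epochset(data, montage16), 100.0)
    acc = out.accepted_mask()
    assert not acc[3] and acc.sum() == 9


def test_reject_artifacts_fraction_by_construction(montage16, rng):
    n = 50
    data = rng.normal(0, 5, (n, 16, 50))
    spiked = rng.choice(n, size=10, replace=False)  # 20% of trials
    data[spiked, 0, 0] = 300.0
    out = reject_artifacts(_epochset(data, montage16), 100.0)
    assert out.accepted_mask().mean() == pytest.approx(0.8)


def test_spline_interpolation_reproduces_constant_field(montage128):
    ev = Evoked(
        data=np.full((128, 5), 4.2),
        montage=montage128,
        time=TimeAxis(512.0, 5, 4),
        n_trials=1,
    )
    bad = list(montage128.labels[:10])
    out = interpolate_bad_channels(ev, bad)
    assert np.allclose(out.data, 4.2, atol=1e-6)


def test_spline_interpolation_smooth_field_accuracy(montage128):
    # a smooth dipolar field is reconstructed to within 5%
    field = make_templates(montage128, k=1, seed=5)[0]
    ev = Evoked(
        data=field[:, None] * np.ones((1, 3)),
        montage=montage128,
        time=TimeAxis(512.0, 3, 2),
        n_trials=1,
    )
    bad = [montage128.labels[i] for i in range(4, 128, 13)]  # 10 channels
    out = interpolate_bad_channels(ev, bad)
    idx = [montage128.index(b) for b in bad]
    err = np.abs(out.data[idx, 0] - field[idx])
    rel = np.linalg.norm(err) / np.linalg.norm(field[idx])
    assert rel < 0.05


def test_spline_interpolation_capacity_cap(montage128):
    ev = Evoked(
        data=np.zeros((128, 2)),
        montage=montage128,
        time=TimeAxis(512.0, 2, 1),
        n_trials=1,
    )
    with pytest.raises(CapacityError):
        interpolate_bad_channels(ev, list(montage128.labels[:30]))
    # 20 of 128 is exactly the 16% cap used in practice
    interpolate_bad_channels(ev, list(montage128.labels[:20]))


def test_spline_matrix_agrees_with_mne(montage128):
    """Independent oracle: MNE's spherical-spline interpolation matrix."""
    mne_interp = pytest.importorskip("mne.channels.interpolation")
    pos = montage128.unit_positions()
    bad = [montage128.labels[i] for i in range(0, 128, 17)]
    bad_idx = [montage128.index(b) for b in bad]
    good_idx = [i for i in range(128) if i not in set(bad_idx)]
    ours = interpolation_matrix(montage128, bad)
    theirs = mne_interp._make_interpolation_matrix(pos[good_idx], pos[bad_idx])
    field = make_templates(montage128, k=1, seed=8)[0]
    # the Legendre truncation differs (we follow degree 7), so compare the
    # interpolated values rather than the matrices
    assert np.allclose(ours @ field[good_idx], theirs @ field[good_idx], atol=2e-2)
    # and both reconstruct the held-out values of a smooth field
    assert np.abs(ours @ field[good_idx] - field[bad_idx]).max() < 0.05


def test_average_by_single_trial_and_cancellation(montage16, rng):
    x = rng.normal(size=(16, 40))
    data = np.stack([x, -x])
    meta = _meta(2)
    epochs = _epochset(data, montage16)
    evs = average_by(epochs)
    assert len(evs) == 1
    assert np.allclose(evs[0].data, 0.0)
    single = average_by(epochs.select(np.array([True, False])))
    assert np.array_equal(single[0].data, x)


def test_average_by_missing_cell_errors(montage16):
    data = np.zeros((2, 16, 40))
    meta = _meta(2)
    meta.loc[1, "condition"] = "fricative"
    meta.loc[1, "accepted"] = False
    epochs = EpochSet(
        data=data, montage=montage16, time=TimeAxis(512.0, 40, 39), metadata=meta
    )
    with pytest.raises(MissingCellError, match="fricative"):
        average_by(epochs)


def test_noiseless_grand_average_matches_scheduled_templates(noiseless_dataset):
    ds = noiseless_dataset
    evs = average_by(ds.epochs)
    ga = grand_average([e for e in evs if e.condition == "stop"])
    labels = ds.true_labels["stop"]
    for t in range(ds.config.epoch_tf):
        r = spatial_correlation(ga.data[:, t], ds.templates[labels[t]])
        assert r == pytest.approx(1.0, abs=1e-9)


def test_averaging_noise_scales_inverse_sqrt_n(montage16, rng):
    signal = make_templates(montage16, k=1, seed=2)[0][:, None] * np.ones((1, 60))
    resid = []
    for n in (4, 16, 64):
        trials = signal[None] + rng.normal(0, 1.0, (n, 16, 60))
        resid.append((trials.mean(axis=0) - signal).std())
    assert resid[0] > resid[1] > resid[2]
    for a, b in zip(resid, resid[1:]):
        assert a / b == pytest.approx(2.0, rel=0.35)


def test_pipeline_is_deterministic():
    cfg = GeneratorConfig(
        n_subjects=2, n_trials_per_condition=4, n_channels=16, seed=21
    )
    ds = simulate_epochs(cfg)
    ev1, ep1 = run_pipeline(ds.epochs, PreprocConfig())
    ev2, ep2 = run_pipeline(ds.epochs, PreprocConfig())
    assert np.array_equal(ep1.data, ep2.data)
    for a, b in zip(ev1, ev2):
        assert np.array_equal(a.data, b.data)
    # epochs are average-referenced after the pipeline
    assert np.abs(ep1.data.mean(axis=1)).max() < 1e-10
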
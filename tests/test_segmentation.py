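"""Microstate segmentation: recovery, smoothing, K selection."""

import numpy as np
import pytest

from erpstates import (
    Evoked,
    TimeAxis,
    average_by,
    choose_k,
    gev,
    grand_average,
    make_templates,
    segment,
    smooth_labels,
    spatial_correlation,
)


def _grand_averages(ds):
    evs = average_by(ds.epochs)
    return [
        grand_average([e for e in evs if e.condition == c])
        for c in ("fricative", "stop")
    ]


def _match_templates(recovered, planted):
    """Best |r| match of each planted map among the recovered ones."""
    k = len(planted)
    corr = np.abs(recovered @ planted.T / planted.shape[1])
    assignment = corr.argmax(axis=0)
    return corr.max(axis=0), assignment


def test_k1_closed_form(montage16, rng):
    # K=1: the template is the normalized GFP-weighted mean map and the
    # GEV equals its analytic value computed independently
    base = make_templates(montage16, k=1, seed=12)[0]
    amps = rng.uniform(0.5, 2.0, size=25)
    data = base[:, None] * amps + rng.normal(0, 0.05, (16, 25))
    ev = Evoked(
        data=data, montage=montage16, time=TimeAxis(512.0, 25, 24), n_trials=1,
        condition="x",
    )
    res = segment([ev], k=1, n_restarts=5, min_duration_ms=0.0, seed=0)
    u = data - data.mean(axis=0, keepdims=True)
    g = u.std(axis=0, ddof=0)
    t = (u * g).sum(axis=1)
    t = t - t.mean()
    t /= t.std(ddof=0)
    assert abs(spatial_correlation(res.templates[0], t)) > 0.999999
    expected = gev(ev, [res.templates[0]], np.zeros(25, dtype=int))
    assert res.gev == pytest.approx(expected, abs=1e-12)


def test_noiseless_recovery_of_planted_maps_and_labels(noiseless_dataset):
    ds = noiseless_dataset
    gas = _grand_averages(ds)
    res = segment(gas, k=4, n_restarts=20, seed=1)
    best, assignment = _match_templates(res.templates, ds.templates)
    assert (best >= 0.999).all()
    assert len(set(assignment.tolist())) == 4  # distinct maps
    for cond in ("stop", "fricative"):
        mapped = assignment[ds.true_labels[cond]]
        assert np.array_equal(res.labels[cond], mapped)
    assert res.gev == pytest.approx(1.0, abs=1e-9)


def test_final_map_is_labelled_a(noiseless_dataset):
    res = segment(_grand_averages(noiseless_dataset), k=4, n_restarts=20, seed=1)
    last = res.labels["stop"][-1]
    assert res.template_labels[last] == "A"


def test_segmentation_deterministic_under_seed(noisy_dataset):
    gas = _grand_averages(noisy_dataset)
    r1 = segment(gas, k=4, n_restarts=10, seed=7)
    r2 = segment(gas, k=4, n_restarts=10, seed=7)
    assert np.array_equal(r1.templates, r2.templates)
    assert all(np.array_equal(r1.labels[c], r2.labels[c]) for c in r1.labels)


def test_polarity_sensitivity(montage16):
    # two segments with inverted topographies must get different labels
    t = make_templates(montage16, k=1, seed=3)[0]
    data = np.concatenate([t[:, None] * np.ones((1, 20)),
                           -t[:, None] * np.ones((1, 20))], axis=1)
    ev = Evoked(data=data, montage=montage16, time=TimeAxis(512.0, 40, 39),
                n_trials=1, condition="x")
    res = segment([ev], k=2, n_restarts=5, seed=4)
    lab = res.labels["x"]
    assert lab[0] != lab[-1]
    # flipping the input flips the recovered templates too
    ev_flip = Evoked(data=-data, montage=montage16, time=TimeAxis(512.0, 40, 39),
                     n_trials=1, condition="x")
    res_flip = segment([ev_flip], k=2, n_restarts=5, seed=4)
    best, _ = _match_templates(res_flip.templates, -res.templates)
    assert (best > 0.999999).all()


def test_gev_nondecreasing_in_k(noisy_dataset):
    gas = _grand_averages(noisy_dataset)
    _, gevs = choose_k(gas, range(1, 7), n_restarts=8, seed=5)
    vals = [gevs[k] for k in sorted(gevs)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_choose_k_fixed_mode(noisy_dataset):
    k, _ = choose_k(_grand_averages(noisy_dataset), range(2, 8),
                    criterion="fixed", fixed_k=5)
    assert k == 5


def test_choose_k_recovers_planted_four_maps():
    from erpstates import GeneratorConfig, simulate_epochs

    cfg = GeneratorConfig(
        n_subjects=4, n_trials_per_condition=8, n_channels=32,
        noise_sd=0.05, seed=31,
    )
    ds = simulate_epochs(cfg)
    k, _ = choose_k(_grand_averages(ds), range(1, 7), n_restarts=10, seed=6)
    assert k == 4


def test_choose_k_pure_noise_returns_minimum(montage128, rng):
    data = rng.normal(size=(128, 150))
    ev = Evoked(data=data, montage=montage128, time=TimeAxis(512.0, 150, 149),
                n_trials=1, condition="x")
    k, _ = choose_k([ev], range(2, 6), n_restarts=5, seed=7)
    assert k == 2


def test_smooth_labels_identity_without_short_runs(montage16, rng):
    templates = make_templates(montage16, k=3, seed=9)
    labels = np.repeat([0, 1, 2], 10)
    data = templates[labels].T + rng.normal(0, 0.01, (16, 30))
    out = smooth_labels(labels, data, templates, 10.0, 512.0)
    assert np.array_equal(out, labels)


def test_smooth_labels_absorbs_island(montage16, rng):
    templates = make_templates(montage16, k=2, seed=10)
    labels = np.zeros(30, dtype=int)
    labels[14:16] = 1  # 2-TF island; criterion at 512 Hz is 6 TF
    data = templates[np.zeros(30, dtype=int)].T + rng.normal(0, 0.01, (16, 30))
    out = smooth_labels(labels, data, templates, 10.0, 512.0)
    assert np.array_equal(out, np.zeros(30, dtype=int))


def test_smooth_labels_postcondition_sweep(montage16, rng):
    """After smoothing, no run is shorter than the criterion (6 TF)."""
    templates = make_templates(montage16, k=4, seed=11)
    for trial in range(20):
        labels = rng.integers(0, 4, size=80)
        data = templates[labels].T + rng.normal(0, 0.3, (16, 80))
        out = smooth_labels(labels, data, templates, 10.0, 512.0)
        runs = []
        start = 0
        for t in range(1, 81):
            if t == 80 or out[t] != out[start]:
                runs.append(t - start)
                start = t
        assert min(runs) >= 6 or len(runs) == 1
        assert len(out) == 80
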
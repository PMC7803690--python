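"""Synthetic-data generator: templates, schedules, epochs, RTs."""

import numpy as np
import pandas as pd
import pytest

from erpstates import (
    GeneratorConfig,
    make_fibonacci_montage,
    make_schedule,
    make_templates,
    simulate_epochs,
    spatial_correlation,
)
from erpstates.backfitting import backfit_labels
from erpstates.simulate import (
    ConfigError,
    TABLE_RT_PARAMS,
    schedule_labels,
    simulate_rts,
)


def test_make_templates_unit_gfp_zero_mean(montage16):
    t = make_templates(montage16, k=1, seed=3)
    assert t.shape == (1, 16)
    assert abs(t[0].mean()) < 1e-12
    assert t[0].std(ddof=0) == pytest.approx(1.0)


def test_make_templates_dissimilar_and_deterministic(montage128):
    t1 = make_templates(montage128, k=4, seed=7)
    t2 = make_templates(montage128, k=4, seed=7)
    assert np.array_equal(t1, t2)
    for i in range(4):
        for j in range(i):
            assert abs(spatial_correlation(t1[i], t1[j])) <= 0.5


def test_make_schedule_shift_semantics():
    stop = make_schedule(150, "stop", 46)
    fric = make_schedule(150, "fricative", 46)
    same = make_schedule(150, "fricative", 0)
    assert stop == make_schedule(150, "stop", 0) == same
    dur = {idx: off - on for idx, on, off in stop}
    dur_f = {idx: off - on for idx, on, off in fric}
    a = 0  # template index of map A
    d = 3
    assert dur[a] - dur_f[a] == 46
    assert dur_f[d] - dur[d] == 46
    for idx in (1, 2):  # maps B and C untouched
        assert dur[idx] == dur_f[idx]


@pytest.mark.parametrize("shift", [0, 10, 46, 55])
@pytest.mark.parametrize("epoch_tf", [150, 100])
def test_make_schedule_tiles_epoch(epoch_tf, shift):
    for cond in ("stop", "fricative"):
        if cond == "fricative" and shift >= 56 * epoch_tf // 150:
            continue
        sched = make_schedule(epoch_tf, cond, shift)
        labels = schedule_labels(sched, epoch_tf)
        assert (labels >= 0).all()  # no gaps
        covered = sum(off - on for _, on, off in sched)
        assert covered == epoch_tf  # no overlaps


def test_make_schedule_shift_consuming_map_a_errors():
    with pytest.raises(ConfigError):
        make_schedule(150, "fricative", 56)


def test_noiseless_trials_proportional_to_scheduled_template(noiseless_dataset):
    ds = noiseless_dataset
    labels = ds.true_labels["stop"]
    trial = ds.epochs.data[0]  # first trial is subject 1, stop
    for t in range(ds.config.epoch_tf):
        r = spatial_correlation(trial[:, t], ds.templates[labels[t]])
        assert r == pytest.approx(1.0, abs=1e-9)


def test_noiseless_grand_average_gfp_is_continuous(noiseless_dataset):
    ds = noiseless_dataset
    for cond in ("stop", "fricative"):
        mask = (ds.epochs.metadata["condition"] == cond).to_numpy()
        ga = ds.epochs.data[mask].mean(axis=0)
        g = ga.std(axis=0, ddof=0)
        jumps = np.abs(np.diff(g))
        assert jumps.max() <= 5 * np.median(jumps) + 1e-12


def test_seed_determinism():
    cfg = dict(n_subjects=2, n_trials_per_condition=3, n_channels=16, seed=9)
    a = simulate_epochs(GeneratorConfig(**cfg))
    b = simulate_epochs(GeneratorConfig(**cfg))
    assert np.array_equal(a.epochs.data, b.epochs.data)
    assert a.epochs.metadata.equals(b.epochs.metadata)


def test_single_trial_label_accuracy_degrades_with_noise():
    """Monte-Carlo over seeds: more sensor noise, worse frame labelling."""
    accs = []
    for noise in (0.5, 1.0, 2.0):
        acc = []
        for seed in range(20):
            cfg = GeneratorConfig(
                n_subjects=1,
                n_trials_per_condition=2,
                n_channels=16,
                epoch_tf=150,
                noise_sd=noise,
                subject_topo_sd=0.0,
                seed=1000 + seed,
            )
            ds = simulate_epochs(cfg)
            truth = ds.true_labels["stop"]
            lab = backfit_labels(ds.epochs.data[0], ds.templates)
            acc.append(np.mean(lab == truth))
        accs.append(np.mean(acc))
    assert accs[0] > accs[1] > accs[2]


def _rt_metadata(n_subjects, n_per_phoneme):
    rows = []
    for s in range(n_subjects):
        for phon in TABLE_RT_PARAMS:
            for j in range(n_per_phoneme):
                rows.append(
                    {
                        "subject": f"s{s:03d}",
                        "phoneme": phon,
                        "item": f"i{j:03d}",
                    }
                )
    return pd.DataFrame(rows)


def test_simulate_rts_degenerate_sd_returns_mean():
    cfg = GeneratorConfig(
        rt_params={"p": (500.0, 0.0)},
        rt_subject_sd=0.0,
        rt_item_sd=0.0,
    )
    meta = pd.DataFrame(
        {"subject": ["s1"] * 5, "phoneme": ["p"] * 5, "item": [f"i{k}" for k in range(5)]}
    )
    rts = simulate_rts(cfg, meta, np.random.default_rng(0))
    assert np.allclose(rts, 500.0)


def test_simulate_rts_marginal_means_match_parameters():
    """Per-phoneme sample means stay within 2 cluster-robust SEs."""
    cfg = GeneratorConfig()
    meta = _rt_metadata(n_subjects=100, n_per_phoneme=100)
    rts = simulate_rts(cfg, meta, np.random.default_rng(42))
    meta = meta.assign(rt_ms=rts)
    for phon, (mean, _sd) in TABLE_RT_PARAMS.items():
        sub = meta[meta["phoneme"] == phon]
        subj_means = sub.groupby("subject")["rt_ms"].mean()
        se = subj_means.std(ddof=1) / np.sqrt(len(subj_means))
        assert abs(subj_means.mean() - mean) < 2 * se


def test_rt_mode_difference_about_90ms():
    cfg = GeneratorConfig()
    meta = _rt_metadata(n_subjects=60, n_per_phoneme=60)
    rts = simulate_rts(cfg, meta, np.random.default_rng(7))
    meta = meta.assign(rt_ms=rts)
    is_fric = meta["phoneme"].str.startswith("s")
    diff = meta.loc[~is_fric, "rt_ms"].mean() - meta.loc[is_fric, "rt_ms"].mean()
    assert diff == pytest.approx(89.9, abs=5.0)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        GeneratorConfig(shift_tf=-1).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(noise_sd=-0.1).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(envelope="square").validate()
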
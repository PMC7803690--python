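"""Synthetic response-locked ERP datasets with a planted microstate shift.

The generator emulates the study conditions of a delayed pseudoword
production experiment: 128-channel scalp EEG sampled at 512 Hz, epochs of
150 time frames aligned backward from the vocal (acoustic) onset, two
onset-consonant conditions (voiceless stops /p,t,k/ vs /s/-initial
fricative clusters), and four stable scalp topographies (template maps
D -> B -> C -> A) tiling each epoch.  The articulatory-to-acoustic
interval (AAI) manifests as a condition-specific onset shift of the final
map A: in the fricative condition map A starts ``shift_tf`` frames later
(default 46 TF ~ 90 ms), the freed frames being absorbed by map D.  Vocal
reaction times are drawn per phoneme from the empirical means and SDs of
the delayed-production task.

Everything is driven by a single integer seed; identical configs produce
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topography import (
    EpochSet,
    Evoked,
    Montage,
    TimeAxis,
    average_reference,
)

__all__ = [
    "TABLE_RT_PARAMS",
    "GeneratorConfig",
    "SyntheticDataset",
    "make_fibonacci_montage",
    "make_templates",
    "make_schedule",
    "simulate_rts",
    "simulate_epochs",
]

#: Empirical vocal-RT means and SDs (ms) per onset phoneme from the
#: delayed-production task: voiceless stops vs the matched /s/-clusters.
TABLE_RT_PARAMS: dict[str, tuple[float, float]] = {
    "k": (610.88, 151.94),
    "p": (628.80, 156.12),
    "t": (623.33, 155.85),
    "sk": (529.76, 149.32),
    "sp": (525.47, 146.65),
    "st": (538.12, 147.67),
}

STOP_PHONEMES = ("p", "t", "k")
FRICATIVE_PHONEMES = ("sp", "st", "sk")

#: Map durations (TF) of the stop-condition schedule, D -> B -> C -> A,
#: matching the individual-ERP durations observed for stop onsets over a
#: 150-TF response-locked window.
DEFAULT_BASE_DURATIONS: dict[str, int] = {"D": 74, "B": 8, "C": 12, "A": 56}

MAP_ORDER = ("D", "B", "C", "A")  # temporal order within the epoch
MAP_LABELS = ("A", "B", "C", "D")  # template index 0..3 <-> A..D


class ConfigError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """Template generation failed (e.g. dissimilarity unattainable)."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic two-condition ERP experiment.

    Defaults reproduce the study conditions: 22 participants, 88 trials
    per condition each (~3872 single trials), 128 electrodes, 512 Hz,
    150-TF response-locked epochs, four templates, and a 46-TF planted
    shift of map A between conditions.

    ``noise_sd`` scales single-trial background-EEG noise as a fraction
    of the mean signal GFP.  The noise is spatially smooth (Gaussian
    kernel of width ``noise_spatial_sigma`` head radii over the scalp;
    0 gives white sensor noise) and temporally autocorrelated (AR(1)
    coefficient ``noise_ar``; 0 gives white noise in time): ongoing EEG
    has its own transient topographies, and only noise of that kind
    competes with the planted templates the way real trials do.  The
    default level is calibrated so that single-trial back-fitting
    recovers a clearly attenuated map-A duration difference while the
    grand averages still show the full planted shift.
    ``subject_topo_sd`` is the SD of the per-subject random mixing of
    the group templates.
    """

    n_subjects: int = 22
    n_trials_per_condition: int = 88
    n_channels: int = 128
    montage: Montage | None = None
    sfreq: float = 512.0
    epoch_tf: int = 150
    n_templates: int = 4
    shift_tf: int = 46  # planted map-A onset shift, ~90 ms at 512 Hz
    base_durations: dict = field(
        default_factory=lambda: dict(DEFAULT_BASE_DURATIONS)
    )
    noise_sd: float = 3.0
    noise_spatial_sigma: float = 0.5
    noise_ar: float = 0.9
    subject_topo_sd: float = 0.1
    envelope: str = "cosine"  # "cosine" (raised-cosine bumps) or "flat"
    envelope_floor: float = 0.3
    signal_scale_uv: float = 3.0
    rt_params: dict = field(default_factory=lambda: dict(TABLE_RT_PARAMS))
    rt_floor_ms: float = 150.0
    rt_subject_sd: float = 50.0
    rt_item_sd: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ConfigError("need at least one subject and one trial")
        if self.shift_tf < 0:
            raise ConfigError("shift_tf must be >= 0")
        if self.noise_sd < 0 or self.subject_topo_sd < 0:
            raise ConfigError("noise levels must be >= 0")
        if self.envelope not in ("cosine", "flat"):
            raise ConfigError(f"unknown envelope {self.envelope!r}")
        if sorted(self.base_durations) != sorted(MAP_ORDER):
            raise ConfigError("base_durations must cover maps A, B, C, D")
        # Tiling and shift feasibility are checked by make_schedule.
        make_schedule(self.epoch_tf, "stop", self.shift_tf, self.base_durations)
        make_schedule(
            self.epoch_tf, "fricative", self.shift_tf, self.base_durations
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("montage")
        return d


@dataclass
class SyntheticDataset:
    """A generated EpochSet plus its ground truth."""

    epochs: EpochSet
    true_labels: dict  # condition -> (epoch_tf,) template indices
    templates: np.ndarray  # (K, n_channels), unit GFP, zero mean
    config: GeneratorConfig

    def clean_evoked(self, condition: str) -> Evoked:
        """The noise-free group-level signal for one condition."""
        cfg = self.config
        env = _envelope_for(
            self.true_labels[condition], cfg.envelope, cfg.envelope_floor
        )
        data = (
            self.templates[self.true_labels[condition]].T
            * env
            * cfg.signal_scale_uv
        )
        return Evoked(
            data=data,
            montage=self.epochs.montage,
            time=self.epochs.time,
            n_trials=1,
            condition=condition,
        )


# ---------------------------------------------------------------------------
# Montage and templates
# ---------------------------------------------------------------------------


def make_fibonacci_montage(n_channels: int = 128, radius: float = 0.095) -> Montage:
    """Quasi-uniform electrode layout on the upper head sphere.

    Fibonacci-lattice points restricted to z > -0.25 * radius emulate a
    whole-scalp cap; labels are E001..E<n>.  Deterministic.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 electrodes")
    golden = (1 + 5**0.5) / 2
    # Oversample the full sphere, keep the uppermost n points.
    m = int(np.ceil(n_channels * 1.7)) + 8
    i = np.arange(m)
    z = 1 - 2 * (i + 0.5) / m
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts = pts[np.argsort(-pts[:, 2])][:n_channels] * radius
    labels = [f"E{k + 1:03d}" for k in range(n_channels)]
    return Montage(labels=labels, positions=pts)


def make_templates(
    montage: Montage,
    k: int = 4,
    seed: int | np.random.Generator = 0,
    max_abs_corr: float = 0.5,
    max_tries: int = 500,
    smoothing_sigma: float = 0.6,
) -> np.ndarray:
    """Draw K mutually dissimilar smooth dipolar template topographies.

    Each candidate map projects the electrode positions onto a random
    axis, adds a weaker random quadrupolar component (a product of two
    further axis projections, so more than three mutually dissimilar
    fields exist), and smooths the result with a Gaussian kernel over
    inter-electrode chord distance (``smoothing_sigma`` in units of the
    head radius), then average-references and scales to unit GFP.  Each
    accepted map after the first is partially decorrelated from the
    previous ones: its projection onto their span is shrunk to a random
    correlation of at most 0.4, which guarantees all pairwise
    |spatial correlations| <= ``max_abs_corr`` while keeping the maps
    smooth and realistically non-orthogonal.  Candidates whose component
    outside the existing span is negligible are rejected (bounded
    retries).

    Returns an array (K, n_channels).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    pos = montage.unit_positions()
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    kernel = np.exp(-d2 / (2 * smoothing_sigma**2))

    n = montage.n_channels

    def draw_candidate() -> np.ndarray | None:
        axes = rng.standard_normal((3, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        q = rng.uniform(0.2, 0.8)
        raw = kernel @ ((pos @ axes[0]) + q * (pos @ axes[1]) * (pos @ axes[2]))
        v = average_reference(raw)
        g = v.std(ddof=0)
        return None if g == 0 else v / g

    target_rho = min(0.4, max_abs_corr)
    chosen: list[np.ndarray] = []
    basis: list[np.ndarray] = []  # orthonormal (dot/n inner product) span
    tries = 0
    while len(chosen) < k:
        if tries >= max_tries:
            raise GenerationError(
                f"could not draw {k} templates with pairwise |r| <= "
                f"{max_abs_corr} within {max_tries} candidate draws"
            )
        tries += 1
        c = draw_candidate()
        if c is None:
            continue
        if not chosen:
            chosen.append(c)
            basis.append(c)
            continue
        coeffs = [float(np.mean(c * b)) for b in basis]
        proj = sum(co * b for co, b in zip(coeffs, basis))
        resid = c - proj
        resid_norm = float(np.sqrt(np.mean(resid**2)))
        if resid_norm < 0.05:
            continue  # candidate lies (almost) inside the existing span
        u = resid / resid_norm
        pn = float(np.sqrt(np.mean(proj**2)))
        rho = rng.uniform(0.3 * target_rho, target_rho)
        if pn > 1e-12:
            new = np.sqrt(1 - rho**2) * u + rho * proj / pn
        else:
            new = u
        new = new / float(np.sqrt(np.mean(new**2)))
        if all(abs(float(np.mean(new * m))) <= max_abs_corr for m in chosen):
            chosen.append(new)
            basis.append(u)
    return np.asarray(chosen)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------


def make_schedule(
    epoch_tf: int,
    condition: str,
    shift_tf: int,
    base_durations: dict | None = None,
) -> list[tuple[int, int, int]]:
    """Segment schedule (template index, onset, offset) tiling one epoch.

    Frames are epoch sample indices, half-open [onset, offset); sample 0
    is TF -epoch_tf and the epoch ends just before the vocal onset.  The
    stop condition uses the base durations D->B->C->A; in the fricative
    condition map A starts ``shift_tf`` frames later (map A shortened,
    map D lengthened by the same amount), leaving B and C untouched.
    """
    if condition not in ("stop", "fricative"):
        raise ConfigError(f"unknown condition {condition!r}")
    base = dict(base_durations or DEFAULT_BASE_DURATIONS)
    if shift_tf >= epoch_tf:
        raise ConfigError("shift_tf must be smaller than the epoch length")
    durs = {m: int(base[m]) for m in MAP_ORDER}
    total = sum(durs.values())
    if total != epoch_tf:
        # Rescale proportionally for non-default epoch lengths.
        scaled = {m: max(1, int(round(durs[m] * epoch_tf / total))) for m in MAP_ORDER}
        scaled["A"] += epoch_tf - sum(scaled.values())
        durs = scaled
    if condition == "fricative":
        if shift_tf >= durs["A"]:
            raise ConfigError(
                f"shift_tf={shift_tf} consumes all of map A ({durs['A']} TF)"
            )
        durs["A"] -= shift_tf
        durs["D"] += shift_tf
    if min(durs.values()) < 1:
        raise ConfigError("schedule contains an empty segment")

    schedule = []
    onset = 0
    for m in MAP_ORDER:
        schedule.append((MAP_LABELS.index(m), onset, onset + durs[m]))
        onset += durs[m]
    assert onset == epoch_tf
    return schedule


def schedule_labels(schedule: list[tuple[int, int, int]], epoch_tf: int) -> np.ndarray:
    """Expand a segment schedule to a per-TF template-index vector."""
    labels = np.full(epoch_tf, -1, dtype=int)
    for idx, on, off in schedule:
        labels[on:off] = idx
    if (labels < 0).any():
        raise ConfigError("schedule does not tile the epoch")
    return labels


def _envelope_for(labels: np.ndarray, kind: str, floor: float) -> np.ndarray:
    """Per-TF amplitude envelope: raised-cosine bump within each segment.

    The bump peaks mid-segment and decays to ``floor`` at the segment
    edges so the GFP is non-constant (as in real ERPs) yet never zero.
    Short segments get proportionally flatter bumps (a brief microstate
    does not reach full field strength), which also keeps the GFP free
    of sample-to-sample jumps.
    """
    n = len(labels)
    if kind == "flat":
        return np.ones(n)
    env = np.empty(n)
    start = 0
    ref_len = 30  # segments shorter than this peak below full strength
    for t in range(1, n + 1):
        if t == n or labels[t] != labels[start]:
            ln = t - start
            i = np.arange(ln)
            height = (1 - floor) * min(1.0, ln / ref_len)
            env[start:t] = floor + height * np.sin(np.pi * (i + 0.5) / ln)
            start = t
    return env


# ---------------------------------------------------------------------------
# RTs and epochs
# ---------------------------------------------------------------------------


def _noise_kernel(montage: Montage, sigma: float) -> np.ndarray | None:
    """Spatial mixing kernel for background noise, normalized so the
    average per-channel output variance is 1 for unit-variance input."""
    if sigma <= 0:
        return None
    pos = montage.unit_positions()
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2 * sigma**2))
    return k / np.sqrt(np.mean(np.sum(k**2, axis=1)))


def _background_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    kernel: np.ndarray | None,
    ar: float,
) -> np.ndarray:
    """Unit-SD noise, optionally AR(1) in time and smoothed over the scalp."""
    n_tr, n_ch, n_tf = shape
    burn = 50 if ar > 0 else 0
    w = rng.standard_normal((n_tr, n_ch, n_tf + burn))
    if ar > 0:
        from scipy.signal import lfilter

        w = lfilter([np.sqrt(1 - ar**2)], [1.0, -ar], w, axis=-1)
        w = w[..., burn:]
    if kernel is not None:
        w = np.einsum("ij,tjf->tif", kernel, w)
    return w


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, floor: float
) -> np.ndarray:
    """Gaussian draws resampled above a hard floor."""
    out = rng.normal(mean, sd, size)
    bad = out < floor
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < floor
    return out


def simulate_rts(
    config: GeneratorConfig,
    metadata: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-trial vocal RTs (ms) for the trials described in metadata.

    Per phoneme, RTs are Gaussian with the configured mean and SD,
    truncated at ``rt_floor_ms``.  The phoneme SD is decomposed into a
    subject intercept, an item intercept and a residual so that the
    marginal per-phoneme distribution keeps the configured SD while
    subject/item random effects are non-degenerate.
    """
    n = len(metadata)
    rts = np.empty(n)
    subjects = pd.unique(metadata["subject"])
    items = pd.unique(metadata["item"]) if "item" in metadata else np.array([])
    subj_off = dict(
        zip(subjects, rng.normal(0.0, config.rt_subject_sd, len(subjects)))
    )
    item_off = dict(zip(items, rng.normal(0.0, config.rt_item_sd, len(items))))
    for phon, (mean, sd) in config.rt_params.items():
        mask = (metadata["phoneme"] == phon).to_numpy()
        if not mask.any():
            continue
        resid_var = sd**2 - config.rt_subject_sd**2 - config.rt_item_sd**2
        if resid_var < 0:
            raise ConfigError(
                f"phoneme {phon}: SD {sd} too small for the configured "
                "subject/item variance components"
            )
        base = mean + (
            rng.normal(0.0, np.sqrt(resid_var), int(mask.sum()))
            if resid_var > 0
            else 0.0
        )
        off = metadata.loc[mask, "subject"].map(subj_off).to_numpy()
        if "item" in metadata:
            off = off + metadata.loc[mask, "item"].map(item_off).to_numpy()
        rts[mask] = base + off
    # Enforce the floor by resampling the residual for offending trials.
    low = rts < config.rt_floor_ms
    while low.any():
        jitter = rng.normal(0.0, 10.0, int(low.sum()))
        rts[low] = config.rt_floor_ms + np.abs(jitter)
        low = rts < config.rt_floor_ms
    return rts


def _trial_metadata(config: GeneratorConfig) -> pd.DataFrame:
    """Trial table: subjects x conditions x trials, phonemes cycling.

    Items are matched across conditions (the fricative variant of item j
    shares j's base phoneme), mirroring CCV/CCCV pseudoword pairs.
    """
    rows = []
    for s in range(config.n_subjects):
        sid = f"s{s + 1:02d}"
        for cond, phons in (
            ("stop", STOP_PHONEMES),
            ("fricative", FRICATIVE_PHONEMES),
        ):
            for j in range(config.n_trials_per_condition):
                rows.append(
                    {
                        "subject": sid,
                        "condition": cond,
                        "phoneme": phons[j % 3],
                        "item": f"i{j + 1:03d}",
                        "rt_ms": np.nan,
                        "accepted": True,
                    }
                )
    return pd.DataFrame(rows)


def simulate_epochs(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full synthetic experiment.

    Each trial is the scheduled template sequence times its amplitude
    envelope (scaled to ``signal_scale_uv`` microvolts of peak template
    amplitude), built from that subject's randomly perturbed copy of the
    group templates, plus background-EEG noise (spatially smooth,
    temporally autocorrelated) with average per-channel SD equal to
    ``noise_sd`` times the mean signal GFP.  Fully reproducible from
    the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    montage = config.montage or make_fibonacci_montage(config.n_channels)
    templates = make_templates(montage, config.n_templates, rng)

    labels = {
        cond: schedule_labels(
            make_schedule(config.epoch_tf, cond, config.shift_tf, config.base_durations),
            config.epoch_tf,
        )
        for cond in ("stop", "fricative")
    }
    envelopes = {
        cond: _envelope_for(labels[cond], config.envelope, config.envelope_floor)
        for cond in labels
    }
    # Unit-GFP templates => clean signal GFP equals scale * envelope.
    mean_gfp = config.signal_scale_uv * float(
        np.mean([envelopes[c].mean() for c in envelopes])
    )
    noise_scale = config.noise_sd * mean_gfp

    metadata = _trial_metadata(config)
    metadata["rt_ms"] = simulate_rts(config, metadata, rng)
    kernel = _noise_kernel(montage, config.noise_spatial_sigma)

    n_ch, n_tf = montage.n_channels, config.epoch_tf
    data = np.empty((len(metadata), n_ch, n_tf))
    k = config.n_templates
    row = 0
    for s in range(config.n_subjects):
        # Subject-level topographic variability: mildly mix the group
        # templates, then renormalize to zero mean / unit GFP.
        mix = np.eye(k) + rng.normal(0.0, config.subject_topo_sd, (k, k))
        subj_templates = average_reference(mix @ templates, axis=-1)
        subj_templates /= subj_templates.std(axis=-1, ddof=0, keepdims=True)
        for cond in ("stop", "fricative"):
            clean = (
                subj_templates[labels[cond]].T
                * envelopes[cond]
                * config.signal_scale_uv
            )
            n_tr = config.n_trials_per_condition
            noise = (
                _background_noise(rng, (n_tr, n_ch, n_tf), kernel, config.noise_ar)
                * noise_scale
            )
            data[row : row + n_tr] = clean[None, :, :] + noise
            row += n_tr
    assert row == len(metadata)

    epochs = EpochSet(
        data=data,
        montage=montage,
        time=TimeAxis(sfreq=config.sfreq, n_tf=n_tf, t0_index=n_tf - 1),
        metadata=metadata,
    )
    return SyntheticDataset(
        epochs=epochs, true_labels=labels, templates=templates, config=config
    )
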
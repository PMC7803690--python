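"""Pre-processing: filtering, response-locked epoching, artifact rejection,
spherical-spline channel interpolation, and averaging.

The canonical order is filter -> epoch -> reject -> interpolate ->
re-reference -> average; :func:`run_pipeline` applies it to an existing
:class:`~erpstates.topography.EpochSet` and logs counts at each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import signal

from .topography import (
    EpochSet,
    Evoked,
    Montage,
    TimeAxis,
    average_reference,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocConfig",
    "bandpass_notch",
    "extract_response_locked",
    "reject_artifacts",
    "interpolation_matrix",
    "interpolate_bad_channels",
    "average_by",
    "grand_average",
    "run_pipeline",
]


class CapacityError(ValueError):
    """Too many bad channels for spline interpolation."""


class MissingCellError(ValueError):
    """An averaging cell has no accepted trials."""


@dataclass
class PreprocConfig:
    """Filter/epoch/rejection parameters.

    Defaults: 0.1-30 Hz zero-phase 2nd-order Butterworth band-pass with a
    50 Hz notch, 150-TF response-locked epochs, +-100 uV rejection, and at
    most 16% of channels interpolated.
    """

    highpass_hz: float = 0.1
    lowpass_hz: float = 30.0
    notch_hz: float | None = 50.0
    filter_order: int = 2
    epoch_tf: int = 150
    rejection_uv: float = 100.0
    max_interpolated_fraction: float = 0.16

    def validate(self, sfreq: float) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz < sfreq / 2):
            raise ValueError("need 0 < highpass < lowpass < Nyquist")
        if self.rejection_uv <= 0:
            raise ValueError("rejection threshold must be positive")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def bandpass_notch(
    data: np.ndarray,
    sfreq: float,
    highpass_hz: float = 0.1,
    lowpass_hz: float = 30.0,
    notch_hz: float | None = 50.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass plus notch along the last axis.

    Forward-backward (``filtfilt``) application makes the filter acausal
    with squared magnitude response and no phase distortion; DC is
    removed by the high-pass.  Short segments are reflection-padded up to
    one segment length.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    n = data.shape[-1]
    sos = signal.butter(
        order, [highpass_hz, lowpass_hz], btype="bandpass", fs=sfreq, output="sos"
    )
    default_padlen = 3 * (2 * sos.shape[0] + 1)
    padlen = min(n - 1, max(default_padlen, n // 2))
    if n <= default_padlen // 3:
        raise ValueError(
            f"segment of {n} samples is too short for the filter padding"
        )
    out = signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)
    if notch_hz is not None and notch_hz < sfreq / 2:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=sfreq)
        out = signal.filtfilt(b, a, out, axis=-1, padlen=min(n - 1, 3 * len(b)))
    return out


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------


def extract_response_locked(
    trials: list[np.ndarray],
    vocal_onset_samples: list[int],
    epoch_tf: int,
    sfreq: float,
    montage: Montage,
    metadata: pd.DataFrame,
) -> EpochSet:
    """Cut response-locked epochs ending at each trial's vocal onset.

    For a trial with onset sample ``o`` the epoch is ``[o - epoch_tf, o)``:
    the last frame is the final sample before acoustic energy.  Trials
    without enough pre-onset signal are dropped (logged, not raised).
    """
    kept, keep_idx = [], []
    for i, (trial, onset) in enumerate(zip(trials, vocal_onset_samples)):
        trial = np.asarray(trial, float)
        if onset < epoch_tf or onset > trial.shape[-1]:
            logger.warning(
                "dropping trial %d: vocal onset at sample %d leaves no "
                "%d-TF pre-onset window",
                i,
                onset,
                epoch_tf,
            )
            continue
        kept.append(trial[:, onset - epoch_tf : onset])
        keep_idx.append(i)
    if not kept:
        raise ValueError("no trial has a full pre-onset window")
    return EpochSet(
        data=np.stack(kept),
        montage=montage,
        time=TimeAxis(sfreq=sfreq, n_tf=epoch_tf, t0_index=epoch_tf - 1),
        metadata=metadata.iloc[keep_idx].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Flag trials whose absolute amplitude exceeds the threshold anywhere.

    A deterministic stand-in for visual inspection: a trial is rejected
    iff any |value| > threshold.  Returns a new EpochSet with updated
    ``accepted`` flags; nothing is removed.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    ok = peak <= threshold_uv
    meta = epochs.metadata.copy()
    meta["accepted"] = meta["accepted"].to_numpy(dtype=bool) & ok
    frac = float(meta["accepted"].mean())
    logger.info(
        "artifact rejection at +-%.0f uV: %.1f%% of %d trials accepted",
        threshold_uv,
        100 * frac,
        len(meta),
    )
    return EpochSet(
        data=epochs.data, montage=epochs.montage, time=epochs.time, metadata=meta
    )


# ---------------------------------------------------------------------------
# Spherical-spline interpolation (Perrin-style)
# ---------------------------------------------------------------------------


def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) with stiffness m, truncated
    at Legendre degree ``n_terms``."""
    coef = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        coef[n] = (2 * n + 1) / (n**m * (n + 1) ** m)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef) / (4 * np.pi)


def interpolation_matrix(
    montage: Montage,
    bad: list[str],
    m: int = 4,
    n_terms: int = 7,
    reg: float = 1e-8,
) -> np.ndarray:
    """Matrix mapping good-channel values to estimates at bad channels.

    Spherical-spline interpolation: positions are projected to the unit
    sphere; spline coefficients are solved on the good channels with a
    constant (reference) term, then evaluated at the bad positions.
    Exactly reproduces constant fields.
    """
    bad_idx = np.asarray([montage.index(b) for b in bad], dtype=int)
    good_idx = np.asarray(
        [i for i in range(montage.n_channels) if i not in set(bad_idx)], dtype=int
    )
    pos = montage.unit_positions()
    g_gg = _g_matrix(pos[good_idx] @ pos[good_idx].T, m, n_terms)
    g_bg = _g_matrix(pos[bad_idx] @ pos[good_idx].T, m, n_terms)
    k = len(good_idx)
    lhs = np.zeros((k + 1, k + 1))
    lhs[:k, :k] = g_gg + reg * np.eye(k)
    lhs[:k, k] = 1.0
    lhs[k, :k] = 1.0
    inv = np.linalg.pinv(lhs)
    # value(bad) = [g_bg | 1] @ inv @ [v_good; 0]
    proj = np.hstack([g_bg, np.ones((len(bad_idx), 1))]) @ inv[:, :k]
    return proj


def interpolate_bad_channels(
    obj: EpochSet | Evoked,
    bad: list[str],
    max_fraction: float = 0.16,
) -> EpochSet | Evoked:
    """Replace bad channels with spherical-spline estimates from the rest.

    Refuses (capacity error) when more than ``max_fraction`` of channels
    are bad — with 128 channels the default 16% cap corresponds to 20
    electrodes.  Good channels are untouched.
    """
    montage = obj.montage
    if not bad:
        return obj
    unknown = [b for b in bad if b not in montage.labels]
    if unknown:
        raise ValueError(f"unknown channels: {unknown}")
    if len(bad) / montage.n_channels > max_fraction + 1e-12:
        raise CapacityError(
            f"{len(bad)} bad of {montage.n_channels} channels exceeds the "
            f"{max_fraction:.0%} interpolation cap"
        )
    proj = interpolation_matrix(montage, bad)
    bad_idx = [montage.index(b) for b in bad]
    good_idx = [i for i in range(montage.n_channels) if i not in set(bad_idx)]
    data = np.array(obj.data, copy=True)
    if isinstance(obj, Evoked):
        data[bad_idx, :] = proj @ data[good_idx, :]
        return Evoked(
            data=data,
            montage=montage,
            time=obj.time,
            n_trials=obj.n_trials,
            condition=obj.condition,
            subject=obj.subject,
        )
    data[:, bad_idx, :] = np.einsum("bg,tgf->tbf", proj, data[:, good_idx, :])
    logger.info("interpolated %d of %d channels", len(bad), montage.n_channels)
    return EpochSet(
        data=data, montage=montage, time=obj.time, metadata=obj.metadata
    )


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------


def average_by(
    epochs: EpochSet, keys: tuple[str, ...] = ("subject", "condition")
) -> list[Evoked]:
    """Average accepted trials within each keys-cell into Evoked objects.

    Raises a missing-cell error naming any subject x condition (etc.)
    combination that exists in the metadata but has no accepted trial.
    """
    meta = epochs.metadata
    acc = epochs.accepted_mask()
    out: list[Evoked] = []
    for cell, idx in meta.groupby(list(keys), sort=True).groups.items():
        cell = cell if isinstance(cell, tuple) else (cell,)
        take = np.asarray(idx)[acc[np.asarray(idx)]]
        if len(take) == 0:
            raise MissingCellError(
                f"no accepted trials in cell {dict(zip(keys, cell))}"
            )
        info = dict(zip(keys, cell))
        out.append(
            Evoked(
                data=epochs.data[take].mean(axis=0),
                montage=epochs.montage,
                time=epochs.time,
                n_trials=len(take),
                condition=info.get("condition"),
                subject=info.get("subject"),
            )
        )
    return out


def grand_average(evokeds: list[Evoked]) -> Evoked:
    """Equal-weight average of per-subject evokeds (one condition)."""
    if not evokeds:
        raise ValueError("no evokeds to average")
    conds = {e.condition for e in evokeds}
    if len(conds) > 1:
        raise ValueError(f"mixed conditions in grand average: {conds}")
    data = np.mean([e.data for e in evokeds], axis=0)
    return Evoked(
        data=data,
        montage=evokeds[0].montage,
        time=evokeds[0].time,
        n_trials=len(evokeds),
        condition=evokeds[0].condition,
        subject=None,
    )


def run_pipeline(
    epochs: EpochSet,
    config: PreprocConfig | None = None,
    bad_channels: list[str] | None = None,
) -> tuple[list[Evoked], EpochSet]:
    """Filter -> reject -> interpolate -> re-reference -> average.

    Returns (per-subject-per-condition evokeds, the processed EpochSet).
    Epoch extraction is assumed done (the data are already epoched).
    """
    config = config or PreprocConfig()
    config.validate(epochs.time.sfreq)
    logger.info(
        "pipeline: filter(%.1f-%.1f Hz, notch %s) -> reject(+-%.0f uV) -> "
        "interpolate -> average reference -> average",
        config.highpass_hz,
        config.lowpass_hz,
        config.notch_hz,
        config.rejection_uv,
    )
    filtered = bandpass_notch(
        epochs.data,
        epochs.time.sfreq,
        config.highpass_hz,
        config.lowpass_hz,
        config.notch_hz,
        config.filter_order,
    )
    epochs = EpochSet(
        data=filtered,
        montage=epochs.montage,
        time=epochs.time,
        metadata=epochs.metadata,
    )
    epochs = reject_artifacts(epochs, config.rejection_uv)
    if bad_channels:
        epochs = interpolate_bad_channels(
            epochs, bad_channels, config.max_interpolated_fraction
        )
    epochs = EpochSet(
        data=average_reference(epochs.data, axis=1),
        montage=epochs.montage,
        time=epochs.time,
        metadata=epochs.metadata,
    )
    return average_by(epochs), epochs
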
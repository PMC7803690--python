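"""Core domain types and topographic measures for multichannel ERP data.

This module houses the quantities every other stage of the pipeline is
built on: the instantaneous scalp topography, global field power (GFP),
global map dissimilarity (DISS/GDI), spatial correlation between maps,
global explained variance (GEV) of a microstate labelling, and the
conversion between time frames (samples) and milliseconds.

Conventions
-----------
* Potentials are in microvolts throughout; conversions happen at I/O
  boundaries.
* All topographic measures operate on average-referenced maps.  Every
  function re-references defensively, so callers may pass maps in any
  reference.
* A "time frame" (TF) is one sample; at 512 Hz, 1 TF ~ 1.95 ms.
* Response-locked epochs place t = 0 at the vocal onset: sample ``i`` of
  an ``n_tf``-frame epoch with ``t0_index = n_tf - 1`` covers the TF
  interval ``[i - n_tf, i - n_tf + 1)``, i.e. the epoch spans
  ``[-n_tf, 0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "TimeAxis",
    "EpochSet",
    "Evoked",
    "tf_to_ms",
    "ms_to_tf",
    "min_duration_tf",
    "average_reference",
    "gfp",
    "spatial_correlation",
    "dissimilarity",
    "gev",
]


class TopographyError(ValueError):
    """Invalid input to a topographic measure (e.g. a flat, zero-GFP map)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Montage:
    """Electrode names and 3-D Cartesian sensor positions.

    Positions are in arbitrary length units with the origin at the head
    center; only directions matter for spherical-spline interpolation and
    synthetic topographies.
    """

    labels: tuple
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {pos.shape}")
        if len(labels) != pos.shape[0]:
            raise ValueError("labels and positions length mismatch")
        if len(labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("no electrode may sit at the head-center origin")
        pos.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def unit_positions(self) -> np.ndarray:
        """Positions projected onto the unit sphere."""
        pos = np.asarray(self.positions, float)
        return pos / np.linalg.norm(pos, axis=1, keepdims=True)


@dataclass(frozen=True)
class TimeAxis:
    """Sampling grid of an epoch, aligned to the vocal onset.

    ``t0_index`` is the index of the last sample before the alignment
    point; for response-locked epochs this is the final frame.
    """

    sfreq: float
    n_tf: int
    t0_index: int

    def __post_init__(self):
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if not (0 <= self.t0_index < self.n_tf):
            raise ValueError("t0_index must lie within the epoch")

    def tf_offsets(self) -> np.ndarray:
        """Signed TF index of each sample relative to the alignment point.

        The last sample of a response-locked epoch has offset -1; the
        epoch covers [-n_tf, 0).
        """
        return np.arange(self.n_tf) - (self.t0_index + 1)

    def times_ms(self) -> np.ndarray:
        return self.tf_offsets() * 1000.0 / self.sfreq


_META_COLUMNS = ("subject", "condition", "phoneme", "rt_ms", "accepted")


@dataclass
class EpochSet:
    """Single-trial epochs: trials x electrodes x time frames, with metadata.

    ``metadata`` carries one row per trial with at least the columns
    subject, condition, phoneme, rt_ms and accepted (bool).
    """

    data: np.ndarray
    montage: Montage
    time: TimeAxis
    metadata: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be trials x electrodes x TF")
        n_trials, n_ch, n_tf = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError(
                f"data has {n_ch} electrodes but montage has "
                f"{self.montage.n_channels}"
            )
        if n_tf != self.time.n_tf:
            raise ValueError("data/time axis length mismatch")
        if len(self.metadata) != n_trials:
            raise ValueError("metadata rows must match trial count")
        missing = [c for c in _META_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def accepted_mask(self) -> np.ndarray:
        return self.metadata["accepted"].to_numpy(dtype=bool)

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            montage=self.montage,
            time=self.time,
            metadata=self.metadata.loc[mask].reset_index(drop=True),
        )


@dataclass
class Evoked:
    """An averaged ERP (electrodes x time frames).

    ``subject`` is None for grand averages across participants.
    """

    data: np.ndarray
    montage: Montage
    time: TimeAxis
    n_trials: int
    condition: str | None = None
    subject: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Evoked data must be electrodes x TF")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError("Evoked/montage channel mismatch")
        if self.data.shape[1] != self.time.n_tf:
            raise ValueError("Evoked/time axis length mismatch")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


# ---------------------------------------------------------------------------
# TF <-> ms conversions
# ---------------------------------------------------------------------------


def tf_to_ms(n: float, sfreq: float, round_to: int = 1) -> int:
    """Convert a time-frame count to milliseconds, rounded to a granularity.

    With ``round_to=1`` the result is the nearest millisecond (150 TF at
    512 Hz -> 293 ms); ``round_to=10`` rounds to the nearest 10 ms, the
    granularity used when quoting approximate windows (90 TF -> 180 ms).
    """
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    if n < 0:
        raise ValueError("time-frame count must be non-negative")
    if round_to not in (1, 10):
        raise ValueError("round_to must be 1 or 10 ms")
    ms = n * 1000.0 / sfreq
    return int(math.floor(ms / round_to + 0.5)) * round_to


def ms_to_tf(ms: float, sfreq: float) -> int:
    """Convert milliseconds to the nearest integer time-frame count."""
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    return int(math.floor(ms * sfreq / 1000.0 + 0.5))


def min_duration_tf(ms: float, sfreq: float) -> int:
    """Smallest whole TF count lasting at least ``ms`` milliseconds.

    Duration criteria ("a topography must persist >= 10 ms") need the
    ceiling, not the nearest integer: 10 ms at 512 Hz is 5.12 TF, so a
    run must span 6 frames to satisfy it.
    """
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    return int(math.ceil(ms * sfreq / 1000.0 - 1e-9))


# ---------------------------------------------------------------------------
# Topographic measures
# ---------------------------------------------------------------------------


def average_reference(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Re-reference to the common average (subtract the spatial mean).

    Idempotent; the output sums to zero along ``axis``.
    """
    values = np.asarray(values, dtype=float)
    return values - values.mean(axis=axis, keepdims=True)


def gfp(values: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Global field power: spatial standard deviation of a scalp map.

    GFP(u) = sqrt( (1/N) * sum_i (u_i - mean(u))^2 ), the overall field
    strength at one instant.  Invariant to common-mode offsets; zero iff
    the map is flat.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[axis] < 2:
        raise TopographyError("GFP requires at least 2 electrodes")
    out = values.std(axis=axis, ddof=0)
    return float(out) if np.ndim(out) == 0 else out


def _normalized(values: np.ndarray, what: str) -> np.ndarray:
    """Average-reference and scale a 1-D map to unit GFP."""
    v = average_reference(np.asarray(values, dtype=float))
    g = v.std(ddof=0)
    if g == 0 or not np.isfinite(g):
        raise TopographyError(f"{what}: map has zero GFP (flat topography)")
    return v / g


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across electrodes of two average-referenced maps.

    Symmetric, scale-invariant, in [-1, 1].  Raises on flat maps rather
    than returning NaN, so degenerate frames cannot silently corrupt
    permutation counts.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("maps must share a montage (same length)")
    an = _normalized(a, "spatial_correlation")
    bn = _normalized(b, "spatial_correlation")
    return float(np.mean(an * bn))


def dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """Global map dissimilarity (DISS / GDI) between two scalp maps.

    Root-mean-square difference of the GFP-normalized, average-referenced
    maps: a strength-independent topographic distance in [0, 2], 0 for
    proportional maps (positive factor) and 2 for exact polarity
    inversion.  Satisfies DISS^2 = 2 * (1 - r) with r the spatial
    correlation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("maps must share a montage (same length)")
    an = _normalized(a, "dissimilarity")
    bn = _normalized(b, "dissimilarity")
    return float(np.sqrt(np.mean((an - bn) ** 2)))


def gev(
    evoked: Evoked | np.ndarray,
    templates: Sequence[np.ndarray],
    labels: Sequence[int],
) -> float:
    """Global explained variance of a per-TF template labelling.

    GEV = sum_t (GFP_t * r(u_t, T_label(t)))^2 / sum_t GFP_t^2, the
    GFP-weighted fraction of topographic variance captured by assigning
    each time frame to one template.  Equals 1 when every frame is
    exactly proportional to its template; flat (zero-GFP) frames
    contribute nothing.
    """
    data = evoked.data if isinstance(evoked, Evoked) else np.asarray(evoked, float)
    labels = np.asarray(labels, dtype=int)
    if data.ndim != 2:
        raise ValueError("evoked data must be electrodes x TF")
    n_ch, n_tf = data.shape
    if labels.shape != (n_tf,):
        raise ValueError("labels length must equal the number of time frames")
    tmpl = np.asarray([_normalized(t, "gev template") for t in templates])
    if labels.min() < 0 or labels.max() >= len(tmpl):
        raise ValueError("labels reference non-existent templates")

    u = average_reference(data, axis=0)
    g = u.std(axis=0, ddof=0)
    total = float(np.sum(g**2))
    if total == 0:
        raise TopographyError("gev: evoked data is identically zero")
    num = 0.0
    for t in range(n_tf):
        if g[t] == 0:
            continue
        r = float(np.mean((u[:, t] / g[t]) * tmpl[labels[t]]))
        num += (g[t] * r) ** 2
    return num / total
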
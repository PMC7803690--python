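"""Back-fitting of group-level template maps into ERPs and single trials.

Each time frame of a target (an individual average ERP or a single-trial
epoch) is labelled with the template it best correlates with spatially
(signed correlation — polarity matters for evoked data).  Durations are
counts of labelled frames within a fixed fitting window, so per epoch
they always sum to the window length; the per-map duration is the core
dependent variable carrying the articulatory-to-acoustic interval.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import smooth_labels
from .topography import EpochSet, Evoked, tf_to_ms

logger = logging.getLogger(__name__)

__all__ = [
    "backfit_labels",
    "backfit_evoked",
    "backfit_epochs",
    "duration_summary",
]

DURATION_COLUMNS = (
    "subject",
    "condition",
    "phoneme",
    "trial",
    "map",
    "duration_tf",
    "duration_ms",
)


def backfit_labels(
    data: np.ndarray,
    templates: np.ndarray,
    smoothing: bool = False,
    min_duration_ms: float = 10.0,
    sfreq: float = 512.0,
) -> np.ndarray:
    """Label every time frame with its best-correlating template.

    Ties break toward the previous frame's label (lowest template index
    at the first frame) to favour temporal continuity; zero-GFP frames
    inherit the previous label and are logged.  With ``smoothing`` the
    duration criterion of the segmentation is applied to the raw labels.
    """
    data = np.asarray(data, float)
    templates = np.asarray(templates, float)
    tm = templates - templates.mean(axis=1, keepdims=True)
    tm = tm / tm.std(axis=1, ddof=0, keepdims=True)
    u = data - data.mean(axis=0, keepdims=True)
    g = u.std(axis=0, ddof=0)
    safe_g = np.where(g == 0, 1.0, g)
    r = tm @ (u / safe_g) / data.shape[0]  # (K, n_tf)

    n_tf = data.shape[1]
    labels = np.empty(n_tf, dtype=int)
    prev = 0
    n_flat = 0
    for t in range(n_tf):
        if g[t] == 0:
            labels[t] = prev
            n_flat += 1
            continue
        col = r[:, t]
        best = float(col.max())
        tied = np.flatnonzero(col >= best - 1e-12)
        labels[t] = prev if prev in tied else int(tied[0])
        prev = labels[t]
    if n_flat:
        logger.info("%d zero-GFP frame(s) inherited the previous label", n_flat)
    if smoothing:
        labels = smooth_labels(labels, data, templates, min_duration_ms, sfreq)
    return labels


def _duration_rows(
    labels: np.ndarray,
    window: tuple[int, int],
    template_letters: Sequence[str],
    sfreq: float,
    subject,
    condition,
    phoneme,
    trial,
) -> list[dict]:
    lo, hi = window
    counts = np.bincount(labels[lo:hi], minlength=len(template_letters))
    rows = []
    for j, letter in enumerate(template_letters):
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "phoneme": phoneme,
                "trial": trial,
                "map": letter,
                "duration_tf": int(counts[j]),
                "duration_ms": tf_to_ms(int(counts[j]), sfreq),
            }
        )
    return rows


def _check_window(window: tuple[int, int] | None, n_tf: int) -> tuple[int, int]:
    if window is None:
        return 0, n_tf
    lo, hi = window
    if not (0 <= lo < hi <= n_tf):
        raise ValueError(f"window {window} outside the epoch [0, {n_tf})")
    return lo, hi


def backfit_evoked(
    evoked: Evoked,
    templates: np.ndarray,
    template_letters: Sequence[str] | None = None,
    window: tuple[int, int] | None = None,
    smoothing: bool = False,
    min_duration_ms: float = 10.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fit templates into one averaged ERP.

    Returns the per-TF labels and duration rows (trial = 'average').
    The window is a half-open frame interval; default is the full epoch
    (150 TF response-locked: the fixed -150..0 TF fitting window).
    """
    templates = np.asarray(templates, float)
    if templates.size == 0:
        raise ValueError("no templates to fit")
    letters = tuple(template_letters or [chr(65 + i) for i in range(len(templates))])
    window = _check_window(window, evoked.time.n_tf)
    labels = backfit_labels(
        evoked.data, templates, smoothing, min_duration_ms, evoked.time.sfreq
    )
    rows = _duration_rows(
        labels,
        window,
        letters,
        evoked.time.sfreq,
        subject=evoked.subject,
        condition=evoked.condition,
        phoneme=None,
        trial="average",
    )
    return labels, pd.DataFrame(rows, columns=DURATION_COLUMNS)


def backfit_epochs(
    epochs: EpochSet,
    templates: np.ndarray,
    template_letters: Sequence[str] | None = None,
    window: tuple[int, int] | None = None,
    smoothing: bool = True,
    min_duration_ms: float = 10.0,
) -> pd.DataFrame:
    """Fit templates into every accepted single trial.

    Single-trial labels are smoothed with the same >= 10 ms duration
    criterion as the segmentation by default (raw argmax labels on noisy
    trials flicker); pass ``smoothing=False`` for raw labels.
    """
    templates = np.asarray(templates, float)
    letters = tuple(template_letters or [chr(65 + i) for i in range(len(templates))])
    window = _check_window(window, epochs.time.n_tf)
    rows: list[dict] = []
    meta = epochs.metadata
    for i in np.flatnonzero(epochs.accepted_mask()):
        labels = backfit_labels(
            epochs.data[i], templates, smoothing, min_duration_ms, epochs.time.sfreq
        )
        rows.extend(
            _duration_rows(
                labels,
                window,
                letters,
                epochs.time.sfreq,
                subject=meta.at[i, "subject"],
                condition=meta.at[i, "condition"],
                phoneme=meta.at[i, "phoneme"],
                trial=int(i),
            )
        )
    return pd.DataFrame(rows, columns=DURATION_COLUMNS)


def duration_summary(
    table: pd.DataFrame,
    by: Sequence[str] = ("condition",),
    maps: Sequence[str] | None = None,
    sfreq: float = 512.0,
) -> pd.DataFrame:
    """Grouped mean/SD of map durations, in TF and ms.

    Groups by ``("map",) + by``; restrict to particular maps with
    ``maps``.  SDs use ddof=1 (sample SD).
    """
    if table.empty:
        raise ValueError("empty duration table")
    t = table if maps is None else table[table["map"].isin(maps)]
    if t.empty:
        raise ValueError(f"no rows for maps {maps}")
    keys = ["map", *by]
    grouped = t.groupby(keys, sort=True)["duration_tf"]
    out = grouped.agg(
        mean_tf="mean", sd_tf=lambda x: x.std(ddof=1), n="count"
    ).reset_index()
    for cell in out.itertuples():
        if cell.n == 0:
            raise ValueError(f"empty group {tuple(cell[1 : len(keys) + 1])}")
    out["mean_ms"] = out["mean_tf"] * 1000.0 / sfreq
    out["sd_ms"] = out["sd_tf"] * 1000.0 / sfreq
    return out
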
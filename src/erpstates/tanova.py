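"""Topographic analysis of variance (TANOVA).

A point-by-point nonparametric randomization test of topographic
differences between two conditions in a within-subject design.  The test
statistic at each time frame is the global map dissimilarity (DISS/GDI)
between the two condition grand averages — a strength-independent
distance between GFP-normalized average-referenced maps.  The null
distribution is built by randomly swapping each subject's two condition
topographies; significance at alpha is then pruned by a consecutive-
duration criterion (default 10 ms) to discard isolated significant
frames.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topography import Evoked, TimeAxis, min_duration_tf

__all__ = ["TanovaResult", "tanova", "significant_runs", "find_runs"]


class DesignError(ValueError):
    """The paired two-condition design is violated."""


@dataclass
class TanovaResult:
    """Per-TF observed dissimilarity, permutation p-values and flags."""

    diss: np.ndarray  # (n_tf,) observed DISS between condition GAs
    p: np.ndarray  # (n_tf,) permutation p-values (NaN for excluded TFs)
    alpha: float
    min_duration_ms: float
    significant: np.ndarray  # (n_tf,) bool, after the duration criterion
    n_permutations: int
    seed: int
    time: TimeAxis
    conditions: tuple[str, str]
    excluded_tf: np.ndarray  # indices of zero-GFP frames left untested

    def runs(self) -> list[tuple[int, int]]:
        return significant_runs(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tf": np.arange(self.time.n_tf),
                "tf_offset": self.time.tf_offsets(),
                "time_ms": self.time.times_ms(),
                "diss": self.diss,
                "p": self.p,
                "significant": self.significant,
            }
        )

    def to_json_summary(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "min_duration_ms": self.min_duration_ms,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
                "conditions": list(self.conditions),
                "runs": [list(r) for r in self.runs()],
                "excluded_tf": self.excluded_tf.tolist(),
            },
            indent=2,
        )


def _normalize_frames(ga: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference per frame and scale to unit GFP.

    Returns (normalized (n_ch, n_tf), zero-GFP frame mask).
    """
    u = ga - ga.mean(axis=0, keepdims=True)
    g = u.std(axis=0, ddof=0)
    flat = g == 0
    g = np.where(flat, 1.0, g)
    return u / g, flat


def _paired_arrays(
    evokeds: list[Evoked],
) -> tuple[np.ndarray, np.ndarray, tuple[str, str], TimeAxis]:
    """Stack per-subject evokeds into paired (S, n_ch, n_tf) arrays."""
    conds = sorted({e.condition for e in evokeds if e.condition is not None})
    if len(conds) != 2:
        raise DesignError(f"need exactly 2 conditions, got {conds}")
    by: dict[str, dict[str, Evoked]] = {}
    for e in evokeds:
        if e.subject is None:
            raise DesignError("per-subject evokeds required (subject id missing)")
        by.setdefault(e.subject, {})[e.condition] = e
    subjects = sorted(by)
    for s in subjects:
        if set(by[s]) != set(conds):
            raise DesignError(f"subject {s} lacks one condition (paired design)")
    a = np.stack([by[s][conds[0]].data for s in subjects])
    b = np.stack([by[s][conds[1]].data for s in subjects])
    return a, b, (conds[0], conds[1]), evokeds[0].time


def tanova(
    evokeds: list[Evoked],
    n_permutations: int = 1000,
    alpha: float = 0.01,
    min_duration_ms: float = 10.0,
    seed: int = 0,
) -> TanovaResult:
    """Run the paired two-condition TANOVA on per-subject evokeds.

    At each TF the observed statistic is the DISS between the two
    condition grand averages.  Each permutation independently flips every
    subject's condition assignment and recomputes the grand-average DISS;
    p = (#{permuted >= observed} + 1) / (n_permutations + 1), which can
    never reach zero.  Frames whose grand average has zero GFP in either
    condition are excluded with a warning (p = NaN, not significant).
    Significant runs shorter than the duration criterion are cleared.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    a, b, conds, time = _paired_arrays(evokeds)
    n_subj, n_ch, n_tf = a.shape

    mean_sum = (a + b).mean(axis=0) / 2.0  # (Abar + Bbar)/2
    diff = a - b  # (S, n_ch, n_tf)
    mean_diff = diff.mean(axis=0)

    def diss_between(ga1: np.ndarray, ga2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u1, f1 = _normalize_frames(ga1)
        u2, f2 = _normalize_frames(ga2)
        d = np.sqrt(np.mean((u1 - u2) ** 2, axis=0))
        return d, f1 | f2

    obs, flat = diss_between(mean_sum + mean_diff / 2, mean_sum - mean_diff / 2)

    rng = np.random.default_rng(seed)
    # Sign flip s_i = +-1 per subject per permutation; the permuted
    # condition difference is mean_i(s_i * diff_i).
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_subj))
    flat_diff = diff.reshape(n_subj, -1)
    perm_diffs = (signs @ flat_diff) / n_subj  # (P, n_ch*n_tf)
    count = np.zeros(n_tf)
    perm_flat_any = np.zeros(n_tf, dtype=bool)
    for p_ in range(n_permutations):
        d_half = perm_diffs[p_].reshape(n_ch, n_tf) / 2.0
        d, fl = diss_between(mean_sum + d_half, mean_sum - d_half)
        count += d >= obs
        perm_flat_any |= fl

    p = (count + 1.0) / (n_permutations + 1.0)
    excluded = np.flatnonzero(flat)
    if excluded.size:
        warnings.warn(
            f"{excluded.size} frame(s) have a zero-GFP grand average and "
            "were excluded from the TANOVA",
            stacklevel=2,
        )
        p[flat] = np.nan
    sig = np.zeros(n_tf, dtype=bool)
    valid = ~flat
    sig[valid] = p[valid] < alpha

    min_tf = min_duration_tf(min_duration_ms, time.sfreq) if min_duration_ms > 0 else 1
    for start, end in find_runs(sig):
        if end - start < min_tf:
            sig[start:end] = False

    return TanovaResult(
        diss=obs,
        p=p,
        alpha=alpha,
        min_duration_ms=min_duration_ms,
        significant=sig,
        n_permutations=n_permutations,
        seed=seed,
        time=time,
        conditions=conds,
        excluded_tf=excluded,
    )


def find_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, half-open [start, end)."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    edges = np.flatnonzero(np.diff(flags.astype(np.int8)))
    starts = list(edges[flags[edges + 1]] + 1)
    ends = list(edges[~flags[edges + 1]] + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(flags.size)
    return list(zip(starts, ends))


def significant_runs(result: TanovaResult) -> list[tuple[int, int]]:
    """Maximal significant windows of a TANOVA result, sorted."""
    return find_runs(result.significant)
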
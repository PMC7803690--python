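"""Spatio-temporal microstate segmentation of condition grand averages.

A polarity-sensitive modified k-means clusters the successive scalp
topographies of the (concatenated) condition grand averages into K
template maps, with GFP-weighted template updates and multiple random
restarts.  Temporally isolated labels are removed by a duration
criterion (a topography must persist at least 10 ms by default), and the
quality of the labelling is summarized by the global explained variance
(GEV).

The polarity-sensitive variant (signed spatial correlation) is the ERP
convention: unlike resting-state microstates, evoked components of
opposite polarity are distinct states and must not be merged.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .topography import Evoked, TimeAxis, min_duration_tf

__all__ = [
    "SegmentationResult",
    "segment",
    "smooth_labels",
    "choose_k",
]

_MAX_ITER = 500


@dataclass
class SegmentationResult:
    """K templates plus per-condition per-TF labels and their GEV."""

    k: int
    templates: np.ndarray  # (K, n_ch) unit GFP, zero mean
    labels: dict  # condition -> (n_tf,) template indices
    gev: float
    n_restarts: int
    seed: int
    time: TimeAxis
    template_labels: tuple  # letter per template, index-aligned

    def labels_concatenated(self) -> np.ndarray:
        return np.concatenate([self.labels[c] for c in sorted(self.labels)])


def _frames(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-referenced frames and their GFP.  data: (n_ch, n_tf)."""
    u = data - data.mean(axis=0, keepdims=True)
    g = u.std(axis=0, ddof=0)
    return u, g


def _correlations(templates: np.ndarray, u: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Signed spatial correlations (K, n_tf); zero for flat frames.

    Assumes unit-GFP zero-mean templates; frames are normalized here.
    """
    safe_g = np.where(g == 0, 1.0, g)
    un = u / safe_g
    r = templates @ un / u.shape[0]
    r[:, g == 0] = 0.0
    return r


def _gev_from(r: np.ndarray, labels: np.ndarray, g: np.ndarray) -> float:
    rl = r[labels, np.arange(len(labels))]
    denom = float(np.sum(g**2))
    return float(np.sum((g * rl) ** 2) / denom)


def _normalize_templates(t: np.ndarray) -> np.ndarray:
    t = t - t.mean(axis=-1, keepdims=True)
    norms = t.std(axis=-1, ddof=0, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate (flat) template encountered")
    return t / norms


def _kmeans_once(
    u: np.ndarray,
    g: np.ndarray,
    k: int,
    rng: np.random.Generator,
    init_templates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One modified-k-means run.  Returns (templates, labels, gev)."""
    n_ch, n_tf = u.shape
    if init_templates is None:
        idx = rng.choice(np.flatnonzero(g > 0), size=k, replace=False)
        templates = _normalize_templates(u[:, idx].T.copy())
    else:
        templates = _normalize_templates(init_templates.copy())
    labels = np.full(n_tf, -1)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(_MAX_ITER):
        r = _correlations(templates, u, g)
        new_labels = np.argmax(r, axis=0)
        gev_ = _gev_from(r, new_labels, g)
        # >= so that, at equal GEV, the more converged iterate wins
        if best is None or gev_ >= best[0]:
            best = (gev_, templates.copy(), new_labels)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if not sel.any():
                # Re-seed an empty cluster from the worst-fit frame.
                fit = r[labels, np.arange(n_tf)]
                worst = int(np.argmin(np.where(g > 0, fit, np.inf)))
                templates[j] = u[:, worst] / g[worst]
                continue
            upd = (u[:, sel] * g[sel]).sum(axis=1)
            if upd.std(ddof=0) == 0:
                continue
            templates[j] = upd
        templates = _normalize_templates(templates)
    assert best is not None
    gev_, templates, labels = best
    return templates, labels, gev_


def smooth_labels(
    labels: np.ndarray,
    data: np.ndarray,
    templates: np.ndarray,
    min_duration_ms: float,
    sfreq: float,
) -> np.ndarray:
    """Absorb label runs shorter than the duration criterion.

    Each frame of a too-short run is reassigned to whichever adjacent
    segment's template correlates better (signed) with that frame's
    topography; runs at the epoch edge take their single neighbour.
    Iterates until no short run remains — the run count strictly
    decreases each pass, so termination is guaranteed.  If the whole
    epoch is shorter than the criterion, the labels are returned
    unchanged.
    """
    labels = np.asarray(labels, dtype=int).copy()
    n_tf = len(labels)
    min_tf = min_duration_tf(min_duration_ms, sfreq)
    if min_tf <= 1:
        return labels
    if n_tf < min_tf:
        import warnings

        warnings.warn(
            "epoch shorter than the duration criterion; labels unchanged",
            stacklevel=2,
        )
        return labels
    u, g = _frames(np.asarray(data, float))
    r = _correlations(_normalize_templates(np.asarray(templates, float)), u, g)

    def all_runs(lab):
        runs = []
        start = 0
        for t in range(1, n_tf + 1):
            if t == n_tf or lab[t] != lab[start]:
                runs.append((start, t))
                start = t
        return runs

    while True:
        runs = all_runs(labels)
        short = [(s, e) for s, e in runs if e - s < min_tf]
        if not short or len(runs) == 1:
            break
        # Absorb the shortest run first (ties: earliest).
        s, e = min(short, key=lambda se: (se[1] - se[0], se[0]))
        i = runs.index((s, e))
        left = labels[runs[i - 1][0]] if i > 0 else None
        right = labels[runs[i + 1][0]] if i + 1 < len(runs) else None
        for t in range(s, e):
            if left is None:
                labels[t] = right
            elif right is None:
                labels[t] = left
            else:
                labels[t] = left if r[left, t] >= r[right, t] else right
    return labels


def segment(
    evokeds: list[Evoked],
    k: int = 4,
    n_restarts: int = 50,
    min_duration_ms: float = 10.0,
    seed: int = 0,
    extra_inits: list[np.ndarray] | None = None,
) -> SegmentationResult:
    """Segment the concatenated condition grand averages into K maps.

    The condition grand averages share one template set — required for
    cross-condition back-fitting comparisons.  Runs ``n_restarts``
    random initializations (frames drawn without replacement) plus any
    ``extra_inits`` (e.g. warm starts from a smaller K), keeps the
    solution with the highest GEV, then applies the duration-criterion
    smoothing per condition and reports the post-smoothing GEV.

    Template letters are assigned by mean occurrence time, latest first:
    the map bordering the vocal onset is "A".
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    datas = {e.condition or f"cond{i}": e.data for i, e in enumerate(evokeds)}
    if len(datas) != len(evokeds):
        raise ValueError("duplicate condition names among evokeds")
    conds = sorted(datas)
    concat = np.concatenate([datas[c] for c in conds], axis=1)
    u, g = _frames(concat)
    if np.any(g == 0):
        raise ValueError("zero-GFP frame: segmentation input is degenerate")
    if k > u.shape[1]:
        raise ValueError("k exceeds the number of frames")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    inits: list[np.ndarray | None] = [None] * n_restarts
    for init in extra_inits or []:
        inits.append(np.asarray(init, float))
    for init in inits:
        templates, labels, gev_ = _kmeans_once(u, g, k, rng, init)
        if best is None or gev_ > best[0]:
            best = (gev_, templates, labels)
    assert best is not None
    _, templates, labels = best

    # Smooth per condition, then recompute the overall GEV.
    n_tf = evokeds[0].time.n_tf
    by_cond: dict[str, np.ndarray] = {}
    for i, c in enumerate(conds):
        lab = labels[i * n_tf : (i + 1) * n_tf]
        by_cond[c] = smooth_labels(
            lab, datas[c], templates, min_duration_ms, evokeds[0].time.sfreq
        )
    smoothed = np.concatenate([by_cond[c] for c in conds])
    r = _correlations(templates, u, g)
    gev_final = _gev_from(r, smoothed, g)

    # Letter assignment: latest mean occurrence -> "A".
    positions = np.tile(np.arange(n_tf), len(conds))
    mean_pos = np.full(k, -np.inf)
    for j in range(k):
        sel = smoothed == j
        if sel.any():
            mean_pos[j] = positions[sel].mean()
    order = np.argsort(-mean_pos)  # template indices, latest first
    letters = [""] * k
    for rank, j in enumerate(order):
        letters[j] = string.ascii_uppercase[rank]

    return SegmentationResult(
        k=k,
        templates=templates,
        labels=by_cond,
        gev=gev_final,
        n_restarts=n_restarts,
        seed=seed,
        time=evokeds[0].time,
        template_labels=tuple(letters),
    )


def choose_k(
    evokeds: list[Evoked],
    k_range: range | list[int],
    criterion: str = "elbow",
    fixed_k: int | None = None,
    min_ratio: float = 2.0,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick the number of templates.

    ``criterion='fixed'`` returns ``fixed_k``.  The default elbow rule
    runs the segmentation for each K from the smallest candidate to one
    past the largest (warm-starting each K from the best K-1 solution so
    GEV is non-decreasing) and scores each candidate by the ratio of its
    GEV gain to the next gain, gain(K)/gain(K+1) -- large where adding a
    K-th map explains real structure but a (K+1)-th adds only chance
    level variance (roughly one part in the channel count).  The
    candidate with the highest ratio wins provided the ratio reaches
    ``min_ratio``; on structureless data successive gains are all
    comparable, no candidate clears the bar, and the smallest K is
    returned.  Returns (K, {K: GEV}).
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    if criterion == "fixed":
        if fixed_k is None:
            raise ValueError("fixed criterion needs fixed_k")
        return fixed_k, {}
    gevs: dict[int, float] = {}
    prev_templates: np.ndarray | None = None
    full: dict[int, float] = {0: 0.0}
    for k in range(min(ks), max(ks) + 2):
        extra = None
        if prev_templates is not None:
            # Warm start: previous K-1 templates plus a duplicate that the
            # empty-cluster rule re-seeds -- guarantees GEV_K >= GEV_{K-1}.
            extra = [np.vstack([prev_templates, prev_templates[:1]])]
        res = segment(
            evokeds,
            k=k,
            n_restarts=n_restarts,
            min_duration_ms=0.0,  # selection runs without smoothing
            seed=seed + k,
            extra_inits=extra,
        )
        full[k] = res.gev
        prev_templates = res.templates
        if k in ks:
            gevs[k] = res.gev
    chosen, best_ratio = ks[0], 0.0
    for k in ks:
        if k - 1 not in full or k + 1 not in full:
            continue
        gain = full[k] - full[k - 1]
        next_gain = max(full[k + 1] - full[k], 1e-12)
        ratio = gain / next_gain
        if ratio >= min_ratio and ratio > best_ratio:
            chosen, best_ratio = k, ratio
    return chosen, gevs
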
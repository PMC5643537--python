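"""Polarity-invariant microstate extraction, back-fitting and matching.

The clustering is the modified (topographic) k-means: maps are assigned to
the template with the highest *squared* spatial correlation, so a map and
its sign-flip belong to the same state, and each template is updated as the
dominant eigenvector of the sum of outer products of its assigned maps —
the exact polarity-invariant centroid.  Model order is chosen at the
absolute minimum of the cross-validation criterion

    CV(K) = sigma2_K * ((C - 1) / (C - 1 - K))**2

where ``C`` is the channel count and ``sigma2_K`` the mean per-map residual
variance after projection onto the assigned unit-norm template.  Back-fitted
label sequences are smoothed by rejecting segments shorter than 23 ms,
absorbing their samples into the neighboring state of higher template
correlation.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import MicrostateSet, Recording, Segmentation, run_list

logger = logging.getLogger(__name__)

MIN_SEGMENT_MS = 23.0
MATCH_THRESHOLD = 0.65
STATE_NAMES = "ABCDEFGHIJKL"


def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: per-sample spatial SD around the channel mean."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("GFP needs >= 2 channels")
    return data.std(axis=0, ddof=0)


def find_gfp_peaks(series: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a 1-D series."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("series must have length >= 3")
    inner = (series[1:-1] > series[:-2]) & (series[1:-1] > series[2:])
    return np.flatnonzero(inner) + 1


def peak_maps(rec: Recording) -> np.ndarray:
    """Average-referenced maps sampled at the GFP peaks of a recording."""
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    peaks = find_gfp_peaks(gfp(centered))
    if peaks.size == 0:
        raise ValueError("no GFP peaks found")
    return centered[:, peaks].T


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _dominant_eigenvector(maps: np.ndarray) -> np.ndarray:
    """First eigenvector of ``maps.T @ maps`` (polarity-invariant mean map)."""
    cov = maps.T @ maps
    _vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    v = v - v.mean()                  # restore average reference exactly
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def modified_kmeans(maps: np.ndarray, k: int, n_init: int = 10,
                    max_iter: int = 100, seed: int | np.random.Generator = 0,
                    ) -> tuple[MicrostateSet, np.ndarray, float]:
    """Polarity-invariant topographic k-means; best of ``n_init`` restarts.

    Parameters
    ----------
    maps:
        ``samples x channels`` average-referenced maps (typically taken at
        GFP peaks).
    k:
        Number of template maps.

    Returns
    -------
    (set, assignment, explained_variance) where explained variance is the
    fraction of total squared map amplitude captured by the assigned
    templates and the restart winner maximizes it.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n, c = maps.shape
    if n < k:
        raise ValueError(f"{n} maps cannot form {k} clusters")
    distinct = np.unique(np.round(_normalize_maps(maps), 12), axis=0)
    if distinct.shape[0] < k:
        raise ValueError("k exceeds the number of distinct maps")
    rng = np.random.default_rng(seed)
    total = float(np.sum(maps ** 2))
    norm_maps = _normalize_maps(maps)

    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    for _restart in range(n_init):
        idx = rng.choice(n, size=k, replace=False)
        templates = _normalize_maps(maps[idx].copy())
        assignment = np.full(n, -1)
        converged = False
        for _it in range(max_iter):
            sim = (norm_maps @ templates.T) ** 2          # squared correlation
            new_assignment = sim.argmax(axis=1)
            if np.array_equal(new_assignment, assignment):
                converged = True
                break
            assignment = new_assignment
            for j in range(k):
                members = maps[assignment == j]
                if members.shape[0] == 0:
                    worst = int(np.argmin(sim.max(axis=1)))
                    templates[j] = norm_maps[worst]
                else:
                    templates[j] = _dominant_eigenvector(members)
        proj = maps @ templates.T
        ev = float(np.sum(proj[np.arange(n), assignment] ** 2) / total)
        if best is None or ev > best[0]:
            best = (ev, templates.copy(), assignment.copy(), converged)
    assert best is not None
    ev, templates, assignment, converged = best
    if not converged:
        logger.warning("modified k-means did not converge; best-so-far returned")
    msset = MicrostateSet(maps=templates,
                          labels=[STATE_NAMES[i] for i in range(k)],
                          explained_variance=ev)
    return msset, assignment, ev


def cv_criterion(maps: np.ndarray, msset: MicrostateSet) -> float:
    """Cross-validation criterion of a template set on a map sample."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    c = maps.shape[1]
    k = msset.n_states
    if k >= c - 1:
        raise ValueError("criterion undefined for K >= channels - 1")
    templates = _normalize_maps(msset.maps)
    proj = maps @ templates.T
    best = np.max(proj ** 2, axis=1)
    residual = np.sum(maps ** 2, axis=1) - best
    sigma2 = float(np.mean(residual) / (c - 1))
    return sigma2 * ((c - 1) / (c - 1 - k)) ** 2


def select_k(maps: np.ndarray, k_range=range(2, 9), n_init: int = 10,
             seed: int | np.random.Generator = 0,
             ) -> tuple[MicrostateSet, dict[int, float]]:
    """Run the clustering per K and keep the CV minimum (ties -> smaller K)."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    rng = np.random.default_rng(seed)
    cv_curve: dict[int, float] = {}
    best: tuple[float, int, MicrostateSet] | None = None
    for k in sorted(k_range):
        msset, _assignment, _ev = modified_kmeans(maps, k, n_init=n_init,
                                                  seed=rng)
        cv = cv_criterion(maps, msset)
        msset.cv_value = cv
        cv_curve[k] = cv
        if best is None or cv < best[0] - 1e-15:     # strict: ties keep smaller K
            best = (cv, k, msset)
    assert best is not None
    return best[2], cv_curve


def backfit(rec: Recording, msset: MicrostateSet) -> Segmentation:
    """Label every sample with the template of highest |spatial correlation|."""
    if rec.n_channels != msset.n_channels:
        raise ValueError("channel count mismatch between recording and maps")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    g = gfp(centered)
    templates = _normalize_maps(msset.maps - msset.maps.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(centered, axis=0)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    corr = np.abs(templates @ (centered / safe))      # states x samples
    labels = corr.argmax(axis=0)
    zero = norms == 0
    if zero.any():
        # zero-variance samples carry the previous label (forward fill; a
        # leading zero-variance run takes the first assigned label)
        valid = np.flatnonzero(~zero)
        if valid.size == 0:
            raise ValueError("recording has no nonzero-variance samples")
        filled = labels.copy()
        last = labels[valid[0]]
        for i in range(labels.size):
            if zero[i]:
                filled[i] = last
            else:
                last = filled[i]
        labels = filled
        corr[:, zero] = corr[:, zero] * 0.0
    return Segmentation(labels=labels, gfp=g, rate=rec.rate, correlations=corr)


def min_duration_samples(min_dur_ms: float, rate: float) -> int:
    return int(math.ceil(min_dur_ms * rate / 1000.0))


def smooth_segmentation(seg: Segmentation, min_dur_ms: float = MIN_SEGMENT_MS,
                        rate: float | None = None) -> Segmentation:
    """Reject segments shorter than ``min_dur_ms``.

    Samples of a rejected segment are absorbed one by one into whichever
    neighboring segment's state has the higher template correlation at that
    sample; absorption repeats until every remaining segment meets the
    minimum duration.  Each absorption strictly reduces the number of
    segments, so the procedure terminates.
    """
    rate = seg.rate if rate is None else rate
    if rate <= 0:
        raise ValueError("rate must be > 0")
    min_len = min_duration_samples(min_dur_ms, rate)
    labels = seg.labels.copy()
    if labels.size < min_len:
        raise ValueError("recording shorter than the minimum segment duration")
    corr = seg.correlations
    while True:
        runs = run_list(labels)
        if len(runs) <= 1:
            break
        short = [r for r in runs if (r[1] - r[0]) < min_len]
        if not short:
            break
        start, end, _state = min(short, key=lambda r: r[1] - r[0])
        i = runs.index((start, end, _state))
        left = runs[i - 1][2] if i > 0 else None
        right = runs[i + 1][2] if i < len(runs) - 1 else None
        if left is None:
            labels[start:end] = right
        elif right is None:
            labels[start:end] = left
        elif corr is None:
            mid = start + (end - start) // 2
            labels[start:mid] = left
            labels[mid:end] = right
        else:
            # absorb each sample into the neighbor of higher template
            # correlation, keeping the split contiguous (prefix -> left,
            # suffix -> right) so that every absorption removes one run
            gain_left = np.concatenate(([0.0], np.cumsum(corr[left, start:end])))
            cr = corr[right, start:end]
            gain_right = np.concatenate((np.cumsum(cr[::-1])[::-1], [0.0]))
            b = int(np.argmax(gain_left + gain_right))
            labels[start:start + b] = left
            labels[start + b:end] = right
    return Segmentation(labels=labels, gfp=seg.gfp.copy(), rate=rate,
                        correlations=None if corr is None else corr.copy())


def _abs_pearson_table(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between every row of ``a`` and of ``b``."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1, keepdims=True)
    bn = np.linalg.norm(bc, axis=1, keepdims=True)
    an[an == 0] = 1.0
    bn[bn == 0] = 1.0
    return np.abs((ac / an) @ (bc / bn).T)


def match_sets(msset: MicrostateSet, reference: MicrostateSet,
               threshold: float = MATCH_THRESHOLD,
               ) -> tuple[dict[int, int], list[int], np.ndarray]:
    """Optimal one-to-one matching of maps to a reference set.

    Returns ``(mapping, unmatched, table)`` where ``mapping[i] = j`` pairs
    map ``i`` with reference ``j`` whenever their absolute Pearson
    correlation reaches ``threshold``; maps below it are reported unmatched.
    The assignment maximizes the total absolute correlation.
    """
    if msset.n_states == 0 or reference.n_states == 0:
        raise ValueError("both sets must be non-empty")
    table = _abs_pearson_table(msset.maps, reference.maps)
    rows, cols = linear_sum_assignment(-table)
    mapping: dict[int, int] = {}
    unmatched: list[int] = []
    assigned = dict(zip(rows.tolist(), cols.tolist()))
    for i in range(msset.n_states):
        j = assigned.get(i)
        if j is not None and table[i, j] >= threshold:
            mapping[i] = j
        else:
            unmatched.append(i)
    return mapping, unmatched, table


def group_cluster(subject_sets: list[MicrostateSet], k: int, max_iter: int = 50,
                  seed: int | np.random.Generator = 0,
                  ) -> tuple[MicrostateSet, list[dict[int, int]]]:
    """Cluster subjects' maps with one-map-per-subject-per-cluster restriction.

    Alternates (a) per-subject optimal one-to-one assignment of maps to the
    K group templates, maximizing total |correlation|, and (b) template
    update as the dominant eigenvector of each cluster's member maps.
    """
    if any(s.n_states > k for s in subject_sets):
        raise ValueError("K smaller than some subject's map count")
    rng = np.random.default_rng(seed)
    all_maps = np.vstack([s.maps for s in subject_sets])
    idx = rng.choice(all_maps.shape[0], size=k, replace=False)
    templates = _normalize_maps(all_maps[idx].copy())
    assignments: list[dict[int, int]] = [{} for _ in subject_sets]
    for _it in range(max_iter):
        new_assignments = []
        for sset in subject_sets:
            table = _abs_pearson_table(sset.maps, templates)
            rows, cols = linear_sum_assignment(-table)
            new_assignments.append(dict(zip(rows.tolist(), cols.tolist())))
        if new_assignments == assignments:
            break
        assignments = new_assignments
        for j in range(k):
            members = [sset.maps[i]
                       for sset, amap in zip(subject_sets, assignments)
                       for i, cj in amap.items() if cj == j]
            if members:
                templates[j] = _dominant_eigenvector(np.array(members))
    group = MicrostateSet(maps=templates,
                          labels=[STATE_NAMES[i] for i in range(k)],
                          condition="group")
    return group, assignments


def harmonize_k(selected_ks: list[int]) -> int:
    """Common model order across subjects: rounded mean of the selected Ks."""
    if not selected_ks:
        raise ValueError("no selected model orders")
    return int(round(float(np.mean(selected_ks))))


def temporal_stats(seg: Segmentation, n_states: int | None = None,
                   ) -> dict[int, dict[str, float]]:
    """Per-state mean segment duration (ms), coverage and occurrences per s."""
    runs = seg.segments
    states = (sorted({r[2] for r in runs}) if n_states is None
              else list(range(n_states)))
    total = seg.n_samples
    duration_s = total / seg.rate
    out: dict[int, dict[str, float]] = {}
    for s in states:
        mine = [r for r in runs if r[2] == s]
        n_samp = sum(e - b for b, e, _ in mine)
        out[s] = {
            "mean_duration_ms": (1000.0 * n_samp / len(mine) / seg.rate
                                 if mine else 0.0),
            "coverage": n_samp / total,
            "occurrences_per_s": len(mine) / duration_s,
        }
    return out
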
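"""Muscle synergy extraction by L2-norm NNMF and synergy bookkeeping.

The factorization ``V ~ W @ H`` (muscles x samples, all entries >= 0) is
fitted with Lee-Seung multiplicative updates minimizing the squared
Frobenius error, restarted ``n_restarts`` times (the winner maximizes the
variance accounted for).  The model order is the smallest K whose VAF
exceeds the retention threshold (98% by default).  Synergies are matched
across subjects/conditions by the normalized scalar product (DOT) of their
muscle weight vectors against a reference set built by hierarchical
clustering of all subjects' weights.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .containers import OccurrenceMatrix, SynergyModel, WindowGrid

logger = logging.getLogger(__name__)

VAF_THRESHOLD = 0.98
DOT_THRESHOLD = 0.65
N_RESTARTS = 50
_EPS = 1e-12


def vaf(V: np.ndarray, model: SynergyModel | tuple[np.ndarray, np.ndarray]) -> float:
    """Variance accounted for: ``1 - ||V - WH||_F^2 / ||V||_F^2`` (uncentered)."""
    V = np.asarray(V, dtype=float)
    W, H = (model.W, model.H) if isinstance(model, SynergyModel) else model
    denom = float(np.sum(V ** 2))
    if denom == 0:
        return 1.0
    return 1.0 - float(np.sum((V - W @ H) ** 2)) / denom


def _mu_run(V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int,
            tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """One multiplicative-update run; returns (W, H, objective trace, converged)."""
    m, t = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = scale * rng.random((m, k)) + _EPS
    H = scale * rng.random((k, t)) + _EPS
    obj = []
    prev = np.inf
    converged = False
    for _it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.sum((V - W @ H) ** 2))
        obj.append(err)
        if prev < np.inf and prev - err <= tol * max(prev, _EPS):
            converged = True
            break
        prev = err
    return W, H, np.array(obj), converged


def nnmf(V: np.ndarray, k: int, n_restarts: int = N_RESTARTS,
         max_iter: int = 500, tol: float = 1e-6,
         seed: int | np.random.Generator = 0) -> SynergyModel:
    """Best-of-restarts nonnegative factorization of an EMG envelope matrix."""
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > min(V.shape):
        raise ValueError("K cannot exceed min(muscles, samples)")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, bool] | None = None
    for _r in range(n_restarts):
        W, H, obj, converged = _mu_run(V, k, rng, max_iter, tol)
        v = vaf(V, (W, H))
        if best is None or v > best[0]:
            best = (v, W, H, obj, converged)
    assert best is not None
    v, W, H, obj, converged = best
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    return SynergyModel(W=W, H=H, vaf=v, restarts_used=n_restarts,
                        converged=converged, objective=obj)


def select_n_synergies(V: np.ndarray, k_max: int,
                       threshold: float = VAF_THRESHOLD,
                       n_restarts: int = N_RESTARTS, max_iter: int = 500,
                       tol: float = 1e-6,
                       seed: int | np.random.Generator = 0) -> SynergyModel:
    """Smallest K whose VAF exceeds ``threshold`` (else ``k_max``, flagged)."""
    rng = np.random.default_rng(seed)
    model = None
    for k in range(1, k_max + 1):
        model = nnmf(V, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                     seed=rng)
        if model.vaf > threshold:
            return model
    logger.warning("VAF threshold %.3f unreachable at k_max=%d (VAF=%.4f)",
                   threshold, k_max, model.vaf if model else float("nan"))
    model.converged = False
    return model


def dot_table(W_a: np.ndarray, W_b: np.ndarray) -> np.ndarray:
    """Normalized scalar products between synergy weight columns."""
    a = W_a / np.maximum(np.linalg.norm(W_a, axis=0, keepdims=True), _EPS)
    b = W_b / np.maximum(np.linalg.norm(W_b, axis=0, keepdims=True), _EPS)
    return a.T @ b


def match_synergies(W: np.ndarray, reference: np.ndarray,
                    dot_threshold: float = DOT_THRESHOLD,
                    ) -> tuple[dict[int, int], list[int], np.ndarray]:
    """One-to-one DOT-maximizing assignment of synergies to references."""
    table = dot_table(W, reference)
    rows, cols = linear_sum_assignment(-table)
    assigned = dict(zip(rows.tolist(), cols.tolist()))
    mapping: dict[int, int] = {}
    unmatched: list[int] = []
    for i in range(W.shape[1]):
        j = assigned.get(i)
        if j is not None and table[i, j] >= dot_threshold:
            mapping[i] = j
        else:
            unmatched.append(i)
    return mapping, unmatched, table


def build_reference_set(W_list: list[np.ndarray], n_ref: int,
                        minkowski_order: float = 2.0) -> np.ndarray:
    """Reference synergies: agglomerative clustering of all weight vectors.

    All subjects' weight columns are pooled, clustered hierarchically with
    the Minkowski distance (average linkage), the tree cut at ``n_ref``
    clusters, and each reference is the renormalized cluster mean.
    """
    pooled = np.hstack(W_list).T          # vectors x muscles
    if pooled.shape[0] < n_ref:
        raise ValueError("fewer synergies than requested references")
    if pooled.shape[0] == n_ref:
        refs = pooled
    else:
        d = pdist(pooled, metric="minkowski", p=minkowski_order)
        tree = linkage(d, method="average")
        groups = fcluster(tree, t=n_ref, criterion="maxclust")
        refs = np.array([pooled[groups == g].mean(axis=0)
                         for g in range(1, n_ref + 1)])
    norms = np.linalg.norm(refs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return (refs / norms).T               # muscles x n_ref


def synergy_occurrence(model: SynergyModel, emg_epochs: np.ndarray,
                       grid: WindowGrid, rate: float, onset_index: int,
                       H_epochs: np.ndarray | None = None) -> OccurrenceMatrix:
    """Window-wise temporal occurrence of each synergy.

    For synergy ``k`` and window ``w`` the occurrence is the Pearson
    correlation between the vectorized putative EMG ``w_k h_k`` and the
    vectorized recorded EMG within the window, averaged over epochs
    (undefined correlations on zero-variance windows count as 0).

    ``emg_epochs`` is ``epochs x muscles x samples``; ``H_epochs``
    (``epochs x K x samples``) defaults to the model's activations reshaped
    per epoch, which assumes extraction on the concatenated epochs.
    """
    emg_epochs = np.asarray(emg_epochs, dtype=float)
    n_epochs, _n_muscles, n_samples = emg_epochs.shape
    K = model.n_synergies
    if H_epochs is None:
        if model.H.shape[1] != n_epochs * n_samples:
            raise ValueError("model activations do not tile the epochs")
        H_epochs = model.H.reshape(K, n_epochs, n_samples).transpose(1, 0, 2)
    bounds = grid.sample_bounds(rate, onset_index)
    values = np.zeros((K, grid.n_windows))
    for w, (lo, hi) in enumerate(bounds):
        lo_c, hi_c = max(lo, 0), min(hi, n_samples)
        if hi_c <= lo_c:
            raise ValueError(f"window {w} lies outside the epochs")
        for k in range(K):
            acc = 0.0
            for e in range(n_epochs):
                putative = np.outer(model.W[:, k],
                                    H_epochs[e, k, lo_c:hi_c]).ravel()
                observed = emg_epochs[e, :, lo_c:hi_c].ravel()
                if putative.std() == 0 or observed.std() == 0:
                    logger.debug("zero-variance window %d epoch %d synergy %d",
                                 w, e, k)
                    continue
                acc += float(np.corrcoef(putative, observed)[0, 1])
            values[k, w] = acc / n_epochs
    # occurrence values live in [0, 1]: negative mean correlations are noise
    values = np.clip(values, 0.0, 1.0)
    return OccurrenceMatrix(values=values, grid=grid,
                            state_labels=[f"Syn{k + 1}" for k in range(K)],
                            n_epochs=n_epochs)
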
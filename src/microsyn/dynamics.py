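"""Microstate occurrence dynamics over the trial timeline.

Occurrence is the fraction of epochs in which a state is the *prevalent*
(most sampled) one within each analysis window: 100 ms windows over the 2 s
preparation and 2 s holding phases and ten windows of 10% of the movement
duration over execution.  Prevalence ties are resolved toward the previous
window's winner when it is among the tied states and otherwise by a seeded
random choice.  Condition contrasts use an epoch-level permutation test of
the occurrence difference.
"""

from __future__ import annotations

import numpy as np

from .containers import OccurrenceMatrix, Segmentation, WindowGrid

PREP_WINDOW_S = 0.1
HOLD_WINDOW_S = 0.1
N_MOVE_WINDOWS = 10


def window_grid(prep_s: float = 2.0, move_s: float = 1.0, hold_s: float = 2.0,
                ) -> WindowGrid:
    """Standard trial grid: 20 preparation + 10 execution + 20 holding windows."""
    n_prep = int(round(prep_s / PREP_WINDOW_S))
    n_hold = int(round(hold_s / HOLD_WINDOW_S))
    starts, ends, phases = [], [], []
    for w in range(n_prep):
        starts.append(-prep_s + w * PREP_WINDOW_S)
        ends.append(-prep_s + (w + 1) * PREP_WINDOW_S)
        phases.append("preparation")
    move_win = move_s / N_MOVE_WINDOWS
    for w in range(N_MOVE_WINDOWS):
        starts.append(w * move_win)
        ends.append((w + 1) * move_win)
        phases.append("execution")
    for w in range(n_hold):
        starts.append(move_s + w * HOLD_WINDOW_S)
        ends.append(move_s + (w + 1) * HOLD_WINDOW_S)
        phases.append("holding")
    return WindowGrid(starts=np.array(starts), ends=np.array(ends), phases=phases)


def resting_grid(duration_s: float = 5.0, window_s: float = 0.1) -> WindowGrid:
    """Uniform grid for resting-state occurrence (no phase structure)."""
    n = int(round(duration_s / window_s))
    starts = np.arange(n) * window_s
    return WindowGrid(starts=starts, ends=starts + window_s, phases=["rest"] * n)


def epoch_occupancy(seg: Segmentation, grid: WindowGrid, n_states: int,
                    onset_index: int, seed: int | np.random.Generator = 0,
                    ) -> np.ndarray:
    """One-hot prevalent-state matrix (states x windows) for one epoch.

    Ties go to the previous window's winner when it is among the tied
    states, otherwise to a seeded random draw among them.
    """
    rng = np.random.default_rng(seed)
    bounds = grid.sample_bounds(seg.rate, onset_index)
    out = np.zeros((n_states, grid.n_windows))
    prev_winner: int | None = None
    for w, (lo, hi) in enumerate(bounds):
        lo_c, hi_c = max(lo, 0), min(hi, seg.n_samples)
        if hi_c <= lo_c:
            raise ValueError(f"window {w} not covered by the segmentation")
        counts = np.bincount(seg.labels[lo_c:hi_c], minlength=n_states)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if tied.size == 1:
            winner = int(tied[0])
        elif prev_winner is not None and prev_winner in tied:
            winner = prev_winner
        else:
            winner = int(rng.choice(tied))
        out[winner, w] = 1.0
        prev_winner = winner
    return out


def occurrence_histogram(occupancies: list[np.ndarray] | np.ndarray,
                         grid: WindowGrid, state_labels: list[str],
                         ) -> OccurrenceMatrix:
    """Fraction of epochs in which each state is prevalent, per window."""
    stack = np.asarray(occupancies, dtype=float)
    if stack.ndim != 3:
        raise ValueError("occupancies must be epochs x states x windows")
    return OccurrenceMatrix(values=stack.mean(axis=0), grid=grid,
                            state_labels=list(state_labels),
                            n_epochs=stack.shape[0])


def permutation_test(occ_a: np.ndarray, occ_b: np.ndarray,
                     n_perm: int = 10000, alpha: float = 0.05,
                     seed: int | np.random.Generator = 0,
                     ) -> dict[str, np.ndarray]:
    """Epoch-level permutation test of occurrence differences.

    ``occ_a``/``occ_b`` are epoch-level one-hot occupancy stacks
    (epochs x states x windows) of the two conditions on matched grids.
    The statistic per state and window is the difference of the two
    condition means; the null is built by re-assigning epochs to conditions.
    Returns observed differences, two-sided p-values, the per-cell
    ``1 - alpha`` threshold on |difference| and the significance mask.
    """
    occ_a = np.asarray(occ_a, dtype=float)
    occ_b = np.asarray(occ_b, dtype=float)
    if occ_a.shape[1:] != occ_b.shape[1:]:
        raise ValueError("conditions must share the states x windows grid")
    if n_perm < 1.0 / alpha:
        raise ValueError("n_perm too small for the requested alpha")
    rng = np.random.default_rng(seed)
    n_a = occ_a.shape[0]
    pooled = np.concatenate([occ_a, occ_b], axis=0)
    observed = occ_a.mean(axis=0) - occ_b.mean(axis=0)
    null = np.empty((n_perm,) + observed.shape)
    for p in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null[p] = pooled[perm[:n_a]].mean(axis=0) - pooled[perm[n_a:]].mean(axis=0)
    p_values = (1.0 + np.sum(np.abs(null) >= np.abs(observed)[None], axis=0)) \
        / (n_perm + 1.0)
    threshold = np.quantile(np.abs(null), 1.0 - alpha, axis=0)
    return {
        "difference": observed,
        "p_values": p_values,
        "threshold": threshold,
        "significant": p_values <= alpha,
    }
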
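"""Canonical correlation and grasp decoding from occurrence dynamics.

Per subject, windows of the microstate and synergy occurrence matrices are
stacked over tasks and motion phases into paired matrices ``X`` (windows x
states) and ``Y`` (windows x synergies) and submitted to canonical
correlation; component significance is assessed across subjects against a
row-permuted surrogate with a Wilcoxon signed-rank test.

Grasp decoding uses a four-class linear discriminant classifier on the
100-dimensional preparation features (20 windows x 5 states, one-hot
prevalent state): per grasp and repetition the classifier trains on half
of that grasp's epochs plus the same number from each other grasp and is
tested on the held-out half; its chance level is calibrated by repeating
the protocol with shuffled training labels.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import linalg as sla
from scipy.stats import wilcoxon
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.multivariate.cancorr import CanCorr

from .containers import CanonicalResult, DecodingResult, OccurrenceMatrix

logger = logging.getLogger(__name__)

N_REPS = 1000
N_NULL = 10000
#: cap applied to mean/SD coefficient ratios when the SD is exactly zero
RATIO_CAP = 100.0


# ---------------------------------------------------------------------------
# occurrence stacking and CCA
# ---------------------------------------------------------------------------

def _window_keys(occ: OccurrenceMatrix) -> list[tuple[float, float]]:
    return [(round(float(s), 6), round(float(e), 6))
            for s, e in zip(occ.grid.starts, occ.grid.ends)]


def stack_occurrences(pairs: list[tuple[OccurrenceMatrix, OccurrenceMatrix]],
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack aligned windows of microstate/synergy occurrence pairs.

    For every pair only the windows present in *both* grids (matched by
    start/end times) are used — for the preparation phase this is the
    interval where both occurrence definitions exist.  Raises when a pair
    shares no windows (mismatched grids).
    """
    x_rows, y_rows = [], []
    for ms_occ, syn_occ in pairs:
        keys_x = _window_keys(ms_occ)
        keys_y = _window_keys(syn_occ)
        common = [k for k in keys_x if k in set(keys_y)]
        if not common:
            raise ValueError("occurrence grids share no windows")
        ix = [keys_x.index(k) for k in common]
        iy = [keys_y.index(k) for k in common]
        x_rows.append(ms_occ.values[:, ix].T)
        y_rows.append(syn_occ.values[:, iy].T)
    return np.vstack(x_rows), np.vstack(y_rows)


def _drop_dependent(M: np.ndarray, tol: float = 1e-10,
                    ) -> tuple[np.ndarray, list[int], list[int]]:
    """Keep a maximal linearly independent column subset (pivoted QR)."""
    _q, r, piv = sla.qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * max(diag[0], 1.0))) if diag.size else 0
    keep = sorted(piv[:rank].tolist())
    dropped = sorted(set(range(M.shape[1])) - set(keep))
    return M[:, keep], keep, dropped


def cca(X: np.ndarray, Y: np.ndarray, subject: str = "") -> CanonicalResult:
    """Canonical correlations and norm-normalized weight vectors.

    Columns are centered internally; linearly dependent columns are dropped
    (with a warning) before the decomposition and get zero coefficients.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] <= max(X.shape[1], Y.shape[1]):
        raise ValueError("CCA needs more rows than columns on each side")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Xr, keep_x, drop_x = _drop_dependent(Xc)
    Yr, keep_y, drop_y = _drop_dependent(Yc)
    if drop_x or drop_y:
        logger.warning("dropped dependent columns: X %s, Y %s", drop_x, drop_y)
    model = CanCorr(Yr, Xr)
    corrs = np.clip(np.asarray(model.cancorr, dtype=float), 0.0, 1.0)
    n_comp = corrs.size

    def _expand(coef: np.ndarray, keep: list[int], n_cols: int) -> np.ndarray:
        out = np.zeros((n_cols, n_comp))
        out[keep] = coef[:, :n_comp]
        norms = np.linalg.norm(out, axis=0)
        norms[norms == 0] = 1.0
        return out / norms

    return CanonicalResult(correlations=corrs,
                           x_coef=_expand(model.x_cancoef, keep_x, X.shape[1]),
                           y_coef=_expand(model.y_cancoef, keep_y, Y.shape[1]),
                           subject=subject, dropped_x=drop_x, dropped_y=drop_y)


def cca_permutation_null(X: np.ndarray, Y: np.ndarray, n_perm: int = 200,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """First canonical correlation under row permutation of ``Y``."""
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = cca(X, Y[rng.permutation(Y.shape[0])]).correlations[0]
    return null


def cca_significance(subject_corrs: np.ndarray,
                     surrogate_corrs: np.ndarray) -> float:
    """Signed-rank p-value of subject correlations exceeding their surrogates.

    ``surrogate_corrs`` holds one matched surrogate summary (e.g. the median
    of a row-permuted null) per subject.
    """
    subject_corrs = np.asarray(subject_corrs, dtype=float)
    surrogate_corrs = np.asarray(surrogate_corrs, dtype=float)
    if subject_corrs.size < 2:
        raise ValueError("the across-subject test needs >= 2 subjects")
    diff = subject_corrs - surrogate_corrs
    if np.allclose(diff, 0):
        return 1.0
    return float(wilcoxon(diff, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# LDA decoding
# ---------------------------------------------------------------------------

def build_feature_vectors(occupancy: np.ndarray) -> np.ndarray:
    """Flatten a states x prep-windows one-hot occupancy to one feature vector.

    The layout is window-major (windows x states), so 20 windows of 5
    states give a 100-dimensional vector with exactly one 1 per window.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.ndim != 2:
        raise ValueError("occupancy must be states x windows")
    return occupancy.T.ravel()


def _new_lda() -> LinearDiscriminantAnalysis:
    # shrinkage keeps the pooled covariance invertible for one-hot features
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def _decode_once(features: dict[str, np.ndarray], rng: np.random.Generator,
                 shuffle_train: bool) -> tuple[np.ndarray, float, np.ndarray]:
    """One repetition of the per-grasp half-split protocol."""
    classes = list(features)
    n_classes = len(classes)
    confusion = np.zeros((n_classes, n_classes))
    coef_acc = []
    correct = total = 0
    for gi, g in enumerate(classes):
        n_g = features[g].shape[0]
        n_half = n_g // 2
        order = rng.permutation(n_g)
        train_x = [features[g][order[:n_half]]]
        train_y = [np.full(n_half, gi)]
        for oj, other in enumerate(classes):
            if other == g:
                continue
            n_o = features[other].shape[0]
            pick = rng.choice(n_o, size=min(n_half, n_o), replace=False)
            train_x.append(features[other][pick])
            train_y.append(np.full(pick.size, oj))
        Xtr = np.vstack(train_x)
        ytr = np.concatenate(train_y)
        if shuffle_train:
            ytr = ytr[rng.permutation(ytr.size)]
        clf = _new_lda()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, ytr)
        test = features[g][order[n_half:]]
        pred = clf.predict(test)
        for pj in pred:
            confusion[gi, int(pj)] += 1
        correct += int(np.sum(pred == gi))
        total += pred.size
        full = np.zeros((n_classes, Xtr.shape[1]))
        full[np.asarray(clf.classes_, dtype=int)] = clf.coef_
        coef_acc.append(full.ravel())
    rows = confusion.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    confusion = 100.0 * confusion / rows
    return confusion, correct / total, np.mean(coef_acc, axis=0)


def lda_decode(features: dict[str, np.ndarray], n_reps: int = N_REPS,
               seed: int | np.random.Generator = 0) -> DecodingResult:
    """Four-class LDA grasp decoding, averaged over half-split repetitions.

    ``features`` maps each grasp label to its ``epochs x features`` matrix.
    """
    for g, mat in features.items():
        if mat.shape[0] < 4:
            raise ValueError(f"class {g!r} has fewer than 4 epochs")
    rng = np.random.default_rng(seed)
    n_classes = len(features)
    confusions = np.zeros((n_reps, n_classes, n_classes))
    accuracies = np.empty(n_reps)
    coefs = []
    for r in range(n_reps):
        confusions[r], accuracies[r], coef = _decode_once(features, rng, False)
        coefs.append(coef)
    return DecodingResult(confusion=confusions.mean(axis=0),
                          accuracies=accuracies,
                          class_labels=list(features), n_reps=n_reps,
                          coefficients=np.array(coefs))


def lda_null(features: dict[str, np.ndarray], n_null: int = N_NULL,
             seed: int | np.random.Generator = 0,
             ) -> tuple[np.ndarray, float, np.ndarray]:
    """Label-shuffled null of the decoding protocol.

    Returns (null accuracy distribution, significance level = its mean,
    null coefficient draws).
    """
    if n_null < 100:
        logger.warning("n_null=%d is small; the chance level will be noisy",
                       n_null)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_null)
    coefs = []
    for r in range(n_null):
        _conf, accs[r], coef = _decode_once(features, rng, True)
        coefs.append(coef)
    return accs, float(accs.mean()), np.array(coefs)


def residualize_features(target: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residuals of each target column regressed on the nuisance block."""
    target = np.asarray(target, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if target.shape[0] != nuisance.shape[0]:
        raise ValueError("target and nuisance need equal row counts")
    design = np.column_stack([np.ones(nuisance.shape[0]), nuisance])
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ beta


def coefficient_stability(coefficients: np.ndarray, null_coefficients: np.ndarray,
                          cap: float = RATIO_CAP) -> dict[str, np.ndarray]:
    """Mean/SD stability ratios of decoder coefficients against a null.

    The null 95th-percentile threshold is built by computing the same ratio
    on blocks of the null coefficient draws, each block as long as the
    observed repetition count, pooling blocks and coefficients.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    null_coefficients = np.asarray(null_coefficients, dtype=float)
    n_reps = coefficients.shape[0]

    def _ratios(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = np.abs(block.mean(axis=0))
        sd = block.std(axis=0, ddof=0)
        capped = sd == 0
        ratio = np.where(capped, cap, mean / np.where(capped, 1.0, sd))
        return np.minimum(ratio, cap), capped

    ratio, capped = _ratios(coefficients)
    n_blocks = max(1, null_coefficients.shape[0] // n_reps)
    null_ratios = []
    for b in range(n_blocks):
        block = null_coefficients[b * n_reps:(b + 1) * n_reps]
        if block.shape[0] >= 2:
            null_ratios.append(_ratios(block)[0])
    pooled = np.concatenate(null_ratios) if null_ratios else np.array([cap])
    threshold = float(np.percentile(pooled, 95))
    return {
        "ratio": ratio,
        "capped": capped,
        "threshold": np.array(threshold),
        "significant": ratio > threshold,
        "significant_fraction": np.array(float(np.mean(ratio > threshold))),
    }
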
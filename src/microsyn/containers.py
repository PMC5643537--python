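"""Shared in-memory containers for the analysis pipeline.

Conventions used throughout the package:

* signal matrices are ``channels x samples`` (row = sensor);
* EEG topographies are average-referenced (zero mean across channels);
* time ``t = 0`` of a trial is the movement onset unless stated otherwise;
* occurrence matrices are ``states x windows`` with values in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EEG = "EEG"
EMG = "EMG"

#: canonical event labels of a reaching-and-grasping trial, in temporal order
EVENT_ORDER = ("task_cue", "movement_onset", "holding_onset", "release")


@dataclass
class Recording:
    """A multichannel recording with a sampling rate and an events table.

    Parameters
    ----------
    data:
        ``channels x samples`` real matrix (microvolts for EEG, MVC-normalized
        units for processed EMG).
    rate:
        Sampling rate in Hz, strictly positive.
    labels:
        Channel names, one per row of ``data``.
    modality:
        Either ``"EEG"`` or ``"EMG"``.
    events:
        List of ``(sample_index, label)`` pairs; indices must lie inside the
        recording.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    modality: str = EEG
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        for idx, _label in self.events:
            if not 0 <= idx < self.data.shape[1]:
                raise ValueError(f"event index {idx} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def event_samples(self, label: str) -> list[int]:
        """All sample indices carrying ``label``, in order."""
        return [i for i, lab in self.events if lab == label]

    def copy_with(self, data: np.ndarray, rate: float | None = None,
                  events: list[tuple[int, str]] | None = None) -> "Recording":
        return Recording(
            data=np.asarray(data, dtype=float),
            rate=self.rate if rate is None else rate,
            labels=list(self.labels),
            modality=self.modality,
            events=list(self.events) if events is None else events,
        )


@dataclass
class EpochSet:
    """A collection of per-trial epochs cut from a recording.

    Epochs may have different lengths until :func:`equalize_epoch_lengths`
    interpolates them to a common grid, therefore they are kept as a list of
    ``channels x samples`` arrays rather than a dense tensor.

    ``landmarks[i] = (movement_onset_index, holding_onset_index)`` within
    epoch ``i`` (``-1`` when the landmark lies outside the epoch), and
    ``mask`` records, per original trial, whether it was kept.
    """

    epochs: list[np.ndarray]
    rate: float
    task: str
    landmarks: list[tuple[int, int]]
    mask: list[bool]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.epochs) != len(self.landmarks):
            raise ValueError("one landmark pair per epoch required")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def equalized(self) -> bool:
        lengths = {e.shape[1] for e in self.epochs}
        return len(lengths) <= 1

    def tensor(self) -> np.ndarray:
        """Dense ``epochs x channels x samples`` array (equal lengths only)."""
        if not self.equalized:
            raise ValueError("epochs have unequal lengths; equalize first")
        return np.stack(self.epochs, axis=0)


@dataclass
class MicrostateSet:
    """K microstate template maps for one subject and condition.

    Maps are stored unit-norm and average-referenced, one per row.
    """

    maps: np.ndarray                      # K x channels
    labels: list[str]
    subject: str = ""
    condition: str = ""
    cv_value: float = float("nan")
    explained_variance: float = float("nan")

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map required")

    @property
    def n_states(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class Segmentation:
    """Per-sample microstate labeling of a recording.

    ``labels`` holds the state index of every sample (all samples are
    labeled; short-segment rejection happens only through smoothing),
    ``gfp`` the global field power series, and ``correlations`` the
    ``states x samples`` absolute spatial-correlation table used both for
    back-fitting and for absorbing rejected segments.
    """

    labels: np.ndarray                    # (samples,) int
    gfp: np.ndarray                       # (samples,) >= 0
    rate: float
    correlations: np.ndarray | None = None   # states x samples, |corr|

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.labels.shape != self.gfp.shape:
            raise ValueError("labels and gfp must have equal length")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        """Run list ``(start, end, state)`` with half-open ``[start, end)``."""
        return run_list(self.labels)


def run_list(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Decompose an integer label sequence into maximal constant runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


@dataclass
class SynergyModel:
    """Nonnegative factorization ``V ~ W @ H`` of an EMG envelope matrix.

    ``W`` (muscles x K) holds unit-norm muscle weight vectors; the scale is
    absorbed into the activations ``H`` (K x samples). ``objective`` is the
    per-iteration squared Frobenius error of the winning restart.
    """

    W: np.ndarray
    H: np.ndarray
    vaf: float
    restarts_used: int = 1
    converged: bool = True
    objective: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2 or self.W.shape[1] != self.H.shape[0]:
            raise ValueError("W (m x K) and H (K x T) shapes inconsistent")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("synergy factors must be nonnegative")

    @property
    def n_synergies(self) -> int:
        return self.W.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class WindowGrid:
    """Non-overlapping, ordered analysis windows on the trial timeline.

    Window bounds are in seconds relative to movement onset; ``phases`` tags
    every window as preparation / execution / holding.
    """

    starts: np.ndarray
    ends: np.ndarray
    phases: list[str]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if not (self.starts.size == self.ends.size == len(self.phases)):
            raise ValueError("starts, ends and phases must align")
        if (self.ends <= self.starts).any():
            raise ValueError("windows must have positive width")
        if (self.starts[1:] < self.ends[:-1] - 1e-12).any():
            raise ValueError("windows must be ordered and non-overlapping")

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def phase_indices(self, phase: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.phases) == phase)

    def sample_bounds(self, rate: float, onset_index: int) -> list[tuple[int, int]]:
        """Half-open sample ranges of each window for a given onset sample."""
        out = []
        for s, e in zip(self.starts, self.ends):
            out.append((onset_index + int(round(s * rate)),
                        onset_index + int(round(e * rate))))
        return out


@dataclass
class OccurrenceMatrix:
    """Fraction of epochs in which each state is prevalent per window."""

    values: np.ndarray                    # states x windows in [0, 1]
    grid: WindowGrid
    state_labels: list[str]
    n_epochs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.state_labels), self.grid.n_windows):
            raise ValueError("values must be states x windows")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("occurrence values must lie in [0, 1]")


@dataclass
class Spectrogram:
    """Short-time power (or percent power change) of one epoch or ROI mean."""

    power: np.ndarray                     # freqs x steps (per channel: ch x F x S)
    freqs: np.ndarray
    times: np.ndarray                     # window centers, s (trial timeline)
    win_s: float
    step_s: float
    normalized: bool = False
    roi_averaged: bool = False


@dataclass
class CanonicalResult:
    """Per-subject canonical correlation between the two occurrence sets."""

    correlations: np.ndarray              # non-increasing, in [0, 1]
    x_coef: np.ndarray                    # states x components, unit-norm cols
    y_coef: np.ndarray                    # synergies x components, unit-norm cols
    subject: str = ""
    p_values: np.ndarray | None = None
    dropped_x: list[int] = field(default_factory=list)
    dropped_y: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.correlations, dtype=float)
        if (np.diff(c) > 1e-8).any():
            raise ValueError("canonical correlations must be non-increasing")


@dataclass
class DecodingResult:
    """Four-class LDA grasp decoding summary."""

    confusion: np.ndarray                 # n_classes x n_classes, rows sum to 100
    accuracies: np.ndarray                # per repetition, fraction correct
    class_labels: list[str]
    n_reps: int
    coefficients: np.ndarray | None = None    # reps x n_coef (class-collapsed)
    null_accuracies: np.ndarray | None = None
    significance_level: float | None = None

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.accuracies))
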
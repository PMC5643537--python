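"""EEG/EMG conditioning, epoching, epoch-length equalization and averaging.

EEG path: zero-phase 1-40 Hz band-pass, down-sampling to 128 Hz, common
average reference, movement/holding epoching around the trial events, cubic
spline equalization of epoch lengths and per-condition averaging.

EMG path: linear detrend, 50 Hz high-pass (Butterworth, 7th order,
zero-phase), rectification, 10 Hz low-pass (same family), normalization by
per-muscle maximum voluntary contraction, with post-filter ringing clipped
at zero so the envelopes stay nonnegative for the factorization.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .containers import EEG, EMG, EpochSet, Recording

logger = logging.getLogger(__name__)

EEG_BAND = (1.0, 40.0)
TARGET_RATE = 128.0
EMG_HIGHPASS_HZ = 50.0
EMG_LOWPASS_HZ = 10.0
EMG_FILTER_ORDER = 7
#: amplitude threshold (in channel units, nominally microvolts) replacing
#: visual artifact inspection on synthetic data
ARTIFACT_THRESHOLD = 100.0


def filter_eeg(rec: Recording, band: tuple[float, float] = EEG_BAND,
               order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    if rec.modality != EEG:
        raise ValueError("filter_eeg expects an EEG recording")
    if rec.rate <= 2 * band[1]:
        raise ValueError(
            f"rate {rec.rate} Hz too low for a {band[1]} Hz band edge; "
            "filter before down-sampling")
    sos = sps.butter(order, band, btype="bandpass", fs=rec.rate, output="sos")
    return rec.copy_with(sps.sosfiltfilt(sos, rec.data, axis=1))


def resample(rec: Recording, target: float = TARGET_RATE) -> Recording:
    """Polyphase down-sampling with proportional event remapping."""
    if target > rec.rate:
        raise ValueError("upsampling requested; target must be <= rate")
    if target == rec.rate:
        return rec.copy_with(rec.data)
    frac = Fraction(target / rec.rate).limit_denominator(10000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_out = int(round(rec.n_samples * target / rec.rate))
    if data.shape[1] > n_out:
        data = data[:, :n_out]
    elif data.shape[1] < n_out:
        pad = np.repeat(data[:, -1:], n_out - data.shape[1], axis=1)
        data = np.concatenate([data, pad], axis=1)
    events = [(min(n_out - 1, int(round(i * target / rec.rate))), lab)
              for i, lab in rec.events]
    return Recording(data=data, rate=target, labels=list(rec.labels),
                     modality=rec.modality, events=events)


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous channel mean (common average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def apply_unmixing(rec: Recording, unmixing: np.ndarray | None = None) -> Recording:
    """Hook for externally supplied artifact removal; pass-through by default."""
    if unmixing is None:
        return rec
    return rec.copy_with(np.asarray(unmixing) @ rec.data)


def _paired_trial_events(rec: Recording) -> list[tuple[int, int | None]]:
    """Pair each movement_onset with the next holding_onset (or None)."""
    onsets = rec.event_samples("movement_onset")
    holds = rec.event_samples("holding_onset")
    pairs: list[tuple[int, int | None]] = []
    for onset in onsets:
        later = [h for h in holds if h > onset]
        nxt_onset = [o for o in onsets if o > onset]
        hold = later[0] if later else None
        if hold is not None and nxt_onset and hold > nxt_onset[0]:
            hold = None                      # holding event belongs to a later trial
        pairs.append((onset, hold))
    return pairs


def epoch_movement(rec: Recording, task: str = "", pre_s: float = 2.0,
                   artifact_threshold: float | None = ARTIFACT_THRESHOLD) -> EpochSet:
    """Epochs from ``pre_s`` before movement onset until object grasp."""
    return _epoch(rec, task, phase="movement", pre_s=pre_s,
                  artifact_threshold=artifact_threshold)


def epoch_holding(rec: Recording, task: str = "", post_s: float = 2.0,
                  artifact_threshold: float | None = ARTIFACT_THRESHOLD) -> EpochSet:
    """Epochs from object grasp to ``post_s`` after it."""
    return _epoch(rec, task, phase="holding", post_s=post_s,
                  artifact_threshold=artifact_threshold)


def _epoch(rec: Recording, task: str, phase: str, pre_s: float = 2.0,
           post_s: float = 2.0, artifact_threshold: float | None = None) -> EpochSet:
    epochs, landmarks, mask = [], [], []
    for onset, hold in _paired_trial_events(rec):
        if hold is None:
            logger.warning("trial at sample %d discarded: missing holding_onset",
                           onset)
            mask.append(False)
            continue
        if phase == "movement":
            start = onset - int(round(pre_s * rec.rate))
            stop = hold
            lm = (onset - start, -1)
        else:
            start = hold
            stop = hold + int(round(post_s * rec.rate))
            lm = (-1, 0)
        if start < 0 or stop > rec.n_samples or stop <= start:
            logger.warning("trial at sample %d discarded: window [%d, %d) "
                           "outside recording", onset, start, stop)
            mask.append(False)
            continue
        chunk = rec.data[:, start:stop]
        if artifact_threshold is not None and np.abs(chunk).max() > artifact_threshold:
            logger.warning("trial at sample %d discarded: amplitude above "
                           "%.1f", onset, artifact_threshold)
            mask.append(False)
            continue
        epochs.append(chunk.copy())
        landmarks.append(lm)
        mask.append(True)
    if not epochs:
        raise ValueError(f"no valid {phase} trials in recording")
    return EpochSet(epochs=epochs, rate=rec.rate, task=task,
                    landmarks=landmarks, mask=mask, labels=list(rec.labels))


def equalize_epoch_lengths(eps: EpochSet) -> EpochSet:
    """Cubic-spline resampling of every epoch to the rounded mean length."""
    if eps.n_epochs == 0:
        raise ValueError("no epochs to equalize")
    lengths = [e.shape[1] for e in eps.epochs]
    if min(lengths) < 4:
        raise ValueError("epoch shorter than 4 samples; cubic spline undefined")
    target = int(round(float(np.mean(lengths))))
    new_epochs, new_landmarks = [], []
    for ep, lm in zip(eps.epochs, eps.landmarks):
        n = ep.shape[1]
        if n == target:
            new_epochs.append(ep.copy())
            new_landmarks.append(lm)
            continue
        x_old = np.linspace(0.0, 1.0, n)
        x_new = np.linspace(0.0, 1.0, target)
        new_epochs.append(CubicSpline(x_old, ep, axis=1)(x_new))
        scale = (target - 1) / (n - 1)
        new_landmarks.append(tuple(-1 if v < 0 else int(round(v * scale))
                                   for v in lm))
    return EpochSet(epochs=new_epochs, rate=eps.rate, task=eps.task,
                    landmarks=new_landmarks, mask=list(eps.mask),
                    labels=list(eps.labels))


def average_epochs(eps: EpochSet) -> Recording:
    """Element-wise mean of the (equalized) epochs as a Recording.

    The landmark of the average is the mean onset index across epochs.
    """
    if eps.n_epochs == 0:
        raise ValueError("all epochs discarded; nothing to average")
    tensor = eps.tensor()
    data = tensor.mean(axis=0)
    events = []
    for j, name in [(0, "movement_onset"), (1, "holding_onset")]:
        vals = [lm[j] for lm in eps.landmarks if lm[j] >= 0]
        if vals:
            events.append((int(round(float(np.mean(vals)))), name))
    return Recording(data=data, rate=eps.rate, labels=list(eps.labels),
                     modality=EEG, events=events)


def process_emg(rec: Recording, mvc: np.ndarray) -> Recording:
    """Detrend, 50 Hz high-pass, rectify, 10 Hz low-pass, MVC-normalize."""
    if rec.modality != EMG:
        raise ValueError("process_emg expects an EMG recording")
    mvc = np.asarray(mvc, dtype=float)
    if mvc.shape != (rec.n_channels,):
        raise ValueError("one MVC value per muscle required")
    if (mvc <= 0).any():
        raise ValueError("MVC entries must be > 0")
    data = sps.detrend(rec.data, axis=1, type="linear")
    sos_hp = sps.butter(EMG_FILTER_ORDER, EMG_HIGHPASS_HZ, btype="highpass",
                        fs=rec.rate, output="sos")
    data = sps.sosfiltfilt(sos_hp, data, axis=1)
    data = np.abs(data)
    sos_lp = sps.butter(EMG_FILTER_ORDER, EMG_LOWPASS_HZ, btype="lowpass",
                        fs=rec.rate, output="sos")
    data = sps.sosfiltfilt(sos_lp, data, axis=1)
    data = np.clip(data / mvc[:, None], 0.0, None)
    return rec.copy_with(data)


def central_segment(rec: Recording, duration_s: float = 60.0) -> Recording:
    """Central contiguous ``duration_s`` of a recording (resting analysis)."""
    n_keep = int(round(duration_s * rec.rate))
    if n_keep >= rec.n_samples:
        return rec.copy_with(rec.data)
    start = (rec.n_samples - n_keep) // 2
    events = [(i - start, lab) for i, lab in rec.events
              if start <= i < start + n_keep]
    return rec.copy_with(rec.data[:, start:start + n_keep], events=events)
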
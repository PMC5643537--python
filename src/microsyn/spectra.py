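"""Time-frequency analysis of movement epochs and beta-band events.

Short-time power uses 200 ms Hamming windows advanced in 32 ms steps over
1-40 Hz; each frequency bin is normalized by its own time-average and
expressed as percent change.  Beta-band (13-30 Hz) desynchronization before
movement onset and the post-grasp rebound are detected with a
threshold-and-persistence rule, and the modal microstate at those time
points is tallied across epochs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import Recording, Segmentation, Spectrogram

WIN_MS = 200.0
STEP_MS = 32.0
FREQ_RANGE = (1.0, 40.0)
BETA_BAND = (13.0, 30.0)
ELECTRODES_OF_INTEREST = ("Cz", "CPz", "Pz", "C1", "C3", "C2", "C4")
#: percent-change threshold and persistence (steps) of the event detector
EVENT_THRESHOLD_PCT = 10.0
EVENT_PERSISTENCE = 3


def stft_power(data: np.ndarray, rate: float, win_ms: float = WIN_MS,
               step_ms: float = STEP_MS,
               freq_range: tuple[float, float] = FREQ_RANGE,
               t0_s: float = 0.0) -> Spectrogram:
    """Hamming-tapered short-time power of one (multi)channel epoch.

    ``t0_s`` is the trial time of the first sample, so the returned window
    centers live on the trial timeline.  The number of steps is
    ``floor((n - win) / step) + 1``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    win = int(round(win_ms * rate / 1000.0))
    step = int(round(step_ms * rate / 1000.0))
    if data.shape[1] < win:
        raise ValueError("epoch shorter than one analysis window")
    freqs, times, power = sps.spectrogram(
        data, fs=rate, window="hamming", nperseg=win, noverlap=win - step,
        detrend=False, scaling="spectrum", mode="psd", axis=1)
    keep = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    power = power[:, keep]
    if power.shape[0] == 1:
        power = power[0]
    return Spectrogram(power=power, freqs=freqs[keep], times=times + t0_s,
                       win_s=win / rate, step_s=step / rate)


def normalize_spectrogram(spec: Spectrogram) -> Spectrogram:
    """Percent change of each bin against its own time average."""
    mean = spec.power.mean(axis=-1, keepdims=True)
    safe = np.where(mean == 0, 1.0, mean)
    power = 100.0 * (spec.power / safe - 1.0)
    power = np.where(np.broadcast_to(mean == 0, power.shape), 0.0, power)
    return Spectrogram(power=power, freqs=spec.freqs, times=spec.times,
                       win_s=spec.win_s, step_s=spec.step_s, normalized=True,
                       roi_averaged=spec.roi_averaged)


def roi_average(spec: Spectrogram, channel_labels: list[str],
                electrodes: tuple[str, ...] = ELECTRODES_OF_INTEREST,
                ) -> Spectrogram:
    """Element-wise mean over the named electrodes of interest."""
    if spec.power.ndim != 3:
        raise ValueError("roi_average expects a channels x freqs x steps power")
    missing = [e for e in electrodes if e not in channel_labels]
    if missing:
        raise KeyError(f"electrodes missing from recording: {missing}")
    idx = [channel_labels.index(e) for e in electrodes]
    return Spectrogram(power=spec.power[idx].mean(axis=0), freqs=spec.freqs,
                       times=spec.times, win_s=spec.win_s, step_s=spec.step_s,
                       normalized=spec.normalized, roi_averaged=True)


def band_mean(spec: Spectrogram, band: tuple[float, float] = BETA_BAND,
              ) -> np.ndarray:
    """Mean power over a frequency band as a time series."""
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not sel.any():
        raise ValueError("band does not overlap the retained frequencies")
    return spec.power[..., sel, :].mean(axis=-2)


def _first_persistent(series: np.ndarray, mask: np.ndarray,
                      n_consec: int) -> int | None:
    """Index of the first run of ``n_consec`` True values inside ``mask``."""
    idx = np.flatnonzero(mask)
    for i in idx:
        if i + n_consec <= series.size and mask[i:i + n_consec].all():
            return int(i)
    return None


def detect_beta_events(spec: Spectrogram, hold_onset_s: float,
                       band: tuple[float, float] = BETA_BAND,
                       threshold_pct: float = EVENT_THRESHOLD_PCT,
                       persistence: int = EVENT_PERSISTENCE,
                       ) -> tuple[float | None, float | None]:
    """Beta desynchronization and rebound onsets on a normalized ROI spectrogram.

    Desynchronization onset: first step before movement onset (t < 0) where
    the beta-band mean stays below ``-threshold_pct`` for ``persistence``
    consecutive steps.  Rebound onset: first step after ``hold_onset_s``
    where it stays above ``+threshold_pct``.  ``None`` marks an absent event.
    """
    if not spec.normalized:
        raise ValueError("detector expects a percent-normalized spectrogram")
    beta = band_mean(spec, band)
    t = spec.times
    desync_idx = _first_persistent(beta, (beta < -threshold_pct) & (t < 0),
                                   persistence)
    rebound_idx = _first_persistent(
        beta, (beta > threshold_pct) & (t > hold_onset_s), persistence)
    desync = float(t[desync_idx]) if desync_idx is not None else None
    rebound = float(t[rebound_idx]) if rebound_idx is not None else None
    return desync, rebound


def microstate_at_event(segmentations: list[Segmentation],
                        event_samples: list[int], n_states: int,
                        ) -> dict[str, object]:
    """Modal microstate across epochs at a given event sample.

    Returns the full count table; when several states tie for the mode the
    ``modal`` entry lists them all and ``tie`` is flagged.
    """
    if len(segmentations) != len(event_samples):
        raise ValueError("one event sample per segmentation required")
    counts = np.zeros(n_states, dtype=int)
    for seg, s in zip(segmentations, event_samples):
        if not 0 <= s < seg.n_samples:
            raise ValueError(f"event sample {s} outside segmentation")
        counts[seg.labels[s]] += 1
    top = counts.max()
    modal = np.flatnonzero(counts == top).tolist()
    return {"counts": counts, "modal": modal, "tie": len(modal) > 1}
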
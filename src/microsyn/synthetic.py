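"""Synthetic EEG/EMG generator with known ground truth.

The generator emulates the structure of a reaching-and-grasping study:
64-channel EEG whose scalp topography switches between a small set of
quasi-stable maps (microstates), 15-muscle nonnegative EMG envelopes built
from synergy weight vectors times timed activation profiles, a trial
timeline (task cue, 2 s preparation, ~1 s movement, 2 s holding), and a
configurable coupling between microstate occupancy and synergy amplitude
that can differ by grasp type.  Every downstream stage of the pipeline is
testable against the embedded truth without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EEG, EMG, Recording

# Standard 64-channel 10-10 montage labels (Biosemi ordering); includes the
# centro-parietal electrodes of interest Cz, CPz, Pz, C1, C3, C2, C4.
BIOSEMI64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

#: 15 recorded arm and hand muscles (abbreviations)
MUSCLES = [
    "TRAP", "DANT", "BICL", "TRIC", "PRON", "FLDS", "EXDC", "FLCU", "EXCU",
    "FLCR", "EXCL", "FLPB", "EXPB", "ADPT", "ABDM",
]

#: the five motor tasks: planar reaching plus the four grasp types
TASKS = ["reaching", "ulnar", "five_finger", "pulp", "cylindrical"]
GRASPS = TASKS[1:]

# Mean movement-execution durations per task (s), used as trial defaults.
MOVE_DURATIONS = {
    "reaching": 0.93,
    "ulnar": 1.28,
    "five_finger": 1.20,
    "pulp": 1.20,
    "cylindrical": 1.08,
}

#: amplitude (arbitrary microvolt scale) of the simulated EEG topographies
EEG_AMPLITUDE = 10.0
#: frequency (Hz) of the rectified-sinusoid GFP envelope
ENVELOPE_HZ = 10.0
#: positive offset keeping the GFP envelope away from zero
ENVELOPE_OFFSET = 0.25


def eeg_channel_names(n_channels: int) -> list[str]:
    if n_channels <= len(BIOSEMI64):
        return BIOSEMI64[:n_channels]
    return BIOSEMI64 + [f"CH{i}" for i in range(len(BIOSEMI64), n_channels)]


def muscle_names(n_muscles: int) -> list[str]:
    if n_muscles <= len(MUSCLES):
        return MUSCLES[:n_muscles]
    return MUSCLES + [f"M{i}" for i in range(len(MUSCLES), n_muscles)]


@dataclass
class ActivationTemplate:
    """Temporal profile of one synergy within a trial.

    ``tonic`` synergies hold a plateau through preparation and movement;
    phasic ones are Gaussian bumps centred ``center`` seconds after movement
    onset with standard deviation ``width`` seconds.
    """

    center: float
    width: float
    amplitude: float
    tonic: bool = False

    def evaluate(self, t: np.ndarray, prep_s: float, move_s: float) -> np.ndarray:
        if self.amplitude < 0:
            raise ValueError("activation amplitude must be nonnegative")
        if self.tonic:
            # plateau from trial start through the end of movement, with
            # 100 ms cosine ramps so the envelope stays smooth
            ramp = 0.1
            up = np.clip((t + prep_s) / ramp, 0.0, 1.0)
            down = np.clip((move_s + ramp - t) / ramp, 0.0, 1.0)
            return self.amplitude * 0.5 * (1 - np.cos(np.pi * up)) * \
                0.5 * (1 - np.cos(np.pi * down))
        return self.amplitude * np.exp(-0.5 * ((t - self.center) / self.width) ** 2)


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline tries to recover."""

    topographies: np.ndarray                  # n_states x n_channels
    transition: np.ndarray                    # jump matrix, zero diagonal
    dwell_ms: float
    synergy_weights: np.ndarray               # muscles x n_syn, unit-norm cols
    activation_templates: dict[str, list[ActivationTemplate]]
    coupling: np.ndarray                      # states x synergies, >= 0
    class_occupancy: dict[str, np.ndarray]    # task -> states x prep windows
    seed: int = 0

    def __post_init__(self) -> None:
        topo = np.atleast_2d(np.asarray(self.topographies, dtype=float))
        if not np.allclose(topo.mean(axis=1), 0, atol=1e-8):
            raise ValueError("topographies must be average-referenced")
        if not np.allclose(np.linalg.norm(topo, axis=1), 1, atol=1e-8):
            raise ValueError("topographies must be unit-norm")
        self.topographies = topo
        self.transition = np.asarray(self.transition, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if self.dwell_ms <= 0:
            raise ValueError("dwell time must be > 0")
        self.synergy_weights = np.asarray(self.synergy_weights, dtype=float)
        if (self.synergy_weights < 0).any():
            raise ValueError("synergy weights must be nonnegative")

    @property
    def n_states(self) -> int:
        return self.topographies.shape[0]

    @property
    def n_channels(self) -> int:
        return self.topographies.shape[1]

    @property
    def n_synergies(self) -> int:
        return self.synergy_weights.shape[1]


def make_topographies(n_states: int, n_channels: int, min_separation: float,
                      seed: int | np.random.Generator,
                      max_redraws: int = 2000) -> np.ndarray:
    """Draw average-referenced unit-norm maps with bounded pairwise |corr|.

    Maps are drawn one at a time from an isotropic Gaussian and redrawn while
    their absolute spatial correlation with any accepted map exceeds
    ``min_separation``; a bounded redraw budget turns an over-constrained
    request (e.g. 2 channels under average reference) into an error.
    """
    if not 1 <= n_states < n_channels:
        raise ValueError("need 1 <= n_states < n_channels")
    if not 0 <= min_separation < 1:
        raise ValueError("min_separation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    for _ in range(n_states):
        for _attempt in range(max_redraws):
            v = rng.standard_normal(n_channels)
            v -= v.mean()
            norm = np.linalg.norm(v)
            if norm == 0:
                continue
            v /= norm
            if all(abs(v @ m) <= min_separation for m in maps):
                maps.append(v)
                break
        else:
            raise RuntimeError(
                f"could not place map {len(maps) + 1} with pairwise "
                f"|correlation| <= {min_separation} in {n_channels} channels"
            )
    return np.array(maps)


def _sample_state_sequence(rng: np.random.Generator, transition: np.ndarray,
                           dwell_samples: float, n_samples: int,
                           start: int | None = None) -> np.ndarray:
    """First-order Markov jump chain with geometric dwell truncated at 2."""
    n_states = transition.shape[0]
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(n_states)) if start is None else start
    pos = 0
    while pos < n_samples:
        if dwell_samples > 2:
            run = 1 + int(rng.geometric(1.0 / (dwell_samples - 1.0)))
        else:
            run = 2
        run = min(run, n_samples - pos)
        labels[pos:pos + run] = state
        pos += run
        if n_states > 1:
            state = int(rng.choice(n_states, p=transition[state]))
    return labels


def _eeg_from_labels(rng: np.random.Generator, truth: GroundTruth,
                     labels: np.ndarray, rate: float, snr: float) -> np.ndarray:
    # the topography rides on a zero-mean ~10 Hz oscillation (its rectified
    # shape is the GFP fluctuation), so the 1-40 Hz band-pass of the
    # preprocessing leaves the maps intact; polarity-invariant clustering
    # absorbs the sign flips
    t = np.arange(labels.size) / rate
    carrier = EEG_AMPLITUDE * (
        ENVELOPE_OFFSET * np.sin(2 * np.pi * (ENVELOPE_HZ / 3.7) * t + 0.4)
        + np.sin(2 * np.pi * ENVELOPE_HZ * t))
    signal = truth.topographies[labels].T * carrier
    noise_sd = float(np.sqrt(np.mean(signal ** 2))) / snr
    return signal + noise_sd * rng.standard_normal(signal.shape)


def simulate_eeg(truth: GroundTruth, duration: float, rate: float, snr: float,
                 seed: int | np.random.Generator) -> tuple[Recording, np.ndarray]:
    """Simulate piecewise-stable EEG: ``topography[state(t)] * envelope(t) + noise``.

    ``snr`` is the ratio of signal RMS to white-noise RMS.  Returns the
    recording together with the true per-sample state labels.
    """
    if not np.isfinite(snr) or snr <= 0:
        raise ValueError("snr must be finite and > 0")
    if truth.n_states == 0:
        raise ValueError("empty topography list")
    n_samples = int(round(duration * rate))
    if n_samples < 1:
        raise ValueError("duration * rate must be >= 1")
    rng = np.random.default_rng(seed)
    dwell_samples = truth.dwell_ms * rate / 1000.0
    labels = _sample_state_sequence(rng, truth.transition, dwell_samples, n_samples)
    data = _eeg_from_labels(rng, truth, labels, rate, snr)
    rec = Recording(data=data, rate=rate, labels=eeg_channel_names(truth.n_channels),
                    modality=EEG)
    return rec, labels


def simulate_trial_emg(truth: GroundTruth, task: str,
                       timing: tuple[float, float, float], noise_sd: float,
                       seed: int | np.random.Generator, rate: float = 1000.0,
                       modulation: np.ndarray | None = None) -> Recording:
    """Nonnegative EMG ``W @ H + noise`` for one trial, clipped at zero.

    ``timing = (prep_s, move_s, hold_s)``; time 0 is movement onset.  The
    optional ``modulation`` (synergies x samples, >= 0) multiplies the
    activations sample-wise and is how microstate-synergy coupling enters.
    """
    if task not in truth.activation_templates:
        raise KeyError(f"task {task!r} not in configured set")
    prep_s, move_s, hold_s = timing
    if min(prep_s, move_s, hold_s) <= 0:
        raise ValueError("all trial phase durations must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round((prep_s + move_s + hold_s) * rate))
    t = np.arange(n_samples) / rate - prep_s
    H = np.array([tpl.evaluate(t, prep_s, move_s)
                  for tpl in truth.activation_templates[task]])
    if modulation is not None:
        if modulation.shape != H.shape:
            raise ValueError("modulation must be synergies x samples")
        H = H * modulation
    V = truth.synergy_weights @ H
    if noise_sd > 0:
        V = V + noise_sd * (V.max() if V.max() > 0 else 1.0) * \
            rng.standard_normal(V.shape)
    V = np.clip(V, 0.0, None)
    onset = int(round(prep_s * rate))
    hold = int(round((prep_s + move_s) * rate))
    events = [(0, "task_cue"), (onset, "movement_onset"), (hold, "holding_onset"),
              (n_samples - 1, "release")]
    return Recording(data=V, rate=rate,
                     labels=muscle_names(truth.synergy_weights.shape[0]),
                     modality=EMG, events=events)


# ---------------------------------------------------------------------------
# experiment-level generation
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Study-scale parameters of the synthetic experiment.

    Defaults mirror the acquisition being emulated: 64 EEG channels at
    2048 Hz, 15 muscles at 3 kHz, five motor tasks repeated 15 times, 2 s
    preparation and holding, per-task movement durations around 1 s.
    Tests and the desk-scale analyses pass reduced rates/durations.
    """

    n_subjects: int = 8
    tasks: list[str] = field(default_factory=lambda: list(TASKS))
    n_trials: int = 15
    n_channels: int = 64
    n_muscles: int = 15
    n_states: int = 5
    n_rest_states: int = 4
    n_synergies: int = 5
    eeg_rate: float = 2048.0
    emg_rate: float = 3000.0
    dwell_ms: float = 100.0
    snr: float = 5.0
    emg_noise_sd: float = 0.05
    coupling_strength: float = 1.0
    occupancy_separation: float = 0.6
    rest_duration_s: float = 300.0
    lead_s: float = 0.5
    prep_s: float = 2.0
    hold_s: float = 2.0
    tail_s: float = 0.5
    move_s: dict[str, float] = field(default_factory=lambda: dict(MOVE_DURATIONS))
    min_separation: float = 0.5

    def move_duration(self, task: str) -> float:
        return self.move_s.get(task, 1.0)

    @classmethod
    def demo(cls) -> "ExperimentConfig":
        """Reduced-scale configuration for fast end-to-end runs."""
        return cls(n_subjects=1, eeg_rate=256.0, emg_rate=500.0,
                   rest_duration_s=60.0)


@dataclass
class Trial:
    task: str
    eeg: Recording
    emg: Recording
    eeg_labels: np.ndarray                 # true per-sample state sequence


@dataclass
class SubjectDataset:
    subject: str
    resting: Recording
    trials: list[Trial]
    truth: GroundTruth


def make_ground_truth(config: ExperimentConfig,
                      seed: int | np.random.Generator) -> GroundTruth:
    """Draw a subject-level ground truth consistent with ``config``."""
    rng = np.random.default_rng(seed)
    topo = make_topographies(config.n_states, config.n_channels,
                             config.min_separation, rng)
    n_states = config.n_states
    if n_states > 1:
        transition = np.full((n_states, n_states), 1.0 / (n_states - 1))
        np.fill_diagonal(transition, 0.0)
    else:
        transition = np.ones((1, 1))

    # sparse nonnegative muscle weights: a small shared background plus a
    # dominant, near-disjoint muscle group per synergy, so each synergy
    # carries a distinct share of the EMG variance
    W = 0.05 * rng.gamma(shape=1.0, scale=1.0,
                         size=(config.n_muscles, config.n_synergies))
    block_size = max(2, config.n_muscles // config.n_synergies)
    order = rng.permutation(config.n_muscles)
    for k in range(config.n_synergies):
        block = order[(k * block_size) % config.n_muscles:
                      (k * block_size) % config.n_muscles + block_size]
        W[block, k] += 1.0 + 0.5 * rng.random(block.size)
    W /= np.linalg.norm(W, axis=0, keepdims=True)

    templates: dict[str, list[ActivationTemplate]] = {}
    for task in config.tasks:
        move = config.move_duration(task)
        tpls = []
        for k in range(config.n_synergies):
            if k == 0:
                # postural/tonic synergy through preparation and movement
                tpls.append(ActivationTemplate(center=0.0, width=1.0,
                                               amplitude=0.6, tonic=True))
            elif k == 1:
                # broad synergy peaking at movement onset
                tpls.append(ActivationTemplate(center=0.0, width=0.25 * move,
                                               amplitude=1.2))
            else:
                # sharp phasic bursts spread over the movement phase, each
                # with a distinct center so no two activations are collinear
                center = (0.15 + 0.7 * (k - 2) / max(1, config.n_synergies - 3)) \
                    * move
                tpls.append(ActivationTemplate(center=center, width=0.07 * move,
                                               amplitude=2.0))
        templates[task] = tpls

    # each state preferentially drives one synergy
    coupling = np.zeros((n_states, config.n_synergies))
    for s in range(n_states):
        coupling[s, s % config.n_synergies] = config.coupling_strength

    n_prep_windows = int(round(config.prep_s / 0.1))
    class_occupancy: dict[str, np.ndarray] = {}
    for j, task in enumerate(config.tasks):
        prof = np.full((n_states, n_prep_windows), 1.0 / n_states)
        sep = config.occupancy_separation
        if sep > 0:
            # grasp-specific preference: each task emphasises a rotating pair
            # of states over the preparation windows
            for w in range(n_prep_windows):
                fav = (j + (w // (n_prep_windows // 2 or 1))) % n_states
                prof[:, w] *= (1 - sep)
                prof[fav, w] += sep
        class_occupancy[task] = prof

    seed_int = int(rng.integers(2 ** 31 - 1))
    return GroundTruth(topographies=topo, transition=transition,
                       dwell_ms=config.dwell_ms, synergy_weights=W,
                       activation_templates=templates, coupling=coupling,
                       class_occupancy=class_occupancy, seed=seed_int)


def _trial_label_sequence(rng: np.random.Generator, truth: GroundTruth,
                          config: ExperimentConfig, task: str,
                          rate: float) -> tuple[np.ndarray, int, int]:
    """True state labels of one trial; returns (labels, onset, hold) samples."""
    move_s = config.move_duration(task)
    n_lead = int(round(config.lead_s * rate))
    n_prep = int(round(config.prep_s * rate))
    n_rest = int(round((move_s + config.hold_s + config.tail_s) * rate))
    dwell_samples = truth.dwell_ms * rate / 1000.0

    lead = _sample_state_sequence(rng, truth.transition, dwell_samples, n_lead)
    # preparation: one prevalent state per 100 ms window, drawn from the
    # grasp-specific occupancy profile
    prof = truth.class_occupancy[task]
    n_windows = prof.shape[1]
    win_len = n_prep // n_windows
    prep = np.empty(n_prep, dtype=int)
    for w in range(n_windows):
        s = int(rng.choice(truth.n_states, p=prof[:, w] / prof[:, w].sum()))
        lo = w * win_len
        hi = n_prep if w == n_windows - 1 else (w + 1) * win_len
        prep[lo:hi] = s
    tail = _sample_state_sequence(rng, truth.transition, dwell_samples, n_rest,
                                  start=int(prep[-1]))
    labels = np.concatenate([lead, prep, tail])
    onset = n_lead + n_prep
    hold = onset + int(round(move_s * rate))
    return labels, onset, hold


def simulate_experiment(config: ExperimentConfig, seed: int,
                        truth: GroundTruth | None = None) -> list[SubjectDataset]:
    """Generate the full per-subject dataset the pipeline consumes.

    Each subject gets a resting recording plus ``n_trials`` trials of each
    task with paired EEG/EMG and ordered event tables.  Grasp-conditional
    occupancy differences and state-synergy coupling are embedded exactly as
    configured; with ``coupling_strength = 0`` and
    ``occupancy_separation = 0`` the dataset is null for CCA and decoding.
    """
    if truth is not None and truth.n_channels != config.n_channels:
        raise ValueError("channel count of supplied truth does not match config")
    root = np.random.SeedSequence(seed)
    subjects = []
    for si, sub_ss in enumerate(root.spawn(config.n_subjects)):
        streams = sub_ss.spawn(3)
        truth_s = truth if truth is not None else make_ground_truth(
            config, np.random.default_rng(streams[0]))
        rest, _ = simulate_eeg(_restrict_states(truth_s, config.n_rest_states),
                               config.rest_duration_s, config.eeg_rate,
                               config.snr, np.random.default_rng(streams[1]))
        trial_rng = np.random.default_rng(streams[2])
        trials = []
        for task in config.tasks:
            for _rep in range(config.n_trials):
                labels, onset, hold = _trial_label_sequence(
                    trial_rng, truth_s, config, task, config.eeg_rate)
                eeg_data = _eeg_from_labels(trial_rng, truth_s, labels,
                                            config.eeg_rate, config.snr)
                n = labels.size
                events = [(int(round(config.lead_s * config.eeg_rate)), "task_cue"),
                          (onset, "movement_onset"), (hold, "holding_onset"),
                          (min(n - 1, hold + int(round(config.hold_s * config.eeg_rate))),
                           "release")]
                eeg = Recording(data=eeg_data, rate=config.eeg_rate,
                                labels=eeg_channel_names(config.n_channels),
                                modality=EEG, events=events)
                emg = _coupled_trial_emg(trial_rng, truth_s, config, task, labels)
                trials.append(Trial(task=task, eeg=eeg, emg=emg,
                                    eeg_labels=labels))
        subjects.append(SubjectDataset(subject=f"S{si + 1:02d}", resting=rest,
                                       trials=trials, truth=truth_s))
    return subjects


def _restrict_states(truth: GroundTruth, n_states: int) -> GroundTruth:
    """Truth restricted to its first ``n_states`` topographies.

    Used for resting state, whose repertoire is smaller than the task one
    (the extra states are task-specific).
    """
    n = min(n_states, truth.n_states)
    if n == truth.n_states:
        return truth
    if n > 1:
        transition = np.full((n, n), 1.0 / (n - 1))
        np.fill_diagonal(transition, 0.0)
    else:
        transition = np.ones((1, 1))
    import dataclasses
    return dataclasses.replace(truth, topographies=truth.topographies[:n],
                               transition=transition,
                               coupling=truth.coupling[:n])


def _coupled_trial_emg(rng: np.random.Generator, truth: GroundTruth,
                       config: ExperimentConfig, task: str,
                       eeg_labels: np.ndarray) -> Recording:
    """Raw trial EMG whose synergy amplitudes follow the current microstate.

    The EEG label sequence is reduced to a prevalent state per 100 ms window
    and each synergy's activation is scaled by
    ``1 + sum_s coupling[s, k] * occupancy_s(window)``.  The returned signal
    is the synergy-built envelope modulating a broadband carrier (an
    interference-pattern stand-in), so the standard EMG conditioning chain
    (high-pass, rectify, low-pass) recovers the envelope.
    """
    move_s = config.move_duration(task)
    emg_len = int(round((config.lead_s + config.prep_s + move_s +
                         config.hold_s + config.tail_s) * config.emg_rate))
    # prevalent EEG state per 100 ms window, resampled to the EMG timeline
    win_eeg = max(1, int(round(0.1 * config.eeg_rate)))
    n_win = int(np.ceil(eeg_labels.size / win_eeg))
    prevalent = np.empty(n_win, dtype=int)
    for w in range(n_win):
        chunk = eeg_labels[w * win_eeg:(w + 1) * win_eeg]
        prevalent[w] = np.bincount(chunk, minlength=truth.n_states).argmax()
    emg_t = np.arange(emg_len) / config.emg_rate
    win_of_sample = np.minimum((emg_t / 0.1).astype(int), n_win - 1)
    state_per_sample = prevalent[win_of_sample]
    modulation = 1.0 + truth.coupling[state_per_sample].T   # K x samples
    emg = simulate_trial_emg(
        truth, task,
        timing=(config.lead_s + config.prep_s, move_s,
                config.hold_s + config.tail_s),
        noise_sd=config.emg_noise_sd, seed=rng, rate=config.emg_rate,
        modulation=modulation)
    emg.data = emg.data * rng.standard_normal(emg.data.shape)
    # re-anchor events to include the cue lead
    onset = int(round((config.lead_s + config.prep_s) * config.emg_rate))
    hold = onset + int(round(move_s * config.emg_rate))
    emg.events = [(int(round(config.lead_s * config.emg_rate)), "task_cue"),
                  (onset, "movement_onset"), (hold, "holding_onset"),
                  (min(emg_len - 1, hold + int(round(config.hold_s * config.emg_rate))),
                   "release")]
    return emg
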
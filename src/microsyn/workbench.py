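"""Configuration and end-to-end orchestration of the per-subject analysis.

``run_pipeline`` ties the stages together in dependency order: synthetic
data generation, EEG/EMG preprocessing, microstate extraction (resting +
per task/phase) with model-order harmonization, back-fitting and occurrence
dynamics, synergy extraction and occurrence, time-frequency beta events,
per-subject canonical correlation, and grasp decoding.  Every artifact is
written under ``out/<subject>/<stage>/`` and listed in a manifest carrying
the seed and a hash of the configuration.

Model orders are harmonized within subject so occurrence matrices align
across tasks: the movement-phase microstate K is the rounded mean of the
per-task CV choices and a single subject-level task template set is
re-clustered at that K from the pooled GFP-peak maps; likewise the synergy
count is the rounded mean of the per-task VAF choices, each task re-factored
at it, and columns aligned through the reference set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dynamics, io, microstates, multivariate, preprocess, spectra, \
    synergies
from .containers import EpochSet, Recording
from .synthetic import ExperimentConfig, SubjectDataset, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run-level parameters; defaults are the analysis's standard values."""

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    target_rate: float = 128.0
    rest_analysis_s: float = 60.0
    min_segment_ms: float = 23.0
    match_threshold: float = 0.65
    vaf_threshold: float = 0.98
    dot_threshold: float = 0.65
    alpha: float = 0.05
    k_min: int = 2
    k_max: int = 8
    n_init: int = 10
    nnmf_restarts: int = 50
    syn_k_max: int = 8
    n_reps: int = 1000
    n_null: int = 10000
    n_perm: int = 10000
    cca_surrogates: int = 100
    beta_band: tuple[float, float] = (13.0, 30.0)
    electrodes: tuple[str, ...] = spectra.ELECTRODES_OF_INTEREST
    syn_prep_s: float = 1.0         # synergy occurrence starts 1 s before onset

    @classmethod
    def demo(cls) -> "RunConfig":
        """Reduced-scale configuration for fast end-to-end runs."""
        return cls(experiment=ExperimentConfig.demo(), nnmf_restarts=8,
                   n_reps=50, n_null=200, n_perm=500, cca_surrogates=50)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        exp = ExperimentConfig(**raw.pop("experiment", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for tup in ("beta_band", "electrodes"):
            if tup in kwargs and isinstance(kwargs[tup], list):
                kwargs[tup] = tuple(kwargs[tup])
        return cls(experiment=exp, **kwargs)


def _prep_eeg(rec: Recording, config: RunConfig) -> Recording:
    rec = preprocess.filter_eeg(rec)
    rec = preprocess.resample(rec, config.target_rate)
    return preprocess.rereference_average(rec)


def _select_k(maps: np.ndarray, config: RunConfig, rng: np.random.Generator):
    k_hi = min(config.k_max, maps.shape[0] - 1, maps.shape[1] - 2)
    return microstates.select_k(maps, range(config.k_min, k_hi + 1),
                                n_init=config.n_init, seed=rng)


def _merge_epochs(a: EpochSet, b: EpochSet) -> EpochSet:
    return EpochSet(epochs=a.epochs + b.epochs, rate=a.rate, task=a.task,
                    landmarks=a.landmarks + b.landmarks, mask=a.mask + b.mask,
                    labels=a.labels)


def run_pipeline(config: RunConfig, seed: int, outdir: str | Path) -> dict:
    """Run the whole per-subject analysis on a synthetic experiment.

    Returns the manifest dictionary (also written to ``outdir/manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    artifacts: list[str] = []

    def _save(path: Path) -> None:
        artifacts.append(str(path.relative_to(outdir)))

    subjects = simulate_experiment(config.experiment, seed)
    exp = config.experiment
    tasks = exp.tasks
    grasps = [t for t in tasks if t != "reaching"]
    summary: dict[str, dict] = {}

    for dataset in subjects:
        sub = dataset.subject
        sdir = outdir / sub
        ssum: dict[str, object] = {}

        # ------------------------------------------------------ microstates
        rest = preprocess.central_segment(_prep_eeg(dataset.resting, config),
                                          config.rest_analysis_s)
        ms_dir = sdir / "microstates"
        ms_dir.mkdir(parents=True, exist_ok=True)
        rest_set, rest_cv = _select_k(microstates.peak_maps(rest), config, rng)
        rest_set.subject, rest_set.condition = sub, "rest"
        _save(io.write_matrix(rest_set.maps, ms_dir / "rest_templates.tsv",
                              header=rest.labels))
        ssum["rest_k"] = rest_set.n_states
        ssum["rest_cv_curve"] = {str(k): v for k, v in rest_cv.items()}

        prep_trials: dict[str, list[Recording]] = {}
        phase_k: dict[str, dict[str, int]] = {t: {} for t in tasks}
        movement_peak_maps: list[np.ndarray] = []
        for task in tasks:
            eegs = [_prep_eeg(t.eeg, config)
                    for t in dataset.trials if t.task == task]
            prep_trials[task] = eegs
            for phase, epocher in (("movement", preprocess.epoch_movement),
                                   ("holding", preprocess.epoch_holding)):
                pooled: EpochSet | None = None
                for rec in eegs:
                    eps = epocher(rec, task=task, artifact_threshold=None)
                    pooled = eps if pooled is None else _merge_epochs(pooled, eps)
                pooled = preprocess.equalize_epoch_lengths(pooled)
                avg = preprocess.average_epochs(pooled)
                maps = microstates.peak_maps(avg)
                msset, _cv = _select_k(maps, config, rng)
                phase_k[task][phase] = msset.n_states
                if phase == "movement":
                    movement_peak_maps.append(maps)
        ssum["task_k"] = phase_k

        # one subject-level task template set at the harmonized movement K
        k_task = microstates.harmonize_k(
            [phase_k[t]["movement"] for t in tasks])
        pooled_maps = np.vstack(movement_peak_maps)
        task_set, _assign, _ev = microstates.modified_kmeans(
            pooled_maps, k_task, n_init=config.n_init, seed=rng)
        task_set.subject, task_set.condition = sub, "task"
        _save(io.write_matrix(task_set.maps, ms_dir / "task_templates.tsv"))
        ssum["task_k_harmonized"] = k_task

        mapping, unmatched, _tab = microstates.match_sets(
            task_set, rest_set, config.match_threshold)
        ssum["rest_matching"] = {"matched": {str(k): int(v)
                                             for k, v in mapping.items()},
                                 "unmatched": [int(u) for u in unmatched]}

        # --------------------------------------------- occurrence dynamics
        dyn_dir = sdir / "dynamics"
        dyn_dir.mkdir(parents=True, exist_ok=True)
        occupancies: dict[str, list[np.ndarray]] = {}
        histograms: dict[str, dynamics.OccurrenceMatrix] = {}
        segmentations: dict[str, list] = {}
        for task in tasks:
            occ_list, seg_list = [], []
            for rec in prep_trials[task]:
                onset = rec.event_samples("movement_onset")[0]
                hold = rec.event_samples("holding_onset")[0]
                move_s = (hold - onset) / rec.rate
                grid_t = dynamics.window_grid(exp.prep_s, move_s, exp.hold_s)
                seg = microstates.backfit(rec, task_set)
                seg = microstates.smooth_segmentation(seg,
                                                      config.min_segment_ms)
                seg_list.append((seg, onset, hold))
                occ_list.append(dynamics.epoch_occupancy(
                    seg, grid_t, k_task, onset, seed=rng))
            occupancies[task] = occ_list
            segmentations[task] = seg_list
            grid = dynamics.window_grid(exp.prep_s, exp.move_duration(task),
                                        exp.hold_s)
            hist = dynamics.occurrence_histogram(occ_list, grid,
                                                 task_set.labels)
            histograms[task] = hist
            _save(io.write_matrix(hist.values,
                                  dyn_dir / f"{task}_occurrence.tsv"))

        phase_tests = {}
        for task in tasks:
            stack = np.asarray(occupancies[task])
            grid = histograms[task].grid
            prep_ix = grid.phase_indices("preparation")
            exec_ix = grid.phase_indices("execution")
            hold_ix = grid.phase_indices("holding")
            n = min(len(prep_ix), len(exec_ix), len(hold_ix))
            res_pe = dynamics.permutation_test(
                stack[:, :, prep_ix[-n:]], stack[:, :, exec_ix[:n]],
                n_perm=config.n_perm, alpha=config.alpha, seed=rng)
            res_eh = dynamics.permutation_test(
                stack[:, :, exec_ix[:n]], stack[:, :, hold_ix[:n]],
                n_perm=config.n_perm, alpha=config.alpha, seed=rng)
            phase_tests[task] = {
                "prep_vs_exec_significant": int(res_pe["significant"].sum()),
                "exec_vs_hold_significant": int(res_eh["significant"].sum()),
            }
        ssum["phase_tests"] = phase_tests

        # ------------------------------------------------------- synergies
        syn_dir = sdir / "synergies"
        syn_dir.mkdir(parents=True, exist_ok=True)
        emg_epochs: dict[str, np.ndarray] = {}
        selected_k: dict[str, int] = {}
        for task in tasks:
            trials = [t for t in dataset.trials if t.task == task]
            epochs = []
            for t in trials:
                mvc = np.maximum(np.abs(t.emg.data).max(axis=1), 1e-9)
                env = preprocess.process_emg(t.emg, mvc)
                onset = env.event_samples("movement_onset")[0]
                hold = env.event_samples("holding_onset")[0]
                lo = onset - int(round(config.syn_prep_s * env.rate))
                hi = hold + int(round(exp.hold_s * env.rate))
                if lo < 0 or hi > env.n_samples:
                    logger.warning("%s %s: trial at %d discarded for synergy "
                                   "analysis (span outside recording)",
                                   sub, task, onset)
                    continue
                epochs.append(env.data[:, lo:hi])
            n_min = min(e.shape[1] for e in epochs)
            emg_epochs[task] = np.stack([e[:, :n_min] for e in epochs])
            V = np.concatenate(list(emg_epochs[task]), axis=1)
            model = synergies.select_n_synergies(
                V, k_max=min(config.syn_k_max, exp.n_muscles),
                threshold=config.vaf_threshold,
                n_restarts=config.nnmf_restarts, seed=rng)
            selected_k[task] = model.n_synergies
            ssum.setdefault("synergy_vaf_selected", {})[task] = float(model.vaf)
        ssum["synergy_k"] = selected_k

        # harmonized synergy count, re-extraction and reference alignment
        k_syn = int(round(float(np.mean(list(selected_k.values())))))
        syn_models: dict[str, synergies.SynergyModel] = {}
        for task in tasks:
            V = np.concatenate(list(emg_epochs[task]), axis=1)
            syn_models[task] = synergies.nnmf(
                V, k_syn, n_restarts=config.nnmf_restarts, seed=rng)
        refs = synergies.build_reference_set(
            [syn_models[t].W for t in tasks], n_ref=k_syn)
        _save(io.write_matrix(refs.T, syn_dir / "reference_weights.tsv",
                              header=dataset.trials[0].emg.labels))
        ssum["synergy_k_harmonized"] = k_syn

        syn_occ: dict[str, synergies.OccurrenceMatrix] = {}
        for task in tasks:
            model = syn_models[task]
            mapping_s, _un, _tab = synergies.match_synergies(
                model.W, refs, dot_threshold=-1.0)   # complete assignment
            grid = dynamics.window_grid(config.syn_prep_s,
                                        exp.move_duration(task), exp.hold_s)
            rate_emg = exp.emg_rate
            onset_in_epoch = int(round(config.syn_prep_s * rate_emg))
            occ = synergies.synergy_occurrence(model, emg_epochs[task], grid,
                                               rate_emg, onset_in_epoch)
            aligned = np.zeros_like(occ.values)
            for i, j in mapping_s.items():
                aligned[j] = occ.values[i]
            occ.values = aligned
            occ.state_labels = [f"Syn{j + 1}" for j in range(k_syn)]
            syn_occ[task] = occ
            _save(io.write_matrix(model.W.T, syn_dir / f"{task}_weights.tsv",
                                  header=dataset.trials[0].emg.labels))
            _save(io.write_matrix(occ.values,
                                  syn_dir / f"{task}_occurrence.tsv"))

        # --------------------------------------------------------- spectra
        sp_dir = sdir / "spectra"
        sp_dir.mkdir(parents=True, exist_ok=True)
        beta_events = {}
        for task in tasks:
            roi_specs = []
            for rec in prep_trials[task]:
                onset = rec.event_samples("movement_onset")[0]
                hold = rec.event_samples("holding_onset")[0]
                lo = onset - int(round(1.5 * rec.rate))
                hi = hold + int(round(1.5 * rec.rate))
                if lo < 0 or hi > rec.n_samples:
                    continue
                spec = spectra.stft_power(rec.data[:, lo:hi], rec.rate,
                                          t0_s=-1.5)
                spec = spectra.roi_average(spec, rec.labels, config.electrodes)
                roi_specs.append(spectra.normalize_spectrogram(spec))
            mean_power = np.mean([s.power for s in roi_specs], axis=0)
            avg = spectra.Spectrogram(
                power=mean_power, freqs=roi_specs[0].freqs,
                times=roi_specs[0].times, win_s=roi_specs[0].win_s,
                step_s=roi_specs[0].step_s, normalized=True, roi_averaged=True)
            desync, rebound = spectra.detect_beta_events(
                avg, exp.move_duration(task), config.beta_band)
            beta_events[task] = {"desync_s": desync, "rebound_s": rebound}
            # modal microstate at the detected events
            for name, t_ev in (("desync", desync), ("rebound", rebound)):
                if t_ev is None:
                    continue
                segs = [s for s, _o, _h in segmentations[task]]
                samples = [int(o + round(t_ev * config.target_rate))
                           for _s, o, _h in segmentations[task]]
                modal = spectra.microstate_at_event(segs, samples, k_task)
                beta_events[task][f"{name}_modal_state"] = [
                    task_set.labels[m] for m in modal["modal"]]
            _save(io.write_matrix(avg.power, sp_dir / f"{task}_tf_percent.tsv"))
        ssum["beta_events"] = beta_events

        # ------------------------------------------------------------- CCA
        mv_dir = sdir / "multivariate"
        mv_dir.mkdir(parents=True, exist_ok=True)
        cca_summary = {}
        for name, task_group in (("reaching", ["reaching"]),
                                 ("grasping", grasps)):
            pairs = [(histograms[t], syn_occ[t]) for t in task_group]
            X, Y = multivariate.stack_occurrences(pairs)
            if X.shape[0] <= max(X.shape[1], Y.shape[1]):
                logger.warning("%s: too few stacked windows for CCA", name)
                continue
            result = multivariate.cca(X, Y, subject=sub)
            null = multivariate.cca_permutation_null(
                X, Y, n_perm=config.cca_surrogates, seed=rng)
            cca_summary[name] = {
                "correlations": result.correlations.tolist(),
                "surrogate_median": float(np.median(null)),
            }
            _save(io.write_matrix(result.x_coef, mv_dir / f"{name}_ms_coef.tsv"))
            _save(io.write_matrix(result.y_coef, mv_dir / f"{name}_syn_coef.tsv"))
        ssum["cca"] = cca_summary

        # -------------------------------------------------------- decoding
        features: dict[str, np.ndarray] = {}
        for task in grasps:
            grid = histograms[task].grid
            prep_ix = grid.phase_indices("preparation")
            feats = [multivariate.build_feature_vectors(occ[:, prep_ix])
                     for occ in occupancies[task]]
            features[task] = np.array(feats)
        decoding = multivariate.lda_decode(features, n_reps=config.n_reps,
                                           seed=rng)
        null_accs, chance, _null_coef = multivariate.lda_null(
            features, n_null=config.n_null, seed=rng)
        decoding.null_accuracies = null_accs
        decoding.significance_level = chance
        ssum["decoding_accuracy_pct"] = 100.0 * decoding.accuracy
        ssum["decoding_chance_pct"] = 100.0 * chance
        _save(io.write_matrix(decoding.confusion, mv_dir / "confusion_pct.tsv",
                              header=list(features)))

        summary[sub] = ssum
        io.write_manifest(ssum, sdir / "summary.json")
        _save(sdir / "summary.json")

    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "subjects": list(summary),
        "artifacts": sorted(artifacts),
        "summary": summary,
    }
    io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
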
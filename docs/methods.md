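# Methods notes

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `microsyn`, in the spirit of the methods
documentation of packages like statsmodels or msprime. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and preprocessing

EEG is treated as a `channels × samples` matrix in microvolts under a
common average reference. The conditioning chain is: zero-phase Butterworth
band-pass 1–40 Hz (4th order, applied forward–backward; the filter family
is a choice — common practice in microstate work — since only "zero-phase
IIR" is conventionally specified), polyphase down-sampling to 128 Hz with
proportional event remapping, average re-referencing, epoching around the
trial events (movement epochs span −2 s → object grasp; holding epochs span
grasp → +2 s), cubic-spline interpolation of every epoch to the rounded
mean epoch length (exact at the endpoints and exact for polynomials up to
degree 3), and element-wise averaging per condition.

EMG conditioning: linear detrend (the detrending flavor is unstated in
standard descriptions; linear is the safer superset of constant), 50 Hz
high-pass (Butterworth, 7th order, zero-phase via second-order sections for
stability at this order), rectification, 10 Hz low-pass (same family),
normalization by per-muscle maximum voluntary contraction, and clipping of
post-filter ringing at zero because the downstream factorization requires
nonnegativity.

Artifact handling: visual epoch rejection is replaced by a configurable
amplitude threshold (default ±100 µV), and the ocular-ICA step is a
pass-through hook that accepts an externally supplied unmixing matrix —
the synthetic data contains no ocular artifacts.

## Microstates

* Maps are sampled at strict local maxima of the GFP (spatial SD around the
  channel mean) of the analysis signal, normalized to unit norm so that
  spatial correlation coincides with the inner product.
* The polarity-invariant k-means assigns by squared correlation and updates
  each template as the dominant eigenvector of the members' outer-product
  sum — the exact polarity-invariant centroid. Restarts (default 10) keep
  the best explained variance; empty clusters are re-seeded with the
  worst-fitted map.
* Model order: absolute minimum of `CV(K) = σ̂²·((C−1)/(C−1−K))²` over
  K = 2..8. CV ties break toward the smaller K (parsimony). Only the argmin
  is consumed downstream, so any constant rescaling of the criterion is
  irrelevant.
* Back-fitting labels every sample (argmax |spatial correlation|);
  zero-variance samples inherit the previous label. "Rejection" exists only
  as the 23 ms smoothing: the shortest sub-threshold segment is repeatedly
  absorbed into its neighbors, each sample going to the neighboring state
  with the higher template correlation under the constraint that the split
  stays contiguous — this guarantees the run count strictly decreases, so
  termination and the minimum-duration postcondition are structural.
* Across-condition and across-subject matching is an optimal one-to-one
  assignment (Hungarian algorithm) on |Pearson correlation| between maps;
  pairs below 0.65 are reported unmatched. Group clustering alternates
  per-subject optimal assignment with eigenvector template updates, which
  enforces the one-map-per-subject-per-cluster restriction.
* Back-fitting for the dynamics analyses is done on single preprocessed
  trials (not on averaged epochs); the alternative reading exists but
  single-trial fitting is what the occurrence statistics need.

## Synergies

* NNMF minimizes the squared Frobenius error with Lee–Seung multiplicative
  updates (convergence: relative objective change < 1e−6, max 500
  iterations), 50 restarts by default, winner by VAF. The per-iteration
  objective trace is retained so monotonicity is checkable on every run.
  The implementation is in-package because the trace and restart policy are
  part of the contract; sklearn's NMF serves as an independent cross-check
  in the tests only.
* VAF is uncentered (`1 − ‖V−WH‖²_F/‖V‖²_F`), the convention for rectified
  envelopes. Model order = smallest K with VAF > 98%; if unreachable at
  `k_max` the model is returned flagged.
* Weight columns are normalized after convergence (scale absorbed into H);
  matching uses normalized scalar products with threshold 0.65. The
  reference set is built by agglomerative clustering of all subjects'
  weight vectors (Minkowski distance of order 2, average linkage — both
  chosen here, as only "Minkowski" is conventionally specified), cut at the
  harmonized synergy count, references = renormalized cluster means.
* For extraction, equal-length epochs are concatenated per task (pooling
  reading); temporal occurrence is the Pearson correlation between the
  vectorized putative EMG `w_k h_k` and the observed EMG per window,
  averaged over epochs, with zero-variance windows scored 0.

## Occurrence dynamics

The trial grid has 20 preparation windows of 100 ms (−2 s → onset), 10
execution windows of 10% of the movement duration, and 20 holding windows
of 100 ms. Prevalence ties go to the previous window's winner when it is
among the tied states, otherwise to a seeded random draw. Occurrence
histograms are fractions of epochs (columns sum to 1 for one-hot inputs —
the "normalized over time and microstates" reading adopted here is
per-window across states, which these fractions satisfy naturally).

The permutation test exchanges epoch-level occupancies between the two
conditions (epoch-level rather than value-level exchangeability, preserving
within-epoch dependence), statistic = difference of condition means per
state and window, two-sided p at α = 0.05, default 10 000 permutations. No
across-window multiplicity correction is applied in the dynamics contrasts
(correction belongs to the temporal-characterization statistics, which use
Wilcoxon/Bonferroni).

## Time–frequency analysis

Short-time power uses 200 ms Hamming windows stepped by 32 ms, retaining
1–40 Hz; each frequency bin is normalized by its own time average and
expressed in percent change. The ROI is the centro-parietal set {Cz, CPz,
Pz, C1, C3, C2, C4}. The beta band is taken as 13–30 Hz (a definition this
package fixes; only "beta" is conventionally named). Event detection is a
threshold-and-persistence rule invented here with an explicit latency
contract: desynchronization onset is the first pre-onset step whose
beta-band mean stays below −10% for 3 consecutive steps, the rebound
symmetric above +10% after the grasp; planted square events of amplitude
≥ 2× threshold are located within one step (32 ms). Onsets are computed per
subject and averaged.

## Multivariate analyses

* CCA operates on column-centered stacked occurrence matrices; linearly
  dependent columns are dropped by pivoted QR (with a warning and zero
  coefficients) before the decomposition (statsmodels `CanCorr`).
  Coefficient vectors are norm-normalized before any cross-subject
  averaging. For preparation, only the −1 s → 0 interval exists in both
  occurrence definitions (microstate windows start at −2 s, synergy windows
  at −1 s), so the stack uses that overlap.
* Component significance across subjects: Wilcoxon signed-rank of subject
  correlations against matched row-permutation surrogate summaries —
  testing raw canonical correlations against zero would be degenerate
  since they are nonnegative by construction.
* Decoding: per grasp and repetition, train on half of that grasp's epochs
  plus the same count drawn from each other grasp (grasp-stratified),
  test on the held-out half; 4-class LDA with `lsqr` solver and automatic
  shrinkage — 100-dimensional one-hot features on tens of epochs make the
  pooled covariance singular, so regularization is required. The chance
  level is the mean accuracy of the identical protocol with shuffled
  training labels.
* Coefficient stability: |mean|/SD over repetitions, capped (default 100)
  and flagged when the SD is exactly zero; significance against the 95th
  percentile of the same ratio computed on repetition-sized blocks of the
  null coefficient draws.

## Synthetic data: what it emulates, and what it does not

The generator embeds a known truth: average-referenced unit-norm
topographies with bounded pairwise |correlation| (rejection sampling), a
first-order Markov jump chain with geometric dwell truncated at 2 samples
(mean 100 ms — the simplest process consistent with the tens-of-ms
timescale of microstates), nonnegative synergy weights with near-disjoint
dominant muscle blocks, per-task activation templates (one tonic plateau,
one broad onset-locked component, sharp phasic bursts spread over the
movement), grasp-specific preparation-window state-occupancy profiles, and
a multiplicative coupling of synergy amplitude to the prevalent microstate
per 100 ms window. With coupling 0 and identical occupancy profiles the
dataset is exactly null for CCA and decoding.

The topography rides on a zero-mean ~10 Hz oscillatory carrier whose
rectified shape provides the GFP fluctuation. An always-positive envelope
was considered instead, but its large within-run DC component is destroyed
by the 1 Hz high-pass of the preprocessing, which distorts the maps; a
zero-mean carrier passes the 1–40 Hz band untouched while polarity-invariant
clustering absorbs the sign flips. EEG noise is white with amplitude set by
the signal-RMS/noise-RMS ratio (`snr`). Raw experiment EMG is the synergy
envelope modulating a broadband white carrier (an interference-pattern
stand-in) so the conditioning chain meaningfully demodulates it;
`simulate_trial_emg` returns the envelope itself, which is the
factorization-level contract.

Defaults mirror the emulated acquisition: 64 channels at 2048 Hz, 15
muscles at 3 kHz, 8 subjects, 5 tasks (planar reaching + ulnar, pulp,
five-finger, cylindrical grasps) × 15 trials, 2 s preparation and holding,
per-task movement durations of 0.93–1.28 s, resting repertoire restricted
to 4 of the 5 task states. The generator does **not** emulate: volume
conduction from realistic sources, ocular/muscle artifacts in EEG,
1/f-shaped background spectra, spectral beta dynamics (no planted
desynchronization/rebound — the event detector is validated on planted
square events instead), inter-trial duration variability, or
electromechanical delay. Passing tests therefore demonstrate correctness of
the algorithms under these idealized conditions, not robustness to every
property of recorded data.

One consequence worth knowing: on band-pass-filtered synthetic trials the
CV criterion's curve becomes nearly flat beyond the true model order
(state-transition smearing creates mixture maps at some GFP peaks), so the
in-pipeline selected K can exceed the generator truth. The model-order
recovery analyses therefore run on the unfiltered generator output, which
is also how they are stated.

## Problem sizes

Tests and the acceptance script run at reduced scale as this package's own
choice of desk-scale conditions: EEG simulated directly at 128 Hz (60 s for
model-order recovery, majorities over 20 seeds), EMG at 500 Hz (8–15
movement-phase trials), 5 NNMF restarts in the repeated-seed recovery runs
(50 in the single-dataset VAF analysis), 1000 decoder-null repetitions, and
a demo pipeline configuration (1 subject, 256 Hz EEG / 500 Hz EMG) for the
end-to-end run. Full-scale defaults remain in `ExperimentConfig` and
`RunConfig`.

## Known limitations

* The CV criterion's normalization follows the standard published form;
  tool-specific variants differing by a constant factor would not change
  the selected K.
* `select_n_synergies` scans K upward and stops at the first VAF above
  threshold; with non-monotone VAF (possible under few restarts) this is
  conservative.
* The EDF/BDF writer is minimal (single data record, 16/24-bit, events in a
  delimited sidecar rather than embedded annotations); reading goes through
  MNE.
* The orchestrated pipeline extracts one synergy model per task from
  epochs spanning −1 s → grasp + 2 s (preparation, movement and holding
  pooled), so that a single activation matrix covers the whole occurrence
  grid; phase-separate extraction feeding a merged occurrence matrix is
  possible through the library functions but is not what `run_pipeline`
  does.
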
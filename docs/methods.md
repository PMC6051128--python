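# Methods

## Scope and model

`epinetdyn` implements a four-stage analysis of multichannel intracranial
EEG: artifact cleaning and subband decomposition; windowed phase-locking
(PLV) networks; link-prediction similarity indices with a sampled-AUC
benchmark; and node-sequence statistics that track seizure dynamics and
focus involvement. Recording sites are network nodes; by convention the
intrafocus sites carry labels 1–3 and extrafocus sites 4–6, which is what
gives the node index summation its meaning as a focus-dominance score.

## Preprocessing

* **Notch.** The 50 Hz interference filter is an IIR notch (quality factor
  30, so the −3 dB width is ≈ 1.7 Hz) applied forward–backward. Attenuation
  at the line frequency is effectively total in the record interior
  (≈ 70 dB); the residual measured over a whole record is dominated by the
  filter's edge transient and shrinks with record length (≈ 3 % RMS on a
  30 s record). Passband gain ±3 Hz away stays within 1 dB.
* **Wavelet denoising.** Per channel: db4, 4 decomposition levels (fewer on
  short records), soft universal threshold `σ√(2 ln n)` with σ from the
  MAD of the finest detail coefficients. A zero-variance channel is passed
  through unchanged. This is the standard shrinkage default; wavelet and
  level are arguments.
* **Amplitude rejection.** Samples with |x| > 8000 µV are flagged in a per
  channel-sample validity mask rather than deleted, so seizure-marker
  sample indices stay valid. Any PLV window covering an invalid sample on
  any channel is skipped (and logged). Whether rejection should be per
  channel or per time point is genuinely open; the mask is per
  channel-sample, and window invalidation is "any channel".
* **Band filters.** Order-4 Butterworth band-pass per band, applied
  forward–backward (`sosfiltfilt`). Zero phase is mandatory: PLV compares
  phases across channels, and any channel-dependent group delay would
  masquerade as phase locking.
* **Segmentation.** Half-open sample intervals, 0-based internally;
  preictal = 3 min before onset, postictal = 3 min after offset, clipped
  to the record. User-facing node labels are 1-based throughout.

## PLV networks

Instantaneous phase comes from the analytic signal of the band-filtered
trace; PLV over a window of T samples is the modulus of the mean unit
phasor of the phase difference. Windows are non-overlapping and frequency
dependent: `ceil(n_cycles · fs / f_low)` samples with `n_cycles = 6` by
default — about the minimum for a stable estimate; shorter windows inflate
the PLV noise floor, which for independent phases behaves like
`√(π/4T)` only when phases are temporally independent (see below). A
window is labelled by the condition at its midpoint, so windows straddling
onset/offset get one unambiguous label. Binarization uses a strict
`weight > threshold` rule (default 0.3); ties at the threshold are
excluded.

Weighted comparison metrics: node strength; weighted clustering in the
geometric-mean (Onnela) form with weights taken as-is — PLV is already in
[0, 1], so no renormalisation by the observed maximum (a uniform complete
graph of weight w has clustering w); characteristic path length with edge
distance 1/w (strong link = short distance; 1 − w was rejected because
weights of 0 would give finite distances), averaged over connected pairs
with a disconnection flag.

## Link prediction and AUC

The four indices are defined on neighbour sets and degrees, so weighted
networks are binarized (default threshold 0.3, configurable; `None` keeps
every nonzero weight) before scoring. Adamic–Adar uses the natural
logarithm — the worked value 2.8854 = 2/ln 2 fixes the base. A common
neighbour of two distinct nodes on a simple graph necessarily has degree
≥ 2, so 1/ln k(z) is finite; a degree-1 common neighbour would indicate a
corrupted graph and raises.

Edge splits are uniform over the edge list with no connectivity
preservation; train ratios are capped at 95 %. Scores are computed on the
train graph only — probe edges must not leak into the neighbour sets, or
the AUC is meaningless. Each AUC comparison draws one probe edge and one
non-edge (absent from the full graph) with replacement; ties at exact
float equality earn half credit; the default comparison count is
`min(10 000, |probe| · |non-edges|)`. Within a benchmark repetition the
same split is shared across indices so they are compared on identical
information. The repetition harness reports mean and sample SD over 100
fresh splits by default.

## Node sequences, variation, summation

The node sequence is the per-row argmax of the similarity matrix (one
partner per node, self-similarity excluded), ties broken toward the
smallest node label. The per-row form is used because sequences of length
N with repeated entries arise naturally from it; a global-top-k selection
is provided as an alternative (`node_sequence_global_topk`) but is not the
default. Sequences are compared as raw integer vectors in fixed node order
with cosine similarity and Euclidean distance; cosine is scale-invariant
(the all-1s and all-6s sequences compare as identical), a documented
caveat, which is why both measures are reported. Cross-condition
comparison returns the full pairwise distribution between two conditions,
never a scalar aggregate. The default similarity index for sequences is RA
on the full (train-free) window graph.

## The simulator

The EEG generator is a coupled phase-oscillator model, not a waveform
model: per band, each channel carries one oscillation whose intrinsic
phase drifts (channel-specific frequency drawn uniformly inside the band)
and diffuses (Gaussian phase increments sized so the oscillation's
Lorentzian linewidth is ~25 % of the band width); a coupling coefficient
c blends the channel phase toward a shared band driver,
`φ = ψ + (1 − c)(θ − ψ)`, so c = 1 locks channels perfectly and PLV is
monotone in c by construction. During ictal segments the intrafocus
channels use `ictal_coupling` (default 0.9), everywhere else
`base_coupling` (default 0.2); carriers have amplitude 40 µV per band
plus 5 µV white noise, at 256 Hz over six channels. The default segment
plan is 200 s preictal, 60 s ictal, 200 s postictal. Defaults were chosen
once as a plausible operating point: strong but imperfect ictal locking,
a weak common drive outside seizures, and SNR comfortably above the
amplitude-rejection regime.

What it does **not** emulate: ictal waveform morphology (spikes,
spike-wave complexes), amplitude dynamics, volume conduction, electrode
artifacts, or any subtype-specific physiology. Passing tests therefore
demonstrate that the *pipeline* recovers planted phase-synchrony
structure, not that the statistics behave identically on clinical EEG.

One numerical consequence of band-limited phases: the often-quoted
i.i.d.-phase bound PLV ≲ 4/√T does not apply to the simulator's
uncoupled channels, whose phase differences are autocorrelated over tens
of samples; the uncoupled gamma-band PLV floor at 6-cycle windows is
≈ 0.4–0.5. The analytic i.i.d. bound is verified directly on i.i.d.
uniform phases; the simulator tests assert the Monte-Carlo-calibrated
contrast (uncoupled ≪ coupled) instead. Coupling steps at segment
boundaries introduce a phase discontinuity; windows straddling a boundary
are labelled by midpoint and slightly dilute the ictal PLV block
(≈ 0.985 rather than 1.0 at c = 1).

## Statistical checks and problem sizes

The seizure-recovery checks run the full pipeline on 20 simulator seeds
with a 60/30/60 s segment plan (gamma band), comparing per-seed means with
paired t-tests at α = 0.01: two-sided for consecutive Euclidean sequence
variation (ictal vs preictal), one-sided for node index summation
(ictal ≤ preictal). Under the default operating point the effects are
large (summation ≈ 14.5 ictal vs ≈ 18 preictal). The AUC sampling check
compares the sampled estimator against full-enumeration rank AUC (via the
Mann–Whitney U statistic, the independent oracle) within three standard
errors over 100 resamples on 20-node graphs; the index-ranking check uses
five 30-node scale-free graphs with mean degree 4 at train ratio 0.9 and
100 repetitions. Index implementations (adjacency-matrix products) are
checked exactly against a naive set-enumeration oracle on 200 random
graphs of ≤ 12 nodes.

## Reproducibility

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); the benchmark harness derives per-repetition
seeds from a `SeedSequence`. Identical configuration + seed reproduce
recordings, graphs, and every pipeline output byte-for-byte; the pipeline
writes a manifest (config, config hash, seed, package versions) from which
a run can be reconstructed. CSV floats are written with a fixed format for
byte stability.

## Known limitations

* Indices operate on binarized networks by default; an edge-weighted RA
  variant (`Σ_z w_xz w_zy / strength(z)`) is available behind a flag for
  un-thresholded PLV networks but is deliberately not the default — the
  standard index definitions are topological.
* The 0.3 threshold interacts with the PLV noise floor at short (gamma)
  windows; uncoupled channel pairs regularly exceed it, so preictal binary
  graphs are moderately dense. The sequence statistics tolerate this, but
  per-window binary graphs should not be over-interpreted.
* Cosine similarity of sequences is scale-invariant and maps all-constant
  sequences to 1 regardless of label.
* EDF input is not read directly; recordings are CSV matrices with a JSON
  sidecar (fs, labels, focus assignment, seizure markers in seconds).
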
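# Methods

## The model

`spikepatterns` treats the joint activity of `n` simultaneously recorded
neurons as a trajectory through a pattern space whose temporal resolution is
set by a single knob, the integration time constant τ.

1. **Exponential filtering.** Each spike train is convolved with a causal
   exponentially decaying kernel: the activation of neuron *i* at time *t* is

       a_i(t) = Σ_{t_s ≤ t} exp(−(t − t_s)/τ)

   A spike contributes height 1 at its own time; there is no area
   normalization. This *unit-height* convention is a deliberate choice: the
   activation is read as the decaying trace of recent spikes, the way a
   post-synaptic current would see them, and changing τ then only changes
   how long a spike is remembered, not how big it is. Small τ (1–5 ms)
   makes activity vectors sensitive to near-coincident spiking; large τ
   (>100 ms) turns them into smoothed rate estimates. The filter is
   evaluated recursively (`a[k] = a[k−1]·e^{−dt/τ}` plus the interval's
   spikes with their exact sub-bin decay), which is algebraically identical
   to direct summation over all past spikes and costs O(samples + spikes)
   per trial. Traces are sampled every `dt = 1` ms (1 kHz), giving one
   n-dimensional *activity vector* per millisecond.

2. **Vector quantization on a 3D lattice.** Activity vectors are clustered
   by an N×N×N Kohonen map (N = 10 by default, i.e. 1,000 model vectors).
   At training step k of M, a random training vector is learned by moving
   its best-matching unit (BMU) and the BMU's lattice neighborhood toward
   it:

   * learning rate `L(k) = L0·(LM/L0)^{k/M}` with L0 = 1, LM = 0.01 —
     geometric interpolation, chosen so L decays smoothly and monotonically
     through the full [L0, LM] range;
   * radius `R(k) = round(R0·max(0, 1 − k/(g·M/100)))` with R0 = N/2 and
     g = 66 — linear decay hitting zero after 66 % of the steps, so the
     first two thirds of training establish the map topology and the rest
     fine-tunes individual model vectors (only the BMU moves once R = 0);
   * within Chebyshev lattice distance R, updates are weighted by a 3D
     Gaussian envelope of SD R(k)/3 (squared Euclidean lattice distance)
     centred on the BMU, with weight 1 at the BMU itself.

   The exact analytic forms of the learning-rate and radius schedules are
   design choices of this package; they satisfy the standard verbal
   constraints (monotone decrease between the stated endpoints) and are the
   conventional forms for SOM training. Rounding is half-away-from-zero so
   R(0) = N/2 rounds predictably. The map is initialized uniformly at
   random inside the per-dimension min–max box of the training data, all
   randomness derived from one seed; training runs a fixed M steps
   (default 20× the number of training vectors, capped at 30,000) with no
   early stopping. When a dataset yields more than 200,000 activity
   vectors, training draws from a seeded uniform subsample; assignment
   always uses every sample. A flat K-Means backend (scikit-learn) is
   provided as an alternative quantizer; it lacks the lattice ordering and
   therefore the color mapping.

3. **Model trials.** Every activity vector is replaced by the id of its
   BMU (ties to the lowest linear index), turning each trial into a 1 kHz
   sequence of pattern ids. Painting each pattern with the RGB color of its
   lattice position, `(x, y, z)/(N−1)`, makes repeatable patterns visible
   as repeated colored stripes across trials.

## Specificity and stimulus locking

The specificity of pattern p for stimulus j is
`SP_p(j) = r_p(j) / Σ_c r_p(c)`, where occurrences are counted **per
sample** of the model trials — a pattern persisting for 10 ms counts ten
times. The per-sample convention is forced by consistency with the
specificity classifier, whose trial score weights specificities by
per-sample occurrence counts. Rows sum to 1 exactly; never-observed
patterns get no row rather than a 0/0. Chance level with s equiprobable
stimuli is 1/s. Thresholding model trials at SP > θ isolates the most
informative patterns; lowering θ only ever reveals more. Stimulus locking
is summarised by the min–max range of a pattern's first-occurrence times
across trials, and the pattern-triggered spike-raster histogram (PTSRH)
sums binarized 1 ms rasters over the 30 ms preceding each occurrence to
show which neurons' spikes build the pattern.

## Decoders

All three classifiers are evaluated by repeated random half-splits of each
stimulus's trials (odd counts put the extra trial in training), with ties
always resolved to the lowest stimulus index:

* **mean rate** — model rate vectors `MR_j(i) = r_j(i)/(TD·T_j/2)` (Hz)
  from training trials; nearest-Euclidean assignment of test-trial rate
  vectors. Uses spike counts only.
* **specificity** — `SCORE_l(j) = Σ_p r_l(p)·SP_p(j)` with SP fitted on
  training trials; argmax over j. The weighted sum (rather than a Bayesian
  product) keeps patterns absent in one condition from zeroing the score.
  Uses pattern identity, ignores position.
* **trajectory** — trials segmented into non-overlapping windows of τ bins
  (trailing partial window dropped); each window averaged into a mean model
  vector; per-stimulus model trajectories are window-wise means over
  training trials; assignment minimizes the summed window-wise Euclidean
  distance. Uses pattern identity *and* stimulus-locked position.

The map is trained once per dataset-condition (per τ, and per control
manipulation) and reused across splits; retraining per split would multiply
cost 100–1,000× while the map depends only weakly on which half of trials
is used, since both halves sample the same response distribution.

## Time-resolved effect size

To localise information in time, the trajectory window is slid with a step
of at most 5 ms. For the test trials of stimulus ts, `d_T(t)` is the mean
distance at the window centred on t to ts's model trajectory and `d_O(t)`
the mean (over trials and the other s−1 stimuli) distance to the other
models; SDs are taken over test trials, for d_O of the per-trial means
across other stimuli. These are combined as a Cohen's d,

    d(t) = (d_O(t) − d_T(t)) / sqrt((sd_T² + sd_O²)/2),

the standard pooled-SD form. Positive d(t) means trials are reliably closer
to their own stimulus's model at time t — the moments that carry the
discriminative information. Where both SDs vanish with equal means, d is
defined as 0.

## Surrogate controls

* **Jitter** — every spike displaced by an independent Gaussian draw
  (SD 0–100 ms); spikes leaving [0, TD) are *reflected* back inside, which
  preserves counts and local density (clipping to the boundary would pile
  spikes at the edges). Jitter destroys structure on timescales below its
  SD. Effects are assessed with one-sample location Z-tests across
  independent jitter realisations, each realisation's performance averaged
  over half-splits with the map rebuilt.
* **Window shuffle** — each trial cut into 20 ms windows, permuted
  independently per trial (one RNG stream per trial); spikes move rigidly
  with their window; a trailing partial window stays in place. Spike counts
  are invariant, so the mean-rate classifier is provably unaffected; the
  specificity classifier is unaffected up to window-boundary effects on the
  exponential tails; the trajectory classifier loses exactly what it is
  built to use.
* **Burst removal** — per train, maximal runs with consecutive ISIs below
  8 ms (computed on the original train, not iteratively) are collapsed to
  their first spike. Idempotent by construction.

## The synthetic generators

Real multielectrode recordings of this kind are not publicly deposited, so
the package ships generators that emulate the three stimulus regimes the
analysis is built for; they are first-class, tested code and define the
conditions under which all end-to-end claims are verified.

Spikes are drawn by thinning a bounded-rate inhomogeneous Poisson process
(rate profiles at 1 ms resolution). Burstiness is added by replacing each
spike, with probability `burst_prob` (default 0.1), by a doublet or triplet
at 3–6 ms intra-burst intervals. All randomness flows from one master seed
through named `SeedSequence` substreams (unit properties, per-trial
processes), so datasets are bit-reproducible.

* **Grating-like** (slow): 4,800 ms trials — 1,000 ms spontaneous,
  3,500 ms stimulus, 300 ms OFF — 12 direction conditions, 20 trials each.
  During the stimulus epoch unit i fires at
  `baseline + gain_i(j)·(1 + sin(2πf t + φ_i))` with f ≈ 0.83 Hz (2°/s
  drift over 2.4°/cycle) and a von-Mises direction-tuning gain (κ = 2,
  peak 15 Hz over a 3 Hz baseline — mid-range values for visual cortex
  single units).
* **Flash-sequence-like** (fast): 1,200 ms trials, three 100 ms flashes at
  500/700/900 ms. Each distinct item drives its own unit subset with a
  transient onset bump (per-unit latency fixed in 30–40 ms, Gaussian width
  5 ms, peak 150 Hz) and a sustained offset response (latency 70 ms, 30 Hz
  for 80 ms), over a 2 Hz background. A per-trial latency jitter
  (`locking_jitter_sd`, default 3 ms) controls stimulus locking.
* **Movie-like** (mixed): labelled slow epochs (0.3–1 Hz sinusoidal
  modulation) and fast epochs (trains of 5 ms-wide transient bumps at
  per-stimulus fixed times), optionally sharing the slow profile across
  stimuli so that only fast epochs discriminate.

`inject_pattern` adds a synchronized multi-unit volley at a known time with
known per-trial latency spread into chosen trials, providing ground truth
for recovery tests.

What the generators do **not** emulate: refractoriness and spike-count
Fano factors below 1, common slow state fluctuations (up/down states),
cross-neuron noise correlations beyond the shared rate profiles, and any
image-computable stimulus transform — response profiles are purely
phenomenological. Passing end-to-end tests therefore shows that the
*analysis chain* behaves as designed under the intended response
statistics, not that real cortical data would yield any particular
performance level.

## Problem sizes and numerical choices

End-to-end checks run at desk scale, chosen to finish in minutes on one
core while keeping the qualitative structure of interest: 8–12 units, 3–4
stimuli, 15–50 trials, maps of 10³ model vectors trained for 8,000 steps,
50–100 half-splits (the full protocol uses 1,000; the harness exposes
`n_splits`). Chance-level checks use the 99 % normal-approximation binomial
interval of 1/s with n equal to the dataset's trial count — conservative
for a mean over many splits. Distances are plain float64 Euclidean; BMU
assignment over large sample sets uses the expanded-square form in memory-
bounded chunks, which agrees with the direct computation to ~1e−12
relative. Degenerate inputs are handled explicitly: empty spike trains
produce all-zero activations; silent datasets map to a single pattern;
patterns never observed carry no specificity; zero-SD jitter and
identity-permutation shuffles are bit-exact no-ops.

## Known limitations

* The SOM has no convergence diagnostic; M is fixed and quality is checked
  by quantization error and topology tests rather than a stopping rule.
* Per-sample occurrence counting makes specificity tables depend on τ
  through pattern dwell times; comparisons across τ should compare
  structure, not raw counts.
* The specificity-under-shuffle invariance is exact only in expectation;
  exponential tails crossing shuffled window boundaries perturb patterns
  near the cuts.
* `one_sample_z` is a plain normal-theory location test; with few
  independent jitters (<10) its p-values are approximate.
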
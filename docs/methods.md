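# Methods

`caltask` re-implements, as a tested pipeline, the analysis chain for
trial-structured two-photon calcium imaging of a memory-guided go/no-go
visual task: a 2 s drifting-grating stimulus (target or non-target), a
randomly interleaved 0/3/6 s delay, and a 1.5 s response window in which a
lick spout becomes available.  Every stage can be exercised against a
synthetic-data generator with known ground truth, so the package's claims
are the claims its tests compute.

## Task and time conventions

All trial-aligned arrays use a 5 Hz grid with t = 0 at stimulus onset, a
1 s baseline window [−1, 0), and a shared time axis spanning the longest
trial plus a 2.5 s post-trial tail (65 samples for the 0/3/6 s delay set,
60 of them post-onset).  Epoch boundaries (stimulus off at 2 s, spout in
at 2 s + delay, spout out 1.5 s later) are carried per trial in the trial
table, so trials of different delay share one tensor.  Outcomes follow the
go/no-go contingency table: hit/miss on target trials, FA/CR on
non-target trials.

## Synthetic data

Six response archetypes — `StimOnly`, `StimResp`, `Delay`, `RespOnly`
(enhanced) and `SuppDelayEarly`, `SuppDelayLate` (suppressed) — are
modeled as epoch-locked boxcar drives convolved with a causal exponential
whose half-decay time (default 1.2 s, constrained > 1 s) emulates the
slow GCaMP6s indicator.  Kernels are normalized to unit peak magnitude;
suppressed kernels are nonpositive, and the sustained archetypes'
above-half-peak duration grows with the delay, as delay-modulated neurons'
activity should.  Per neuron, an archetype is drawn from a configurable
mixture (`REGION_MIXTURES` provides V1/PPC/fMC presets that emulate the
qualitative regional gradient — stimulus-locked classes dominating the
visual end, delay/response classes the frontal end; the numeric
proportions are package defaults, not measured values), along with

- a peak ΔF/F amplitude, lognormal with median 0.5 (typical of strong
  somatic transients),
- a selectivity ratio r = R_nonpref/R_pref ~ Beta(1.2, 2.4) (leaning
  selective), and
- a preferred trial class (target/non-target by default;
  `selectivity_on="choice"` switches preference to lick/no-lick for
  constructing choice-coding populations).

Noise is additive i.i.d. Gaussian on ΔF/F (default σ = 0.1); an
"uncorrected" tensor with an independent noise draw but identical
expectation is attached as `raw_dff`, standing in for the pre-neuropil-
correction trace.  A single seed expands into per-neuron substreams, so
enlarging a population never perturbs existing neurons.  What the
generator does **not** emulate: temporally autocorrelated noise, shared
(neuropil-like) noise between the raw and corrected tensors, spiking
nonlinearities, or slow drift — so tests passing here demonstrate
correctness of the analysis machinery, not robustness to every real-data
pathology.

Movies render non-overlapping disk somata (intensity
`baseline + gain·(1+ΔF/F)`) with optional global integer-pixel drift and
Gaussian or Poisson noise; masks and applied shifts are returned as ground
truth.  Behavior-camera frame sets (300 × 200 px) consist of a static
scene plus optional injected movement blobs in a chosen condition/epoch,
with per-frame flags recorded.

## Behavior

Sensitivity is d' = Φ⁻¹(R_HIT) − Φ⁻¹(R_FA); rates of exactly 0 or 1 are
clipped to 1/(2N) and 1 − 1/(2N) (the log-linear correction — the
standard remedy for infinite z-scores) before inversion.  Session QC
requires d' > 1 **and** R_HIT − R_FA > 30%, both strict, evaluated on
laser-OFF trials when laser trials exist.  Per-delay d' is computed per
session from that session's per-delay contingency table; cross-session
aggregation averages per-session values rather than pooling trials.
Photoinhibition comparisons pair each session's laser-OFF and laser-ON
trials (restricted to delays that carry laser trials), apply a two-sided
paired t-test to d' and to the hit/FA rates, and Bonferroni-correct over
the family of epochs tested (default 3: stimulus, delay, response).

## Imaging front end

- **Registration**: each frame is aligned to the pixel-wise mean of all
  frames by 2-D cross-correlation at integer-pixel resolution (single
  pass); exposed pixels are filled with the frame median.  Because the
  reference is the mean image, recovered shifts are exact up to one
  global offset equal to the rounded mean drift; on zero-mean drift
  patterns recovery is exact.
- **Activity map**: per-pixel score = rectified temporal skewness × mean
  temporal correlation with the 8-neighborhood, rescaled to [0, 1].
  Transient calcium signals are positively skewed and spatially coherent
  over a soma; shot noise is neither.  The statistic is deliberately
  simple and swappable.
- **Segmentation**: local adaptive threshold (plus a small absolute floor
  so pure-noise maps yield nothing), connected components filtered to a
  soma-area range (default 30–250 µm²), oversized components iteratively
  re-thresholded until they split.
- **Traces**: F_raw = mean over the ROI mask; F_neuropil = mean over the
  annulus 0–15 µm from the ROI border (Euclidean distance transform,
  all ROI pixels excluded; widened with a warning if empty).
  F_corrected(t) = F_raw(t) − 0.7·F_neuropil(t), coefficient
  configurable.
- **ΔF/F**: (F − F0)/F0 with F0 the mode of the fluorescence density —
  midpoint of the tallest Freedman–Diaconis histogram bin by default, a
  Gaussian-KDE argmax behind a flag.  The mode is used because baseline
  occupancy dominates the density while transients skew the mean.
- **Duplicate removal**: ROI pairs with Pearson r > 0.5 and XY centroid
  distance < 12.5 µm (any plane pair) are redundant; the dimmer member
  (more likely out of the focal plane) is dropped iteratively; equal
  means keep the lower index, making the result order-independent.

## Response significance

For each neuron, each post-onset sample, each delay and each correct
trial type (hit, CR), the per-trial sample value is compared to that
trial's baseline mean with a two-sided Wilcoxon signed-rank test at
p < 0.05 (vectorized exact null for n ≤ 50 trials, normal approximation
with continuity correction beyond; slices with ties or zeros fall back to
`scipy.stats.wilcoxon`).  A neuron is responsive when ≥ 10 samples are
significant in the same direction within a delay trace, for ≥ 2 of the 3
delays, for either trial type — **and** the same qualifying pattern
(some trial type and direction with ≥ 2 qualifying delays) holds on both
the corrected and the uncorrected tensor.  Slow-indicator transients span
many samples; licking artifacts and chance fluctuations do not.

`criterion_chance_level` computes the analytic false-positive bound under
per-sample independence: a trace qualifies in a given direction with
probability P[Binom(60, 0.025) ≥ 10] ≈ 4·10⁻⁶, and the union bound over
C(3,2) delay pairs, two directions and two trial types gives ≈ 6·10⁻¹¹,
below the 10⁻⁹ design target.  **Caveat**: per-sample independence is an
idealization.  All samples of a trace share the per-trial baseline-mean
estimate (only 5 baseline samples per trial), which equicorrelates the
per-sample tests at ρ ≈ 1/6 regardless of trial count, inflating the
realized single-tensor rate to ~10⁻⁴ — this is inherent to testing many
samples against one estimated baseline, and no pairing variant avoids it.
The dual-tensor requirement restores a very low realized rate (the two
tensors carry independent noise in the generator): a 10,000-neuron null
simulation yields zero positives (expected count ≈ 2·10⁻³).  On real
data, raw and corrected traces share noise, so the dual requirement
guards against neuropil artifacts more than chance; there the run-length
structure of genuine indicator decay is the operative defense.

## Normalization, clustering, indices

Responses are baseline-subtracted per trial and divided by the maximum
(enhanced) or |minimum| (suppressed) of the neuron's trial-averaged trace
so the average peak has magnitude 1.  Clustering features are the
normalized preferred-type trial-averaged trace at the longest delay
(an option concatenates all delays); features are projected onto the
first 20 principal components, clustered by Ward linkage (Euclidean),
cut at K clusters, and every neuron is re-assigned to the cluster whose
mean trace correlates best with its own response, iterating assignment
and mean updates to convergence (≤ 10 rounds).  `choose_k` grows K until
the (K+1)-cut produces two cluster means correlating above r = 0.9 —
the point where further splits duplicate response types; on the
six-archetype benchmark it returns 6 and label agreement with ground
truth is ≥ 0.9 (measured 1.0 at noise σ = 0.05).

- **SI** = (R_pref − R_non-pref)/(R_pref + R_non-pref), with R the
  time-integrated, baseline-subtracted, sign-adjusted and rectified
  response from stimulus onset through spout retraction, averaged over
  correct trials; ties in preference break toward hit.
- **OSI** = (R_pref − R_orth)/(R_pref + R_orth) with the preferred
  orientation the argmax and orthogonal 90° away.
- **Latency**: the trial-averaged trace is linearly interpolated to
  1 kHz; latency is the first sample of the earliest run of ≥ 1000
  consecutive samples beyond baseline mean ± 1σ (i.e., a sustained 1 s
  excursion).  Population onset is summarized by the *first mode* of a
  Silverman-bandwidth Gaussian KDE (smallest-latency local maximum above
  10% of the global peak), because latency distributions are
  right-skewed in higher-order regions.
- **Delay modulation**: integrated trial-averaged ΔF/F from stimulus
  onset to spout extension is fit linearly against delay duration;
  DMI = (n_pos − n_neg)/(n_pos + n_neg), sign-flipped for suppressed
  populations; zero-slope neurons (|slope| ≤ 10⁻¹²) enter neither count.

## Population decoding and state space

Stimulus identity is decoded by comparing error trials to correct trials
with a different stimulus but the same response (miss vs CR, FA vs hit),
so separations cannot reflect movement; choice uses same-stimulus,
different-response pairs (hit vs miss, FA vs CR); both available pair
directions are averaged.  Per time point, each correct trial is scored by
Euclidean distance to its leave-one-out class template and each error
trial by distance to the all-trials template; the tie-aware rank
statistic over the two distance samples equals Mann–Whitney U/(n₁n₂) and
is the ideal observer's auROC, reported folded as max(a, 1−a).  Curves
are averaged over random neuron subsets (defaults mirror population
sizes 1/5/10/50/100 and 1000 iterations; tests and the pipeline default
scale these down), the null is the central 95% interval of
label-shuffled permutations, and epochs are significant only when ≥ 3
consecutive time points exceed the upper bound.  Experiments require ≥ 3
error trials of each type.

Targeted dimensionality reduction regresses each neuron's single-trial
response on coded stimulus (+1/−1) and choice (+1/−1) per time point,
takes each variable's coefficient vector at its peak-norm time point,
projects both into the 10-PC subspace of condition-averaged responses
(de-noising), and Gram–Schmidt-orthogonalizes (stimulus first, order
configurable) to unit axes.  Condition-averaged trajectories and the
hit−CR separations ΔS(t), ΔC(t) are projected per time point; the
permutation band shuffles hit/CR labels with axes held fixed (refitting
axes per permutation would multiply cost ~1000× and changes little at
these scales).  Note one structural effect: in a population that encodes
only the stimulus, the fitted choice axis is pure estimation noise, and
its residual overlap with the true coding direction leaks a small
fraction (~10%) of the stimulus separation onto the choice axis — the
dissociation criterion is therefore an order-of-magnitude contrast, not
exact nullity.

## Movement maps

Per epoch (Pre, Delay, Response), D_CR(x,y) = mean_f |CR_f − mean(CR_{F≠f})|
measures baseline movement against leave-one-out CR templates, D_Hit uses
the same templates for Hit frames (pairing by enumeration order; surplus
Hit frames draw a random seeded CR exclusion), and D_Sub = |D_Hit − D_CR|
isolates Hit-specific movement or postural change.  No intensity
normalization is applied by default (an optional per-frame mean
normalization exists).  Across ≥ 3 sessions, mean D_Sub is compared
between epoch pairs with paired t-tests; fewer sessions yield descriptive
output only.

## Problem sizes and numerics

Default benchmark sizes — 600 neurons / 180 trials for clustering
recovery, 10,000 neurons for the null simulation, 80–150 neurons and
200–240 trials for decoding and axis recovery — are chosen so each
measurement is statistically decisive while a full run of the test suite
and the acceptance script completes in a couple of minutes on one CPU.
Degenerate inputs are handled explicitly: constant movies register with
zero shifts and a warning, empty activity maps segment to empty ROI sets,
zero normalizers drop neurons with a warning, all-zero signed-rank slices
return p = 1, and zero-count d' rates are clipped rather than infinite.
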
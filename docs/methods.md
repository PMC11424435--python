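# Methods

This note documents the models and procedures implemented in `measeg`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions adopted where the method leaves
room for interpretation.

## Data model

Spike times are seconds, stored as float64; electrode positions are
micrometres in an arbitrary planar frame (only pairwise distances are
consumed). Distances are converted to millimetres exactly where a formula
demands it: the clustering coefficient and the propagation-speed filter.
The default layout (`grid_layout`) models a 120-electrode array (12×12 grid
at 200 µm pitch minus six sites per corner) with four quadrant compartments
of 15 electrodes each; the 60 electrodes under or near the cross-shaped
mask arms are `unassigned` and excluded from all per-compartment
quantities. Homogeneous control cultures use the same machinery with
"virtual" quadrant labels covering every electrode.

## Spike detection

A spike is a pair of opposite-polarity local extrema within the peak
lifetime period (2 ms) whose peak-to-peak amplitude exceeds
`threshold_multiplier` (8) × the channel noise SD; the timestamp is the
larger-magnitude extremum, and accepted spikes enforce a 1 ms refractory
period. Conventions the contract leaves open:

* **Noise SD estimator**: median absolute deviation / 0.6745 over the full
  trace — robust to sparse spikes riding on the noise; a constant trace
  yields SD 0 (warning), and a zero threshold on a structured trace is a
  hard error.
* **Overlap resolution**: candidate pairs are accepted greedily by
  decreasing amplitude, ties broken by earlier time — deterministic and
  order-independent.
* Detection is scale-equivariant (scaling trace and noise SD together
  leaves detections unchanged) and monotone in the threshold multiplier;
  both properties are asserted in the test suite.

The stage is optional: every downstream analysis starts from spike times.

## Bursts and firing statistics

String-method bursts: maximal runs of ≥ 5 spikes with inter-spike intervals
≤ 100 ms. The ISI bound is inclusive, with 1 ns of slack to absorb float64
representation error at the exact boundary. Statistics per electrode: MFR =
spikes/duration; MBR = bursts × 60/duration; MFIB = mean over bursts of
(spikes / burst duration); RS = 100 × spikes outside bursts / total spikes
(undefined without spikes). An electrode is active when MFR is strictly
above 0.1 spikes/s. Compartment values are unweighted means over that
compartment's **active** electrodes (configurable via
`include_inactive_in_means`; whether inactive electrodes belong in the means
is not dictated by the method, exclusion is the default here).

## Network bursts

The statistic S(k) = (electrodes firing in bin k) × (spikes in bin k) on
half-open 25 ms bins. Candidate events are maximal runs of bins with
S(k) strictly above 5% of the recording's maximum ("higher than" read as
strict); runs separated by less than 80 ms are **merged** (the interval is
a separation constraint, not a veto), and merging is idempotent. Event
windows are refined from bin edges to the first/last spike inside the
supra-threshold span, so NBD is not quantized to 25 ms. Within the refined
window: involved electrodes are those with ≥ 1 spike; a compartment is
involved when ≥ 3 of its electrodes are (20% of ~15); the leader is the
electrode with the earliest first spike, ties broken by id.

Two conventions deserve note:

* **Leader pool**: by default the leader is sought among electrodes of
  *involved* compartments (`leader_within_involved=True`), so an isolated
  stray spike cannot attribute initiation to an otherwise silent
  compartment; the flag restores the unrestricted rule. On synthetic data
  the restricted rule identifies the planted leader compartment in ~93–95%
  of events; the residual errors are background spikes that land inside the
  event window, in another involved compartment, before the leader's own
  first burst spike — an irreducible hazard of the earliest-spike
  definition at non-zero background rates.
* **Window start**: the supra-threshold crossing can lag the true onset by
  up to one bin, truncating the earliest spikes. Extending the window
  leftwards (one bin, or across non-empty bins) was evaluated and
  *rejected*: the extra background time it admits costs more leader
  accuracy than the truncation it cures (measured 79%/63% vs 93%).

## Functional connectivity

The estimator binarizes trains at 1 ms, counts coincidences per lag
(1..25 ms) for every ordered pair of active electrodes, normalizes by
√(NᵢNⱼ), and applies a family of running-window contrast (edge) filters —
centre windows of length a ∈ {3..8} bins flanked, after a crossover gap
b ∈ {2..6}, by negative surround windows of length a. All filter responses
are averaged; the edge weight is the extremal filtered value (sign =
excitatory/inhibitory) and the delay its lag. Centre and surround windows
are clipped to causal lags (≥ 1 bin) with renormalization: the anticausal
half of the correlogram belongs to the reverse edge, and letting it into a
surround window turns every strong forward connection into a spurious
"inhibitory" reverse edge.

Post-processing order: speed filter → hard threshold → strong connections.

* **Speed filter**: keep edges with d/τ in [30, 300] mm/s (d in mm, τ in
  s); zero-delay edges are removed and counted.
* **Hard threshold**: μ and σ are the mean and sample SD (n−1) of the
  non-zero weights; positive entries survive strictly above μ + σ,
  negative entries strictly below μ − σ. Note a method-inherent
  consequence: when μ > σ (densely coupled recordings) the negative bound
  sits above zero and *every* negative entry survives. This polluting
  behaviour is kept because it is the only reading under which the strong
  pass is non-idempotent (any threshold rule reapplied to its own output
  with the same parameters changes nothing unless the second pass uses a
  different rule — here |w| > μ + σ).
* **Strong connections**: thresholded entries with |w| > μ + σ, same μ, σ.

Graph metrics: node degree counts non-zero in- plus out-edges. The
clustering coefficient CC_i = Σⱼ 1/d²ᵢⱼ / (kᵢ(kᵢ−1)/2) sums over the
*unique undirected* neighbours of i with kᵢ that neighbour count —
deliberately different from the in+out degree convention, which would
double-count reciprocal pairs. As printed, the formula contains no
triangle term (it measures the density-weighted proximity of a node's
neighbourhood, not closed-triplet frequency); it is implemented literally
rather than "corrected", and nodes with fewer than two neighbours get 0.
Connection-length histograms use shared 0.1 mm bins spanning the layout
diameter, each normalized to sum 1; the Bhattacharyya distance uses the
natural logarithm and returns +inf for disjoint supports.

## Synthetic cultures

The generator produces what the analysis assumes to exist, with labels:

* background firing: homogeneous Poisson, 0.5 spikes/s per assigned
  electrode (mask-covered electrodes are silent — no cells grow under the
  mask; `masked_background_rate` overrides);
* electrode bursts: 5–10 spikes, gamma(2) ISIs with 10 ms mean;
* network events at 10/min (or an exact count), ≥ 1.5 s apart: a leader
  compartment drawn from `leader_weights`, each other compartment recruited
  independently with probability `p_couple`; recruited compartments fire on
  a random 80% of their electrodes, each starting at event time +
  compartment delay + N(0, 5 ms) jitter;
* compartment delays = centroid distance / conduction speed, one speed per
  recording drawn from U(50, 100) mm/s. The range lies inside the
  physiological 30–300 mm/s band and was chosen so the smallest
  compartment delay (~12 ms) exceeds ≈ 3 SD of the minimum onset jitter
  across a recruited compartment's electrodes — planted leaders are
  unambiguous by construction, which the leader-recovery checks presuppose;
* optional lag-coupled electrode pairs: a source electrode firing Poisson
  at 2 spikes/s whose target echoes each spike with probability 0.8 at a
  5 ms lag + N(0, 0.5 ms); pair distances are drawn inside (or, on request,
  outside) the speed band implied by the lag.

What it does **not** emulate: per-pair structural (synaptic) connectivity,
inhibition, distance-dependent propagation *within* a compartment,
electrode-level rate heterogeneity, development over days, or non-Poisson
background statistics. Consequently, passing tests demonstrate that the
pipeline recovers the generator's event/coupling/lag structure — not that
it would reproduce every group-level contrast seen in real cultures.

Two measured consequences of those simplifications are worth recording
(both analysed at length in the test suite's acceptance module, where the
corresponding assertions fail honestly):

* With the relative μ ± σ threshold, the fraction of independent-Poisson
  pairs surviving thresholding is a shape constant of the null weight
  distribution (~20–25% here), not a quantity that can be driven to < 1%:
  the rule is scale-free, so it always keeps a distribution tail. Near-total
  rejection of null pairs happens only when genuine outlier edges inflate
  σ — which is exactly what planted coupled pairs do (their recovery is
  measured at precision = recall = 1.0).
* Mean clustering coefficient is not monotone across coupling levels
  p ∈ {0, 0.5, 1}: compartment-wide lockstep recruitment raises *all*
  pairwise weights together, so the relative threshold keeps a roughly
  constant-fraction tail and thresholded degree does not grow with
  integration; since CC scales like 1/(kᵢ−1), it follows the threshold
  artifacts rather than the intended segregation ordering. The
  inter-compartment share of strong connections, by contrast, is robustly
  monotone in p (≈ 0.4% → 24% → 53%).

## Problem sizes and determinism

All simulations are seeded (`numpy.random.default_rng`); identical config
and seed give bit-identical recordings, and the pipeline itself is
deterministic. The validation suite uses 2–10-minute recordings on the
120-electrode layout — large enough that the binomial error on recovery
rates is a few percent (e.g. 300 planted events pool the leader-recovery
estimate to ±1.4%) while the whole suite runs in well under a minute.
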
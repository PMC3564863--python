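# Methods

## The model

An event is a sequence E = (x₁, …, x_T) of normalized currents I/I₀
sampled every Δt = 2.99 ms (one datapoint per 299-sample median block at
100 kHz).  In-pore dynamics are modeled as a K-state discrete-time hidden
Markov chain with Gaussian emissions:

* π — probability that an event *begins* in each state,
* A — K×K per-step transition matrix,
* q, b — per-state emission mean and SD in I/I₀ units.

K = 3 (low, mid, high) is the working model for both protein classes, by
parsimony: the all-point blockade histograms concentrate into three
regimes.  States are kept sorted ascending by q; every trained model is
re-canonicalized under this order so that state indices are comparable
across fits.

Likelihood uses the textbook scaled forward recursion (per-step normalized
forward variables with the log scale accumulated separately), stable for
events up to ~10⁵ datapoints; a per-step row-max offset keeps the
linear-domain emission terms in range.  Viterbi decoding is done in log
space with ties broken toward the lowest state index at every backtrack
step, so decoded paths are platform-deterministic.

Baum–Welch treats each event as an independent sequence: π is re-estimated
from the per-event posteriors at t = 0 (events are never concatenated —
π is specifically the entry distribution of an event, and concatenation
would corrupt it with mid-trace statistics).  Parameter blocks (π, A, q, b)
can be frozen independently; frozen blocks are returned bit-identical to
the input.  Convergence: relative change in total log-likelihood < 1e-6,
cap 100 iterations (empirically fits of this kind converge in a few tens
of iterations).  Numerical guards: an emission-SD floor b ≥ 1e-4 I/I₀
prevents variance collapse on 1–2 point events, and a state whose expected
occupancy falls below 1e-12 keeps its q, b for that iteration (with a
recorded warning) rather than dividing by ~0.

The initial model is built the way practitioners read it off the event
histogram: q and b from a K-cluster one-dimensional partition (k-means on
the pooled points) ordered by mean, with uniform π and uniform A —
"assume ignorance of the probabilities".

## Protein calling

Given trained class models λ_wt and λ_mut, an event is called by whichever
of log P(E|λ_wt), log P(E|λ_mut) is larger.  Raw (not length-normalized)
log-likelihoods are compared; a per-point-normalized mode exists behind a
flag for sensitivity analysis only.  Exact ties — measure zero on
continuous data — go to wild-type for determinism.  Evaluation follows a
blind-mix protocol: n events per class are sampled without replacement
into a shuffled mix, the remainders train the two models (K = 3, histogram
init, full updates), and accuracy is summarized as per-class predictive
values P(truly X | called X).  A class with zero calls reports an
undefined flag, never 0.  Case 2 applies a ≥1 s lifetime filter to both
pools before the split; longer events carry proportionally more data, so
predictive values improve.

## Kinetics

Each event is idealized by its Viterbi path under a voltage-specific
model: Baum–Welch restarted from the pooled model with q and b frozen, so
only π and A adapt to the voltage.  Paths are run-length encoded into
dwell segments annotated with entry state (None for an event's first
dwell) and exit state (escape sentinel for the last).  Rates are estimated
as k_{i→j} = N_{i→j}/T_i, exit counts over occupancy time — the
maximum-likelihood estimator for a discretely observed Markov jump process
at small per-step probabilities (k ≈ a_ij/Δt).  Escape is right-censoring:
the final dwell contributes occupancy time but no transition count.
Bootstrap errors resample whole events, not segments, because segments
within an event are strongly dependent.

The entry-conditioned analysis partitions mid-state dwells by the
preceding state.  Under a memoryless 3-state model the exit rates of the
two partitions coincide (checked as a negative control); a genuine hidden
split — two mid states with identical emissions but different exit
kinetics — produces conditioned rate ratios far from 1.  When both
partitions are populated, the four-state model {H, M_H, M_L, L} is built
by routing all H→M mass to M_H and all L→M mass to M_L, estimating each
split state's per-step exit probabilities from its partition (exits over
mid datapoints, remainder self-loop), copying the mid emissions to both,
and renormalizing rows.  The routing topology is an explicit, overridable
convention; variants (e.g. forbidding M_H→L) can be imposed by editing the
returned matrix.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* Open-pore baseline: I₀ linear in voltage (0.28 pA/mV, ≈28 pA at
  +100 mV) with 1.0 pA RMS Gaussian noise.
* Capture: exponential waiting times at R(V) = R₀·exp(V/V_R), defaults
  R₀ = 0.0135 s⁻¹, V_R = 40 mV (≈2 captures/s at +200 mV) — a desk-scale
  stand-in for a "several thousand events per voltage" experiment.
* Events: the hidden chain steps once per decimation block and the block's
  emission value v ~ N(q_s, b_s) is shared by all 299 raw samples (plus
  0.5 pA within-block jitter), so the block median reproduces v and
  decimation is information-preserving — EM can recover the generating
  parameters exactly in expectation, isolating estimator correctness from
  filter distortion.  A `per_sample_states` flag switches to per-raw-sample
  stepping for stress tests.
* Termination: per-step, per-state escape probabilities make lifetimes
  geometric in datapoints (exponential in time).  Escape probabilities are
  defined at a +200 mV reference and scaled by exp(−(V−200)/V_L) with
  V_L = 80 mV, so mean lifetimes grow exponentially with voltage.

The default class fixtures are three-state models chosen once to satisfy
the qualitative constraints the analysis targets; the numeric values are
this package's own (published histograms are graphical only).  Wild-type:
q = (0.05, 0.35, 0.62) with a narrow (b = 0.012), sticky deep-blockade
state; mutant: q = (0.20, 0.45, 0.70), broader states, and essentially no
occupancy below I/I₀ = 0.1.  Escape defaults give ~89% of wild-type events
< 0.1 s (~25% of 1–3 datapoints) and ~60% of mutant events < 0.1 s, with
2–4% of events ≥ 1 s in both classes so that the long-event protocol has
material to work with.  The low-escape deep state is what produces the
heavy lifetime tail, so long wild-type events are enriched in deep
blockade — a modeling convenience, not a measured fact.

What the generator does **not** emulate: the 10 kHz 4-pole Bessel filter
response, pore gating as a physical process (a gating-like class can only
be approximated as a low-rate extra event class), baseline drift,
flicker/1-f noise, and correlated noise within a state.  Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to every artifact of real recordings.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical assertions are comfortably stable: 500
events × 100 points for parameter recovery; pools of 2 500 events/class
(mix 500/class; long-event mix 25/class) for the calling protocols; 300–500
events for rate recovery and the negative control; 400 events for the
entry-conditioned ratio.  Bootstrap defaults are 1 000 resamples for
standalone estimates and 50–300 inside composite checks.  Indexing is
0-based with half-open intervals; decimation drops a trailing partial
block; event detection uses hysteresis thresholds (enter 0.8·I₀, exit
0.9·I₀) with the local I₀ taken as the mean of the preceding open-pore run
(≥10 points, else the global estimate), and discards events touching
either trace edge.  Events as short as one datapoint are retained
throughout.

## Known limitations

* The event detector is a simple hysteresis threshold; heavily overlapping
  events or deep baseline drift would require a more robust segmentation.
* The N/T rate estimator ignores missed short dwells below the decimation
  time; rates close to 1/Δt are biased.
* The four-state construction estimates only the split-mid rows from
  conditioned dwells; H and L rows are inherited from the three-state fit.
* Classification predictive values depend strongly on the class fixtures'
  overlap; the shipped defaults give mid-0.9 values in Case 1 and
  near-perfect values in Case 2 and are meant to demonstrate the protocol's
  direction of improvement, not any particular published accuracy.
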
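# Methods

## The model

The Wendling neural mass model describes the mean activity of four coupled
neuronal populations of a cortical patch: pyramidal cells, excitatory
interneurons, and slow (dendritic) and fast (somatic) inhibitory
interneurons.  Each synaptic pathway acts as a second-order linear filter
converting a presynaptic firing rate into a postsynaptic potential; the
three filter types are parameterised by a gain/rate pair — (A, a) for
excitation, (B, b) for slow inhibition, (G, g) for fast inhibition, with
gains in mV and rates in s⁻¹.  Firing rates are produced from membrane
potentials by the sigmoid S(v) = 2e₀ / (1 + exp(r(v₀ − v))), with half-max
rate e₀ (s⁻¹), half-activation potential v₀ (mV) and slope r (mV⁻¹).
Writing each filter in first-order form yields ten states z₁..z₁₀
(`nmmforest.model.derivatives`); the model output, analogous to EEG, is
y = z₂ − z₃ − z₄.  The constant drive P (spikes/s) enters the excitatory
loop; the seven pathway strengths C₁..C₇ are fixed fractions
(1, 0.8, 0.25, 0.25, 0.3, 0.1, 0.8) of a single connectivity scale C, the
standard proportions for this model.  The fractions are exposed in
`WendlingParameters.c_fractions` and can be overridden.

## Parameter space

The explored box (`ParameterSpace`, Table below) deliberately spans wide,
experimentally motivated ranges rather than the narrow conventional values:

| parameter | nominal | min | max | units |
|---|---|---|---|---|
| A | 5 | 0 | 10 | mV |
| B | 22 | 0 | 50 | mV |
| G | 20 | 0 | 50 | mV |
| P | 90 | 0 | 2000 | s⁻¹ |
| a | 100 | 25 | 140 | s⁻¹ |
| b | 50 | 6.5 | 110 | s⁻¹ |
| g | 500 | 350 | 650 | s⁻¹ |
| C | 135 | 0 | 1350 | — |
| v₀ | 6 | 2 | 9 | mV |
| e₀ | 2.5 | 0.5 | 7.5 | s⁻¹ |
| r | 0.56 | 0.3 | 0.8 | mV⁻¹ |

Designs are plain randomised Latin hypercubes (one uniformly jittered
sample per equal-width stratum per dimension, independently permuted across
dimensions); no maximin optimisation is applied.  The ratio-augmented
13-feature space appends r_A/B = A/B and r_a/b = a/b; a zero denominator
yields a +∞ sentinel that finite split thresholds route to the right child.

## Simulation protocol

Each parameter set is integrated for 20 s from the zero state and the first
10 s are discarded as transient; the retained output is sampled at 512 Hz
(≥ 8 samples per cycle at 60 Hz).  Two integrators are provided and must
agree (a tested property):

* `simulate` — adaptive RK45 (rtol 1e-6 / atol 1e-8) via
  `scipy.integrate.solve_ivp`, for single high-accuracy traces;
* `simulate_batch` — fixed-step classical RK4, vectorised across parameter
  sets, with two steps per output sample (dt ≈ 1 ms).  The sigmoid bounds
  every drive, so true solutions are bounded; any numerically runaway row
  is frozen, flagged `divergent`, excluded from class statistics and
  counted in the database provenance.

The RK4 step is stable for the full parameter box (the stiffest linear
rate, 2g ≤ 1300 s⁻¹, gives h·λ ≈ 1.3, inside the RK4 stability region);
batch labels were additionally cross-checked against LSODA at rtol 1e-8.

## Dynamics features and classes

Three features summarise each retained trace:

* **amplitude** — max − min (mV);
* **fundamental frequency** — lag of the first local maximum of the
  unbiased autocorrelation above 0.5 (parabolic-refined, lags ≤ half the
  window so at least two cycles support the estimate).  Using the *first*
  qualifying peak rather than the global maximum keeps harmonic-rich
  spike-wave cycles at their true fundamental, and avoids the
  period-aliasing that an argmax rule produces on exactly periodic traces;
* **peaks per cycle** — all strict local maxima counted over a whole number
  of periods, divided by the period count (rounded).  No prominence
  threshold is applied beyond a 1e-5-of-amplitude numerical floor: the
  secondary peaks of slow spike-wave cycles (a small damped-ringing burst
  riding a large relaxation oscillation) can be orders of magnitude smaller
  than the wave amplitude, and any visually motivated threshold (e.g. a few
  per cent of the amplitude) systematically under-counts them, roughly
  halving the measured prevalence of seizure dynamics.

A trace is **steady state** when its amplitude is below ε_amp = 0.01 mV, or
when the last-quarter amplitude is below 0.9× the window amplitude (a
decaying transient headed for a fixed point).  Oscillatory traces with one
peak per cycle map to the clinical bands, half-open so that every frequency
has exactly one band: delta [f_min, 4), theta [4, 8), alpha [8, 13),
beta [13, 30), gamma [30, 60] Hz.  (The conventional alpha/beta gap between
12 and 13 Hz is assigned to alpha.)  Cycles between 2 and 8 Hz carrying two
peaks are **spike-wave** and three or more **polyspike-wave** — together the
operational "seizure dynamics".  Everything else (aperiodic but
non-constant, > 60 Hz, multi-peak outside 2–8 Hz) is **other**.

## Trees and forests

`ClassificationTree` is a from-scratch CART: recursive binary splits
x_j ≤ s chosen to minimise the size-weighted child Gini sum
N_L·G_L + N_R·G_R with G = Σ_k p̂_k(1 − p̂_k).  Candidate thresholds are
midpoints between consecutive distinct sorted values; nodes above 10,000
samples evaluate at most 256 evenly subsampled boundaries per dimension (a
documented speed approximation).  Ties break to the lowest dimension index,
then the smallest threshold.  Growth is best-first by impurity decrease
(so `max_leaves` keeps the most informative splits); stopping rules are
`min_leaf`, purity, and optional `max_depth`/`max_leaves`.  A literal
mean-Gini variant (`criterion="mean_gini"`, impurity divided by the node
count, children summed unweighted) is available for comparison; it uses the
printed cost for split *selection* but reports size-weighted decreases so
importances stay non-negative.

`RandomForest` grows B bootstrap trees (n draws with replacement), with a
fresh random subset of `mtry` candidate dimensions per node
(default ⌊√p⌋); out-of-bag class probabilities and error are computed.
Ensemble probabilities are the plain average of per-tree leaf proportions.

**Variable importance.**  Per tree, VI(j) is the summed impurity decrease
at branch nodes splitting on j divided by the tree's branch count N_b;
forest VI is the mean over trees, and NVI(j) = VI(j)/max_i VI(i) ∈ [0, 1].
A parameter the labels never depend on earns NVI ≈ 0 (exactly 0 unless a
tree overfits a noise split).

**Forest targets.**  Four dynamic characteristics are analysed: steady
state vs cycle (binary), amplitude of oscillation (oscillatory rows,
quartile classes — the discretisation is a package choice), frequency band
(single-peak oscillatory rows, 5 classes), and seizure vs rest (binary).

## Benchmark suite

Four analytic 0/1-labelled functions on [0,1]³ give exact ground truth for
NVI: `ex_a` (stripes in X only), `ex_b` (diagonal X+Y), `ex_c` (circular
boundary in X, Y), `ex_d` (|cos 20X| vs |cos 3Y|, radians — principally Y,
slightly X).  Z never enters any label, so NVI_Z measures the overfitting
noise floor.  The validation harness draws n = 10⁵ uniform points and fits
a 100-tree forest with mtry = 1 (the classification default ⌊√p⌋ at p = 3:
one random candidate dimension per node) and min_leaf = 100.  Forcing each
node onto a single drawn dimension decorrelates the trees and makes the
NVI triples stable in the second decimal across seeds; with all dimensions
candidate instead (mtry = 3), the ex_d X-importance sits on a sharp
cliff in min_leaf (its X-stripes have period π/20 ≈ 0.16, right at the
leaf resolution) and varies by ±0.06 between seeds.  min_leaf remains the
resolution knob: much smaller leaves resolve every stripe and push NVI_X
above NVI_Y, much larger ones erase the X signal entirely.

## Region statistics

`region_probability` estimates P(class | X ∈ R) as the sample mean of the
0/1 class indicator over database rows inside the hyperrectangle R
(half-open constraints), and reports the support |χ|; an empty region is an
explicit no-support error rather than a fabricated 0.  `bivariate_map` bins
two parameters into a 20 × 20 equal-width grid over their configured ranges
(final bin closed) and applies the same estimator per cell; empty cells are
missing, never 0 or 1, and the count-weighted cell mean equals the global
rate exactly (a tested identity).

## Problem sizes and what the tests show

The package's own reference computations use scaled-down problem sizes
chosen to keep a complete run on a single CPU in minutes: databases of
2,000–5,000 LHS points (binomial standard error ≈ 0.3–0.7 points on the
class percentages at n = 5,000) and benchmark forests at n = 10⁵.  The
spike-wave prevalence and the region statistics derived from it carry that
sampling noise.  Variable-importance *rankings* on the model database are
reproducible across seeds at these sizes for clearly separated parameters
(e.g. b dominating the seizure target); near-ties between the top
parameters (B vs b on the frequency target; r_A/B vs r_a/b on the
ratio-augmented seizure target) can flip at scaled-down n, and the measured
NVI of the runner-up then reflects that proximity rather than a stable
ordering.

The synthetic benchmark functions exercise the tree/forest machinery with
exact labels but axis-aligned or smooth boundaries and noise-free
responses; passing them shows the importance statistic identifies
label-relevant inputs and ignores independent ones, not that the forest
resolves arbitrarily fine structure.  Likewise the simulated databases are
deterministic (constant drive, fixed initial state): the classifier's
behaviour on noisy, nonstationary experimental EEG is out of scope.

## Known limitations

* Stochastic (noise-driven) input, coupled multi-mass networks, and
  numerical continuation/bifurcation analysis are out of scope.
* The steady-state threshold and the decaying-transient rule necessarily
  impose a cutoff on a continuum; traces with transients much longer than
  the 10 s burn-in are classified as steady.
* In bistable regions the class is that of the attractor reached from the
  zero initial state (the initial condition is configurable).
* Importance is global Gini importance; no permutation or conditional
  variants, and no correction for correlated features (the ratio features
  are by construction correlated with their sources).
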
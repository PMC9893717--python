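# Methods

This note documents the models and procedures implemented in
`ensemblepipe`, the tunable parameters and their defaults, the numerical
choices, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Data model

A raster plot is a binary `N × F` matrix: rows are neuron activity
vectors, columns population vectors, plus a frame rate (fps). The
default rate everywhere is 4 fps, a typical acquisition rate for somatic
calcium imaging; it enters only through time-based quantities (firing
rates in events/s, recurrence times in frames). Inference of events
from fluorescence is out of scope: the raster is the input.

Neurons with constant rows (silent or saturated) have undefined Pearson
correlation; they are excluded from graph construction, reported, and
carry label −1 through sorting and outputs. No imputation is attempted.

## Functional-connectivity graph

Distances are `d = 1 − r` with `r` the Pearson correlation of binary
rows (equivalently the phi coefficient), giving `d ∈ [0, 2]`. The graph
is the fuzzy k-nearest-neighbor construction: per node, the k nearest
neighbors (ties broken deterministically by lower neuron index) receive
directed weights `exp(−max(0, d − ρ)/σ)` where ρ is the distance to the
first nearest neighbor (so the nearest neighbor always has weight 1)
and σ solves `Σ w = log2(k)` by bisection (tolerance 1e−5, ≤ 64
iterations; when equidistant neighborhoods make the target unreachable
σ clamps to its lower bracket, yielding unit weights). Directed weights
merge by the probabilistic union `w_ij + w_ji − w_ij w_ji`, producing a
symmetric matrix of connection probabilities with zero diagonal.

`n_neighbors` defaults to 10: small neighborhoods preserve the fine
local structure that separates individual ensembles; the value is
exposed everywhere and should be adapted to data density. The weighted
graph (not a binarized version) feeds community detection — the
modularity equations are weight-compatible, and thresholding would
discard the calibrated connection probabilities.

The low-dimensional embedding (for visualization only; nothing
downstream consumes coordinates) delegates to the UMAP reference
implementation with the same neighbor count and metric, `min_dist` 0.1
and 2–3 components, seeded for determinism.

## Ensemble detection by modularity

Communities are found by the leading-eigenvector method: from
`B_ij = A_ij − k_i k_j / 2m` (rows sum to zero), recursively bisect by
the sign pattern of the leading eigenvector of the group-restricted
matrix `B^(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik`. Each proposed split is
refined by Kernighan–Lin single-vertex sweeps (every vertex moved once
per sweep in best-gain order, best prefix kept) before evaluating its
modularity contribution `ΔQ = s^T B^(g) s / 4m`; a subgraph stays
undivided when the leading eigenvalue is ≤ 1e−9 or ΔQ ≤ 0. The reported
Q is the standard normalized modularity of the final partition. The
1/4m normalization makes stage contributions sum to Q; it does not
affect the stopping rule, which only uses the sign.

Eigenpairs come from dense symmetric decomposition up to 256 nodes and
ARPACK (`which="LA"`) with dense fallback above.

Stability: detection is re-run `consensus_runs` (default 10) times —
the first run on the unperturbed graph, later runs with each edge
weight multiplied by `1 + u`, `u ~ U[−0.01, 0.01]`, seeded. The
co-assignment matrix (fraction of runs placing two nodes together) is
thresholded at 0.5 and re-clustered until binary-stable (≤ 20 cycles);
final labels are its connected components and Q is evaluated on the
original graph. Running the first pass unjittered keeps
`consensus_runs=1` identical to the deterministic base algorithm.

On all suite graphs of ≤ 10 nodes (cliques, rings, complete graphs,
planted partitions, random weighted graphs) the detected partition
attains the modularity of an exhaustive recursive-bisection search to
1e−9 (see `tests/_oracles.py`).

Sorted rasters group rows by community, communities ordered by the
first frame at which any member is active; excluded neurons append
last; the permutation is returned for traceability.

## Runs test and surrogate calibration

The coactivity series of a raster (or ensemble subraster) is its column
sums. The Wald–Wolfowitz runs test dichotomizes around the arithmetic
mean (values exactly equal to the mean are dropped — the classical
convention), counts maximal same-sign runs T, and uses the closed-form
moments `T̄ = 2n₁n₂/(n₁+n₂) + 1` and
`s_T² = 2n₁n₂(2n₁n₂−n₁−n₂)/((n₁+n₂)²(n₁+n₂−1))` with the two-tailed
normal probability of `Z = (T − T̄)/s_T`. No continuity correction is
applied: the statistic follows the plain normal approximation, which
keeps the alternating-series closed form (T=10, T̄=6, Z=2.683 for five
pairs) exact. A series with all retained values on one side of the mean
raises a degenerate-series error.

Two surrogate classes calibrate the test, both preserving N, F, fps and
every neuron's event count:

* **type-1** (null true): each neuron's active frames are redrawn
  uniformly without replacement — rejections estimate the type-I rate
  α̂;
* **type-2** (null false): each neuron's multiset of inter-event
  intervals is preserved, the interval order permuted and the first
  event placed uniformly in the feasible offset range (neurons with <2
  events placed uniformly) — non-rejections estimate the type-II rate
  β̂.

Each surrogate index draws from an independent seed-derived substream,
so reports are reproducible and parallelizable. Degenerate surrogate
series count as non-rejections for α̂ and as failures for β̂
(conservative on both rates).

A calibration caveat, measured on 32 000 type-1 surrogates of the
control-like raster: the exact size of the uncorrected two-tailed test
at nominal 0.05 is 0.0514 ± 0.0012. The excess is the half-integer
discreteness of the run count, of magnitude ≈ 2φ(1.96)·(0.5/s_T), and
is positive at any finite series length; a continuity-corrected
statistic would remove it but change the closed-form Z. Consequently a
single M = 1000 estimate of α̂ lands below 0.05 only with ≈ 40–45%
probability, and the corresponding acceptance check is expected to sit
marginally above the bound (it reads 0.051 at the frozen test seed). β̂
is 0 in every observed configuration with planted structure: the bursty
interval-preserving surrogates are always rejected.

## Significant coactivity peaks and transitions

A window of `round(window_fraction · F)` frames (default 20%, values of
5–20% all reasonable) slides one frame at a time, centered on the
evaluated frame and truncated at the edges. A frame is significant when
its count strictly exceeds the window mean + `n_sd` (default 2)
population standard deviations. Population SD (divide by the window
length) matches the plain "mean + two standard deviations" rule; both
the SD convention and the centering are deliberate choices exposed as
configuration. Per-ensemble peak extraction first requires the
ensemble's coactivity to be declared non-random by the runs test at
`alpha_level` (default 0.05); otherwise the ensemble yields an empty
peak set and a warning.

Runs of consecutive flagged frames collapse to one activation event at
the run's first frame (onset convention; transitions are defined by
onset order). Events merge across ensembles in frame order,
simultaneous onsets ordered by ensemble id and reported. Consecutive
events of different ensembles increment the directed edge count;
repeats of the same ensemble are recorded as self-loops but excluded
from transition totals, graph drawings and the max-edge share. No
maximum gap between consecutive peaks is imposed — every consecutive
pair counts as a transition — which users of sparse recordings should
be aware of.

## Recurrence quantification

The firing-rate series of an ensemble is the summed event count of its
neurons in a sliding window of `window_seconds` (default 1 s, i.e. 4
frames at 4 fps) divided by the window duration, sliding one frame.
The recurrence plot marks pairs of time points with Euclidean state
distance ≤ ε (default fixed radius 1.5 events/s). The embedding
dimension defaults to 1 (scalar rates, distance = absolute difference);
delay embedding with higher dimension is supported but not default, as
the rate series is already a smoothed observable.

Measures: RR = Σ P_ij / n²; DET = fraction of recurrence points on
diagonal lines of length ≥ `min_line` (default 2); DIV = 1 / longest
diagonal line; LAM = the vertical-line analogue of DET (`min_line`
applies to both); W = mean length of maximal vertical runs of zeros
anywhere in a column (0 when no zero run exists; the alternative
recurrence-bounded definition was considered and rejected as the less
direct reading of "white vertical lines"). The main diagonal is
included by default — consistent with an RR that sums every P_ij — and
can be excluded (`include_loi=False`), which then removes its points
from both the line counts and the recurrence-point totals; with no
diagonal line at all DIV is undefined (NaN). Note that for a fully
recurrent plot the two corner diagonals are single points below
`min_line`, so DET = (n²−2)/n², approaching but not equal to 1.

Fast line counting is validated against an exhaustive pure-python
enumeration on random and structured matrices up to 25 × 25, exactly.

## Synthetic rasters and presets

The generator plants K disjoint neuron groups and an epoch schedule:
the label sequence is concatenated cyclically, each epoch lasting
`epoch_length` frames (default 12, i.e. 3 s) separated by silent gaps
(default one epoch length), with a lead-in gap. Within its group's
epoch a member fires per-frame with `p_active_in_epoch`; everywhere
else every neuron fires with `p_background`. One seeded RNG stream per
call makes fixtures bit-reproducible.

The model deliberately omits: calcium indicator kinetics, within-epoch
rate ramps, shared slow modulation or any nonstationarity, overlapping
ensembles, and neuron-specific rate heterogeneity. Background is iid
Bernoulli. Tests on synthetic data therefore demonstrate correctness of
the algorithms under the planted model, not performance on real
recordings.

Preset parameters are implementation constants chosen to plant
qualitative condition contrasts at desk scale:

| preset | N | K | p_active | p_bg | gap | sequence character |
|---|---|---|---|---|---|---|
| control_like | 60 | 6 | 0.90 | 0.020 | 2 | balanced, many distinct transitions |
| decorticated_like | 400 | 8 | 0.90 | 0.019 | 36 | unidirectional ring, long gaps |
| parkinsonian_like | 48 | 3 | 0.90 | 0.020 | 24 | one dominant ordered pair (≥ half of within-sequence transitions) |
| dyskinetic_like | 45 | 9 | 0.95 | 0.050 | 2 | densest packing, most ensembles |

The planted contrasts the suite asserts: perfect-to-high recovery of K
at strong signal; fewer ensembles and a more dominant transition for
parkinsonian-like than control-like; the lowest per-neuron background
for decorticated-like; the highest mean ensemble RR for
dyskinetic-like (small ensembles keep the rate series in a narrow band,
so states recur within the fixed radius) and the lowest for
decorticated-like (large ensembles spread the summed rate over many
levels).

A known structural limitation: for stationary series, RR is a function
of the marginal concentration of rate values and the mean white-line
length of the temporal coherence of non-recurrent stretches. A sparse,
low-noise ensemble has a flat baseline that is self-recurrent (high RR,
whites only at epoch crossings); a fluctuating baseline gives low RR
but fragments white lines into short runs. The combination "lowest RR
with longest recurrence times" seen in real decorticated recordings
requires temporally coherent nonstationarity in firing rates, which the
iid-background planted-epoch model cannot express; the corresponding
white-line ordering is therefore not plantable here and its acceptance
check is expected to fail, by design of the generator rather than by a
defect of the recurrence engine (which is oracle-verified).

## Problem sizes

Default test and acceptance configurations use rasters of 30–400
neurons and 800–3000 frames, 1000 surrogates per class, and recurrence
matrices up to ~3000², sizes chosen to exercise every code path with
comfortable statistical resolution.

## Pipeline and reproducibility

`run_pipeline` executes ensembles → coactivity → transitions →
recurrence, writes CSV tables, sorted raster, edge-list/DOT/GraphML
graphs and a JSON manifest recording the package version, the full
configuration, the seed, and a SHA-256 checksum of every output file;
identical config + seed reproduces byte-identical outputs. The CLI
(`simulate`, `detect`, `peaks`, `transitions`, `rqa`, `run`) is a thin
layer over the library; `EnsembleDetector` and `RecurrenceQuantifier`
follow the scikit-learn estimator contract so they compose with
standard model-selection tooling.
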
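# ensemblepipe

Detection and dynamics of **neuronal ensembles** in binary activity
rasters, as recorded by calcium imaging of brain microcircuits (dozens of
neurons over thousands of frames). From a raster plot `R` — a binary
`N × F` matrix whose rows are neuron activity vectors `V_A` and whose
columns are population vectors `V_P` — the package:

1. builds a weighted **functional-connectivity graph**: pairwise
   correlation distances `d_ij = 1 − r_ij` between activity vectors are
   turned into a fuzzy k-nearest-neighbor graph with local weights
   `w_ij = exp(−max(0, d_ij − ρ_i)/σ_i)` (ρ_i the nearest-neighbor
   distance, σ_i calibrated so local weights sum to `log2 k`),
   symmetrized by probabilistic union `w_ij + w_ji − w_ij·w_ji`;
2. identifies **ensembles as graph communities** by Newman's
   leading-eigenvector modularity method — recursive spectral bisection
   of the modularity matrix `B_ij = A_ij − k_i k_j / 2m` and its
   group-restricted generalization, with Kernighan–Lin refinement and a
   consensus wrapper over seeded weight-jittered re-runs;
3. validates each ensemble's **coactivity** (per-frame count of active
   members) against randomness with the Wald–Wolfowitz **runs test**
   `Z = (T − T̄)/s_T`, calibrating its type-I/II error empirically with
   two surrogate classes (uniform event redraw; inter-event-interval
   preserving permutation), and extracts **significant coactivity
   peaks** with a sliding-window dynamic threshold (local mean + 2 SD);
4. converts per-ensemble peak onsets into a directed, count-weighted
   **ensemble transition graph**;
5. quantifies each ensemble's firing-rate dynamics with **recurrence
   analysis**: fixed-radius (ε = 1.5) recurrence plots of the 1-s
   sliding-window rate, and the measures RR, DET, DIV, LAM and the mean
   white vertical line length W.

A synthetic-raster module generates rasters with planted ensembles,
activation sequences and background noise — including four presets that
encode qualitative contrasts between experimental conditions of striatal
microcircuits (control-like, decorticated-like, parkinsonian-like,
dyskinetic-like) — so the whole pipeline is testable against known
ground truth.

All indices (neurons, frames, ensemble ids) are 0-based, in files and
interfaces alike.

## Worked example

Simulate a parkinsonian-like raster (48 neurons, 3 ensembles, one
dominant recurring transition) and run the full pipeline:

```sh
ensemblepipe simulate parkinsonian_like --seed 7 --out demo_sim
cat > demo.yaml <<'YAML'
input_path: demo_sim/raster_matrix.txt
fps: 4.0
n_neighbors: 10
consensus_runs: 10
surrogates: 1000
seed: 7
output_dir: demo_out
YAML
ensemblepipe run --config demo.yaml
```

which prints

```json
{
  "n_ensembles": 3,
  "modularity_q": 0.6665648061838043,
  "alpha_hat": 0.044,
  "beta_hat": 0.0,
  "transitions": 82,
  "output_dir": "demo_out"
}
```

The three planted ensembles are recovered (partition modularity
Q ≈ 0.67 on the connectivity graph). Of 1000 uniform-redraw surrogates,
4.4% are rejected by the runs test (`alpha_hat`, the estimated type-I
error, near the nominal 5%), and every interval-preserving surrogate is
correctly rejected (`beta_hat` = 0, no type-II errors): the coactivity
structure is real. The 82 inter-ensemble transitions are dominated by a
single ordered pair (45% of transitions, visible in
`demo_out/transitions.tsv`), the planted signature of this condition.
Per-ensemble recurrence measures land in `demo_out/rqa.csv`, e.g. for
ensemble 0: RR = 0.466, DET = 0.961, LAM = 0.983 — a strongly
deterministic, laminar rate trajectory, as expected for regularly
recurring epochs.

The same stages are available as a library: `EnsembleDetector` is a
scikit-learn clusterer (`fit`, `fit_predict`, `labels_`,
`modularity_q_`) over raster rows, and `RecurrenceQuantifier` a
fit-style recurrence engine; `run_pipeline(PipelineConfig(...))` writes
every table, graph export and a JSON manifest for reproducibility.

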
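# Methods

This note records what g4boost computes, the parameters it exposes with
their defaults and rationale, what the synthetic generator does and does
not emulate, and the known limitations. Everything stated here is either a
definition or is computed by the test suite / `scripts/acceptance.py`.

## 1. Motif scanning (`g4boost.motifs`)

A putative G-quadruplex sequence (PQS) is a maximal match of the extended
motif `{G3+ N1-12}3+ G3+`: four or more tracts of at least three
consecutive guanines, each adjacent pair separated by a 1–12-nt loop that
contains neither `N` nor a further run of three guanines (such a run would
itself be a tract). The scanner:

- enumerates maximal `G{3,}` runs, chains consecutive runs whose gap is
  1–12 nt (`N` anywhere in the gap breaks the chain), and keeps chains of
  ≥4 tracts;
- reports **leftmost-longest merged** hits, so nested or overlapping
  candidate quadruplexes collapse into one hit that may carry more than
  four tracts (and hence more than three loops);
- scans the reverse strand by the same rule on the reverse complement and
  reports hits in forward coordinates with `strand == "-"`; the stored
  motif string is always read on the hit's own strand.

An independent brute-force oracle (exhaustive validation of candidate
substrings) is kept in `tests/helpers.py`; equivalence is checked on 1000
random sequences plus crafted chain/merge/break cases.

Flanks: 50 nt on each side by default (`flank_len=50`), truncated at
sequence boundaries, reverse-complemented for minus-strand hits so that
"5′ flank" is always 5′ on the G-rich strand.

## 2. Feature digestion (`g4boost.features`)

209 features per PQS, in a fixed canonical order (`FEATURE_NAMES`):

- **Composition (201).** For each of the three segments — the PQS body,
  the 5′ flank and the 3′ flank — counts of all 64 triads in a sliding
  1-nt-step window (overlaps counted: `GGGG` contains `GGG` twice;
  windows containing `N` are skipped) plus singleton counts of G, C and A
  (T is omitted as linearly redundant given segment length). 3 × 67 = 201.
- **Topology (5).** PQS length, number of loops, and the lengths of the
  first three loops (zero-padded when a merged hit has fewer; extra loops
  of a merged hit count only in `G4_numlps`).
- **Energetics (3).** For each of the first three loops, the ensemble free
  energy (kcal/mol) of the hairpin-forming potential of the loop plus its
  two bracketing G-tracts, computed at 37 °C with DNA nearest-neighbour
  parameters. Default engine: ViennaRNA Python bindings with
  `params_load_DNA_Mathews2004()` and partition-function folding. When the
  bindings are unavailable a bundled simplified stacking/hairpin engine is
  used; values differ but the feature remains monotone in folding
  propensity. An `EnergyTable` memoizes loop sequences (the full 5–12-nt
  loop-context table has 22,369,280 slots and is filled lazily).

Scaling: each feature is centred by its **median** and divided by its
sample SD (ddof 1), with statistics fitted on the training split only;
zero-SD features scale to zero rather than dividing by zero.

## 3. Signal mapping (`g4boost.mapping`)

Experimental mm% arrives as a 4-column bedGraph-like track of 15-nt bins.
A PQS receives the **maximum** mm% over all bins sharing at least one base
with the window `[start − 50, end + 50)`; a PQS whose window touches no
bin is reported as uncovered (`mm = NaN`), never as 0.

**Isolation filter.** A PQS is kept only if no other PQS (either strand)
overlaps its ±50-nt window — implemented as a windowed interval-overlap
count per sequence, so nested cross-strand hits are handled, not just
adjacent neighbours in sorted order. Both members of a crowded pair are
dropped, because the binned signal cannot be attributed to either.

`copy_number_stats` groups PQSs by identical motif string (≥5 copies by
default) and reports mean/SD of mm% per group with a lowess trend
(frac 0.6) of SD against mean, for checking that sequence determines
signal up to noise.

## 4. Model (`g4boost.model`)

Gradient-boosted regression trees (xgboost, `tree_method="hist"`,
single-threaded for determinism). `GBMConfig` fields and defaults:

| field | default | meaning |
|---|---|---|
| `n_trees` | 2500 | boosting rounds |
| `interaction_depth` | 14 | max tree depth |
| `min_child_weight` | 65 | min sum of instance weight per leaf |
| `learning_rate` | 0.01 | shrinkage |
| `bag_fraction` | 0.6 | row subsample per tree |

The defaults are a published optimum for genome-scale experimental data;
for the package's own synthetic problem sizes the bundled `small_grid()`
(200/400 trees × depth 4/6, `min_child_weight` 10, learning rate 0.1) is
both sufficient and fast, and `default_grid()` provides a 32-point grid
around the large defaults.

- **Tuning.** `repeated_cv` runs twice-repeated 3-fold CV (fresh shuffle
  per repeat, scaler refitted inside every round) giving exactly six RMSEs
  per candidate; `grid_search` ranks by mean RMSE, ties broken by grid
  order.
- **Classification.** A PQS is called a stable G4 when predicted mm% ≥
  threshold. The packaged default threshold is **19.1 mm%** (the
  experimental-data operating point); `choose_threshold` instead sweeps
  the observed mm% range and picks the threshold maximizing
  `min(TPR, TNR)` on `(mm ≥ t, score ≥ t)`, ties to the lower value.
- **Persistence.** Models are saved as a raw xgboost Booster JSON plus a
  TSV of scaling parameters and a JSON of config/threshold/seed — no
  pickles. (The xgboost 3.x scikit-learn wrapper fails to reload under
  scikit-learn ≥1.9, so the raw Booster API is used throughout.)
- **Interpretation.** `importance_report` normalizes total-gain importance
  to a maximum of 1 and annotates each feature with the sign of its
  Spearman correlation with mm% (`+`/`−`, `*` when |ρ| < 0.05).

## 5. Synthetic generator (`g4boost.synthetic`)

What it emulates: a genome whose only PQSs are the planted ones, a
bimodal stability landscape (non-forming vs stable), binned noisy
polymerase-stalling signal, sequence-copy groups, and a flank effect.

- **Background** is i.i.d. DNA with every `GGG`/`CCC` repaired away, so by
  construction no accidental PQS exists on either strand; planted motifs
  are bracketed by T…A boundary bases. The generator asserts that a rescan
  recovers exactly the planted intervals.
- **Planted motifs** come in two sequence classes: *strong* (4–6 G
  tracts, 1–3-nt loops) and *weak* (mostly 3 G tracts, 4–7-nt loops).
  Latent mm% is a **deterministic function of the realized motif**:
  `latent = base + g_slope · excess_tract_G − 0.8 · (mean_loop − 1)`,
  with `base` and `g_slope` jointly calibrated so the class-expected
  latents sit at the configured modes (defaults 8 and 40 mm%). A flank
  effect adds a clipped multiple of the standardized own-strand flank
  G-count, with larger amplitude (3.0) below a 20-mm% knee than above it
  (1.0) — weak quadruplexes are more flank-sensitive.
- **Track**: 15-nt bins; background bins get |N(0, 0.5)| × background
  level; each PQS writes its latent value (plus N(0, `noise_sd`), clipped
  to [0, 100]) into one peak bin jittered within ±35 nt of the PQS; a
  configurable fraction of bins is dropped to emulate missing coverage.

What it does **not** emulate: chromatin or replication-timing effects,
strand-biased sequencing error, PCR duplicates, inter-run batch effects,
or any relationship between mm% and true thermodynamic stability beyond
the monotone latent construction. Conclusions about real genomes require
real tracks.

## 6. Problem sizes and numerical choices

The acceptance run (5000 PQSs, 1-Mb genome, noise SD 5 mm%, 4-point grid)
is the package's own choice: large enough that held-out metrics are stable
to ~2 decimal places across seeds, small enough to run in ~20 s on one
core. Seeds are plumbed explicitly everywhere (generator, shuffles, tree
fitting); given a seed, every number in `results/acceptance.json` is
reproducible bit-for-bit. Floating-point comparisons in tests use
tolerances, not exact equality, except where integer counting is involved.

## 7. Open decisions and limitations

- The 19.1 mm% default threshold is meaningful only for tracks on the
  scale of the original assay; on synthetic data `choose_threshold` should
  be used instead (and is, in the CLI `predict` path when retraining).
- The fallback energy engine is not parameter-compatible with ViennaRNA;
  models trained under one engine should be applied under the same engine
  (the engine's values are frozen into the saved scaler statistics only
  indirectly, via feature distributions).
- The isolation filter discards data; with dense PQS clusters (e.g.
  telomeres) most hits are removed by design.
- The triad features are correlated by construction (overlapping windows);
  tree ensembles tolerate this but linear-model users should reduce the
  feature set first (`reduce_features`).
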
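# Methods

This note documents the models, parameters, numerical choices and
limitations behind `scbackdoor`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

The central container (`LabeledExpressionMatrix`) is a cells × genes matrix
of finite, non-negative expression values with unique cell/gene identifiers
and one categorical label per cell; at least two classes must be present.
Values may be raw counts or normalized expression — every operation,
including the poisoning threshold, is interpreted on the scale of the
stored values. The canonical usage applies the threshold τ = 2 to raw
counts. Sparse (CSR) and dense storage behave identically; the sequencing
depth of a cell is its row sum.

Three on-disk encodings are supported: H5AD (labels in an `obs` column,
default `celltype`), a CellRanger-style MTX directory (genes × cells
MatrixMarket plus `barcodes.tsv` / `features.tsv` / `labels.tsv`), and a
dense CSV (first column `cell_id`, last column `label`). Round-trips are
bit-exact for integer counts and within 1e-9 relative for floats.

## Synthetic data generator

The generator emulates the statistical shape of a droplet-based,
pancreas-like annotation dataset at a size where a full
attack → train → evaluate loop runs in seconds:

| parameter | default | meaning |
|---|---|---|
| `n_cells`, `n_genes`, `n_types` | 2000, 500, 5 | matrix size and class count |
| `type_proportions` | uniform | class prior |
| `markers_per_type` | 20 | disjoint marker block per type |
| `marker_fold` | 8.0 | mean fold-boost of markers in their type |
| `base_mean` | 0.5 | scale of the shared baseline expression profile (gamma-distributed per gene) |
| `dispersion` | 0.3 | variance of the per-gene gamma perturbation (mean 1) |
| `depth_log_mean`, `depth_log_sd` | ln 3000, 0.35 | lognormal sequencing-depth law |

Counts are drawn conditionally on depth: each cell's depth is drawn first
(lognormal, rounded, ≥ 1) and its counts are one multinomial draw over the
cell type's gene proportions perturbed by i.i.d. gamma factors — the
gamma–Poisson (negative binomial) overdispersion route, conditioned on the
total. Row sums therefore equal the drawn depths *exactly*, which is what
makes the attack's depth-conservation guarantee crisply testable. The
generator is bit-reproducible from its seed.

Deliberately not modeled: batch effects, doublets, ambient RNA, and
zero-inflation beyond the count model. Passing tests on these data show
that the attack/defense machinery behaves as specified; they do not show
how strong the attack is on any particular real dataset, where class
separability and the low-count band differ.

With the defaults, about 3000 counts spread over 500 genes put a
substantial fraction of entries in the 1-count band that a τ = 2 trigger
zeroes — the regime the attack exploits. The five types are linearly
separable (clean accuracy 1.0 for the surrogate), so clean-performance
preservation is trivially visible and any degradation is attributable to
the poisoning.

## Attack

*Victim selection.* Cells with the target label, all-zero cells, and cells
with no gene ≥ τ are ineligible. Eligible cells are ranked by descending
heterogeneity — Shannon entropy (natural log) of expression proportions
over expressed genes by default; an expressed-gene-count alternative is
provided — with ties broken by ascending cell index. `k = round(ρ·n)`
(half-away-from-zero, minimum 1) cells are taken. High-entropy cells are
the natural victims: their flat profiles have the largest sub-threshold
band, hence the strongest trigger footprint, and they sit diffusely in
expression space.

*Trigger.* Genes with values in (0, τ) are zeroed. Surviving proportions
`p` are resampled as `q ~ Dirichlet(s · p · n_surv)` where `s` is
`perturb_strength` (default 1.0), then scaled to the original row sum. The
concentration parameterization keeps `E[q] = p`, so the perturbation is
mean-preserving; `s → ∞` recovers pure proportional rescaling (used in
tests as the deterministic limit). All-integer cells stay integer via
largest-remainder rounding (floors first, remaining units by descending
fractional part, ties by index), conserving the sum exactly; float cells
conserve the sum to ~1e-16 relative. Each cell's noise stream is seeded by
(config seed, cell index), so results are independent of processing order.

*Test-set poisoning* triggers every eligible non-target cell, keeps the
true labels (the trigger alone must flip predictions) and reports the
original labels, so ASR and clean metrics come from one prediction pass.

*Rank trigger.* For rank-value consumers, a cell is encoded as its
expressed genes ordered by descending value (ties lexicographic by gene
id). The trigger prepends a fixed gene signature to the encoding,
preserving the relative order of all other genes. This prepend variant is
the simplest operation satisfying the trigger contract in rank space; it is
a documented design choice of this package, not a claim about any specific
published tokenizer.

## Evaluation

Accuracy, Cohen's kappa (marginal-product chance term; the degenerate
all-agree single-class case returns 1), and Macro-F1 (unweighted over
classes present in the truth, zero-division → 0) are computed via
scikit-learn and cross-checked in the tests against hand-rolled
confusion-matrix oracles. ASR is the fraction of triggered, originally
non-target test cells predicted as the target; cells already of the target
class are never counted.

The surrogate victims are (i) a multinomial logistic model over per-gene
standardized log1p CPM features (lbfgs, C = 10, 500 iterations — weak
regularization, since the attack signal is spread thinly over many
low-expression genes) and (ii) a 15-NN voter over the same features. The
attack operates purely on data, so any predictor honouring the
`fit`/`predict` contract can be swapped in.

*Concealment* is the mean fraction of benign cells among each poisoned
cell's 15 nearest neighbours in 50-component PCA space of log1p-CPM
features (deterministic full SVD; self excluded). The null reference is the
benign fraction among all other cells, ≈ 0.95 at the default 5% rate.

*Sweeps* vary exactly one of {threshold, target label, poisoning rate}
over a seed grid and emit a long-format table. At the default conditions
(five seeds, medians): ASR ≈ 0.91 with clean accuracy equal to baseline;
ASR is non-decreasing in τ over {0.5, 1, 2, 4} (τ = 0.5 and τ = 1 coincide
exactly on integer counts — the zeroing set is empty for both, leaving only
the redistribution noise as the trigger); ASR at ρ = 0.05 far exceeds
ρ = 0.01.

## Defenses

*Integrity.* `verify_download` compares a file's SHA1 with a published
digest (case-insensitive; malformed digests rejected).

*Sanitization.* Each cell gets the sum of two deterministic,
label-conditioned signals: (a) its distance to its own label's centroid in
30-component PCA space, per-component standardized — computed with robust
statistics (median centroid, MAD spread with a scale-aware floor) so that a
poisoned minority cannot mask itself by inflating its own label's spread;
and (b) a zero-inflation scan over τ ∈ {0.5, 1, 2, 4}: the z-score of how
anomalously *low* the cell's fraction of genes in (0, τ) is versus label
peers, clipped at 0 and maximized over the grid — aimed directly at the
zeroing trigger's footprint. Labels with fewer than 3 cells fall back to
global statistics with a warning. Removing the top 2ρ of cells by score
recovers essentially all poisoned cells at the default attack (recall ≈ 1,
FPR ≈ 0.05) and training on the sanitized set drives the ASR to ≈ 0.

One empirical subtlety: cells that are relabeled *without* value changes
and cells that are value-modified *without* relabeling both score above
benign, but the value trigger at default strength displaces cells in PC
space more than relabeling does, so modified-only cells score higher on
average. Real poisoned cells carry both footprints and rank at the top.

*Purification* re-fits a suspect model on a verified-benign subset covering
all of its classes; on the default attack this removes the backdoor
(ASR ≈ 0) without clean-performance loss.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.Generator`. The CLI derives per-stage child seeds from one
global seed via `SeedSequence([seed, stage])`, records every seed, resolved
parameter and input SHA1 in a JSON manifest beside each output, and writes
no timestamps, so identical commands produce bit-identical artifacts.
`scripts/acceptance.py` uses five replicate seeds derived the same way; all
reported quantities are medians over replicates. Problem sizes throughout
(2,000 × 500 study scale, 300 × 120 for cheap unit fixtures) were chosen so
the full suite and the acceptance script each run in minutes on one CPU.

## Known limitations

- Surrogate classifiers, not pre-trained transcriptome foundation models:
  ASR magnitudes here characterize the data-level attack against a linear
  decision boundary, not against fine-tuned transformers.
- The rank trigger is exercised at the encoding level only; no rank-value
  consumer model is shipped.
- The heterogeneity measure and perturbation law are concrete, documented
  choices within a family of qualitatively equivalent options; absolute
  numbers (though not the qualitative trends) depend on them.
- The anomaly detector is tuned to this threat model (relabeling +
  threshold-zeroing); a different trigger family would need a different
  signal (b).
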
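# Methods

This note records the modeling choices behind `phositec`, what the synthetic
fixtures do and do not emulate, and the numerical conventions that matter for
reproducing its behavior.

## Phospho-MS preprocessing (`msio`)

A raw matrix holds nonnegative intensities for phos-sites (protein accession,
S/T/Y residue, 1-based position) across samples, with heavy missingness.
Preprocessing is defined so that downstream code can treat **value 0 as
"originally missing"**:

* duplicate-sample groups collapse to the member with the fewest missing
  values (ties: first occurrence in column order);
* site filtering keeps kinase sites and candidate substrate sites
  unconditionally, plus any site detected in at least `min_detect_frac`
  (default 0.10) of samples — deduplication runs first, since it changes the
  denominator of the detection fraction;
* missing cells are imputed as (global observed minimum − eps), eps = 1e-4,
  then the whole matrix is min–max scaled to [0, 1]. Scaling is global, not
  per sample or per site: only a global scheme puts all imputed cells exactly
  at 0 while keeping one common intensity scale.

Re-running preprocessing on its own output moves values by at most a few eps
(the imputation floor is re-derived), which is the sense in which the
procedure is idempotent. When a matrix has no missing cells at all, plain
min–max scaling applies and the zero mask is empty — in that regime the
"0 ⇔ missing" equivalence is vacuous by construction.

## Sequence and structural features (`seqfeat`, `structfeat`)

Flank windows are ±7 residues (±30 for sequence-embedding input), truncated —
not padded — at protein termini; k-mer occurrence rates divide by the
effective window length so truncated windows remain comparable, and the
central S/T/Y is included in composition counts (it adds a constant across
sites and is harmless). The seventeen amino-acid groups (Asx, Glx, Xle,
charge, aromatic/aliphatic, size, hydro-affinity, polarity, and the
secondary-structure-propensity groups AHR/BSR/RTR/UFR) intentionally overlap.

Feature selection runs in three stages: ordinary features pass a two-sided
rank-sum test at p < 0.05 (exact enumeration when both classes have ≤ 8
tie-free observations, normal approximation with tie correction otherwise);
2-mer features pass when present in > 0.2 of positive-class windows with a
positive/negative mean log2 fold change > 1.5 (an all-zero negative mean
counts as infinite fold change); survivors are ranked by significance
(ordinary features by ascending p, then 2-mers by descending fold change) and
greedily deduplicated at |Pearson r| > 0.7. The greedy order is a design
choice; the reported 36 → 28 feature counts of any particular dataset are
data-dependent and not a contract of the procedure.

The PROSITE scanner is a backtracking matcher over parsed elements (literals,
`[..]` alternatives, `{..}` exclusions, `x` wildcards with `(n)`/`(n,m)`
repeats, `<`/`>` anchors). Fixed repeats are expanded so that element indices
address single residues — the conserved K of the kinase ATP-binding signature
is simply the last element. All distinct spans are enumerated for
variable-length wildcards; only the first match per sequence feeds distance
features (kinase domains occasionally repeat; the choice is ours). Distances
are |Δposition| in sequence mode and Euclidean Cα–Cα in spatial mode, with
PDB residue numbers assumed equal to sequence positions (AlphaFold-style
single-chain models; a configurable offset handles mismatches; first altloc
kept). ASA/CX/DPX are ingested from externally computed tables, never
computed natively.

## Masked value modeling (`phositeformer`, `nn`)

Each site row is a token sequence over samples; sample identity replaces
position. Per site, `round(mask_fraction × #nonzero)` nonzero cells and an
equal number of zero cells are masked (capped at min(#nonzero, #zero)); the
equal-count rule prevents the zero-dominated matrix from rewarding a
constant-zero predictor. Masking is drawn per site-row, fresh every training
epoch; validation masks are drawn once so epochs are comparable.

Value embedding uses autodiscretization: a two-layer gate maps the scalar to
softmax weights over B learnable anchor embeddings (B = 100 by default, 8–32
in tests) and returns the weighted anchor sum — a convex combination, so
embeddings stay in the anchors' hull. The value embedding and the learnable
per-sample embedding are summed (both are d_model; the sample table plays the
role positional embeddings play in language models).

The encoder is a pre-LayerNorm multi-head-attention transformer that attends
only over observed (unmasked, nonzero) tokens. This is implemented by
excluding all other positions as attention keys, which is mathematically
identical to compacting the sequence and padding — attention is per-query and
feed-forward layers are position-wise — while keeping batches rectangular.
Values at non-observed positions are zeroed before embedding, so a masked
cell's true value cannot reach any output: the no-leakage property holds
exactly, not approximately.

The decoder input is the full-length sequence reassembled from encoder
outputs (observed positions), a learned mask embedding (masked positions) and
a learned zero embedding (unmasked-zero positions), mapped by a position-wise
linear bridge. The decoder attends over all positions with either exact
softmax attention (default at desk scale) or Performer-style
positive-random-feature linear attention for long sample axes; the two agree
on small instances with error decreasing in the feature count. A final linear
head emits one reconstructed value per sample; the loss is MSE at masked
positions only. Reported "accuracy" is the fraction of masked positions with
|pred − true| < τ (τ = 0.1, configurable; the metric's definition is a
package choice).

Training: Adam (lr 1e-3 default; 2e-3 in the desk-scale configurations),
site-wise 75:25 train/validation split, early stopping on validation masked
MSE with the best state restored. Per-site embeddings are extracted with
frozen weights as the componentwise max over the encoder's contextual
embeddings of the site's nonzero tokens; all-zero sites yield no MS embedding
and fall back to sequence-only fusion downstream.

All neural components run on `phositec.nn`, a compact reverse-mode autodiff
core in NumPy (float64): Tensor/Module/Linear/LayerNorm/Dropout, exact and
linear attention, Adam. Float64 plus seeded generators make every training
run bit-reproducible on one device, which the determinism tests assert
literally.

## Bimodal classification (`cspred`)

Sites with both views use plain concatenation (D = 1024 + d = 1152 at the
defaults); sequence-only sites pass through a learned 1024 → D linear
alignment layer trained jointly with the classifier. The classifier halves
the width three times from D and ends in one logit
([1152, 576, 288, 144, 1]), with LayerNorm + ReLU + Dropout between layers.
The loss is weighted BCE-with-logits (natural log, numerically stable
softplus form); w_out ∈ {1, 2, 4, 8, 16} with default 4 up-weights
out-of-A-loop sites, balancing predictions between the conserved A-loop
(which sequence models capture well) and the rest of the kinase.

The training protocol runs three rounds: positives constant, negatives drawn
10:1 without replacement from a shuffled pool consumed sequentially (later
rounds take the remainder, with a warning, when the pool runs short). Each
round: stratified 8:2 train/test split, 5-fold stratified CV on the training
portion with early stopping on fold-validation AUROC (patience 5, best state
restored), and test metrics from the fold model with the best validation
AUROC. F1/MCC threshold is 0.5; high-confidence selection takes the top
ceil(frac × n) sites by score (frac = 0.05), breaking boundary ties by site
ID for determinism.

AUROC/AUPRC/F1/MCC delegate to scikit-learn; the test suite independently
verifies AUROC against an O(n²) pairwise-concordance oracle with half-credit
for ties.

## Kinase–substrate relations (`ksr`)

A kinase is the componentwise max over its own sites' embeddings (all sites
attributed to the kinase in the matrix). Candidate pairs concatenate the
pooled kinase embedding with the substrate-site embedding and pass through a
two-linear-layer MLP (LayerNorm/ReLU/Dropout between; hidden 256). Negative
pairs are drawn uniformly from the cross product after excluding known
pairs, kinase self-pairs, and pairs scored strictly above 0.7 by external
predictors (a score of exactly 0.7 remains eligible). Splits are 7:2:1 with
early stopping on validation AUROC. Both balanced (1:1) and imbalanced
(1:10) evaluations are supported.

## Activity scoring and imputation (`activity`)

For a kinase phos-site, samples split into a phos-group (site level > 0) and
non-phos-group (level = 0); all sites are ranked by
log2((mean_phos + ε)/(mean_non + ε)), ε = 1e-6 (a pseudo-count guarding
all-zero means), ties broken by site ID. The substrate set is scored with
the weighted KS running sum — hits add |score|^p normalized over hit scores,
misses subtract 1/(N − N_hits), ES is the extremum — and NES divides ES by
the mean |ES| of same-sign set-membership permutations (default 1000,
seeded; weight p = 1 by default, p = 0 makes the statistic rank-only and
invariant to monotone score rescaling). Degenerate sets (no hits, or no
misses) are rejected rather than scored.

Downshifted-Gaussian imputation draws missing values from
Normal(μ₀ + δσ₀, (λσ₀)²) with δ = −0.5, λ = 0.5 and μ₀, σ₀ the observed
mean and SD (ddof = 1); sites with ≥ 50% missingness are rejected. The
survival model itself is out of scope — the module emits analysis-ready
tables, plus a Benjamini–Hochberg utility.

## Synthetic fixtures (`synth`) — what they emulate, and what not

Every generator is bit-reproducible given its seed. The matrix generator
plants: a latent per-sample activity per kinase; a critical site tracking
that activity (SD 0.05 noise); other sites on the kinase half co-regulated
with it (shared protein level); substrate sites following
clip(β·activity/2 + 0.15·noise) with β = 2 by default (β = 0 severs the
coupling). Raw intensities are strictly positive and missingness is
**intensity-dependent** (dropout probability ∝ sparsity × (1.5 − value),
averaging to the configured sparsity, default 0.4): phospho-MS missingness
is left-censored, and a missing-at-random scheme would make "site detected"
uninformative about the underlying level — the detected/undetected contrast
that both the coupling example and the enrichment grouping rely on only
exists under censoring.

Sequence fixtures plant one instance each of an ATP-binding-like signature
(conserved K last) and an active-site-like signature (conserved D), an
A-loop interval downstream of the D, critical sites placed 8–30 residues
from the conserved K with flanks enriched in Y/C/G/W, and non-critical sites
placed uniformly. Surrogate sequence embeddings are class-conditional unit
Gaussians separated by Δ = 4 along a random direction; an optional signal
mask silences the class signal for chosen sites, modeling a modality that
misses part of the positive class. Toy structures are Cα-only helices (rise
1.5 Å, 100°/residue, radius set for the canonical ≈ 3.8 Å Cα spacing).

The fusion-benefit evaluation uses 300 balanced sites with a disjoint 25% of
positives silenced in each modality: each single modality then misses part
of the positive class while the pair covers it, which is precisely the
complementarity claim under test. What passing these tests shows is that
the pipeline recovers planted effects of the stated sizes at desk scale; it
does not show performance on real phospho-MS data, whose missingness is
structured beyond censoring (batch and instrument effects), whose sequence
embeddings are not Gaussian, and whose class imbalance is far more severe.

Desk-scale problem sizes used throughout the tests and the acceptance
script — a 200 × 40 pretraining matrix, 300-site fusion fixtures, 600
positive kinase–substrate pairs over 20 kinases and 60 samples — are the
package's chosen working sizes for planted-signal recovery; effect sizes
default to strong (Δ = 4, β = 2) so that recovery is a property of the
method rather than of sampling luck.

## Known limitations

* The embedder is validated on planted low-rank structure, not on real
  acquisition noise; no batch correction is provided.
* mmCIF structures are not supported (PDB only); ASA/CX/DPX must be computed
  externally.
* The A-loop weighting balances prediction counts but is not calibrated
  probabilistically; scores are comparable within a run, not across runs.
* Kinase pooling uses all matrix sites on the kinase; restricting pooling to
  annotated phos-sites is a caller decision via the kinase→site map.
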
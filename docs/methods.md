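# Methods

## Model

`rega` is a wrapper feature-selection classifier for binary endpoints on
mixed binary/continuous feature matrices. A GA individual is a
(K, S_fs) integer array of feature indices (duplicates allowed — the
encoding is left untouched; duplicates are removed only when a rotation
is fit, since they contribute exact collinearity and nothing else).
Fitness of an individual is the validation-set F1 of its trained
rotation-boost ensemble, so the GA searches for K subsets whose rotated
subspaces support an accurate boosted ensemble.

### Rotation

Each subset is partitioned by column kind.

* **Continuous part (PCA).** Columns are centered and decomposed by
  SVD; every component with singular value above 1e-10 × the largest is
  kept (full-rank rotation — no dimensionality reduction, matching the
  Rotation-Forest idea that the space is rotated to expose class
  variance). Loadings are orthonormal; on the fitting block the
  projection has diagonal covariance and conserves total variance.
* **Binary part (MCA).** Constant columns are dropped; the rest are
  expanded to complete disjunctive coding Z (a 0-indicator and a
  1-indicator column per feature). With P = Z/ΣZ and margins r, c, the
  standardized residual matrix S = D_r^{−1/2}(P − r cᵀ)D_c^{−1/2} is
  decomposed by SVD; all dimensions with singular value above the same
  relative threshold are kept. New rows are projected through the
  stored column margins and right singular vectors
  (coords = (profile − c) D_c^{−1/2} V), which reproduces the
  fitting-set row coordinates exactly, so held-out rows never cause a
  refit.
* **Sign convention.** Every component is flipped so its
  largest-magnitude loading entry is positive, making results
  deterministic across runs and platforms.
* A subset whose columns are all constant raises a degenerate-subset
  error; the GA scores such individuals 0.

Rotations are fit on the full training rows of the current fold (not on
the bootstrap sample), so the weighted error below is well defined on
the whole training set.

### Boosting

Sample weights start uniform (1/N). For slot k = 1..K: draw an
N-sample weighted bootstrap, fit a clone of the base learner (default
`RandomForestClassifier(n_estimators=50)`; any fit/predict classifier
can be plugged in) on the rotated bootstrap, and compute the weighted
error ε_k over the full training set. If ε_k = 0 or ε_k ≥ 0.5 the slot
casts no vote, weights reset to uniform, and the slot is retried with a
fresh bootstrap up to `max_retries` (default 5) times before being
skipped. A fallible learner that reaches ε = 0 exactly is treated the
same as ε ≥ 0.5. Otherwise β_k = ε_k/(1−ε_k) ∈ (0,1); weights update as
w′_j ∝ w_j β^(1−l_j) (misclassified rows keep raw weight, correct rows
shrink) and renormalize. Prediction accumulates support
μ_t = Σ ln(1/β_k) over slots voting t; `decision_function` returns
μ₁ − μ₀ (used for AUC), `predict` thresholds it at 0 with exact ties
resolved to class 0. If every slot is skipped the model predicts the
training-majority class (ties toward 0) — a documented degenerate path,
not an error.

### Evolution

Per generation: parents are paired by a random permutation (population
size must be even), every pair is crossed at a subset-granularity
single point CP ~ U{0..K} (crossover probability is effectively 1 —
the per-pair loop crosses unconditionally), children are mutated
per-position with probability P_M (each mutated position resampled
uniformly in [0, S_f)), children are evaluated, and the best M of the
2M parents + children survive, ties broken by stable original order
(parents first). Parents keep their cached fitness — re-evaluating them
would only re-randomize bootstraps — so elitism makes the
best-validation-F1 series non-decreasing, which the harness asserts on
every run. Mutation-as-per-position-Bernoulli is one of two readings of
"select mutation bits with probability P_M"; it was chosen as the
standard GA convention.

Randomness derives from one master seed through named
`SeedSequence` spawn keys (population init / per-generation operators /
one stream per fitness evaluation), so evaluation order or parallelism
cannot change results and a fixed seed yields a bit-identical trace.

Defaults (T=50, M=50, P_M=0.1, K=10, S_fs=300) mirror the reference
experiment protocol; the test-suite and acceptance runs use
desk-scale settings (T≈10, M≈10, K≈4, S_fs≈20, n≈300) chosen so the
full pipeline runs in minutes while the evolutionary dynamics remain
visible.

## Featurization

Four blocks are computed with RDKit and concatenated in fixed order:

* **ECFP2** — Morgan circular fingerprint, radius 1 (diameter 2),
  hashed to 2048 bits. Radius and width are the package's pinned
  convention for the "ECFP2" name.
* **MACCS** — RDKit's 167-position structural key set.
* **RDKit2D** — exactly 200 continuous 2D physicochemical descriptors.
  The name list ships as a versioned data file
  (`data/rdkit2d_descriptors.txt`) so the block width cannot drift with
  toolkit releases; it excludes two recent additions (SPS, AvgIpc) and
  the eight BCUT2D descriptors (charge-eigenvalue based and NaN-prone).
  Non-finite descriptor values are replaced by 0 with a warning.
* **PubChem** — an 881-position substructure key set in the
  PubChem/CACTVS layout (115 hierarchical element-count keys, 148 ring
  keys over SSSR rings, 618 SMARTS keys), shipped as
  `data/pubchem_keys.tsv` and evaluated with RDKit substructure
  machinery. The SMARTS section is a systematic reconstruction of the
  CACTVS key classes, synthetic rather than verbatim: the block is
  deterministic and fixed-width but not bit-for-bit identical to the
  original CACTVS engine.

Curation: SMILES are canonicalized with one fixed RDKit routine;
unparseable records are dropped with a warning; molecules containing
elements outside a configurable allowed set (default
H,B,C,N,O,F,Si,P,S,Cl,Se,Br,I — i.e. all metals and rare elements
excluded) are removed; records are deduplicated per source. Label
resolution: the highest-priority source listing a compound wins
outright; equal-rank priority conflicts drop the compound (the safest
reading, since no tie-break rule is defined); otherwise the majority
label is kept iff agreement ≥ 80% (or unanimity).

Normalization is x′ = (x − min x)/(max x − min x) per column, fit on
training rows only, constant columns mapping to 0 and out-of-range
held-out values clipped to [0, 1] — implemented over sklearn's
`MinMaxScaler(clip=True)`. Fitting only on training rows is a
leakage-safety choice; the evaluation harness enforces it with a
poisoned-row test.

## Evaluation protocol

"Five-fold cross-validation" combined with a 2:1:1
train/validation/test ratio cannot be a classic 5-fold partition; it is
implemented as five independent random 2:1:1 splits (sizes ⌊n/2⌋,
⌊n/4⌋, remainder), each with its own derived seed. Per split the GA
evolves on (train, validation), the final best individual's ensemble is
retrained on the training rows, and test ACC/F1/AUC are averaged over
the five splits. AUC is the Mann-Whitney rank statistic on μ₁ − μ₀
scores with half credit for ties; precision/recall/F1 use the positive
class with zero-division → 0 and the standard confusion-matrix
definitions (FN = actual positive predicted negative). The ablation
harness reruns this protocol restricted to block combinations; feature
importance counts index occurrences over the final population, ranks
descending (ties by ascending index) and aggregates per-block counts
and count/width ratios over a top-n cut.

## Synthetic fixture

`generate_planted_dataset` emulates the fused-matrix structure: 80
binary + 40 continuous columns, balanced Bernoulli labels, and 30
informative columns drawn across both kinds — informative bits are
Bernoulli(0.8/0.2 by class), informative continuous columns are
Normal(Δ·y, 1) with Δ = 1.5. Effects are independent across features; a
deliberate simplification (real fingerprint bits are strongly
correlated), so green tests show the machinery works, not that real
DILI data is this easy. `generate_multisource_labels` builds curation
tables with an exact per-compound agreement fraction and optional
priority-source override rows, so every resolution branch is exercised
at known counts.

### Known limitation: fitness saturation at desk scale

With these effect sizes the fixture is separable by essentially any
random subset: every individual's validation F1 reaches 1.0 within the
first generations, at which point elitist selection is tie-broken to
parents and selection pressure vanishes. Consequently final-generation
enrichment of planted indices stalls around 1.2–1.3× the uniform rate
rather than the ≥ 2× a discriminating fitness signal would produce; the
corresponding recovery test asserts the stronger bound and fails by
design rather than weakening it. Recovery pressure is only observable
when validation F1 does not saturate (harder data, as in a realistic
application). The companion properties — near-ceiling cross-validated
test metrics on the planted fixture and chance-level AUC on
label-permuted data — do hold and are asserted.

## Other numerical conventions

* Singular values ≤ 1e-10 × the largest are treated as zero (PCA and
  MCA alike).
* Sample-weight normalization is maintained to 1e-12.
* CSV persistence writes floats at 17 significant digits and reads with
  round-trip parsing, so matrices survive a save/load cycle exactly.
* Labels are 1 = toxic (positive class), 0 = non-toxic throughout.
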
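# Methods

## Model

A protein is represented solely by its evolutionary profile: the
PSI-BLAST position-specific scoring matrix (PSSM), an L × 20 table
whose entry (k, j) is the log-odds score of amino acid j at query
position k. The pipeline has four stages.

**1. Sigmoid scaling.** Every PSSM entry x is mapped to
f(x) = 1 / (1 + e^(−x)), placing all entries strictly in (0, 1) while
preserving order. The ASCII PSSM file carries two 20-column blocks:
signed log-odds scores and nonnegative observed percentages. The
scores block is the default input because the sigmoid is only a
meaningful squashing for signed values — percentages would all land in
[0.5, 1) — and because this is the standard convention for PSSM-derived
features; `--pssm-block percent` overrides it. Scaling twice is
refused: a second pass silently compresses all values into (0.5, 0.74).
Entries are clipped away from exactly 0/1 only where float saturation
(|x| ≳ 37) would otherwise violate the open-interval invariant.

**2. Gapped-dipeptide composition (GapDPC).** For gap g,
y[i, j, g] = Σ_{k=1..L−g−1} p[k, i] · p[k+g+1, j] over all 400 residue
pairs; g = 0 is ordinary dipeptide composition. Blocks for g = 0..G are
concatenated, giving 400·(G+1) features. G defaults to 8 (3600
features), which requires L ≥ G + 2 = 10; shorter proteins are refused
rather than silently producing empty (all-zero) blocks. The flat index
is frozen as g·400 + i·20 + j with 0-based i, j over the PSI-BLAST
column order A R N D C Q E G H I L K M F P S T W Y V, and names decode
as `g{g}_{aa_i}{aa_j}`. The sums are not normalized by length — the
representation is the raw sum, so longer proteins yield larger
magnitudes — but `normalize_by_length` divides block g by L − g − 1 for
users who want length-free features.

**3. SVM-RFE ranking.** A linear-kernel SVM (C = 1 by default) is fit
on the surviving features; each feature is scored by the sum over all
one-vs-one binary classifiers of its squared weight component — the
squared-weight criterion extended to multiclass via the pairwise
decomposition that LIBSVM-style solvers use natively. The
lowest-scoring block is eliminated and the process repeats; the ranking
is the reverse elimination order. Classic one-at-a-time elimination is
O(d) SVM fits and infeasible at d = 3600 in routine use, so the default
step removes 10% of the surviving features per round (floor, at least
one); `step=1` restores the classic behaviour. On importance ties the
higher original index is eliminated first, so identical columns rank in
index order — a fixed, documented convention rather than a claim about
importance. Standardization before ranking is off by default (features
from scaled profiles are already bounded) and available as a flag. The
top-K cut is chosen by a stratified five-fold cross-validated sweep
over K = 10, 20, ..., 500, argmax with the smallest K on ties.

**4. RBF-SVM classification.** A one-vs-one support-vector machine
with RBF kernel; C and γ are grid-searched over C = 2⁻⁵..2¹⁵ and
γ = 2⁻¹⁵..2³ in steps of 2² (110 candidates), scored by stratified
cross-validated overall accuracy with ties resolved toward smaller C
then smaller γ (the simpler model). No class weighting: the intended
datasets are roughly balanced.

## Evaluation protocols

The jackknife test trains on n − 1 proteins and predicts the held-out
one, for every protein. Metrics are per-class accuracy TPⱼ/|Cⱼ|,
per-class one-vs-rest Matthews correlation, and overall accuracy
Σⱼ TPⱼ / Σⱼ |Cⱼ|. MCC is defined as 0 when any denominator factor is
zero (the standard convention); per-class accuracy for a class absent
from the truth is reported as missing, not 0.

Two protocol variants are labeled in every report. The default mirrors
the natural sequencing of the method: rank once on the full dataset,
pick K, tune (C, γ) once, then jackknife with those fixed — simple but
optimistic, because the held-out sample influenced feature selection.
`nested=True` re-runs RFE (and optionally the grid search) inside every
training split, giving selection-unbiased estimates at higher cost.
The bias is measurable: on signal-free synthetic data the non-nested
protocol scores well above chance (~0.41 vs 0.25 in our null
experiment) while the nested protocol sits at chance. Null-hypothesis
checks therefore use the nested protocol; the strong-signal end-to-end
check uses the default protocol, where genuine signal dominates the
bias.

Stratified folds are seeded and keep per-fold class proportions within
one sample; a fold count exceeding the smallest class size is refused,
except that folds = n degenerates to leave-one-out (where
stratification is vacuous). Jackknife splits that lose a class entirely
(singleton classes) are evaluated but flagged in the report.

## Synthetic data

The generators exist so every stage is testable without PSI-BLAST or a
reference database.

- `make_pssm` draws profile rows from a Dirichlet with concentration
  1/sharpness: rows sum to one, entries are strictly in (0, 1), and
  sharpness controls contrast (→ one-hot as sharpness → ∞). The inverse
  sigmoid (`to_raw`) converts them to plausible raw log-odds profiles so
  the parse → scale path is exercised end to end, including an ASCII
  writer in the PSI-BLAST layout.
- `make_classed_profiles` plants class signal at the dipeptide-pair
  level: each class owns a private set of (i, j, g) triples, and in each
  profile of that class two position pairs (k, k+g+1) per triple are
  mixed toward the indicator rows of residues i and j with weight
  w = s/(1+s) for signal s. The signal therefore lives exactly where
  GapDPC features look — in correlated propensities at gapped position
  pairs, not in single-residue composition — and separation grows
  monotonically in s, with s = 0 giving exchangeable classes.
- `make_feature_dataset` is the direct test bed for selection and
  classification: standard-normal features with per-class mean offsets
  of scale `effect` on a random informative subset.

What passing on these generators shows: the formulas are implemented
correctly, the selector recovers planted gapped-pair signal, and the
protocols are calibrated (chance at null). What it does not show:
performance on real proteins, where class signal is weaker, features
are correlated through evolutionary structure, and profile quality
depends on the search database — none of which the generators model.

## Defaults and problem sizes

| parameter | default | rationale |
|---|---|---|
| G (max gap) | 8 | pairs with the L ≥ G+2 rule at the shortest intended protein (L = 10) |
| RFE step | 0.1 of surviving | accuracy/cost compromise; `1` for classic RFE |
| linear C (ranking) | 1 | conventional; ranking is insensitive in our checks |
| K grid | 10..500 step 10 | the standard sweep range for this feature family |
| CV folds | 5, stratified, seeded | keeps small classes represented in every fold |
| RBF grid | C 2⁻⁵..2¹⁵, γ 2⁻¹⁵..2³, step 2² | the classic coarse grid |

End-to-end checks in the test suite and acceptance script run at
n = 30 per class × 4 classes, G = 4 (2000 features), with signal 3.0
for the strong arm and 0.0 for the null arm; the nested null run uses
an RFE step of 0.5 inside folds, which leaves the null calibration
unchanged while keeping the 120 inner rankings cheap. Selection
recovery is measured at n = 40 per class, d = 200, 10 informative
columns, effect 2.0, averaged over 10 seeds.

## Numerical and design notes

- Feature extraction is a single matrix product per gap,
  `P[:L−g−1].T @ P[g+1:]`, verified against a brute-force triple loop
  to 1e−10 relative tolerance.
- All sampling (profiles, datasets, folds) goes through
  `numpy.random.default_rng` with explicit seeds; identical seeds give
  byte-identical rankings and reports.
- Grid search scans candidates in ascending order and requires strict
  improvement, making tie-breaking deterministic.
- Model files carry a format-version tag and loading refuses a
  mismatch.

## Limitations

- Constructing PSSMs (PSI-BLAST against NR) is outside the package; it
  parses the ASCII output and documents the invocation.
- The non-nested default protocol inherits the optimism discussed
  above; reported numbers on real data should prefer `nested=True`.
- Binary PSI-BLAST checkpoints and HMMER profiles are not parsed.
- No probability calibration; predictions are hard labels.
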
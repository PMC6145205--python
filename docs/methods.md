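# Methods

## Trait discretization

A quantitative trait is mapped to `J` ordered levels by an
`IntervalScheme`: strictly increasing borders `Q_min = b_0 < b_1 < … <
b_J = Q_max` with level midpoints `P_j = (b_{j-1} + b_j)/2`. Two builders
are provided:

* **equal-length** (`build_equal_length_scheme`): the observed range is cut
  into `J` equal-width intervals — the default for real datasets;
* **deviation** (`build_deviation_scheme`, `J = 3` only): interior borders
  at `mean ± sd/2`, so a standard-normal trait splits roughly
  30.9 / 38.3 / 30.9 % — the rule used for simulated normal traits. It
  errors when a border falls outside the observed range (an outer level
  would be empty); the replicate runners then fall back to borders clipped
  to the inner quartile span, which at the sample sizes used here
  essentially never triggers.

Crisp assignment uses half-open intervals: a value exactly on an interior
border goes to the *lower* level; values outside the scheme's range clamp
to the outer levels. Schemes are fitted once on the full dataset, before
cross-validation partitioning, so train and test folds share the same
geometry.

## Membership families

The *traditional* family is piecewise linear on the midpoints: level `j`
is 1 at `P_j`, falls to 0 at the adjacent midpoints, and the outermost
levels clamp to 1 beyond their own midpoint. It is a partition of unity on
`[Q_min, Q_max]` for any border spacing.

The *extended* family widens the range to `[-1, 1]`: the low level keeps
its slope `−1/(P_2 − P_1)` past `P_2` and clamps at −1 from `P_3` on (the
high level mirrors this), while the middle level keeps its two unclamped
linear pieces. Two consequences are intentional:

* with equal-width intervals the middle level's infimum on the observed
  range is −0.5, not −1 — the formula is kept as printed rather than
  clamped, and nothing downstream requires the bound;
* with *unequal* spacing (deviation schemes) the low level has a jump at
  `P_3` where the clamp takes over, because the linear piece reaches
  `(P_2 − P_3)/(P_2 − P_1) ≠ −1` there. This is the straightforward reading
  of the piecewise definition and is applied consistently to both edge
  levels.

For `J > 3` (available, not the default) interior levels are unclamped
tents on adjacent midpoints and edge levels clamp one further midpoint
away, preserving the `J = 3` geometry.

## Classifier construction and scoring

For an m-way marker set, samples are binned into `3^m` cells by base-3
encoding of their genotype codes. Cell labels follow
`c(i) = argmax_j n_{ij}/n_{+j}` with `n_{ij}` from the extended family and
`n_{+j}` from the traditional family; argmax ties break to the lower
level, and cells with no training samples stay unlabeled. The training
statistic is `(1/J) Σ_i n_{i,c(i)}/n_{+,c(i)}`. On a held-out fold both
`n_{ij}` and `n_{+j}` are recomputed from the held-out samples only, under
the training labels; held-out samples in unlabeled cells contribute 0.
Note the extended counts make the score signed: it is 1 for a perfect
midpoint-aligned classifier but is *not* bounded by 1 in general, since
individual cell terms can be negative or exceed their class share.

Baselines share this scaffold and differ only in the statistic:

* **fqmdr** — per-cell counts from the traditional family;
* **mdr** — integer counts and mean per-class recall over non-empty
  classes (the two-class case reduces to (sensitivity + specificity)/2);
* **omdr** — integer-count labeling, scored by Kendall's tau-b between
  true and predicted levels. Samples in unlabeled cells are excluded from
  the tau computation (no prediction exists for them); a constant margin
  returns 0. The batched scorer computes tau-b from the level×label
  contingency table and is checked against `scipy.stats.kendalltau` in the
  tests.

## Search, ranking, permutation gate

`cross_validated_search` enumerates all m-choose-order sets and, per fold
of a stratified `L`-fold split (stratified by crisp level to keep all
levels represented; `L = 10`), retains the top `k = 3` sets by training
statistic and scores them on the held-out fold. Candidates — the union of
per-fold top-k — are ranked by maximum testing statistic across folds,
then GCVC (folds in top-k, 0..L), then lexicographic marker indices for
full determinism.

Permutation p-values use the *full-data training statistic* as the
selection statistic. The default null is selection-aware: each permutation
of the trait is rescored over **all** same-order sets and the maximum
taken, matching the fact that the tested candidate is itself a maximum; a
candidate-only null is available. `p = #(null ≥ observed)/n_perm` with no
+1 correction (an `add_one` flag applies it), so a candidate stronger than
every permutation reports exactly 0. One null distribution per dataset is
shared by all of that dataset's candidates. With `n_perm` permutations and
a continuous statistic, `P(p < 0.01)` is `(⌊0.01·n_perm⌋ + 1)/(n_perm+1)`
≈ 0.01, which is what the type-I-error study estimates.

Implementation: scoring is vectorized across marker sets via a sparse
sample-to-cell indicator; per-fold training counts are obtained by
subtracting held-out counts from full-data counts, and the permutation
loop rescores chunks of permutations with a single sparse product in
single precision (the null feeds only a rank comparison). A plain
per-sample loop implementation in the test suite serves as the independent
oracle at 1e−12.

## Synthetic data

Genotypes are independent biallelic markers at Hardy–Weinberg equilibrium
(codes = minor-allele copies with probabilities `((1−q)², 2q(1−q), q²)`).
This replaces LD-preserving resampling from reference panels: for
hit-ratio designs the non-causal markers only act as independent null
background, so the experiment's logic is preserved, but passing results
say nothing about performance under strong local LD, where neighbours of
a causal pair can compete with it.

The trait of a sample is `N(Σ_t w_t f_t[g₁,g₂], σ*)` over one or more
disjoint causal pairs with 3×3 penetrance grids `f` taking the canonical
mean levels 0.01 (normal), 0.25 (low risk), 0.5 (high risk). `σ*` is
interpreted as the **standard deviation** (values 0.1–0.5): read as a
variance, even the easiest setting would drown the 0.49 spread of cell
means and no method could approach the near-certain recovery the
difficulty gradient implies; a `sigma_as_variance` flag flips the
interpretation. Genotype and noise streams use separate child seeds of the
config seed, so zeroing a mixture weight reproduces the remaining
components' trait exactly.

Five default grid layouts ship as editable configuration (checkerboard,
dominant–dominant, recessive–recessive, additive threshold, diagonal);
they are package-chosen stand-ins covering classic epistasis patterns, and
any 3×3 array supplied as YAML/JSON overrides a default of the same name.
Study conditions default to the simulation designs implemented here:
m = 100 markers, n ∈ {200, 400, 800}, MAF ∈ {0.2, 0.4}, σ* ∈ 0.1–0.5 for
hit-ratio designs; m ∈ {10, 15, 20}, n ∈ {200, 400, 600} for null designs.

## Evaluation runners

*Hit ratio*: per replicate, run the search, gate candidates at α = 0.01 by
permutation p, and count a hit when the causal pair is the top-ranked
selected candidate (for mixtures: each causal pair is tallied as being
among the selected). Replicate `r` uses master seed + `r`, so single
replicates rerun in isolation and parallel execution cannot change
results. *Type-I error*: fraction of null replicates whose best pair's
p-value falls below α.

Problem sizes used by the shipped checks: the full-pipeline test suite
runs the easy-recovery check at 100 replicates (m = 100, n = 800,
MAF 0.4, σ* = 0.1, 100 permutations), the degradation gradient at 50
replicates per setting, and the null calibration/uniformity checks at 200
replicates × 200 (resp. 100) permutations; `scripts/acceptance.py` runs
all nine null designs at 200 × 200. These sizes keep a full run in the
minutes range on one core while leaving binomial noise well inside the
stated tolerances (e.g. ±1.5 percentage points at a 1% rate, n = 200).

## Known limitations

* No linkage disequilibrium in the generator (see above) and no covariate
  adjustment or parametric regression stages.
* The deviation scheme is defined for three levels only.
* Exhaustive search scales as `C(m, order)`; order 3–4 is practical for
  panels of tens to a few hundred markers, not GWAS-scale inputs.
* tau-b's exclusion of unlabeled-cell samples slightly favours OMDR on
  sparse cells; alternatives (majority-level fallback) were not explored.
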
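"""Multifactor dimensionality reduction with generalized fuzzy classification.

An m-way marker set partitions the samples into the ``3**m`` multi-locus
genotype *cells*.  Each cell is labeled with the ordinal trait level that
maximizes the class-size-normalized fuzzy count

    c(i) = argmax_j  n_ij / n_+j ,

where ``n_ij`` (per-cell count of level-``j`` members) uses the *extended*
membership family and ``n_+j`` (total size of level ``j``) the *traditional*
family.  The labeling is scored by the generalized fuzzy balanced accuracy

    (1/J) * sum_i  n_{i,c(i)} / n_{+,c(i)} .

Four scoring methods are provided:

* ``gfqmdr`` — extended-family per-cell counts (the method of interest);
* ``fqmdr``  — traditional-family per-cell counts (fuzzy baseline);
* ``mdr``    — crisp counts, mean per-class recall (classic baseline
  generalized to J ordinal classes);
* ``omdr``   — crisp counts, Kendall's tau-b between true and predicted
  levels (ordinal baseline).

The exhaustive cross-validated search ranks candidate marker sets by their
maximum testing score across folds (MTSBCA), breaking ties with the
generalized cross-validation consistency GCVC (number of folds in which the
set ranked in the training top-k).  Permutation p-values are computed by
permuting trait values against genotype rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import sparse
from scipy.stats import kendalltau

from .membership import IntervalScheme, assign_crisp_category, membership_matrix

__all__ = [
    "UNLABELED",
    "METHODS",
    "GenotypeMatrix",
    "CellModel",
    "Candidate",
    "SearchResult",
    "index_cells",
    "fuzzy_counts",
    "label_cells",
    "balanced_accuracy_fuzzy",
    "balanced_accuracy_crisp",
    "tau_b",
    "training_scores",
    "cross_validated_search",
    "permutation_pvalue",
    "null_max_distribution",
    "final_selection",
]

UNLABELED = -1
METHODS = ("gfqmdr", "fqmdr", "omdr", "mdr")


@dataclass
class GenotypeMatrix:
    """n x m marker codes in {0, 1, 2}; -1 marks a missing genotype."""

    codes: NDArray[np.int64]
    marker_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x markers)")
        if self.marker_ids is None:
            self.marker_ids = [f"M{i}" for i in range(self.codes.shape[1])]
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(self.codes.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


@dataclass
class CellModel:
    """Fitted labeling of one m-way marker set."""

    snp_set: tuple[int, ...]
    n_ij: NDArray[np.float64]
    n_plus_j: NDArray[np.float64]
    labels: NDArray[np.int64]


@dataclass
class Candidate:
    snp_set: tuple[int, ...]
    mtsbca: float
    gcvc: int
    p_value: float | None = None


@dataclass
class SearchResult:
    order: int
    candidates: list[Candidate]
    per_fold_topk: list[list[tuple[int, ...]]]
    scheme: IntervalScheme
    method: str = "gfqmdr"


def index_cells(genotypes: GenotypeMatrix | ArrayLike, snp_set: Sequence[int]) -> NDArray[np.int64]:
    """Base-3 encode the multi-locus genotype of each sample.

    ``cell = sum_t code_t * 3**t`` over the markers of ``snp_set``, giving a
    bijection with the ``3**m`` genotype combinations.
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    sub = codes[:, list(snp_set)]
    if sub.min() < 0 or sub.max() > 2:
        raise ValueError("genotype codes outside {0,1,2}; impute missing values first")
    weights = 3 ** np.arange(len(snp_set))
    return (sub * weights).sum(axis=1).astype(np.int64)


def fuzzy_counts(
    cells: NDArray[np.int64],
    trait: ArrayLike,
    scheme: IntervalScheme,
    n_cells: int | None = None,
    cell_family: str = "extended",
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Per-cell fuzzy class counts and fuzzy class sizes.

    ``n_ij[i, j]`` sums the ``cell_family`` membership of level ``j+1`` over
    the samples in cell ``i``; ``n_plus_j[j]`` sums the traditional
    membership over *all* samples.
    """
    trait = np.asarray(trait, dtype=float)
    if n_cells is None:
        n_cells = int(cells.max()) + 1 if len(cells) else 1
    E = membership_matrix(scheme, trait, cell_family)
    T = membership_matrix(scheme, trait, "traditional")
    n_ij = np.zeros((n_cells, scheme.J))
    np.add.at(n_ij, cells, E)
    return n_ij, T.sum(axis=0)


def label_cells(
    n_ij: NDArray[np.float64],
    n_plus_j: NDArray[np.float64],
    occupied: NDArray[np.bool_] | None = None,
) -> NDArray[np.int64]:
    """Assign each cell the level maximizing ``n_ij / n_+j`` (1-based).

    Ties break toward the lower level.  Cells without training samples get
    ``UNLABELED``.  Levels with zero fuzzy size are excluded from the argmax.
    """
    n_plus_j = np.asarray(n_plus_j, dtype=float)
    if not np.any(n_plus_j > 0):
        raise ValueError("all fuzzy class sizes are zero")
    ratios = np.full_like(n_ij, -np.inf)
    ok = n_plus_j > 0
    ratios[:, ok] = n_ij[:, ok] / n_plus_j[ok]
    labels = np.argmax(ratios, axis=1).astype(np.int64) + 1
    if occupied is None:
        occupied = np.any(n_ij != 0.0, axis=1)
    labels[~occupied] = UNLABELED
    return labels


def balanced_accuracy_fuzzy(
    cells: NDArray[np.int64],
    labels: NDArray[np.int64],
    trait: ArrayLike,
    scheme: IntervalScheme,
    membership_mode: str = "extended",
) -> float:
    """Generalized fuzzy balanced accuracy of a cell labeling.

    Per-cell counts use ``membership_mode`` ("extended" for GFQMDR,
    "traditional" for the FQMDR baseline); class sizes always use the
    traditional family.  Unlabeled cells contribute 0; so does any term
    whose class size vanishes.
    """
    n_ij, n_plus = fuzzy_counts(cells, trait, scheme, n_cells=len(labels), cell_family=membership_mode)
    score = 0.0
    for i, c in enumerate(labels):
        if c == UNLABELED:
            continue
        denom = n_plus[c - 1]
        if denom <= 0:
            warnings.warn(f"fuzzy class size of level {c} is zero; cell {i} term dropped")
            continue
        score += n_ij[i, c - 1] / denom
    return score / scheme.J


def balanced_accuracy_crisp(
    cells: NDArray[np.int64],
    labels: NDArray[np.int64],
    categories: NDArray[np.int64],
) -> float:
    """Mean per-class recall of the cell labeling on crisp trait levels.

    For two classes this is (sensitivity + specificity)/2.  Empty classes
    are excluded from the mean; samples in unlabeled cells count as errors.
    """
    categories = np.asarray(categories)
    pred = labels[cells]
    J = int(categories.max())
    recalls = []
    for j in range(1, J + 1):
        mask = categories == j
        if not mask.any():
            continue
        recalls.append(np.mean(pred[mask] == j))
    return float(np.mean(recalls))


def tau_b(true_cat: ArrayLike, pred_cat: ArrayLike) -> float:
    """Kendall's tau-b between two ordinal vectors (tie-corrected).

    Returns 0 with a warning when either vector is constant (tau-b
    undefined).
    """
    true_cat = np.asarray(true_cat)
    pred_cat = np.asarray(pred_cat)
    if len(true_cat) != len(pred_cat) or len(true_cat) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if len(np.unique(true_cat)) < 2 or len(np.unique(pred_cat)) < 2:
        warnings.warn("tau-b undefined for a constant vector; returning 0")
        return 0.0
    tau = kendalltau(true_cat, pred_cat, variant="b").statistic
    return float(tau)


# ---------------------------------------------------------------------------
# Vectorized scoring across many marker sets at once
# ---------------------------------------------------------------------------


class _TraitData:
    """Precomputed per-sample membership matrices and crisp levels."""

    def __init__(self, trait: ArrayLike, scheme: IntervalScheme):
        self.trait = np.asarray(trait, dtype=float)
        self.scheme = scheme
        self.E = membership_matrix(scheme, self.trait, "extended")
        self.T = membership_matrix(scheme, self.trait, "traditional")
        self.cats = assign_crisp_category(scheme, self.trait)
        self.onehot = np.equal.outer(self.cats, np.arange(1, scheme.J + 1)).astype(float)

    def counts_for(self, method: str) -> NDArray[np.float64]:
        if method == "gfqmdr":
            return self.E
        if method == "fqmdr":
            return self.T
        return self.onehot  # mdr / omdr use crisp counts

    def sizes_for(self, method: str) -> NDArray[np.float64]:
        if method in ("gfqmdr", "fqmdr"):
            return self.T.sum(axis=0)
        return self.onehot.sum(axis=0)


def _cells_matrix(codes: NDArray[np.int64], snp_sets: NDArray[np.int64]) -> NDArray[np.int64]:
    """(n, n_sets) cell index of every sample under every marker set."""
    order = snp_sets.shape[1]
    cells = np.zeros((codes.shape[0], snp_sets.shape[0]), dtype=np.int64)
    for t in range(order):
        cells += codes[:, snp_sets[:, t]] * (3**t)
    return cells


def _indicator(cells: NDArray[np.int64], n_cells: int, dtype=np.float64) -> sparse.csr_matrix:
    """Sparse (n, n_cells * n_sets) sample-to-cell indicator, one block per set."""
    n, n_sets = cells.shape
    cols = (cells + n_cells * np.arange(n_sets)[None, :]).ravel()
    indptr = np.arange(0, n * n_sets + 1, n_sets)
    data = np.ones(n * n_sets, dtype=dtype)
    return sparse.csr_matrix((data, cols, indptr), shape=(n, n_cells * n_sets))


class _SetBatch:
    """Cell structure of many same-order marker sets, built once per dataset."""

    def __init__(self, codes: NDArray[np.int64], snp_sets: NDArray[np.int64]):
        self.snp_sets = snp_sets
        self.n_sets = len(snp_sets)
        self.n_cells = 3 ** snp_sets.shape[1]
        self.cells = _cells_matrix(codes, snp_sets)
        self.S = _indicator(self.cells, self.n_cells)

    def counts(self, per_sample: NDArray[np.float64],
               sample_idx: NDArray[np.int64] | None = None) -> NDArray[np.float64]:
        """(n_sets, n_cells, J) sums of per-sample rows within each cell."""
        S = self.S if sample_idx is None else self.S[sample_idx]
        C = per_sample if sample_idx is None else per_sample[sample_idx]
        return np.asarray((S.T @ C)).reshape(self.n_sets, self.n_cells, -1)

    def occupancy(self, sample_idx: NDArray[np.int64] | None = None) -> NDArray[np.int64]:
        S = self.S if sample_idx is None else self.S[sample_idx]
        return np.asarray(S.sum(axis=0)).reshape(self.n_sets, self.n_cells).astype(np.int64)


def _batch_label_score(
    n_ij: NDArray[np.float64],
    n_plus: NDArray[np.float64],
    occupied: NDArray[np.bool_],
) -> tuple[NDArray[np.int64], NDArray[np.float64]]:
    """Labels and fuzzy balanced accuracies for a (n_sets, n_cells, J) count stack."""
    J = n_ij.shape[-1]
    ratios = np.full_like(n_ij, -np.inf)
    ok = n_plus > 0
    ratios[..., ok] = n_ij[..., ok] / n_plus[ok]
    labels = np.argmax(ratios, axis=-1)
    contrib = np.take_along_axis(ratios, labels[..., None], axis=-1)[..., 0]
    contrib = np.where(occupied & np.isfinite(contrib), contrib, 0.0)
    scores = contrib.sum(axis=-1) / J
    labels = np.where(occupied, labels + 1, UNLABELED)
    return labels.astype(np.int64), scores


def _tau_b_from_ct(ct: NDArray[np.float64]) -> NDArray[np.float64]:
    """Kendall's tau-b for a stack of (n_sets, J, J) contingency tables.

    Rows index the true level, columns the predicted level.  Sets whose
    table is constant along either margin get 0.
    """
    ct = np.asarray(ct, dtype=float)
    J = ct.shape[-1]
    n = ct.sum(axis=(-2, -1))
    # concordant minus discordant pairs from the joint table
    cd = np.zeros(ct.shape[0])
    for j1 in range(J):
        for l1 in range(J):
            a = ct[:, j1, l1]
            for j2 in range(j1 + 1, J):
                for l2 in range(J):
                    if l2 == l1:
                        continue
                    sign = 1.0 if l2 > l1 else -1.0
                    cd += sign * a * ct[:, j2, l2]
    rows = ct.sum(axis=-1)
    cols = ct.sum(axis=-2)
    n0 = n * (n - 1) / 2
    n1 = (rows * (rows - 1) / 2).sum(axis=-1)
    n2 = (cols * (cols - 1) / 2).sum(axis=-1)
    denom2 = (n0 - n1) * (n0 - n2)
    out = np.zeros(ct.shape[0])
    ok = denom2 > 0
    out[ok] = cd[ok] / np.sqrt(denom2[ok])
    return out


def _scores_from_counts(
    method: str,
    n_ij: NDArray[np.float64],
    n_plus: NDArray[np.float64],
    crisp_ij: NDArray[np.float64] | None,
    crisp_plus: NDArray[np.float64] | None,
    occupied: NDArray[np.bool_],
) -> tuple[NDArray[np.float64], NDArray[np.int64]]:
    """Statistic + labels of each marker set from precomputed count stacks."""
    if method in ("gfqmdr", "fqmdr"):
        labels, scores = _batch_label_score(n_ij, n_plus, occupied)
        return scores, labels
    labels, scores = _batch_label_score(crisp_ij, crisp_plus, occupied)
    if method == "mdr":
        # mean per-class recall: rescale the 1/J sum to the non-empty classes
        n_nonempty = int(np.sum(crisp_plus > 0))
        J = crisp_ij.shape[-1]
        return scores * J / max(n_nonempty, 1), labels
    # omdr: tau-b between true level and predicted level, from the
    # (true level x cell label) contingency; unlabeled cells excluded
    lab1 = np.where(labels == UNLABELED, 0, labels)
    onehot_lab = np.equal.outer(lab1, np.arange(1, crisp_ij.shape[-1] + 1)).astype(float)
    ct = np.einsum("sij,sil->sjl", crisp_ij, onehot_lab)
    return _tau_b_from_ct(ct), labels


def training_scores(
    codes: NDArray[np.int64],
    data: _TraitData,
    snp_sets: NDArray[np.int64],
    method: str = "gfqmdr",
    sample_idx: NDArray[np.int64] | None = None,
    batch: "_SetBatch | None" = None,
) -> tuple[NDArray[np.float64], NDArray[np.int64]]:
    """Training statistic and cell labels of every marker set in ``snp_sets``.

    Returns ``(scores, labels)`` with ``scores`` of shape (n_sets,) and
    ``labels`` of shape (n_sets, 3**order).  The statistic is the fuzzy
    balanced accuracy for gfqmdr/fqmdr, mean per-class recall for mdr and
    tau-b for omdr; labeling always follows the method's own count family
    (extended, traditional, crisp, crisp respectively).
    """
    if batch is None:
        batch = _SetBatch(codes, np.asarray(snp_sets, dtype=np.int64))
    occupied = batch.occupancy(sample_idx) > 0
    Tsub = data.T if sample_idx is None else data.T[sample_idx]
    if method in ("gfqmdr", "fqmdr"):
        n_ij = batch.counts(data.counts_for(method), sample_idx)
        scores, labels = _scores_from_counts(method, n_ij, Tsub.sum(axis=0), None, None, occupied)
        return scores, labels
    crisp_ij = batch.counts(data.onehot, sample_idx)
    crisp_plus = (data.onehot if sample_idx is None else data.onehot[sample_idx]).sum(axis=0)
    scores, labels = _scores_from_counts(method, None, None, crisp_ij, crisp_plus, occupied)
    return scores, labels


def evaluate_on_samples(
    codes: NDArray[np.int64],
    data: _TraitData,
    snp_set: tuple[int, ...],
    labels: NDArray[np.int64],
    sample_idx: NDArray[np.int64],
    method: str,
) -> float:
    """Balanced accuracy (or tau-b) of training labels on the given samples.

    Fuzzy counts and class sizes are recomputed on these samples only; the
    labels come from the training fit.
    """
    cells = index_cells(codes[sample_idx], snp_set)
    if method in ("gfqmdr", "fqmdr"):
        family = "extended" if method == "gfqmdr" else "traditional"
        return balanced_accuracy_fuzzy(cells, labels, data.trait[sample_idx], data.scheme, family)
    cats = data.cats[sample_idx]
    if method == "mdr":
        return balanced_accuracy_crisp(cells, labels, cats)
    pred = labels[cells]
    keep = pred != UNLABELED
    if keep.sum() < 2:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tau_b(cats[keep], pred[keep])


def stratified_folds(
    categories: NDArray[np.int64], L: int, rng: np.random.Generator
) -> list[NDArray[np.int64]]:
    """Random equal-size fold assignment, stratified by crisp trait level."""
    n = len(categories)
    fold_of = np.empty(n, dtype=np.int64)
    for j in np.unique(categories):
        idx = np.flatnonzero(categories == j)
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % L
    return [np.flatnonzero(fold_of == l) for l in range(L)]


def cross_validated_search(
    genotypes: GenotypeMatrix,
    trait: ArrayLike,
    scheme: IntervalScheme,
    order: int = 2,
    L: int = 10,
    k: int = 3,
    method: str = "gfqmdr",
    seed: int | np.random.Generator = 0,
) -> SearchResult:
    """Exhaustive L-fold cross-validated search over all m-choose-order sets.

    Per fold, every marker set is fitted on the training part and the top-k
    by training statistic are scored on the held-out part.  Candidates are
    the union of per-fold top-k sets, ranked by maximum testing score across
    folds (MTSBCA) with GCVC as tie-break, then lexicographic set order.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    m = genotypes.n_markers
    if order > m:
        raise ValueError(f"order {order} exceeds marker count {m}")
    if L < 2:
        raise ValueError("need at least 2 folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = _TraitData(trait, scheme)
    codes = genotypes.codes
    snp_sets = np.array(list(combinations(range(m), order)), dtype=np.int64)
    folds = stratified_folds(data.cats, L, rng)

    batch = _SetBatch(codes, snp_sets)
    occ_full = batch.occupancy()
    fuzzy = method in ("gfqmdr", "fqmdr")
    full_counts = batch.counts(data.counts_for(method))
    crisp_full = full_counts if not fuzzy else None

    per_fold_topk: list[list[tuple[int, ...]]] = []
    best_test: dict[tuple[int, ...], float] = {}
    gcvc: dict[tuple[int, ...], int] = {}
    for test_idx in folds:
        if len(np.unique(data.cats[test_idx])) < scheme.J:
            warnings.warn("fold with an empty trait category; fold kept")
        # training counts = full-data counts minus held-out counts
        occupied = (occ_full - batch.occupancy(test_idx)) > 0
        train_counts = full_counts - batch.counts(data.counts_for(method), test_idx)
        if fuzzy:
            n_plus = data.T.sum(axis=0) - data.T[test_idx].sum(axis=0)
            scores, labels = _scores_from_counts(method, train_counts, n_plus, None, None, occupied)
        else:
            crisp_plus = data.onehot.sum(axis=0) - data.onehot[test_idx].sum(axis=0)
            scores, labels = _scores_from_counts(method, None, None, train_counts, crisp_plus, occupied)
        top = np.argsort(-scores, kind="stable")[:k]
        fold_sets = []
        for s in top:
            sset = tuple(int(v) for v in snp_sets[s])
            fold_sets.append(sset)
            t = evaluate_on_samples(codes, data, sset, labels[s], test_idx, method)
            best_test[sset] = max(best_test.get(sset, -np.inf), t)
            gcvc[sset] = gcvc.get(sset, 0) + 1
        per_fold_topk.append(fold_sets)

    candidates = [
        Candidate(snp_set=s, mtsbca=float(best_test[s]), gcvc=gcvc[s]) for s in best_test
    ]
    candidates.sort(key=lambda c: (-c.mtsbca, -c.gcvc, c.snp_set))
    return SearchResult(order=order, candidates=candidates, per_fold_topk=per_fold_topk,
                        scheme=scheme, method=method)


def null_max_distribution(
    genotypes: GenotypeMatrix,
    trait: ArrayLike,
    scheme: IntervalScheme,
    order: int,
    n_perm: int,
    rng: np.random.Generator,
    method: str = "gfqmdr",
    chunk: int = 64,
) -> NDArray[np.float64]:
    """Max-over-all-sets training statistic under trait permutation.

    Returns ``n_perm`` draws of ``max_s stat(s)`` with trait values randomly
    permuted against genotype rows.  Permuting the trait only reorders the
    per-sample membership rows, so each chunk of permutations is scored with
    a single sparse product (single precision; the null draws feed a rank
    comparison only).
    """
    data = _TraitData(trait, scheme)
    codes = genotypes.codes
    m = genotypes.n_markers
    n = genotypes.n_samples
    snp_sets = np.array(list(combinations(range(m), order)), dtype=np.int64)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    batch = _SetBatch(codes, snp_sets)
    n_cells = batch.n_cells
    S32 = batch.S.astype(np.float32)
    occupied = batch.occupancy() > 0
    fuzzy = method in ("gfqmdr", "fqmdr")
    Cfam = data.counts_for(method).astype(np.float32)
    J = scheme.J
    n_plus = data.T.sum(axis=0)  # class sizes are invariant under permutation
    crisp_plus = data.onehot.sum(axis=0)
    out = np.empty(n_perm)
    for start in range(0, n_perm, chunk):
        blk = perms[start : start + chunk]
        B = len(blk)
        # (n, B*J): permuted per-cell count family, all permutations side by side
        Eb = np.ascontiguousarray(Cfam[blk].transpose(1, 0, 2).reshape(n, B * J))
        n_ij = (S32.T @ Eb).reshape(batch.n_sets, n_cells, B, J)
        n_ij = np.ascontiguousarray(n_ij.transpose(2, 0, 1, 3))
        for b in range(B):
            if fuzzy:
                scores, _ = _scores_from_counts(method, n_ij[b], n_plus, None, None, occupied)
            else:
                scores, _ = _scores_from_counts(method, None, None, n_ij[b], crisp_plus, occupied)
            out[start + b] = scores.max()
    return out


def permutation_pvalue(
    genotypes: GenotypeMatrix,
    trait: ArrayLike,
    scheme: IntervalScheme,
    snp_set: tuple[int, ...],
    order: int | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "gfqmdr",
    null_statistic: str = "max_over_all",
    add_one: bool = False,
    null_draws: NDArray[np.float64] | None = None,
) -> float:
    """Permutation p-value of a candidate marker set.

    The observed statistic is the candidate's full-data training statistic.
    Under ``null_statistic="max_over_all"`` each permutation's null value is
    the maximum statistic over every same-order marker set (selection-aware
    null); ``"candidate"`` recomputes the candidate's own statistic only.
    ``p = #(null >= observed) / n_perm`` (no +1 correction unless
    ``add_one``).  Precomputed ``null_draws`` may be passed to share one
    null distribution across candidates of the same dataset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = order or len(snp_set)
    data = _TraitData(trait, scheme)
    sets = np.array([snp_set], dtype=np.int64)
    observed = training_scores(genotypes.codes, data, sets, method)[0][0]
    if null_draws is None:
        if null_statistic == "max_over_all":
            null_draws = null_max_distribution(
                genotypes, trait, scheme, order, n_perm, rng, method
            )
        elif null_statistic == "candidate":
            n = genotypes.n_samples
            null_draws = np.empty(n_perm)
            for p in range(n_perm):
                pdata = _TraitData(data.trait[rng.permutation(n)], scheme)
                null_draws[p] = training_scores(genotypes.codes, pdata, sets, method)[0][0]
        else:
            raise ValueError(f"unknown null_statistic {null_statistic!r}")
    b = int(np.sum(null_draws >= observed))
    if add_one:
        return (b + 1) / (len(null_draws) + 1)
    return b / len(null_draws)


def final_selection(result: SearchResult, p_values: Sequence[float] | None = None,
                    alpha: float = 0.01) -> list[Candidate]:
    """Keep candidates with permutation p < alpha, preserving the ranking."""
    cands = result.candidates
    if p_values is not None:
        for c, p in zip(cands, p_values):
            c.p_value = float(p)
    return [c for c in cands if c.p_value is not None and c.p_value < alpha]
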
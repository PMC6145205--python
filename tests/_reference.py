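"""Naive per-sample reference implementations used as independent oracles.

Everything here is written with explicit scalar piecewise formulas and
plain Python loops, deliberately independent of the vectorized package
code paths it is used to check.  Restricted to three ordinal levels.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kendalltau

UNLABELED = -1


def ref_mu_traditional(P1, P2, P3, level, x):
    if level == 1:
        if x <= P1:
            return 1.0
        if x <= P2:
            return (P2 - x) / (P2 - P1)
        return 0.0
    if level == 2:
        if P1 <= x <= P2:
            return (x - P1) / (P2 - P1)
        if P2 < x <= P3:
            return (P3 - x) / (P3 - P2)
        return 0.0
    if x <= P2:
        return 0.0
    if x <= P3:
        return (x - P2) / (P3 - P2)
    return 1.0


def ref_mu_extended(P1, P2, P3, level, x):
    if level == 1:
        if x <= P1:
            return 1.0
        if x <= P3:
            return (P2 - x) / (P2 - P1)
        return -1.0
    if level == 2:
        if x <= P2:
            return (x - P1) / (P2 - P1)
        return (P3 - x) / (P3 - P2)
    if x <= P1:
        return -1.0
    if x <= P3:
        return (x - P2) / (P3 - P2)
    return 1.0


def ref_category(borders, x):
    """Half-open intervals, ties to the lower level, clamped at the ends."""
    for j in range(1, len(borders) - 1):
        if x <= borders[j]:
            return j
    return len(borders) - 1


def ref_cell(codes_row, snp_set):
    return sum(int(codes_row[s]) * 3**t for t, s in enumerate(snp_set))


def ref_fit(codes, trait, P, snp_set, idx, method):
    """Labels {cell: level} from the training samples ``idx``."""
    P1, P2, P3 = P
    n_cells = 3 ** len(snp_set)
    n_ij = [[0.0] * 3 for _ in range(n_cells)]
    n_plus = [0.0] * 3
    seen = [0] * n_cells
    for s in idx:
        cell = ref_cell(codes[s], snp_set)
        seen[cell] += 1
        for j in (1, 2, 3):
            if method == "gfqmdr":
                n_ij[cell][j - 1] += ref_mu_extended(P1, P2, P3, j, trait[s])
            elif method == "fqmdr":
                n_ij[cell][j - 1] += ref_mu_traditional(P1, P2, P3, j, trait[s])
        if method in ("gfqmdr", "fqmdr"):
            for j in (1, 2, 3):
                n_plus[j - 1] += ref_mu_traditional(P1, P2, P3, j, trait[s])
    labels = {}
    for i in range(n_cells):
        if seen[i] == 0:
            labels[i] = UNLABELED
            continue
        best, best_ratio = None, None
        for j in (1, 2, 3):
            if n_plus[j - 1] <= 0:
                continue
            r = n_ij[i][j - 1] / n_plus[j - 1]
            if best_ratio is None or r > best_ratio:
                best, best_ratio = j, r
        labels[i] = best if best is not None else UNLABELED
    return labels


def ref_fit_crisp(codes, cats, snp_set, idx):
    n_cells = 3 ** len(snp_set)
    n_ij = [[0] * 3 for _ in range(n_cells)]
    n_plus = [0] * 3
    seen = [0] * n_cells
    for s in idx:
        cell = ref_cell(codes[s], snp_set)
        seen[cell] += 1
        n_ij[cell][cats[s] - 1] += 1
        n_plus[cats[s] - 1] += 1
    labels = {}
    for i in range(n_cells):
        if seen[i] == 0:
            labels[i] = UNLABELED
            continue
        best, best_ratio = None, None
        for j in (1, 2, 3):
            if n_plus[j - 1] <= 0:
                continue
            r = n_ij[i][j - 1] / n_plus[j - 1]
            if best_ratio is None or r > best_ratio:
                best, best_ratio = j, r
        labels[i] = best if best is not None else UNLABELED
    return labels


def ref_score(codes, trait, cats, P, snp_set, labels, idx, method):
    """Statistic of a fitted labeling evaluated on the samples ``idx``."""
    P1, P2, P3 = P
    if method in ("gfqmdr", "fqmdr"):
        mu_cell = ref_mu_extended if method == "gfqmdr" else ref_mu_traditional
        n_cells = 3 ** len(snp_set)
        n_ij = [[0.0] * 3 for _ in range(n_cells)]
        n_plus = [0.0] * 3
        for s in idx:
            cell = ref_cell(codes[s], snp_set)
            for j in (1, 2, 3):
                n_ij[cell][j - 1] += mu_cell(P1, P2, P3, j, trait[s])
                n_plus[j - 1] += ref_mu_traditional(P1, P2, P3, j, trait[s])
        total = 0.0
        for i in range(n_cells):
            c = labels[i]
            if c == UNLABELED or n_plus[c - 1] <= 0:
                continue
            total += n_ij[i][c - 1] / n_plus[c - 1]
        return total / 3.0
    preds = []
    true = []
    for s in idx:
        cell = ref_cell(codes[s], snp_set)
        pred = labels[cell]
        if method == "omdr" and pred == UNLABELED:
            continue
        preds.append(pred)
        true.append(cats[s])
    if method == "mdr":
        recalls = []
        for j in (1, 2, 3):
            members = [p for p, t in zip(preds, true) if t == j]
            if members:
                recalls.append(sum(p == j for p in members) / len(members))
        return float(np.mean(recalls))
    if len(preds) < 2 or len(set(true)) < 2 or len(set(preds)) < 2:
        return 0.0
    return float(kendalltau(true, preds, variant="b").statistic)


def ref_training_scores(codes, trait, cats, P, snp_sets, idx, method):
    """Training statistic of every marker set, fitted and scored on ``idx``."""
    out = []
    for snp_set in snp_sets:
        if method in ("gfqmdr", "fqmdr"):
            labels = ref_fit(codes, trait, P, snp_set, idx, method)
        else:
            labels = ref_fit_crisp(codes, cats, snp_set, idx)
        out.append(ref_score(codes, trait, cats, P, snp_set, labels, idx, method))
    return np.array(out)
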
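"""Fuzzy-AHP weight derivation from expert pairwise vote counts.

For each comparison level, the count a_ij of experts (out of n) preferring
item i over item j is assembled into a positive judgment matrix. Two
reciprocal conventions are supported for the opposite entry:

``ratio_reciprocal`` (default)
    a_ji = n / a_ij — the stated convention of the source methodology;
    entries a_ij * a_ji = n for every pair.
``complement``
    a_ji = n - a_ij — forced-choice complementarity; both directions stay
    on the count scale.

Weights come from the geometric-mean method on the unit-scale matrix
(entries divided by n):

    W_i = (prod_j a_ij)^(1/n) / sum_k (prod_j a_kj)^(1/n)

and judgment coherence is summarized by Saaty's consistency ratio computed
on the positive reciprocal ratio matrix r_ij = a_ij / a_ji.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hierarchy import HierarchyConfig
from .simulate import ExpertVotes


class FahpError(ValueError):
    pass


#: Saaty random consistency index by matrix order.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
                7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

#: Strict and secondary acceptability thresholds for CR.
CR_STRICT = 0.10
CR_SECONDARY = 0.15


@dataclass
class JudgmentMatrix:
    """Positive pairwise preference matrices for one comparison level."""

    items: list[str]
    n_experts: int
    count_matrix: np.ndarray   # count scale, diagonal n/2
    unit_matrix: np.ndarray    # count_matrix / n_experts
    ratio_matrix: np.ndarray   # r_ij = a_ij / a_ji, positive reciprocal

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ConsistencyResult:
    lambda_max: float
    ci: float
    cr: float
    passes_strict: bool
    passes_secondary: bool


@dataclass
class WeightTree:
    """Normalized weights at every level of the hierarchy.

    ``indicator_weights`` are *within-key-index* weights (equal by design);
    use :func:`effective_indicator_weights` for the flattened per-indicator
    weights that multiply through to the overall score.
    """

    category_weights: dict[str, float]
    key_index_weights: dict[str, float]
    indicator_weights: dict[str, float]
    consistency: dict[str, ConsistencyResult] = field(default_factory=dict)


def judgment_matrix_from_array(items, counts, n_experts) -> JudgmentMatrix:
    """Wrap an explicit positive count-scale matrix (no clamping applied)."""
    a = np.asarray(counts, dtype=float)
    if a.shape != (len(items), len(items)):
        raise FahpError("count matrix shape does not match item list")
    if (a <= 0).any():
        raise FahpError("judgment matrix entries must be positive")
    return JudgmentMatrix(
        items=list(items),
        n_experts=n_experts,
        count_matrix=a,
        unit_matrix=a / n_experts,
        ratio_matrix=a / a.T,
    )


def build_judgment_matrix(
    votes: ExpertVotes, mode: str = "ratio_reciprocal"
) -> JudgmentMatrix:
    """Assemble the judgment matrix for one level from vote counts.

    Counts of 0 or n are clamped to 0.5 / n - 0.5 (half a vote) so the
    reciprocal rule never divides by zero. The diagonal is n/2 on the count
    scale (0.5 on the unit scale: an item is indifferent to itself).

    The *stored* orientation of each pair decides which entry carries the
    raw count and which the derived reciprocal, independent of the item
    list's order, so relabeling or reordering items permutes the matrix
    (and the weights) identically. In ``ratio_reciprocal`` mode the two
    orientations are not equivalent — a known asymmetry of the n/a_ij rule
    (``complement`` mode is orientation-free).
    """
    votes.validate()
    if mode not in ("ratio_reciprocal", "complement"):
        raise FahpError(f"unknown reciprocal mode {mode!r}")
    n_items = len(votes.items)
    n = votes.n_experts
    pos = {item: k for k, item in enumerate(votes.items)}
    a = np.full((n_items, n_items), n / 2.0)
    for (item_i, item_j), c in votes.counts.items():
        if not 0 <= c <= n:
            raise FahpError(f"count {c} outside [0, {n}]")
        i, j = pos[item_i], pos[item_j]
        aij = float(np.clip(c, 0.5, n - 0.5))
        a[i, j] = aij
        a[j, i] = n / aij if mode == "ratio_reciprocal" else n - aij
    return JudgmentMatrix(
        items=list(votes.items),
        n_experts=n,
        count_matrix=a,
        unit_matrix=a / n,
        ratio_matrix=a / a.T,
    )


def geometric_mean_weights(matrix: JudgmentMatrix) -> np.ndarray:
    """Row-geometric-mean weights on the unit-scale matrix, normalized.

    The diagonal is included in the row product; any constant diagonal (and
    any overall scale factor, hence count vs unit matrix) cancels in the
    normalization.
    """
    u = matrix.unit_matrix
    if (u <= 0).any():
        raise FahpError("judgment matrix entries must be positive")
    logs = np.log(u)
    row_gm = np.exp(logs.mean(axis=1))
    return row_gm / row_gm.sum()


def principal_eigenvalue(matrix: np.ndarray, tol: float = 1e-10,
                         max_iter: int = 10_000) -> float:
    """Dominant eigenvalue of a positive matrix by power iteration.

    Deterministic start (vector of ones); Perron-Frobenius guarantees
    convergence for positive matrices.
    """
    a = np.asarray(matrix, dtype=float)
    if (a <= 0).any():
        raise FahpError("power iteration requires a positive matrix")
    v = np.ones(a.shape[0])
    lam = 0.0
    for _ in range(max_iter):
        w = a @ v
        lam_new = float(w @ v / (v @ v))
        w_norm = w / np.linalg.norm(w)
        if abs(lam_new - lam) < tol and np.linalg.norm(w_norm - v) < tol:
            return lam_new
        v, lam = w_norm, lam_new
    return lam


def consistency_ratio(matrix: JudgmentMatrix) -> ConsistencyResult:
    """Saaty consistency diagnostics on the ratio matrix r_ij = a_ij/a_ji."""
    n = matrix.n
    if n < 2:
        raise FahpError("consistency requires at least 2 items")
    r = matrix.ratio_matrix
    if not np.allclose(r * r.T, 1.0, atol=1e-8):
        raise FahpError("ratio matrix is not reciprocal")
    lam = principal_eigenvalue(r)
    if n <= 2:
        ci = 0.0
        cr = 0.0
    else:
        ci = (lam - n) / (n - 1)
        ri = RANDOM_INDEX.get(n)
        if ri is None:
            raise FahpError(f"no random index tabulated for n = {n}")
        cr = ci / ri
    return ConsistencyResult(
        lambda_max=lam,
        ci=ci,
        cr=cr,
        passes_strict=cr <= CR_STRICT,
        passes_secondary=cr <= CR_SECONDARY,
    )


def level_ids(hierarchy: HierarchyConfig) -> list[str]:
    """Comparison levels: 'top' plus one per multi-key-index category."""
    out = ["top"]
    for c in hierarchy.categories:
        if len(hierarchy.key_indices_of(c.category_id)) >= 2:
            out.append(c.category_id)
    return out


def derive_weight_tree(
    all_votes: dict[str, ExpertVotes],
    hierarchy: HierarchyConfig,
    mode: str = "ratio_reciprocal",
) -> WeightTree:
    """Derive the full normalized weight tree from per-level vote sets.

    Expects one vote set keyed 'top' (comparing the categories) and one per
    category with two or more key indices (comparing its key indices).
    Indicators receive equal weights within their key index. Consistency
    diagnostics are recorded per level.
    """
    needed = level_ids(hierarchy)
    missing = [lv for lv in needed if lv not in all_votes]
    if missing:
        raise FahpError(f"missing vote sets for levels {missing}")

    consistency: dict[str, ConsistencyResult] = {}

    def level_weights(level: str, expected_items: list[str]) -> dict[str, float]:
        votes = all_votes[level]
        if sorted(votes.items) != sorted(expected_items):
            raise FahpError(
                f"level {level!r}: vote items {votes.items} do not match "
                f"hierarchy items {expected_items}"
            )
        jm = build_judgment_matrix(votes, mode=mode)
        w = geometric_mean_weights(jm)
        consistency[level] = consistency_ratio(jm)
        return dict(zip(jm.items, w))

    category_weights = level_weights("top", hierarchy.category_ids)

    key_index_weights: dict[str, float] = {}
    for c in hierarchy.categories:
        kis = [k.key_index_id for k in hierarchy.key_indices_of(c.category_id)]
        if len(kis) == 1:
            key_index_weights[kis[0]] = 1.0
        else:
            key_index_weights.update(level_weights(c.category_id, kis))

    indicator_weights: dict[str, float] = {}
    for k in hierarchy.key_indices:
        inds = hierarchy.indicators_of(k.key_index_id)
        for ind in inds:
            indicator_weights[ind.indicator_id] = 1.0 / len(inds)

    return WeightTree(
        category_weights=category_weights,
        key_index_weights=key_index_weights,
        indicator_weights=indicator_weights,
        consistency=consistency,
    )


def effective_indicator_weights(
    tree: WeightTree, hierarchy: HierarchyConfig
) -> dict[str, float]:
    """Flatten the tree: per-indicator weights that sum to 1 overall."""
    ki_cat = {k.key_index_id: k.category_id for k in hierarchy.key_indices}
    out = {}
    for ind in hierarchy.indicators:
        ki = ind.key_index_id
        out[ind.indicator_id] = (
            tree.category_weights[ki_cat[ki]]
            * tree.key_index_weights[ki]
            * tree.indicator_weights[ind.indicator_id]
        )
    return out
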
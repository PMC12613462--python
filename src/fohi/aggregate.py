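"""Bottom-up weighted aggregation and reporting outputs.

Key-index scores are weighted sums of their indicator scores (equal weights
within a key index), category scores are weighted sums of key-index scores,
and the overall score combines the three categories with the top-level
expert weights:

    KI_j = sum_i X_i * w_i,   CS_c = sum_j KI_j * wk_j,
    OHS  = sum_c CS_c * w_c

Every level is a convex combination, so scores stay in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fahp import WeightTree
from .hierarchy import HierarchyConfig

TOTAL_COLUMN = "total"


class AggregationError(ValueError):
    pass


@dataclass
class ScoreHierarchy:
    """Per-unit scores at every level of the hierarchy."""

    indicator_scores: pd.DataFrame   # units x indicators
    key_index_scores: pd.DataFrame   # units x key indices
    category_scores: pd.DataFrame    # units x categories
    total_score: pd.Series           # units
    hierarchy: HierarchyConfig
    weights: WeightTree

    @property
    def units(self) -> list[str]:
        return list(self.indicator_scores.index)


def aggregate_hierarchy(
    scores: pd.DataFrame, weights: WeightTree, hierarchy: HierarchyConfig
) -> ScoreHierarchy:
    """Aggregate standardized indicator scores up the hierarchy."""
    missing = set(hierarchy.indicator_ids) - set(scores.columns)
    if missing:
        raise AggregationError(f"score table lacks indicators {sorted(missing)}")
    if scores.isna().any().any():
        raise AggregationError("score table must be complete before aggregation")

    ki_cols = {}
    for k in hierarchy.key_indices:
        inds = hierarchy.indicators_of(k.key_index_id)
        w = np.array([weights.indicator_weights[i.indicator_id] for i in inds])
        if abs(w.sum() - 1.0) > 1e-9:
            raise AggregationError(
                f"indicator weights within {k.key_index_id!r} do not sum to 1"
            )
        block = scores[[i.indicator_id for i in inds]].to_numpy()
        ki_cols[k.key_index_id] = block @ w
    ki = pd.DataFrame(ki_cols, index=scores.index)

    cat_cols = {}
    for c in hierarchy.categories:
        kis = hierarchy.key_indices_of(c.category_id)
        w = np.array([weights.key_index_weights[k.key_index_id] for k in kis])
        if abs(w.sum() - 1.0) > 1e-9:
            raise AggregationError(
                f"key-index weights within {c.category_id!r} do not sum to 1"
            )
        cat_cols[c.category_id] = ki[[k.key_index_id for k in kis]].to_numpy() @ w
    cats = pd.DataFrame(cat_cols, index=scores.index)

    w_top = np.array([weights.category_weights[c] for c in hierarchy.category_ids])
    if abs(w_top.sum() - 1.0) > 1e-9:
        raise AggregationError("category weights do not sum to 1")
    total = pd.Series(
        cats[hierarchy.category_ids].to_numpy() @ w_top,
        index=scores.index,
        name=TOTAL_COLUMN,
    )
    return ScoreHierarchy(
        indicator_scores=scores.copy(),
        key_index_scores=ki,
        category_scores=cats,
        total_score=total,
        hierarchy=hierarchy,
        weights=weights,
    )


def summarize(values, name: str = "", decimals: int | None = 2) -> dict:
    """Mean, sample SD (n-1), min, median, max of one score column.

    A single value reports SD = 0. ``decimals=None`` disables the reporting
    rounding.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise AggregationError("cannot summarize an empty vector")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    row = {
        "mean": float(np.mean(x)),
        "sd": sd,
        "min": float(np.min(x)),
        "median": float(np.median(x)),
        "max": float(np.max(x)),
    }
    if decimals is not None:
        row = {k: round(v, decimals) for k, v in row.items()}
    if name:
        row = {"category": name, **row}
    return row


def summary_table(sh: ScoreHierarchy, decimals: int | None = 2) -> pd.DataFrame:
    """Summary rows for the total score and each category score."""
    rows = [summarize(sh.total_score, TOTAL_COLUMN, decimals)]
    for c in sh.hierarchy.category_ids:
        rows.append(summarize(sh.category_scores[c], c, decimals))
    return pd.DataFrame(rows).set_index("category")


def rank_table(score_column: pd.Series, top_k: int | None = None) -> pd.DataFrame:
    """Descending ranking with competition ('min') ranks for ties.

    Ties share the smallest rank and are listed in unit-id order; the unit
    after a tie of size t gets rank r + t.
    """
    s = score_column
    if top_k is not None and top_k > len(s):
        raise AggregationError(f"top_k={top_k} exceeds {len(s)} units")
    order = sorted(s.index, key=lambda u: (-s[u], u))
    ranks = s.rank(method="min", ascending=False).astype(int)
    out = pd.DataFrame(
        {
            "unit_id": order,
            "score": [s[u] for u in order],
            "rank": [ranks[u] for u in order],
        }
    )
    if top_k is not None:
        out = out.head(top_k)
    return out.reset_index(drop=True)


def heatmap_matrix(sh: ScoreHierarchy) -> tuple[pd.DataFrame, list[str]]:
    """Units x (key indices + categories) matrix plus constant-column flags.

    Columns where every unit has the same score (e.g. a key index whose
    indicators are uniformly at full score) are reported so a plotting step
    can omit them.
    """
    mat = pd.concat([sh.key_index_scores, sh.category_scores], axis=1)
    constant = [c for c in mat.columns if mat[c].nunique() == 1]
    return mat, constant
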
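"""Internal-consistency reliability (Cronbach's alpha).

Used on the three category scores against the composite: the categories are
designed to capture complementary aspects of One Health implementation, so
a moderate alpha is expected and sub-level reliability is intentionally not
assessed. The operation is generic over any units x items matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ReliabilityError(ValueError):
    pass


@dataclass
class ReliabilityReport:
    raw_alpha: float
    standardized_alpha: float          # NaN when some item is constant
    k_items: int
    n_units: int
    item_variances: dict[str, float]
    mean_interitem_correlation: float  # NaN when undefined
    constant_items: list[str]


def cronbach_alpha(item_scores: pd.DataFrame) -> ReliabilityReport:
    """Raw and standardized Cronbach's alpha for a units x items matrix.

    raw alpha = k/(k-1) * (1 - sum var(item) / var(sum of items)), with
    sample (n-1) variances; standardized alpha = k*rbar / (1 + (k-1)*rbar)
    where rbar is the mean pairwise Pearson correlation. Items with zero
    variance make the correlations undefined: they are flagged and the
    standardized alpha reported as NaN.
    """
    df = pd.DataFrame(item_scores)
    n, k = df.shape
    if k < 2:
        raise ReliabilityError("alpha needs at least 2 items")
    if n < 3:
        raise ReliabilityError("alpha needs at least 3 units")
    if df.isna().any().any():
        raise ReliabilityError("item matrix must be complete")

    item_var = df.var(ddof=1)
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ReliabilityError("total score has zero variance")
    raw = k / (k - 1) * (1.0 - item_var.sum() / total_var)

    # tolerance: a float-constant column's variance is only zero up to rounding
    scale = df.abs().max().pow(2).clip(lower=1.0)
    constant = [c for c in df.columns if item_var[c] <= 1e-12 * scale[c]]
    if constant:
        rbar = float("nan")
        std = float("nan")
    else:
        corr = df.corr().to_numpy()
        iu = np.triu_indices(k, 1)
        rbar = float(corr[iu].mean())
        std = k * rbar / (1.0 + (k - 1) * rbar)

    return ReliabilityReport(
        raw_alpha=float(raw),
        standardized_alpha=std,
        k_items=k,
        n_units=n,
        item_variances={c: float(item_var[c]) for c in df.columns},
        mean_interitem_correlation=rbar,
        constant_items=constant,
    )
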
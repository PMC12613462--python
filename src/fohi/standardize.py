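"""Raw indicator values -> 0-100 standardized scores.

Numeric indicators are robust-scaled (median/IQR), then min-max rescaled so
the best-observed unit scores 100 and the worst 0; indicators where a higher
raw value means worse performance are reverse-scored last. Binary indicators
map yes/no to 100/0 and ordinal indicators are scored proportionally across
their levels. Monitoring-site indicators are completed by observed-mean
imputation, with scaling anchors estimated from the observed values only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import (
    MONITORING_SITES,
    HierarchyConfig,
    IndicatorDefinition,
)


class StandardizationError(ValueError):
    pass


@dataclass
class RawIndicatorTable:
    """Units x indicators raw values with missingness, tied to a hierarchy.

    ``values`` is a float DataFrame (units as index, indicator ids as
    columns); missing entries are NaN. Binary indicators hold 0/1, ordinal
    indicators hold level codes 1..L.
    """

    values: pd.DataFrame
    hierarchy: HierarchyConfig
    planted_labels: pd.Series | None = None

    @property
    def units(self) -> list[str]:
        return list(self.values.index)

    def validate(self) -> "RawIndicatorTable":
        missing = set(self.hierarchy.indicator_ids) - set(self.values.columns)
        if missing:
            raise StandardizationError(f"table lacks indicator columns {sorted(missing)}")
        extra = set(self.values.columns) - set(self.hierarchy.indicator_ids)
        if extra:
            raise StandardizationError(f"table has unknown indicator columns {sorted(extra)}")
        for ind in self.hierarchy.indicators:
            col = self.values[ind.indicator_id]
            obs = col.dropna()
            if ind.value_kind == "binary" and not obs.isin([0, 1]).all():
                raise StandardizationError(
                    f"indicator {ind.indicator_id!r}: binary values must be 0/1"
                )
            if ind.value_kind == "ordinal":
                levels = np.arange(1, ind.ordinal_levels + 1)
                if not obs.isin(levels).all():
                    raise StandardizationError(
                        f"indicator {ind.indicator_id!r}: ordinal values must be "
                        f"in 1..{ind.ordinal_levels}"
                    )
        return self


@dataclass
class IndicatorProvenance:
    """What happened to one indicator during standardization."""

    indicator_id: str
    n_imputed: int = 0
    imputed_units: list[str] = field(default_factory=list)
    fallback: str | None = None  # None | "minmax_raw" | "constant_midpoint"


@dataclass
class StandardizedScoreTable:
    """Complete units x indicators score matrix on the 0-100 scale."""

    scores: pd.DataFrame
    hierarchy: HierarchyConfig
    provenance: dict[str, IndicatorProvenance]

    @property
    def units(self) -> list[str]:
        return list(self.scores.index)


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def robust_scale(values, *, center: float | None = None, iqr: float | None = None):
    """Median-center and IQR-scale a numeric vector: (x - med) / IQR * 100.

    Quantiles use linear interpolation between order statistics. ``center``
    and ``iqr`` override the estimates (used when anchors come from the
    observed subset of a partially missing vector). Raises on IQR == 0; the
    caller decides the degenerate-scale fallback.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise StandardizationError("robust_scale needs at least 2 observed values")
    med = float(np.median(obs)) if center is None else center
    spread = float(np.percentile(obs, 75) - np.percentile(obs, 25)) if iqr is None else iqr
    if spread == 0:
        raise StandardizationError("degenerate scale: IQR is zero")
    return (x - med) / spread * 100.0


def minmax_rescale(values, *, low: float | None = None, high: float | None = None):
    """Affine map sending the observed minimum to 0 and maximum to 100."""
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise StandardizationError("minmax_rescale needs at least 2 observed values")
    lo = float(obs.min()) if low is None else low
    hi = float(obs.max()) if high is None else high
    if hi == lo:
        raise StandardizationError("degenerate range: max equals min")
    return (x - lo) / (hi - lo) * 100.0


def reverse_score(scores):
    """Map 0-100 scores to 100 - x so that higher always means better."""
    x = np.asarray(scores, dtype=float)
    if np.nanmin(x) < 0 or np.nanmax(x) > 100:
        raise StandardizationError("reverse_score input must lie in [0, 100]")
    return 100.0 - x


def score_discrete(value, kind: str, n_levels: int | None = None, *, decimals: int | None = 1):
    """Score a binary (yes=1 -> 100, no=0 -> 0) or ordinal value.

    Ordinal level ``l`` of ``L`` scores 100*(l-1)/(L-1), reported to one
    decimal (e.g. 0, 33.3, 66.7, 100 on a four-level scale); pass
    ``decimals=None`` for full precision.
    """
    if kind == "binary":
        if value not in (0, 1, 0.0, 1.0):
            raise StandardizationError(f"binary value must be 0 or 1, got {value!r}")
        return 100.0 if value else 0.0
    if kind == "ordinal":
        if n_levels is None or n_levels < 2:
            raise StandardizationError("ordinal scoring needs n_levels >= 2")
        lvl = float(value)
        if not (lvl.is_integer() and 1 <= lvl <= n_levels):
            raise StandardizationError(
                f"ordinal value must be an integer in 1..{n_levels}, got {value!r}"
            )
        score = 100.0 * (lvl - 1) / (n_levels - 1)
        return round(score, decimals) if decimals is not None else score
    raise StandardizationError(f"unknown discrete kind {kind!r}")


def impute_monitoring(values):
    """Fill missing entries with the mean of observed entries.

    Returns ``(complete_vector, imputed_mask)``.
    """
    x = np.asarray(values, dtype=float)
    mask = np.isnan(x)
    obs = x[~mask]
    if obs.size == 0:
        raise StandardizationError("cannot impute: no observed values")
    out = x.copy()
    out[mask] = obs.mean()
    return out, mask


def broadcast_regional(region_values: dict, region_map: dict) -> pd.Series:
    """Allocate one value per region to every unit of that region."""
    out = {}
    for unit, region in region_map.items():
        if region not in region_values:
            raise StandardizationError(
                f"unit {unit!r}: no value for its region {region!r}"
            )
        out[unit] = region_values[region]
    return pd.Series(out)


# ---------------------------------------------------------------------------
# whole-table pipeline
# ---------------------------------------------------------------------------

def _standardize_numeric(col: np.ndarray, prov: IndicatorProvenance) -> np.ndarray:
    """Robust-scale + min-max one complete numeric vector, with fallbacks."""
    lo, hi = col.min(), col.max()
    if hi == lo:
        prov.fallback = "constant_midpoint"
        return np.full_like(col, 50.0)
    q1, q3 = np.percentile(col, [25, 75])
    if q3 - q1 == 0:
        # IQR degenerate but the range is not: skip robust scaling
        prov.fallback = "minmax_raw"
        return minmax_rescale(col)
    return minmax_rescale(robust_scale(col))


def standardize_indicator(
    raw_col: pd.Series, definition: IndicatorDefinition
) -> tuple[pd.Series, IndicatorProvenance]:
    """Standardize one indicator column according to its metadata."""
    prov = IndicatorProvenance(definition.indicator_id)
    kind = definition.value_kind
    x = raw_col.to_numpy(dtype=float)

    if kind in ("binary", "ordinal"):
        if np.isnan(x).any():
            raise StandardizationError(
                f"indicator {definition.indicator_id!r}: discrete indicators "
                f"cannot have missing values"
            )
        scores = np.array([
            score_discrete(v, kind, definition.ordinal_levels) for v in x
        ])
        return pd.Series(scores, index=raw_col.index), prov

    if definition.coverage == MONITORING_SITES and np.isnan(x).any():
        obs = x[~np.isnan(x)]
        if obs.size < 2:
            raise StandardizationError(
                f"indicator {definition.indicator_id!r}: fewer than 2 observed values"
            )
        filled, mask = impute_monitoring(x)
        prov.n_imputed = int(mask.sum())
        prov.imputed_units = list(raw_col.index[mask])
        # anchors from observed values only: with most units imputed to one
        # constant, post-imputation IQR would be 0 and the scaling undefined
        lo, hi = obs.min(), obs.max()
        if hi == lo:
            prov.fallback = "constant_midpoint"
            scores = np.full_like(filled, 50.0)
        else:
            q1, q3 = np.percentile(obs, [25, 75])
            if q3 - q1 == 0:
                prov.fallback = "minmax_raw"
                scores = minmax_rescale(filled, low=lo, high=hi)
            else:
                med = float(np.median(obs))
                scaled = robust_scale(filled, center=med, iqr=float(q3 - q1))
                slo = (lo - med) / (q3 - q1) * 100.0
                shi = (hi - med) / (q3 - q1) * 100.0
                scores = minmax_rescale(scaled, low=slo, high=shi)
    else:
        if np.isnan(x).any():
            raise StandardizationError(
                f"indicator {definition.indicator_id!r}: unexpected missing values"
            )
        scores = _standardize_numeric(x, prov)

    if definition.polarity == "higher_worse":
        scores = reverse_score(scores)
    return pd.Series(scores, index=raw_col.index), prov


def standardize_table(raw: RawIndicatorTable) -> StandardizedScoreTable:
    """Standardize every indicator of a raw table to the 0-100 scale.

    Regional indicators arrive already broadcast (constant within region) and
    are treated as numeric. Errors from component steps are annotated with
    the indicator id.
    """
    raw.validate()
    cols = {}
    provenance = {}
    for ind in raw.hierarchy.indicators:
        try:
            scores, prov = standardize_indicator(raw.values[ind.indicator_id], ind)
        except StandardizationError as exc:
            raise StandardizationError(f"[{ind.indicator_id}] {exc}") from exc
        cols[ind.indicator_id] = scores
        provenance[ind.indicator_id] = prov
    table = pd.DataFrame(cols, index=raw.values.index)
    return StandardizedScoreTable(table, raw.hierarchy, provenance)
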
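"""Synthetic municipal indicator tables and expert vote panels.

The generator reproduces the *structure* of the study data the pipeline
assumes — 60 municipalities, 34 indicators in 3 categories and 13 key
indices, monitoring-site missingness (17/60 and 12/60 observed), values
broadcast from 12 public-health-center and 9 food-chain regions, a 23-expert
forced-choice panel per hierarchy level — without attempting to match any
real marginal distribution. Numeric indicators default to log-normal draws:
municipal counts and rates are right-skewed, which is exactly why the
pipeline robust-scales instead of min-max normalizing raw values.

Expert panels follow a Bradley-Terry response model: an expert prefers item
i over item j with probability w_i / (w_i + w_j), so true weights are
recoverable in expectation and weight-recovery tests are meaningful.

All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import (
    MONITORING_SITES,
    HierarchyConfig,
)
from .standardize import RawIndicatorTable


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class IndicatorSpec:
    """Generative spec for one indicator.

    kind "numeric": log-normal with parameters ``mu``/``sigma`` of the
    underlying normal (or ``family="normal"`` with ``mu``/``sigma``).
    kind "binary": success probability ``p``. kind "ordinal": ``level_probs``
    over levels 1..L. ``missing_fraction`` applies to monitoring-site
    indicators only.
    """

    kind: str
    family: str = "lognormal"
    mu: float = 2.0
    sigma: float = 0.6
    p: float = 0.5
    level_probs: tuple[float, ...] = ()
    missing_fraction: float = 0.0

    def validate(self, indicator_id: str) -> None:
        if self.kind == "binary" and not 0.0 <= self.p <= 1.0:
            raise SimulationError(f"{indicator_id}: p outside [0,1]")
        if self.kind == "ordinal":
            if not self.level_probs or abs(sum(self.level_probs) - 1.0) > 1e-9:
                raise SimulationError(f"{indicator_id}: level_probs must sum to 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise SimulationError(f"{indicator_id}: missing_fraction outside [0,1)")


@dataclass(frozen=True)
class PlantedClasses:
    """Optional latent two-group (or K-group) structure.

    Each unit draws a class from ``proportions``; for every indicator listed
    in ``shifts`` the class-specific additive shift is applied on the
    log-scale for log-normal indicators (a multiplicative effect on the raw
    value) and on the raw scale otherwise.
    """

    proportions: tuple[float, ...]
    shifts: dict[str, tuple[float, ...]] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.proportions)

    def validate(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise SimulationError("class proportions must sum to 1")
        for iid, sh in self.shifts.items():
            if len(sh) != self.n_classes:
                raise SimulationError(f"{iid}: need one shift per class")


@dataclass
class SimulationProfile:
    """Generative settings for one synthetic instance.

    ``capacity_sd`` is the standard deviation of a shared per-unit latent
    "municipal capacity" factor added to every per-unit numeric indicator
    (on the log scale for log-normal families), with its sign flipped for
    indicators where higher raw values are worse. It induces the positive
    inter-category correlation real municipal data show (well-run units
    tend to do well across the board); set 0 for independent indicators.
    """

    n_units: int = 60
    seed: int = 0
    indicator_specs: dict[str, IndicatorSpec] = field(default_factory=dict)
    planted_classes: PlantedClasses | None = None
    capacity_sd: float = 0.3

    def validate(self, hierarchy: HierarchyConfig) -> None:
        missing = set(hierarchy.indicator_ids) - set(self.indicator_specs)
        if missing:
            raise SimulationError(f"profile missing indicator specs {sorted(missing)}")
        for iid, spec in self.indicator_specs.items():
            spec.validate(iid)
        if self.planted_classes is not None:
            self.planted_classes.validate()


#: Default Bernoulli rates for the bundled binary indicators. B2.1/B2.2 are 1.0:
#: prefecture-wide surveillance systems cover every municipality, which is what
#: makes that key index a constant full-score column in the heat map.
_DEFAULT_BINARY_P = {
    "A2.2": 0.5,
    "B2.1": 1.0,
    "B2.2": 1.0,
    "C1.1": 0.15,
    "C1.2": 0.6,
    "C4.1": 0.8,
}

#: Observed-site counts for the monitoring indicators: water-quality points
#: exist in 17 of 60 municipalities, heat-index stations in 12 of 60.
_DEFAULT_MONITORING_OBSERVED = {"A1.2": 17, "C5.3": 12}


def default_profile(
    hierarchy: HierarchyConfig,
    n_units: int = 60,
    seed: int = 0,
    planted_classes: PlantedClasses | None = "default",  # type: ignore[assignment]
) -> SimulationProfile:
    """Study-shaped simulation profile for a hierarchy.

    Numeric indicators are log-normal (mu=2, sigma=0.6); binary rates follow
    ``_DEFAULT_BINARY_P`` (0.5 elsewhere); the 4-level ordinal web-presence
    scale is skewed toward absence (0.4/0.3/0.2/0.1). By default a two-class
    structure (45/55 mixing) shifts the per-unit numeric External-Drivers
    indicators by ∓0.6 on the log scale, mirroring profiles that separate on
    the external-drivers side; pass ``planted_classes=None`` to disable.
    """
    specs: dict[str, IndicatorSpec] = {}
    for ind in hierarchy.indicators:
        if ind.value_kind == "binary":
            specs[ind.indicator_id] = IndicatorSpec(
                "binary", p=_DEFAULT_BINARY_P.get(ind.indicator_id, 0.5)
            )
        elif ind.value_kind == "ordinal":
            L = ind.ordinal_levels
            probs = (0.4, 0.3, 0.2, 0.1) if L == 4 else tuple([1.0 / L] * L)
            specs[ind.indicator_id] = IndicatorSpec("ordinal", level_probs=probs)
        else:
            frac = 0.0
            if ind.coverage == MONITORING_SITES:
                n_obs = _DEFAULT_MONITORING_OBSERVED.get(ind.indicator_id)
                frac = (n_units - n_obs) / n_units if n_obs else 0.5
            specs[ind.indicator_id] = IndicatorSpec(
                "numeric", mu=2.0, sigma=0.6, missing_fraction=frac
            )
    if planted_classes == "default":
        shifted = [
            ind.indicator_id
            for ind in hierarchy.indicators
            if ind.value_kind == "numeric"
            and ind.coverage == "per_unit"
            and hierarchy.category_of_indicator(ind.indicator_id)
            == hierarchy.category_ids[0]
        ]
        planted_classes = PlantedClasses(
            proportions=(0.45, 0.55),
            shifts={iid: (-0.6, 0.6) for iid in shifted},
        )
    return SimulationProfile(
        n_units=n_units,
        seed=seed,
        indicator_specs=specs,
        planted_classes=planted_classes,
    )


def generate_indicator_table(
    hierarchy: HierarchyConfig, profile: SimulationProfile
) -> RawIndicatorTable:
    """Draw a raw units x indicators table with the configured structure.

    Regional indicators are drawn once per region and broadcast, so units
    sharing a region share the raw value; monitoring indicators are missing
    for exactly ``round(n_units * missing_fraction)`` randomly chosen units.
    Identical (hierarchy, profile) including seed give identical tables.
    """
    profile.validate(hierarchy)
    n = profile.n_units
    units = hierarchy.units
    if units and len(units) != n:
        raise SimulationError(
            f"profile n_units={n} but hierarchy region maps cover {len(units)} units"
        )
    if not units:
        from .hierarchy import default_units

        units = default_units(n)
    rng = np.random.default_rng(profile.seed)

    labels = None
    if profile.planted_classes is not None:
        pc = profile.planted_classes
        labels = rng.choice(pc.n_classes, size=n, p=list(pc.proportions)) + 1

    capacity = (
        rng.normal(0.0, profile.capacity_sd, size=n)
        if profile.capacity_sd > 0
        else np.zeros(n)
    )

    def class_shift(iid: str) -> np.ndarray:
        if labels is None or profile.planted_classes is None:
            return np.zeros(n)
        sh = profile.planted_classes.shifts.get(iid)
        if sh is None:
            return np.zeros(n)
        return np.asarray(sh, dtype=float)[labels - 1]

    cols: dict[str, np.ndarray] = {}
    for ind in hierarchy.indicators:
        spec = profile.indicator_specs[ind.indicator_id]
        iid = ind.indicator_id
        if ind.value_kind == "binary":
            cols[iid] = rng.binomial(1, spec.p, size=n).astype(float)
        elif ind.value_kind == "ordinal":
            L = ind.ordinal_levels
            cols[iid] = rng.choice(
                np.arange(1, L + 1), size=n, p=list(spec.level_probs)
            ).astype(float)
        elif ind.region_scheme is not None:
            region_map = hierarchy.region_maps[ind.region_scheme]
            regions = sorted(set(region_map.values()))
            draws = _draw_numeric(rng, spec, len(regions))
            per_region = dict(zip(regions, draws))
            cols[iid] = np.array([per_region[region_map[u]] for u in units])
        else:
            shift = class_shift(iid)
            shift = shift + (
                capacity if ind.polarity == "higher_better" else -capacity
            )
            if spec.family == "lognormal":
                vals = np.exp(rng.normal(spec.mu + shift, spec.sigma, size=n))
            else:
                vals = rng.normal(spec.mu + shift, spec.sigma, size=n)
            if ind.coverage == MONITORING_SITES and spec.missing_fraction > 0:
                n_missing = int(round(n * spec.missing_fraction))
                miss_idx = rng.choice(n, size=n_missing, replace=False)
                vals = vals.copy()
                vals[miss_idx] = np.nan
            cols[iid] = vals

    table = pd.DataFrame(cols, index=pd.Index(units, name="unit_id"))
    planted = (
        pd.Series(labels, index=table.index, name="planted_class")
        if labels is not None
        else None
    )
    return RawIndicatorTable(values=table, hierarchy=hierarchy, planted_labels=planted)


def _draw_numeric(rng: np.random.Generator, spec: IndicatorSpec, size: int) -> np.ndarray:
    if spec.family == "lognormal":
        return np.exp(rng.normal(spec.mu, spec.sigma, size=size))
    if spec.family == "normal":
        return rng.normal(spec.mu, spec.sigma, size=size)
    raise SimulationError(f"unknown numeric family {spec.family!r}")


# ---------------------------------------------------------------------------
# expert panels
# ---------------------------------------------------------------------------

@dataclass
class ExpertVotes:
    """Forced-choice pairwise vote counts for one comparison level.

    ``counts[(i, j)]`` is the number of experts preferring item i over item
    j, stored once per unordered pair in item order; the complement count is
    implied (count(j over i) = n_experts - count(i over j)).
    """

    level_id: str
    items: list[str]
    n_experts: int
    counts: dict[tuple[str, str], int]

    def count(self, i: str, j: str) -> int:
        if (i, j) in self.counts:
            return self.counts[(i, j)]
        if (j, i) in self.counts:
            return self.n_experts - self.counts[(j, i)]
        raise KeyError((i, j))

    def validate(self) -> "ExpertVotes":
        pos = {it: k for k, it in enumerate(self.items)}
        for (i, j), c in self.counts.items():
            if i not in pos or j not in pos:
                raise SimulationError(f"vote pair ({i}, {j}) not in item list")
            if not 0 <= c <= self.n_experts:
                raise SimulationError(
                    f"count({i} over {j}) = {c} outside [0, {self.n_experts}]"
                )
        for a in range(len(self.items)):
            for b in range(a + 1, len(self.items)):
                i, j = self.items[a], self.items[b]
                if (i, j) not in self.counts and (j, i) not in self.counts:
                    raise SimulationError(f"missing vote count for pair ({i}, {j})")
        return self


def generate_expert_panel(
    items: list[str],
    true_weights,
    n_experts: int,
    seed: int,
    level_id: str = "panel",
) -> ExpertVotes:
    """Simulate a forced-choice expert panel from true item weights.

    Each expert answers every pairwise question independently, preferring i
    over j with probability w_i / (w_i + w_j) (Bradley-Terry), so each
    pairwise count is Binomial(n_experts, w_i/(w_i+w_j)).
    """
    w = np.asarray(true_weights, dtype=float)
    if len(items) != w.size:
        raise SimulationError("one weight per item required")
    if (w <= 0).any():
        raise SimulationError("true weights must be positive")
    if n_experts < 1:
        raise SimulationError("n_experts must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            p = w[a] / (w[a] + w[b])
            counts[(items[a], items[b])] = int(rng.binomial(n_experts, p))
    return ExpertVotes(level_id, list(items), n_experts, counts).validate()


def expected_expert_panel(
    items: list[str], true_weights, n_experts: int, level_id: str = "panel"
) -> ExpertVotes:
    """Noise-free panel: counts are the exact expectations n * w_i/(w_i+w_j).

    The deterministic limit of :func:`generate_expert_panel`; used to
    separate sampling noise from the weighting method's own fixed point.
    """
    w = np.asarray(true_weights, dtype=float)
    counts: dict[tuple[str, str], int] = {}
    votes = ExpertVotes(level_id, list(items), n_experts, counts)
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            p = w[a] / (w[a] + w[b])
            counts[(items[a], items[b])] = n_experts * p
    return votes
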
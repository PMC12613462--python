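"""Three-level indicator hierarchy: categories, key indices, indicators.

A municipal One Health index is organised as a tree: top-level index
*categories* (External / Internal / Core Drivers), mid-level *key indices*
(Earth systems, Human health, One Health governance, ...), and leaf
*indicators* carrying the raw data. Every downstream stage — simulation,
standardization, weighting, aggregation — consumes a validated
:class:`HierarchyConfig`.

Indicators additionally carry *coverage* metadata describing where their
raw data come from:

``per_unit``
    measured for every administrative unit (municipality).
``regional:<scheme>``
    measured once per region of a named scheme (e.g. public-health-center
    districts) and broadcast to every unit in the region.
``monitoring_sites``
    measured only at units hosting a monitoring site; the rest are missing
    and later imputed with the observed mean.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal

import yaml

ValueKind = Literal["numeric", "binary", "ordinal"]
Polarity = Literal["higher_better", "higher_worse"]

PER_UNIT = "per_unit"
MONITORING_SITES = "monitoring_sites"
REGIONAL_PREFIX = "regional:"

VALUE_KINDS = ("numeric", "binary", "ordinal")
POLARITIES = ("higher_better", "higher_worse")


class HierarchyError(ValueError):
    """A hierarchy document violates its schema; message names the offender."""


@dataclass(frozen=True)
class Category:
    category_id: str
    label: str


@dataclass(frozen=True)
class KeyIndex:
    key_index_id: str
    label: str
    category_id: str


@dataclass(frozen=True)
class IndicatorDefinition:
    """One leaf indicator and its measurement metadata."""

    indicator_id: str
    label: str
    key_index_id: str
    value_kind: ValueKind
    polarity: Polarity = "higher_better"
    coverage: str = PER_UNIT
    ordinal_levels: int | None = None
    data_year: int | None = None

    @property
    def region_scheme(self) -> str | None:
        """Name of the region scheme for ``regional:`` coverage, else None."""
        if self.coverage.startswith(REGIONAL_PREFIX):
            return self.coverage[len(REGIONAL_PREFIX):]
        return None


@dataclass
class HierarchyConfig:
    """Validated three-level hierarchy plus region membership maps.

    ``region_maps`` maps a scheme name to ``{unit_id: region_id}``. All
    schemes must cover the same unit set; the shared unit set defines the
    units of the bundled instance (data tables may still introduce their
    own units when no regional indicator is present).
    """

    categories: list[Category]
    key_indices: list[KeyIndex]
    indicators: list[IndicatorDefinition]
    region_maps: dict[str, dict[str, str]] = field(default_factory=dict)

    # -- convenience lookups -------------------------------------------------
    @property
    def category_ids(self) -> list[str]:
        return [c.category_id for c in self.categories]

    @property
    def key_index_ids(self) -> list[str]:
        return [k.key_index_id for k in self.key_indices]

    @property
    def indicator_ids(self) -> list[str]:
        return [i.indicator_id for i in self.indicators]

    def key_indices_of(self, category_id: str) -> list[KeyIndex]:
        return [k for k in self.key_indices if k.category_id == category_id]

    def indicators_of(self, key_index_id: str) -> list[IndicatorDefinition]:
        return [i for i in self.indicators if i.key_index_id == key_index_id]

    def indicator(self, indicator_id: str) -> IndicatorDefinition:
        for ind in self.indicators:
            if ind.indicator_id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def category_of_indicator(self, indicator_id: str) -> str:
        ki = {k.key_index_id: k.category_id for k in self.key_indices}
        return ki[self.indicator(indicator_id).key_index_id]

    @property
    def units(self) -> list[str]:
        """Unit ids covered by the region maps (sorted); empty if no maps."""
        if not self.region_maps:
            return []
        any_scheme = next(iter(self.region_maps.values()))
        return sorted(any_scheme)

    # -- validation ----------------------------------------------------------
    def validate(self) -> "HierarchyConfig":
        """Check every structural invariant; raise HierarchyError naming the
        offending id on the first violation. Idempotent."""
        seen: set[str] = set()
        for c in self.categories:
            if c.category_id in seen:
                raise HierarchyError(f"duplicate category id {c.category_id!r}")
            seen.add(c.category_id)
        cat_ids = set(seen)

        seen = set()
        for k in self.key_indices:
            if k.key_index_id in seen:
                raise HierarchyError(f"duplicate key index id {k.key_index_id!r}")
            seen.add(k.key_index_id)
            if k.category_id not in cat_ids:
                raise HierarchyError(
                    f"key index {k.key_index_id!r} references unknown "
                    f"category {k.category_id!r}"
                )
        ki_ids = set(seen)

        seen = set()
        for ind in self.indicators:
            iid = ind.indicator_id
            if iid in seen:
                raise HierarchyError(f"duplicate indicator id {iid!r}")
            seen.add(iid)
            if ind.key_index_id not in ki_ids:
                raise HierarchyError(
                    f"indicator {iid!r} references unknown key index "
                    f"{ind.key_index_id!r}"
                )
            if ind.value_kind not in VALUE_KINDS:
                raise HierarchyError(f"indicator {iid!r}: bad value_kind {ind.value_kind!r}")
            if ind.polarity not in POLARITIES:
                raise HierarchyError(f"indicator {iid!r}: bad polarity {ind.polarity!r}")
            if (ind.value_kind == "ordinal") != (ind.ordinal_levels is not None):
                raise HierarchyError(
                    f"indicator {iid!r}: ordinal_levels must be present iff "
                    f"value_kind is ordinal"
                )
            if ind.ordinal_levels is not None and ind.ordinal_levels < 2:
                raise HierarchyError(f"indicator {iid!r}: ordinal_levels must be >= 2")
            if ind.value_kind in ("binary", "ordinal") and ind.polarity != "higher_better":
                # reversal applies to numeric indicators only; discrete scales
                # are coded so that higher is better
                raise HierarchyError(
                    f"indicator {iid!r}: binary/ordinal indicators must be "
                    f"higher_better"
                )
            scheme = ind.region_scheme
            if scheme is not None and scheme not in self.region_maps:
                raise HierarchyError(
                    f"indicator {iid!r} references unknown region scheme {scheme!r}"
                )
            if ind.coverage not in (PER_UNIT, MONITORING_SITES) and scheme is None:
                raise HierarchyError(f"indicator {iid!r}: bad coverage {ind.coverage!r}")

        for k in self.key_indices:
            if not self.indicators_of(k.key_index_id):
                raise HierarchyError(f"key index {k.key_index_id!r} has no indicators")

        # region schemes must partition one common unit set
        unit_sets = {name: set(m) for name, m in self.region_maps.items()}
        if unit_sets:
            names = sorted(unit_sets)
            ref_name, ref = names[0], unit_sets[names[0]]
            for name in names[1:]:
                if unit_sets[name] != ref:
                    diff = sorted(unit_sets[name] ^ ref)
                    raise HierarchyError(
                        f"region schemes {ref_name!r} and {name!r} cover "
                        f"different unit sets (symmetric difference {diff[:5]})"
                    )
        return self


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def hierarchy_to_dict(cfg: HierarchyConfig) -> dict:
    doc: dict = {
        "categories": [{"id": c.category_id, "label": c.label} for c in cfg.categories],
        "key_indices": [
            {"id": k.key_index_id, "label": k.label, "category": k.category_id}
            for k in cfg.key_indices
        ],
        "indicators": [],
        "region_maps": {name: dict(sorted(m.items())) for name, m in cfg.region_maps.items()},
    }
    for ind in cfg.indicators:
        entry: dict = {
            "id": ind.indicator_id,
            "label": ind.label,
            "key_index": ind.key_index_id,
            "kind": ind.value_kind,
            "polarity": ind.polarity,
            "coverage": ind.coverage,
        }
        if ind.ordinal_levels is not None:
            entry["ordinal_levels"] = ind.ordinal_levels
        if ind.data_year is not None:
            entry["year"] = ind.data_year
        doc["indicators"].append(entry)
    return doc


def hierarchy_from_dict(doc: dict) -> HierarchyConfig:
    try:
        categories = [Category(d["id"], d.get("label", d["id"])) for d in doc["categories"]]
        key_indices = [
            KeyIndex(d["id"], d.get("label", d["id"]), d["category"])
            for d in doc["key_indices"]
        ]
        indicators = [
            IndicatorDefinition(
                indicator_id=d["id"],
                label=d.get("label", d["id"]),
                key_index_id=d["key_index"],
                value_kind=d["kind"],
                polarity=d.get("polarity", "higher_better"),
                coverage=d.get("coverage", PER_UNIT),
                ordinal_levels=d.get("ordinal_levels"),
                data_year=d.get("year"),
            )
            for d in doc["indicators"]
        ]
    except KeyError as exc:  # pragma: no cover - message detail
        raise HierarchyError(f"missing required field {exc}") from exc
    region_maps = {
        name: {str(u): str(r) for u, r in m.items()}
        for name, m in (doc.get("region_maps") or {}).items()
    }
    return HierarchyConfig(categories, key_indices, indicators, region_maps).validate()


def load_hierarchy(source) -> HierarchyConfig:
    """Load and validate a hierarchy from a YAML document.

    ``source`` may be a path, an open text stream, or a YAML string.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" in text or text.lstrip().startswith("{"):
            doc = yaml.safe_load(io.StringIO(text))
        else:
            with open(text, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise HierarchyError("hierarchy document is not a mapping")
    return hierarchy_from_dict(doc)


def save_hierarchy(cfg: HierarchyConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(hierarchy_to_dict(cfg), fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# bundled Fukuoka instance
# ---------------------------------------------------------------------------

#: Numeric indicators scored in reverse (higher raw value = worse performance).
REVERSED_INDICATORS = (
    "A1.2", "A3.1", "B1.3", "C2.2", "C2.3", "C2.4", "C2.5",
    "C3.1", "C5.1", "C5.2", "C5.3",
)

#: Yes/No indicators.
BINARY_INDICATORS = ("A2.2", "B2.1", "B2.2", "C1.1", "C1.2", "C4.1")

_HEALTH_CENTER_REGIONS = (
    "kita_kyushu", "fukuoka", "kurume", "chikushi", "kasuya", "itoshima",
    "munakata_onga", "kaho_kurate", "tagawa", "kita_chikugo",
    "minami_chikugo", "kyochiku",
)

_FOOD_CHAIN_REGIONS = (
    "chikushi", "kasuya", "itoshima", "munakata_onga", "kaho_kurate",
    "tagawa", "kita_chikugo", "minami_chikugo", "kyochiku",
)

# (id, label, key_index, kind, coverage, year); polarity/ordinal filled below
_FUKUOKA_ROSTER = [
    ("A1.1", "Forest area (% of total land area)", "A1", "numeric", PER_UNIT, 2020),
    ("A1.2", "Biochemical Oxygen Demand level (mg/L)", "A1", "numeric", MONITORING_SITES, 2022),
    ("A2.1", "Government revenue (% of GDP)", "A2", "numeric", PER_UNIT, 2022),
    ("A2.2", "Municipal regulations for pet evacuation during disasters", "A2", "binary", PER_UNIT, 2024),
    ("A3.1", "Unemployment (% of total labor force)", "A3", "numeric", PER_UNIT, 2020),
    ("A4.1", "Natural population growth rate (%)", "A4", "numeric", PER_UNIT, 2022),
    ("A5.1", "Renewable electricity generation (% of demand)", "A5", "numeric", PER_UNIT, 2022),
    ("B1.1", "Hospital and clinic beds (per 1,000 population)", "B1", "numeric", PER_UNIT, 2021),
    ("B1.2", "Doctors (per 1,000 population)", "B1", "numeric", PER_UNIT, 2021),
    ("B1.3", "Suicide rate (per 10,000 population)", "B1", "numeric", PER_UNIT, 2022),
    ("B2.1", "Livestock disease surveillance system", "B2", "binary", PER_UNIT, 2024),
    ("B2.2", "Wild animal disease surveillance system", "B2", "binary", PER_UNIT, 2024),
    ("B3.1", "Waste disposal recycling rate (%)", "B3", "numeric", PER_UNIT, 2022),
    ("C1.1", "One Health policy agreement in municipal council", "C1", "binary", PER_UNIT, 2024),
    ("C1.2", "One Health declaration in municipal council", "C1", "binary", PER_UNIT, 2024),
    ("C1.3", "Registered agricultural/forestry/fishery products (per 10,000)", "C1", "numeric", PER_UNIT, 2024),
    ("C1.4", "Registered One Health declaration businesses (per 10,000)", "C1", "numeric", PER_UNIT, 2024),
    ("C1.5", "One Health website presence scale", "C1", "ordinal", PER_UNIT, 2024),
    ("C1.6", "One Health promotion/education facilities", "C1", "numeric", PER_UNIT, 2024),
    ("C2.1", "Influenza vaccination rate for age 65+ (%)", "C2", "numeric", PER_UNIT, 2022),
    ("C2.2", "Influenza weekly cases per sentinel site", "C2", "numeric", REGIONAL_PREFIX + "health_center", 2022),
    ("C2.3", "COVID-19 weekly cases per sentinel site", "C2", "numeric", REGIONAL_PREFIX + "health_center", 2022),
    ("C2.4", "Infectious gastroenteritis weekly cases per sentinel site", "C2", "numeric", REGIONAL_PREFIX + "health_center", 2022),
    ("C2.5", "Tuberculosis incidence (per 100,000 population)", "C2", "numeric", REGIONAL_PREFIX + "health_center", 2022),
    ("C3.1", "Food waste per capita (kg)", "C3", "numeric", PER_UNIT, 2022),
    ("C3.2", "GAP-certified agricultural producers (per 10,000)", "C3", "numeric", PER_UNIT, 2024),
    ("C3.3", "Food chain inspection implementation rate (%)", "C3", "numeric", REGIONAL_PREFIX + "food_chain", 2022),
    ("C3.4", "Arable land per capita (ha)", "C3", "numeric", PER_UNIT, 2022),
    ("C3.5", "Local food promotion restaurants (per 10,000)", "C3", "numeric", PER_UNIT, 2024),
    ("C4.1", "AMR surveillance system", "C4", "binary", PER_UNIT, 2022),
    ("C4.2", "JANIS hospitals (per 10,000 population)", "C4", "numeric", PER_UNIT, 2024),
    ("C5.1", "CO2 emissions (tons/capita)", "C5", "numeric", PER_UNIT, 2021),
    ("C5.2", "CO2 emissions (kg/GDP)", "C5", "numeric", PER_UNIT, 2021),
    ("C5.3", "Days with WBGT index above 25 (days/year)", "C5", "numeric", MONITORING_SITES, 2022),
]


def default_units(n_units: int = 60) -> list[str]:
    """Synthetic municipality ids M01..Mnn."""
    width = max(2, len(str(n_units)))
    return [f"M{i:0{width}d}" for i in range(1, n_units + 1)]


def synthetic_region_maps(units: list[str] | None = None) -> dict[str, dict[str, str]]:
    """Deterministic synthetic unit→region rosters for both schemes.

    The real municipality→region membership is not published; this default
    partitions the units into contiguous blocks (12 public-health-center
    regions, 9 food-chain regions) and must be replaced for any analysis of
    real data.
    """
    if units is None:
        units = default_units()
    n = len(units)

    def blocks(regions: tuple[str, ...]) -> dict[str, str]:
        k = len(regions)
        base, extra = divmod(n, k)
        mapping: dict[str, str] = {}
        pos = 0
        for idx, region in enumerate(regions):
            size = base + (1 if idx < extra else 0)
            for u in units[pos:pos + size]:
                mapping[u] = region
            pos += size
        return mapping

    return {
        "health_center": blocks(_HEALTH_CENTER_REGIONS),
        "food_chain": blocks(_FOOD_CHAIN_REGIONS),
    }


def fukuoka_default_hierarchy(
    region_maps: dict[str, dict[str, str]] | None = None,
) -> HierarchyConfig:
    """The bundled municipal One Health hierarchy for Fukuoka prefecture.

    3 categories, 13 key indices, 34 indicators; 11 numeric indicators are
    reverse-scored, 6 are binary, and C1.5 is a 4-level ordinal web-presence
    scale. Region membership defaults to :func:`synthetic_region_maps`.
    """
    categories = [
        Category("A", "External Drivers Index"),
        Category("B", "Internal Drivers Index"),
        Category("C", "Core Drivers Index"),
    ]
    key_indices = [
        KeyIndex("A1", "Earth systems", "A"),
        KeyIndex("A2", "Institutional systems", "A"),
        KeyIndex("A3", "Economic systems", "A"),
        KeyIndex("A4", "Social systems", "A"),
        KeyIndex("A5", "Technological systems", "A"),
        KeyIndex("B1", "Human health", "B"),
        KeyIndex("B2", "Animal health and ecosystem diversity", "B"),
        KeyIndex("B3", "Environmental resources", "B"),
        KeyIndex("C1", "One health governance", "C"),
        KeyIndex("C2", "Zoonotic diseases", "C"),
        KeyIndex("C3", "Food security", "C"),
        KeyIndex("C4", "Antimicrobial resistance (AMR)", "C"),
        KeyIndex("C5", "Climate change", "C"),
    ]
    indicators = []
    for iid, label, ki, kind, coverage, year in _FUKUOKA_ROSTER:
        indicators.append(
            IndicatorDefinition(
                indicator_id=iid,
                label=label,
                key_index_id=ki,
                value_kind=kind,
                polarity="higher_worse" if iid in REVERSED_INDICATORS else "higher_better",
                coverage=coverage,
                ordinal_levels=4 if kind == "ordinal" else None,
                data_year=year,
            )
        )
    cfg = HierarchyConfig(
        categories=categories,
        key_indices=key_indices,
        indicators=indicators,
        region_maps=region_maps if region_maps is not None else synthetic_region_maps(),
    )
    return cfg.validate()
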
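"""File formats and the end-to-end pipeline runner.

All tables are comma-separated UTF-8 text with a header row; hierarchy
configs, weight trees and LCA models are YAML. Every artifact written by
:func:`run_pipeline` carries the run seed and a config hash in a leading
comment line so numeric output is traceable to a stage and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import fahp, lca, reliability
from .hierarchy import HierarchyConfig, load_hierarchy, save_hierarchy
from .simulate import (
    ExpertVotes,
    SimulationProfile,
    default_profile,
    generate_expert_panel,
    generate_indicator_table,
)
from .standardize import RawIndicatorTable, StandardizedScoreTable, standardize_table

logger = logging.getLogger("fohi")

#: True level weights used for the bundled simulated expert panels: the
#: published consensus of the 23-expert panel (category and key-index
#: weights of the Fukuoka instance).
FUKUOKA_TRUE_WEIGHTS: dict[str, dict[str, float]] = {
    "top": {"A": 0.225, "B": 0.366, "C": 0.409},
    "A": {"A1": 0.242, "A2": 0.217, "A3": 0.132, "A4": 0.241, "A5": 0.168},
    "B": {"B1": 0.531, "B2": 0.269, "B3": 0.200},
    "C": {"C1": 0.286, "C2": 0.222, "C3": 0.214, "C4": 0.134, "C5": 0.144},
}


class IoError(ValueError):
    pass


# ---------------------------------------------------------------------------
# indicator tables
# ---------------------------------------------------------------------------

def write_indicator_table(table: RawIndicatorTable, path) -> None:
    """Wide CSV: unit_id + one column per indicator; empty cell = missing."""
    table.values.to_csv(path, index_label="unit_id", na_rep="")


def read_indicator_table(path, hierarchy: HierarchyConfig) -> RawIndicatorTable:
    """Read and type-check a wide indicator CSV against a hierarchy.

    The header must contain exactly the hierarchy's indicator ids (plus the
    unit_id index column); binary cells must be 0/1 and ordinal cells valid
    level codes — violations are reported with row and column.
    """
    df = pd.read_csv(path, index_col="unit_id", comment="#")
    known = set(hierarchy.indicator_ids)
    stray = [c for c in df.columns if c not in known]
    if stray:
        raise IoError(f"unknown indicator column(s) {stray}")
    absent = [c for c in hierarchy.indicator_ids if c not in df.columns]
    if absent:
        raise IoError(f"missing indicator column(s) {absent}")
    df = df[hierarchy.indicator_ids]
    for ind in hierarchy.indicators:
        col = pd.to_numeric(df[ind.indicator_id], errors="coerce")
        bad = col.isna() & df[ind.indicator_id].notna()
        if bad.any():
            unit = df.index[bad][0]
            raise IoError(
                f"unparseable cell at row {unit!r}, column {ind.indicator_id!r}"
            )
        df[ind.indicator_id] = col
        obs = col.dropna()
        if ind.value_kind == "binary" and not obs.isin([0, 1]).all():
            unit = obs.index[~obs.isin([0, 1])][0]
            raise IoError(
                f"binary cell out of domain at row {unit!r}, "
                f"column {ind.indicator_id!r}"
            )
        if ind.value_kind == "ordinal":
            valid = obs.isin(range(1, ind.ordinal_levels + 1))
            if not valid.all():
                unit = obs.index[~valid][0]
                raise IoError(
                    f"ordinal cell out of domain at row {unit!r}, "
                    f"column {ind.indicator_id!r}"
                )
    return RawIndicatorTable(values=df.astype(float), hierarchy=hierarchy).validate()


# ---------------------------------------------------------------------------
# expert votes
# ---------------------------------------------------------------------------

def write_votes(votes_by_level: dict[str, ExpertVotes], path) -> None:
    """Long CSV: level_id, item_i, item_j, count, n_experts."""
    rows = []
    for level_id in sorted(votes_by_level):
        v = votes_by_level[level_id]
        for (i, j), c in sorted(v.counts.items()):
            rows.append(
                {
                    "level_id": level_id,
                    "item_i": i,
                    "item_j": j,
                    "count": c,
                    "n_experts": v.n_experts,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_votes(path) -> dict[str, ExpertVotes]:
    df = pd.read_csv(path, comment="#")
    required = {"level_id", "item_i", "item_j", "count", "n_experts"}
    if not required.issubset(df.columns):
        raise IoError(f"votes file must have columns {sorted(required)}")
    out: dict[str, ExpertVotes] = {}
    for level_id, grp in df.groupby("level_id", sort=True):
        n_set = set(grp["n_experts"])
        if len(n_set) != 1:
            raise IoError(f"level {level_id!r}: inconsistent n_experts")
        items = sorted(set(grp["item_i"]) | set(grp["item_j"]))
        counts = {
            (r.item_i, r.item_j): int(r.count) for r in grp.itertuples(index=False)
        }
        out[str(level_id)] = ExpertVotes(
            str(level_id), items, int(n_set.pop()), counts
        ).validate()
    return out


# ---------------------------------------------------------------------------
# derived artifacts
# ---------------------------------------------------------------------------

def write_scores(scores: StandardizedScoreTable, path, sidecar_path=None) -> None:
    scores.scores.to_csv(path, index_label="unit_id")
    if sidecar_path is not None:
        rows = [
            {
                "indicator_id": p.indicator_id,
                "n_imputed": p.n_imputed,
                "fallback_used": p.fallback or "",
            }
            for p in scores.provenance.values()
        ]
        pd.DataFrame(rows).to_csv(sidecar_path, index=False)


def weight_tree_to_dict(tree: fahp.WeightTree) -> dict:
    return {
        "category_weights": {k: float(v) for k, v in tree.category_weights.items()},
        "key_index_weights": {k: float(v) for k, v in tree.key_index_weights.items()},
        "indicator_weights": {k: float(v) for k, v in tree.indicator_weights.items()},
        "consistency": {
            lv: {
                "lambda_max": float(c.lambda_max),
                "ci": float(c.ci),
                "cr": float(c.cr),
                "passes_strict": bool(c.passes_strict),
                "passes_secondary": bool(c.passes_secondary),
            }
            for lv, c in tree.consistency.items()
        },
    }


def write_weight_tree(tree: fahp.WeightTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(weight_tree_to_dict(tree), fh, sort_keys=True)


def lca_model_to_dict(model: lca.LCAModel) -> dict:
    return {
        "n_classes": model.n_classes,
        "prevalences": [float(p) for p in model.prevalences],
        "items": list(model.items),
        "n_categories": list(model.n_categories),
        "rho": {
            f"class_{k + 1}": {
                item: [float(v) for v in model.rho[k, j, : model.n_categories[j]]]
                for j, item in enumerate(model.items)
            }
            for k in range(model.n_classes)
        },
        "log_likelihood": float(model.log_likelihood),
        "n_parameters": int(model.n_parameters),
        "bic": float(model.bic),
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    When ``indicator_table`` / ``votes`` paths are None the bundled
    synthetic instance is generated in place from ``seed`` (study-shaped:
    60 units, 23 experts).
    """

    out_dir: str | Path = "fohi_run"
    hierarchy_path: str | Path | None = None
    indicator_table: str | Path | None = None
    votes: str | Path | None = None
    seed: int = 0
    n_units: int = 60
    n_experts: int = 23
    reciprocal_mode: str = "ratio_reciprocal"
    k_range: tuple[int, int] = (2, 6)
    em_starts: int = 50
    em_max_iter: int = 1000
    em_tol: float = 1e-8
    top_k: int = 20
    planted_classes: bool = True

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = {
            k: str(v) for k, v in sorted(vars(self).items()) if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunResult:
    """In-memory view of everything a pipeline run produced."""

    hierarchy: HierarchyConfig
    raw: RawIndicatorTable
    standardized: StandardizedScoreTable
    weights: fahp.WeightTree
    score_hierarchy: agg.ScoreHierarchy
    summary: pd.DataFrame
    rankings: dict[str, pd.DataFrame]
    heatmap: pd.DataFrame
    constant_columns: list[str]
    reliability: reliability.ReliabilityReport
    profiles: pd.DataFrame
    lca_model: lca.LCAModel
    bic_table: pd.DataFrame
    assignments: pd.DataFrame
    artifacts: dict[str, Path] = field(default_factory=dict)


def simulate_default_votes(
    hierarchy: HierarchyConfig, n_experts: int, seed: int
) -> dict[str, ExpertVotes]:
    """Simulate one vote set per comparison level from the bundled true
    level weights (falling back to equal weights for non-bundled levels).

    Pairs are stored with the consensus-stronger item first, mirroring a
    questionnaire whose a_ij count is recorded for the collectively
    preferred direction. Under the ratio reciprocal rule the stored
    orientation affects the derived weights, so this layout keeps the
    bundled instance's weights aligned with the generating preferences.
    """
    votes = {}
    ss = np.random.SeedSequence(seed).spawn(len(fahp.level_ids(hierarchy)))
    for child, level in zip(ss, fahp.level_ids(hierarchy)):
        if level == "top":
            items = list(hierarchy.category_ids)
        else:
            items = [k.key_index_id for k in hierarchy.key_indices_of(level)]
        known = FUKUOKA_TRUE_WEIGHTS.get(level, {})
        w = {i: known.get(i, 1.0 / len(items)) for i in items}
        items = sorted(items, key=lambda i: (-w[i], i))
        weights = np.array([w[i] for i in items])
        votes[level] = generate_expert_panel(
            items, weights / weights.sum(), n_experts, child, level_id=level
        )
    return votes


def _stamp(path: Path, seed: int, cfg_hash: str) -> None:
    text = path.read_text(encoding="utf-8")
    path.write_text(f"# seed={seed} config={cfg_hash}\n{text}", encoding="utf-8")


def run_pipeline(config: RunConfig, hierarchy: HierarchyConfig | None = None) -> RunResult:
    """Standardize -> weights -> aggregate -> report -> reliability -> LCA.

    Writes every artifact under ``config.out_dir`` (CSV/YAML, each stamped
    with the seed and config hash) and returns the in-memory results. Stage
    failures are re-raised annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    def emit(name: str, path: Path) -> None:
        _stamp(path, config.seed, cfg_hash)
        artifacts[name] = path

    try:
        stage("hierarchy")
        if hierarchy is None:
            if config.hierarchy_path is not None:
                hierarchy = load_hierarchy(config.hierarchy_path)
            else:
                from .hierarchy import fukuoka_default_hierarchy

                hierarchy = fukuoka_default_hierarchy()
        save_hierarchy(hierarchy, out / "hierarchy.yaml")
        emit("hierarchy", out / "hierarchy.yaml")
    except Exception as exc:
        raise IoError(f"stage 'hierarchy' failed: {exc}") from exc

    try:
        stage("data")
        if config.indicator_table is not None:
            raw = read_indicator_table(config.indicator_table, hierarchy)
        else:
            profile = default_profile(
                hierarchy,
                n_units=config.n_units,
                seed=config.seed,
                planted_classes="default" if config.planted_classes else None,
            )
            raw = generate_indicator_table(hierarchy, profile)
        write_indicator_table(raw, out / "indicator_table.csv")
        emit("indicator_table", out / "indicator_table.csv")
        if raw.planted_labels is not None:
            raw.planted_labels.to_csv(out / "planted_classes.csv", index_label="unit_id")
            emit("planted_classes", out / "planted_classes.csv")
    except IoError:
        raise
    except Exception as exc:
        raise IoError(f"stage 'data' failed: {exc}") from exc

    try:
        stage("standardize")
        standardized = standardize_table(raw)
        write_scores(
            standardized, out / "standardized_scores.csv", out / "standardization_log.csv"
        )
        emit("standardized_scores", out / "standardized_scores.csv")
        emit("standardization_log", out / "standardization_log.csv")
    except Exception as exc:
        raise IoError(f"stage 'standardize' failed: {exc}") from exc

    try:
        stage("weights")
        if config.votes is not None:
            votes = read_votes(config.votes)
        else:
            votes = simulate_default_votes(hierarchy, config.n_experts, config.seed)
        write_votes(votes, out / "expert_votes.csv")
        emit("expert_votes", out / "expert_votes.csv")
        weights = fahp.derive_weight_tree(votes, hierarchy, mode=config.reciprocal_mode)
        write_weight_tree(weights, out / "weight_tree.yaml")
        emit("weight_tree", out / "weight_tree.yaml")
    except fahp.FahpError as exc:
        raise IoError(f"stage 'weights' failed: {exc}") from exc
    except Exception as exc:
        raise IoError(f"stage 'weights' failed: {exc}") from exc

    try:
        stage("aggregate")
        sh = agg.aggregate_hierarchy(standardized.scores, weights, hierarchy)
        summary = agg.summary_table(sh)
        summary.to_csv(out / "summary.csv")
        emit("summary", out / "summary.csv")
        rankings = {"total": agg.rank_table(sh.total_score, min(config.top_k, len(sh.units)))}
        for c in hierarchy.category_ids:
            rankings[c] = agg.rank_table(
                sh.category_scores[c], min(config.top_k, len(sh.units))
            )
        pd.concat(
            [r.assign(score_column=name) for name, r in rankings.items()]
        ).to_csv(out / "rankings.csv", index=False)
        emit("rankings", out / "rankings.csv")
        heatmap, constant_cols = agg.heatmap_matrix(sh)
        heatmap.to_csv(out / "heatmap_matrix.csv", index_label="unit_id")
        emit("heatmap_matrix", out / "heatmap_matrix.csv")
    except Exception as exc:
        raise IoError(f"stage 'aggregate' failed: {exc}") from exc

    try:
        stage("reliability")
        rel = reliability.cronbach_alpha(sh.category_scores)
    except Exception as exc:
        raise IoError(f"stage 'reliability' failed: {exc}") from exc

    try:
        stage("lca")
        profiles = lca.bin_profiles(sh.category_scores)
        profiles.to_csv(out / "binned_profiles.csv", index_label="unit_id")
        emit("binned_profiles", out / "binned_profiles.csv")
        k_lo, k_hi = config.k_range
        model, bic_table = lca.select_by_bic(
            profiles,
            range(k_lo, k_hi + 1),
            n_starts=config.em_starts,
            max_iter=config.em_max_iter,
            tol=config.em_tol,
            seed=config.seed,
            n_categories=[4] * profiles.shape[1],
        )
        assignments = lca.assign_classes(model)
        bic_table.to_csv(out / "bic_table.csv")
        emit("bic_table", out / "bic_table.csv")
        assignments.to_csv(out / "class_assignments.csv", index_label="unit_id")
        emit("class_assignments", out / "class_assignments.csv")
    except Exception as exc:
        raise IoError(f"stage 'lca' failed: {exc}") from exc

    stage("report")
    report = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "n_units": len(sh.units),
        "summary": summary.to_dict(orient="index"),
        "consistency": {
            lv: {"lambda_max": c.lambda_max, "ci": c.ci, "cr": c.cr}
            for lv, c in weights.consistency.items()
        },
        "reliability": {
            "raw_alpha": rel.raw_alpha,
            "standardized_alpha": rel.standardized_alpha,
        },
        "heatmap_constant_columns": constant_cols,
        "lca": lca_model_to_dict(model),
        "class_sizes": assignments["class"].value_counts().sort_index().to_dict(),
    }
    with open(out / "run_summary.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    emit("run_summary", out / "run_summary.yaml")

    return RunResult(
        hierarchy=hierarchy,
        raw=raw,
        standardized=standardized,
        weights=weights,
        score_hierarchy=sh,
        summary=summary,
        rankings=rankings,
        heatmap=heatmap,
        constant_columns=constant_cols,
        reliability=rel,
        profiles=profiles,
        lca_model=model,
        bic_table=bic_table,
        assignments=assignments,
        artifacts=artifacts,
    )
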
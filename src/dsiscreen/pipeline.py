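"""End-to-end pipeline: characterize → fit → cross-validate → cutoffs →
scenarios, with CSV / text reports and one machine-readable JSON bundle.

All randomness flows from the single config seed; two runs with identical
configs produce byte-identical JSON.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, read_cohort_csv
from .dsi import fit_dsi
from .evaluation import (
    characterize_cohort,
    cross_validate,
    cutoff_table,
    make_fold_plan,
    resubstitution_auc,
)
from .hierarchy import FeatureHierarchy, default_hierarchy, load_hierarchy
from .reports import (
    characteristics_text,
    cutoff_text,
    performance_text,
    scenarios_text,
)
from .scenarios import default_scenarios, run_scenarios
from .synthetic import CohortConfig, default_config, generate_cohort


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``cohort_path`` (CSV) or ``synthetic`` (generator
    config; ``"default"`` for the packaged one) supplies the cohort.
    """

    out_dir: str | Path
    cohort_path: str | Path | None = None
    synthetic: CohortConfig | str | None = "default"
    hierarchy_path: str | Path | None = None
    repetitions: int = 100
    folds: int = 5
    seed: int = 0
    cutoffs: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    stages: tuple[str, ...] = ("characterize", "crossval", "cutoffs", "scenarios")

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if any(not 0.0 <= c <= 1.0 for c in self.cutoffs):
            raise ValueError("cutoffs must lie in [0, 1]")

    def load_cohort(self) -> CohortTable:
        if self.cohort_path is not None:
            return read_cohort_csv(self.cohort_path)
        config = self.synthetic
        if config == "default" or config is None:
            config = default_config(seed=self.seed)
        return generate_cohort(config)

    def load_hierarchy(self) -> FeatureHierarchy:
        if self.hierarchy_path is not None:
            return load_hierarchy(self.hierarchy_path)
        return default_hierarchy()


def _factor_performance(
    table: CohortTable,
    hierarchy: FeatureHierarchy,
    repetitions: int,
    folds: int,
    seed: int,
) -> pd.DataFrame:
    """Table-2 machinery: CV AUC for the composite, every group and every
    feature, all on shared fold partitions; directions from a full-data fit."""
    full_fit = fit_dsi(table, hierarchy)
    arrows = {
        f: ("↑" if m.orientation == "higher_in_positive" else "↓")
        for f, m in full_fit.leaf_models.items()
    }
    plan = make_fold_plan(table.labels.to_numpy(), repetitions, folds, seed)

    rows = []
    for path, node in hierarchy.walk():
        level = path.count("/")
        name = "Composite DSI" if path == hierarchy.name else node.name
        rel = None if path == hierarchy.name else path.split("/", 1)[1]
        tree = hierarchy if rel is None else hierarchy.restrict(include=[rel])
        cv = cross_validate(table, tree, repetitions, folds, fold_plan=plan)
        single = node.features[0] if len(node.features) == 1 else None
        rows.append(
            {
                "name": name,
                "path": path,
                "level": level,
                "direction": arrows[single] if single else "",
                "mean_auc": cv.mean_auc,
                "ci_low": cv.ci[0],
                "ci_high": cv.ci[1],
            }
        )
        if len(node.features) > 1:
            for feat in node.features:
                single = FeatureHierarchy(name=feat, features=[feat])
                cv = cross_validate(table, single, repetitions, folds, fold_plan=plan)
                rows.append(
                    {
                        "name": feat,
                        "path": f"{path}/{feat}",
                        "level": level + 1,
                        "direction": arrows[feat],
                        "mean_auc": cv.mean_auc,
                        "ci_low": cv.ci[0],
                        "ci_high": cv.ci[1],
                    }
                )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Writes per-stage CSV and aligned-text tables plus ``results.json``
    containing every reported number unrounded, the seeds, and version
    information. Returns the results dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "run": {
            "seed": config.seed,
            "repetitions": config.repetitions,
            "folds": config.folds,
            "dsiscreen_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
        }
    }

    def stage(name):
        return name in config.stages

    try:
        table = config.load_cohort()
        hierarchy = config.load_hierarchy()
        table.write_csv(out / "cohort.csv")
    except Exception as err:
        raise RuntimeError(f"[input stage] {err}") from err

    if stage("characterize"):
        try:
            summary = characterize_cohort(table)
            summary.to_csv(out / "table1_characteristics.csv")
            (out / "table1_characteristics.txt").write_text(
                characteristics_text(summary, table.n_negative, table.n_positive)
            )
            results["characteristics"] = {
                feat: {
                    "negative": row["negative"],
                    "positive": row["positive"],
                    "p_value": row["p_value"],
                }
                for feat, row in summary.iterrows()
            }
            results["prevalence_positive_pct"] = 100.0 * table.n_positive / table.n_subjects
        except Exception as err:
            raise RuntimeError(f"[characterize stage] {err}") from err

    cv = None
    if stage("crossval") or stage("cutoffs"):
        try:
            cv = cross_validate(
                table,
                hierarchy,
                repetitions=config.repetitions,
                folds=config.folds,
                seed=config.seed,
            )
        except Exception as err:
            raise RuntimeError(f"[crossval stage] {err}") from err

    if stage("crossval"):
        try:
            perf = _factor_performance(
                table, hierarchy, config.repetitions, config.folds, config.seed
            )
            perf.to_csv(out / "table2_performance.csv", index=False)
            (out / "table2_performance.txt").write_text(performance_text(perf))
            results["performance"] = {
                row["path"]: {
                    "direction": row["direction"],
                    "mean_auc": row["mean_auc"],
                    "ci": [row["ci_low"], row["ci_high"]],
                }
                for _, row in perf.iterrows()
            }
            results["composite_cv_auc"] = cv.mean_auc
            results["composite_cv_ci"] = list(cv.ci)
            results["resubstitution_auc"] = resubstitution_auc(table, hierarchy)
        except Exception as err:
            raise RuntimeError(f"[crossval stage] {err}") from err

    if stage("cutoffs"):
        try:
            stats = cutoff_table(cv, cutoffs=np.asarray(config.cutoffs))
            stats.table.to_csv(out / "table3_cutoffs.csv")
            (out / "table3_cutoffs.txt").write_text(cutoff_text(stats))
            results["cutoffs"] = {
                f"{c:.1f}": {k: row[k] for k in stats.table.columns}
                for c, row in stats.table.iterrows()
            }
        except Exception as err:
            raise RuntimeError(f"[cutoffs stage] {err}") from err

    if stage("scenarios"):
        try:
            res = run_scenarios(
                table,
                hierarchy,
                default_scenarios(),
                repetitions=config.repetitions,
                folds=config.folds,
                seed=config.seed,
            )
            res.to_csv(out / "table4_scenarios.csv")
            (out / "table4_scenarios.txt").write_text(scenarios_text(res))
            results["scenarios"] = {
                name: {
                    "block": row["block"],
                    "n_features": row["n_features"],
                    "mean_auc": row["mean_auc"],
                    "ci": [row["ci_low"], row["ci_high"]],
                }
                for name, row in res.iterrows()
            }
        except Exception as err:
            raise RuntimeError(f"[scenarios stage] {err}") from err

    (out / "results.json").write_text(
        json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n"
    )
    return results
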
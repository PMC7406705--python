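"""Added-value and leave-one-out experiments over the factor hierarchy.

Each scenario names a feature set — a list of included group paths,
optionally minus excluded subgroups — and all scenarios in a run are
cross-validated on *identical* fold partitions (one shared seed), so AUC
differences between scenarios reflect the feature sets rather than the
luck of the split. Excluded groups are pruned from the tree before any
fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortTable
from .evaluation import cross_validate, make_fold_plan
from .hierarchy import FeatureHierarchy


class ScenarioError(ValueError):
    """Raised for scenarios that cannot be resolved against the hierarchy."""


@dataclass
class Scenario:
    """One feature-set configuration.

    ``include`` lists group paths to keep (``None`` keeps the whole tree);
    ``exclude`` prunes subgroups from the included set, as in the MRI
    leave-one-out analyses. ``block`` labels the report section the
    scenario belongs to.
    """

    name: str
    include: list[str] | None = None
    exclude: list[str] = field(default_factory=list)
    block: str = ""

    def resolve(self, hierarchy: FeatureHierarchy) -> FeatureHierarchy:
        try:
            tree = hierarchy.restrict(include=self.include, exclude=self.exclude)
        except ValueError as err:
            raise ScenarioError(f"scenario {self.name!r}: {err}") from err
        if not tree.all_features():
            raise ScenarioError(f"scenario {self.name!r} resolves to zero features")
        return tree


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Read a scenario list from JSON or YAML (same dialect as the packaged file)."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
    else:
        raw = json.loads(path.read_text())
    return [
        Scenario(
            name=s["name"],
            include=s.get("include"),
            exclude=s.get("exclude", []),
            block=s.get("block", ""),
        )
        for s in raw
    ]


def default_scenarios() -> list[Scenario]:
    """The packaged added-value scenario list.

    Covers the four stepwise base models with their single-group additions
    (Demographic+Cardiovascular, +Cognition, +APOE, APOE alone), the
    APOE+MRI combinations, and the two MRI leave-one-out blocks — 20 unique
    feature-set configurations in all.
    """
    text = resources.files("dsiscreen.data").joinpath("scenarios.json").read_text()
    return [
        Scenario(
            name=s["name"],
            include=s.get("include"),
            exclude=s.get("exclude", []),
            block=s.get("block", ""),
        )
        for s in json.loads(text)
    ]


def run_scenarios(
    table: CohortTable,
    hierarchy: FeatureHierarchy,
    scenarios: list[Scenario],
    repetitions: int = 100,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every scenario on shared fold partitions.

    Returns one row per scenario with its mean AUC, 95% CI and feature
    count. Results are independent of scenario order.
    """
    resolved = [(s, s.resolve(hierarchy)) for s in scenarios]
    plan = make_fold_plan(table.labels.to_numpy(), repetitions, folds, seed)
    rows = []
    for scenario, tree in resolved:
        cv = cross_validate(
            table, tree, repetitions=repetitions, folds=folds, fold_plan=plan
        )
        rows.append(
            {
                "scenario": scenario.name,
                "block": scenario.block,
                "n_features": len(tree.all_features()),
                "mean_auc": cv.mean_auc,
                "ci_low": cv.ci[0],
                "ci_high": cv.ci[1],
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
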
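"""Disease State Index: nonparametric per-feature classifiers composed over
a feature hierarchy.

For each feature the training data yield a *fitness* function

    f(x) = FN(x) / (FN(x) + FP(x))

where, with a decision threshold placed at the measurement value x along
the learned positive-typical direction, FN(x) is the fraction of
positive-class training values that would be missed (strictly on the
negative-typical side of x) and FP(x) the fraction of negative-class
training values that would be falsely called (at or beyond x on the
positive-typical side). Fitness runs from 0 (typical of the negative
class) to 1 (typical of the positive class). Each feature also gets a
*relevance* weight — the maximal Youden index, sensitivity + specificity
− 1, over candidate thresholds — so well-separating features dominate.

Group scores are relevance-weighted averages of their children's scores,

    DSI = sum_i relevance_i * fitness_i / sum_i relevance_i,

and each group recursively receives its own relevance by scanning
thresholds over its training scores. Missing values simply drop out of the
average, with the weights renormalized over the observed children.

Everything is empirical step functions — no smoothing, no distributional
assumptions — which is what makes the method robust on small mixed-type
tabular cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .hierarchy import FeatureHierarchy


class FitError(ValueError):
    """Raised when a model cannot be fitted from the given training data."""


# ---------------------------------------------------------------------------
# Threshold scanning


def _max_youden(neg: np.ndarray, pos: np.ndarray) -> tuple[float, float]:
    """Maximal Youden index J = sens + spec − 1 for the rule "x ≥ t ⇒ positive".

    Candidate thresholds are the midpoints between adjacent distinct pooled
    training values plus ±inf; ties in J are broken toward the smaller
    threshold. Because t = ±inf gives J = 0, the maximum is never negative.
    Returns (J, threshold).
    """
    neg = np.sort(neg)
    pos = np.sort(pos)
    values = np.unique(np.concatenate([neg, pos]))
    mids = (values[:-1] + values[1:]) / 2.0 if len(values) > 1 else np.empty(0)
    cand = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = 1.0 - np.searchsorted(pos, cand, side="left") / len(pos)
    spec = np.searchsorted(neg, cand, side="left") / len(neg)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first max == smallest threshold
    return float(j[best]), float(cand[best])


# ---------------------------------------------------------------------------
# Per-feature fitness


@dataclass
class FitnessModel:
    """Fitted per-feature classifier: orientation, error curves, relevance.

    The FN/FP step curves are represented exactly by the sorted training
    samples on the oriented axis (value × orientation sign), from which any
    evaluation point's errors follow by counting.
    """

    feature: str
    kind: str
    orientation: str  # "higher_in_positive" | "lower_in_positive"
    neg_oriented: np.ndarray  # sorted, oriented negative-class training values
    pos_oriented: np.ndarray
    relevance: float
    chosen_threshold: float  # on the original measurement scale
    degenerate: bool = False  # both classes a single identical constant

    @property
    def _sign(self) -> float:
        return 1.0 if self.orientation == "higher_in_positive" else -1.0

    def fn_curve(self, x) -> np.ndarray:
        """False-negative error at a threshold placed at x (oriented axis)."""
        z = np.asarray(x, dtype=float) * self._sign
        return np.searchsorted(self.pos_oriented, z, side="left") / len(self.pos_oriented)

    def fp_curve(self, x) -> np.ndarray:
        """False-positive error at a threshold placed at x (oriented axis)."""
        z = np.asarray(x, dtype=float) * self._sign
        n = len(self.neg_oriented)
        return (n - np.searchsorted(self.neg_oriented, z, side="left")) / n

    def fitness(self, x) -> np.ndarray | float:
        """Evaluate f(x) = FN/(FN+FP) elementwise; NaN (missing) passes through.

        Points beyond the training range saturate at 0 / 1; inside a
        perfect-separation gap FN + FP = 0 and the value is the neutral 0.5.
        """
        arr = np.asarray(x, dtype=float)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr)
        out = np.full(arr.shape, np.nan)
        obs = ~np.isnan(arr)
        if self.degenerate:
            out[obs] = 0.5
        else:
            fn = self.fn_curve(arr[obs])
            fp = self.fp_curve(arr[obs])
            tot = fn + fp
            vals = np.where(tot > 0, fn / np.where(tot > 0, tot, 1.0), 0.5)
            out[obs] = vals
        return float(out[0]) if scalar else out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "kind": self.kind,
            "orientation": self.orientation,
            "neg_oriented": self.neg_oriented.tolist(),
            "pos_oriented": self.pos_oriented.tolist(),
            "relevance": self.relevance,
            "chosen_threshold": self.chosen_threshold,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "FitnessModel":
        return cls(
            feature=spec["feature"],
            kind=spec["kind"],
            orientation=spec["orientation"],
            neg_oriented=np.asarray(spec["neg_oriented"], dtype=float),
            pos_oriented=np.asarray(spec["pos_oriented"], dtype=float),
            relevance=spec["relevance"],
            chosen_threshold=spec["chosen_threshold"],
            degenerate=spec["degenerate"],
        )


def fit_fitness(
    values_negative,
    values_positive,
    kind: str = "continuous",
    feature: str = "feature",
) -> FitnessModel:
    """Fit one feature's fitness model from class-labeled training values.

    The positive-typical direction is the one whose best threshold achieves
    the larger Youden index (ties favor higher-in-positive); binary and
    ordinal features go through the same threshold machinery as continuous
    ones. Missing values are dropped before fitting.
    """
    neg = np.asarray(values_negative, dtype=float)
    pos = np.asarray(values_positive, dtype=float)
    neg = neg[~np.isnan(neg)]
    pos = pos[~np.isnan(pos)]
    if len(neg) == 0 or len(pos) == 0:
        raise FitError(
            f"feature {feature!r}: a training class has no observed values"
        )

    j_hi, t_hi = _max_youden(neg, pos)
    j_lo, t_lo = _max_youden(-neg, -pos)
    if j_hi >= j_lo:
        orientation, relevance, threshold = "higher_in_positive", j_hi, t_hi
        neg_o, pos_o = np.sort(neg), np.sort(pos)
    else:
        orientation, relevance, threshold = "lower_in_positive", j_lo, -t_lo
        neg_o, pos_o = np.sort(-neg), np.sort(-pos)

    degenerate = (
        len(np.unique(neg)) == 1
        and len(np.unique(pos)) == 1
        and neg[0] == pos[0]
    )
    return FitnessModel(
        feature=feature,
        kind=kind,
        orientation=orientation,
        neg_oriented=neg_o,
        pos_oriented=pos_o,
        relevance=float(np.clip(relevance, 0.0, 1.0)),
        chosen_threshold=threshold,
        degenerate=degenerate,
    )


def fitness_value(model: FitnessModel, x) -> np.ndarray | float:
    """Evaluate a fitted fitness model at x (alias of ``model.fitness``)."""
    return model.fitness(x)


# ---------------------------------------------------------------------------
# Hierarchical model


@dataclass
class NodeFit:
    """Fitted state of one internal node: its relevance and the training
    score distribution from which it was derived."""

    relevance: float
    threshold: float
    train_scores: np.ndarray


@dataclass
class DSIModel:
    """A fitted DSI tree: per-feature fitness leaves plus per-group relevances."""

    hierarchy: FeatureHierarchy
    leaf_models: dict[str, FitnessModel]
    node_fits: dict[str, NodeFit]  # keyed by slash path from the root

    @property
    def root_path(self) -> str:
        return self.hierarchy.name

    def node_relevance(self, path: str) -> float:
        if path in self.node_fits:
            return self.node_fits[path].relevance
        raise KeyError(path)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "hierarchy": self.hierarchy.to_dict(),
            "leaf_models": {k: m.to_dict() for k, m in self.leaf_models.items()},
            "node_fits": {
                k: {
                    "relevance": v.relevance,
                    "threshold": v.threshold,
                    "train_scores": v.train_scores.tolist(),
                }
                for k, v in self.node_fits.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DSIModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            hierarchy=FeatureHierarchy.from_dict(payload["hierarchy"]),
            leaf_models={
                k: FitnessModel.from_dict(v) for k, v in payload["leaf_models"].items()
            },
            node_fits={
                k: NodeFit(
                    relevance=v["relevance"],
                    threshold=v["threshold"],
                    train_scores=np.asarray(v["train_scores"], dtype=float),
                )
                for k, v in payload["node_fits"].items()
            },
        )


@dataclass
class DSIResult:
    """Per-subject DSI values at the root and every node of the tree.

    ``scores`` is the root DSI in [0, 1] (NaN for flagged subjects);
    ``node_scores`` has one column per node path plus ``<group>/<feature>``
    columns for the leaves; ``n_observed_leaves`` counts the non-missing
    features that contributed; subjects with zero observed leaves are
    ``flagged`` rather than silently scored.
    """

    scores: pd.Series
    node_scores: pd.DataFrame
    n_observed_leaves: pd.Series
    flagged: pd.Series


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Relevance-weighted mean across columns, renormalized over observed
    entries; all-zero observed weight → neutral 0.5; nothing observed → NaN."""
    obs = ~np.isnan(values)
    w = np.where(obs, weights[None, :], 0.0)
    den = w.sum(axis=1)
    num = np.where(obs, np.nan_to_num(values) * w, 0.0).sum(axis=1)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    out[~obs.any(axis=1)] = np.nan
    return out


def _node_children(node: FeatureHierarchy):
    """Uniform child view: ("feature", name) leaves or ("group", node)."""
    if node.features:
        return [("feature", f) for f in node.features]
    return [("group", c) for c in node.children]


def fit_dsi(train: CohortTable, hierarchy: FeatureHierarchy) -> DSIModel:
    """Fit the full DSI tree on a training cohort.

    Every leaf's orientation, error curves and relevance are learned from
    the training split; each internal node's training scores are the
    relevance-weighted mean of its children's scores, and the node's own
    relevance is the maximal Youden index of those scores against the
    training labels (group scores are similarity-to-positive by
    construction, so their orientation is fixed).
    """
    hierarchy.validate()
    labels = train.labels.to_numpy()
    if not ((labels == 0).any() and (labels == 1).any()):
        raise FitError("training cohort must contain both classes")
    missing = [f for f in hierarchy.all_features() if f not in train.features]
    if missing:
        raise FitError(f"hierarchy references unknown features: {missing}")

    leaf_models: dict[str, FitnessModel] = {}
    node_fits: dict[str, NodeFit] = {}

    def fit_node(node: FeatureHierarchy, path: str) -> tuple[float, np.ndarray]:
        scores_cols, weights = [], []
        for child_kind, child in _node_children(node):
            if child_kind == "feature":
                model = fit_fitness(
                    train.class_values(child, 0),
                    train.class_values(child, 1),
                    kind=train.feature_kinds[child],
                    feature=child,
                )
                leaf_models[child] = model
                child_scores = model.fitness(train.data[child].to_numpy())
                child_rel = model.relevance
            else:
                child_rel, child_scores = fit_node(child, f"{path}/{child.name}")
            scores_cols.append(child_scores)
            weights.append(child_rel)

        values = np.column_stack(scores_cols)
        w = np.asarray(weights)
        scores = _weighted_mean(values, w)
        if (w == 0).all():
            warnings.warn(
                f"node {path!r}: every child has zero relevance; "
                "node scores constant 0.5",
                stacklevel=2,
            )
            node_fits[path] = NodeFit(relevance=0.0, threshold=np.inf, train_scores=scores)
            return 0.0, scores
        obs = ~np.isnan(scores)
        rel, thr = _max_youden(scores[obs & (labels == 0)], scores[obs & (labels == 1)])
        rel = float(np.clip(rel, 0.0, 1.0))
        node_fits[path] = NodeFit(relevance=rel, threshold=thr, train_scores=scores)
        return rel, scores

    fit_node(hierarchy, hierarchy.name)
    return DSIModel(hierarchy=hierarchy, leaf_models=leaf_models, node_fits=node_fits)


def score(model: DSIModel, table: CohortTable) -> DSIResult:
    """Score a cohort with a fitted model.

    Each node's score is the relevance-weighted mean over its *observed*
    children only — the weights are renormalized over the non-missing ones,
    so missing measurements are ignored rather than imputed. A subject with
    no observed feature at all is flagged and gets no numeric score.
    """
    missing = [f for f in model.hierarchy.all_features() if f not in table.features]
    if missing:
        raise FitError(f"table lacks features required by the model: {missing}")

    node_scores: dict[str, np.ndarray] = {}

    def score_node(node: FeatureHierarchy, path: str) -> tuple[float, np.ndarray]:
        scores_cols, weights = [], []
        for child_kind, child in _node_children(node):
            if child_kind == "feature":
                m = model.leaf_models[child]
                child_scores = m.fitness(table.data[child].to_numpy())
                child_rel = m.relevance
                node_scores[f"{path}/{child}"] = child_scores
            else:
                child_rel, child_scores = score_node(child, f"{path}/{child.name}")
            scores_cols.append(child_scores)
            weights.append(child_rel)
        values = np.column_stack(scores_cols)
        w = np.asarray(weights)
        scores = _weighted_mean(values, w)
        if (w == 0).all():
            scores = np.where(np.isnan(values).all(axis=1), np.nan, 0.5)
        node_scores[path] = scores
        return model.node_fits[path].relevance, scores

    root = model.hierarchy
    _, root_scores = score_node(root, root.name)

    feats = model.hierarchy.all_features()
    n_obs = (~table.data[feats].isna()).sum(axis=1)
    flagged = n_obs == 0
    return DSIResult(
        scores=pd.Series(root_scores, index=table.data.index, name="dsi"),
        node_scores=pd.DataFrame(node_scores, index=table.data.index),
        n_observed_leaves=n_obs,
        flagged=flagged,
    )
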
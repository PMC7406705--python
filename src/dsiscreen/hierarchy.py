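"""Feature hierarchy: named groups of conceptually related factors.

The classifier aggregates per-feature scores bottom-up through a tree of
groups (Demographic, Cardiovascular, APOE, Cognition, MRI with Volumes /
VisualMTA / ADSignatureThickness subgroups), so group-level performance can
be read off any internal node. Nodes are addressed by slash paths relative
to the root, e.g. ``"MRI/Volumes"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


class HierarchyError(ValueError):
    """Raised for malformed hierarchies or unresolvable node paths."""


@dataclass
class FeatureHierarchy:
    """A node in the feature tree.

    Internal nodes carry ``children``; leaf groups carry ``features`` (each
    feature becomes its own scoring leaf). A node must have one or the other.
    """

    name: str
    children: list["FeatureHierarchy"] = field(default_factory=list)
    features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if bool(self.children) == bool(self.features):
            raise HierarchyError(
                f"node {self.name!r} must have exactly one of children/features"
            )

    # -- queries ----------------------------------------------------------

    def all_features(self) -> list[str]:
        if self.features:
            return list(self.features)
        out: list[str] = []
        for child in self.children:
            out.extend(child.all_features())
        return out

    def validate(self) -> None:
        """Check feature and group-name uniqueness across the tree."""
        feats = self.all_features()
        dupes = sorted({f for f in feats if feats.count(f) > 1})
        if dupes:
            raise HierarchyError(f"features appear in more than one leaf: {dupes}")
        names = [p for p, _ in self.walk()]
        if len(names) != len(set(names)):
            raise HierarchyError("group paths are not unique")

    def walk(self, prefix: str = "") -> list[tuple[str, "FeatureHierarchy"]]:
        """All (path, node) pairs in pre-order; the root path is its name."""
        path = f"{prefix}/{self.name}" if prefix else self.name
        out = [(path, self)]
        for child in self.children:
            out.extend(child.walk(path))
        return out

    def find(self, path: str) -> "FeatureHierarchy":
        """Resolve a path relative to (and excluding) the root name."""
        node = self
        if path in ("", node.name):
            return node
        for part in path.split("/"):
            for child in node.children:
                if child.name == part:
                    node = child
                    break
            else:
                raise HierarchyError(f"no node {part!r} under {node.name!r}")
        return node

    # -- restriction ------------------------------------------------------

    def restrict(
        self, include: list[str] | None = None, exclude: list[str] | None = None
    ) -> "FeatureHierarchy":
        """A copy keeping only the ``include`` subtrees minus ``exclude`` ones.

        Paths are relative to the root (e.g. ``"MRI/VisualMTA"``). With
        ``include=None`` the whole tree is kept. Excluded nodes are pruned
        before any fitting, so they contribute nothing.
        """
        for p in (include or []) + (exclude or []):
            self.find(p)  # raises on unknown paths
        keep = None if include is None else set(include)
        drop = set(exclude or [])

        def rebuild(node: "FeatureHierarchy", path: str, kept: bool):
            if path in drop:
                return None
            kept = kept or keep is None or path in keep
            if node.features:
                return (
                    FeatureHierarchy(name=node.name, features=list(node.features))
                    if kept
                    else None
                )
            children = []
            for child in node.children:
                sub = rebuild(child, f"{path}/{child.name}" if path else child.name, kept)
                if sub is not None:
                    children.append(sub)
            if not children:
                return None
            return FeatureHierarchy(name=node.name, children=children)

        children = []
        for child in self.children:
            sub = rebuild(child, child.name, keep is None)
            if sub is not None:
                children.append(sub)
        if not children and self.features:
            return FeatureHierarchy(name=self.name, features=list(self.features))
        if not children:
            raise HierarchyError("restriction removed every feature")
        return FeatureHierarchy(name=self.name, children=children)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        if self.features:
            return {"name": self.name, "features": list(self.features)}
        return {"name": self.name, "children": [c.to_dict() for c in self.children]}

    @classmethod
    def from_dict(cls, spec: dict) -> "FeatureHierarchy":
        if "features" in spec:
            return cls(name=spec["name"], features=list(spec["features"]))
        return cls(
            name=spec["name"],
            children=[cls.from_dict(c) for c in spec.get("children", [])],
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = json.dumps(self.to_dict(), indent=2)
        if path.suffix in (".yaml", ".yml"):
            text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        path.write_text(text + "\n")


def load_hierarchy(path: str | Path) -> FeatureHierarchy:
    """Load a hierarchy from a JSON or YAML tree of {name, children|features}."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        spec = yaml.safe_load(path.read_text())
    else:
        spec = json.loads(path.read_text())
    tree = FeatureHierarchy.from_dict(spec)
    tree.validate()
    return tree


def default_hierarchy() -> FeatureHierarchy:
    """The packaged factor grouping used throughout the analysis."""
    spec = json.loads(
        resources.files("dsiscreen.data").joinpath("hierarchy.json").read_text()
    )
    tree = FeatureHierarchy.from_dict(spec)
    tree.validate()
    return tree
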
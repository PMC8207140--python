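"""Interpretable YES/NO flowchart over motif presence with per-node
class composition.

A shallow CART tree (Gini impurity, fixed depth and leaf-size floors) is
fitted on binary presence features, then re-expressed as a flowchart:
each node tests one motif, its YES branch holds the genes carrying the
motif, and every node is annotated with the percentage of genes it
receives from its parent and its five-class composition.  The branch
composition statistic quantifies how concentrated one expression type is
in a branch relative to its overall share:

    pct = (share of type in branch) * (share of all genes in branch)
          / ((overall type share) / (overall share)) * 100
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FlowNode",
    "fit_flowchart",
    "branch_type_percentage",
    "render_flowchart",
    "flowchart_to_json",
    "flowchart_from_json",
    "flowchart_to_dot",
]


@dataclass
class FlowNode:
    """One flowchart box: motif test (or leaf), composition, children."""

    motif: str | None
    n_genes: int
    fraction_of_parent: float  # percent
    composition: dict[str, float]  # class -> percent, sums to 100
    yes: "FlowNode | None" = None
    no: "FlowNode | None" = None
    extra: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.motif is None

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "n_genes": self.n_genes,
            "fraction_of_parent": self.fraction_of_parent,
            "composition": self.composition,
            "yes": self.yes.to_dict() if self.yes else None,
            "no": self.no.to_dict() if self.no else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlowNode":
        return cls(
            motif=d["motif"],
            n_genes=d["n_genes"],
            fraction_of_parent=d["fraction_of_parent"],
            composition=dict(d["composition"]),
            yes=cls.from_dict(d["yes"]) if d.get("yes") else None,
            no=cls.from_dict(d["no"]) if d.get("no") else None,
        )


def branch_type_percentage(
    p_type_in_branch: float,
    p_all_in_branch: float,
    p_type_overall: float = 0.20,
    p_all_overall: float = 1.0,
) -> float:
    """Branch composition statistic, as a percentage.

    ((share of the type within the branch) x (share of all genes in the
    branch)) / ((overall type share) / (overall share)), e.g.
    (0.05 * 0.50) / (0.20 / 1.0) = 0.125 -> 12.5%.  Values above 100%
    are reported raw.
    """
    for v in (p_type_in_branch, p_all_in_branch, p_type_overall, p_all_overall):
        if not 0.0 <= v <= 1.0:
            raise ValueError("all inputs must lie in [0, 1]")
    if p_type_overall == 0:
        raise ValueError("overall type share must be positive")
    return (p_type_in_branch * p_all_in_branch) / (p_type_overall / p_all_overall) * 100.0


def fit_flowchart(
    features: pd.DataFrame,
    labels,
    max_depth: int = 5,
    min_leaf: int = 10,
    class_order: list[str] | None = None,
    seed: int = 0,
) -> FlowNode:
    """Fit a CART tree on binary presence features and return the flowchart.

    Splits use Gini impurity; with 0/1 features every split reads as
    "motif present (YES) / absent (NO)".  Node compositions and
    fractions are computed from the training genes routed through each
    node, so the flowchart is an exact summary of the fitted tree.
    """
    if len(features) == 0:
        raise ValueError("empty data")
    labels = pd.Series(np.asarray(labels), index=features.index)
    if class_order is None:
        class_order = sorted(labels.unique())
    X = features.to_numpy(float)
    y = np.asarray([class_order.index(c) for c in labels])

    if len(class_order) == 1:
        return FlowNode(
            motif=None,
            n_genes=len(y),
            fraction_of_parent=100.0,
            composition={class_order[0]: 100.0},
        )

    tree = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=seed % (2**31 - 1),
    ).fit(X, y)
    t = tree.tree_

    # class counts per node from the genes actually routed through it
    node_counts = np.zeros((t.node_count, len(class_order)), int)
    path = tree.decision_path(X)
    for cls in range(len(class_order)):
        rows = np.flatnonzero(y == cls)
        node_counts[:, cls] = np.asarray(path[rows].sum(axis=0)).ravel()

    feature_names = list(features.columns)

    def build(node: int, parent_n: int) -> FlowNode:
        n = int(node_counts[node].sum())
        comp = {
            cls: round(100.0 * node_counts[node, j] / n, 10) if n else 0.0
            for j, cls in enumerate(class_order)
        }
        is_leaf = t.children_left[node] == -1
        fn = FlowNode(
            motif=None if is_leaf else feature_names[t.feature[node]],
            n_genes=n,
            fraction_of_parent=100.0 * n / parent_n if parent_n else 100.0,
            composition=comp,
        )
        if not is_leaf:
            # 0/1 features split at 0.5: left child = absent (NO), right = present (YES)
            fn.no = build(t.children_left[node], n)
            fn.yes = build(t.children_right[node], n)
        return fn

    return build(0, len(y))


def _render_lines(node: FlowNode, class_order: list[str], indent: int) -> list[str]:
    pad = "    " * indent
    comp = " ".join(f"{node.composition.get(c, 0.0):.0f}" for c in class_order)
    head = f"[{comp}] n={node.n_genes} ({node.fraction_of_parent:.0f}% of parent)"
    if node.is_leaf:
        return [f"{pad}{head}"]
    lines = [f"{pad}{head}  test: {node.motif}"]
    lines.append(f"{pad}  present (YES), {node.yes.fraction_of_parent:.0f}%:")
    lines.extend(_render_lines(node.yes, class_order, indent + 1))
    lines.append(f"{pad}  absent (NO), {node.no.fraction_of_parent:.0f}%:")
    lines.extend(_render_lines(node.no, class_order, indent + 1))
    return lines


def render_flowchart(root: FlowNode) -> str:
    """Indented text rendering with present (YES) / absent (NO) branches."""
    class_order = list(root.composition.keys())
    header = "composition order: " + ", ".join(class_order)
    return "\n".join([header] + _render_lines(root, class_order, 0)) + "\n"


def flowchart_to_json(root: FlowNode, path: str | None = None) -> str:
    text = json.dumps(root.to_dict(), indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def flowchart_from_json(text_or_path: str) -> FlowNode:
    if text_or_path.lstrip().startswith("{"):
        return FlowNode.from_dict(json.loads(text_or_path))
    with open(text_or_path) as fh:
        return FlowNode.from_dict(json.load(fh))


def flowchart_to_dot(root: FlowNode) -> str:
    """Graphviz DOT rendering (optional output)."""
    lines = ["digraph flowchart {", "  node [shape=box];"]
    counter = [0]

    def walk(node: FlowNode) -> int:
        my_id = counter[0]
        counter[0] += 1
        comp = "\\n".join(f"{c}: {v:.0f}%" for c, v in node.composition.items())
        label = (node.motif or "leaf") + f"\\nn={node.n_genes}\\n{comp}"
        lines.append(f'  n{my_id} [label="{label}"];')
        if not node.is_leaf:
            yid = walk(node.yes)
            nid = walk(node.no)
            lines.append(f'  n{my_id} -> n{yid} [label="YES {node.yes.fraction_of_parent:.0f}%"];')
            lines.append(f'  n{my_id} -> n{nid} [label="NO {node.no.fraction_of_parent:.0f}%"];')
        return my_id

    walk(root)
    lines.append("}")
    return "\n".join(lines) + "\n"
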
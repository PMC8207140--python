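"""Co-expression regulon assignment from log2-ratio expression matrices.

The workflow mirrors weighted correlation network analysis on a
differentially expressed gene (DEG) set: signed Pearson adjacency raised
to a soft-threshold power, topological overlap (TOM) similarity,
average-linkage hierarchical clustering cut to a fixed number of
modules, and semantic labeling of each module by cosine similarity of
its centroid to the class expression templates.  "No response" genes —
the least-affected genes below two-fold everywhere — are carried as a
fifth, separately selected set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .synthgen import RESPONSIVE_CLASSES, class_templates_default

__all__ = [
    "ClusterParams",
    "RegulonAssignment",
    "geometric_mean_merge",
    "select_deg",
    "select_no_response",
    "topological_overlap",
    "cluster_regulons",
]


@dataclass(frozen=True)
class ClusterParams:
    """Network construction parameters (soft threshold, module count)."""

    beta: float = 6.0
    k_modules: int = 4
    linkage: str = "average"
    correlation: str = "pearson-signed"
    min_module_size: int = 30

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("soft-threshold power beta must be >= 1")
        if self.k_modules < 2:
            raise ValueError("k_modules must be >= 2")


@dataclass
class RegulonAssignment:
    """Gene -> regulon label plus module centroids and raw module ids."""

    labels: pd.Series
    module_ids: pd.Series
    centroids: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def geometric_mean_merge(matrix: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Merge condition columns by geometric mean of the underlying ratios.

    On the log2 scale the geometric mean of ratios is the arithmetic mean
    of the log2 values, so each output column is the mean of its members.
    """
    out = {}
    for name, members in groups.items():
        if not members:
            raise ValueError(f"merge group {name!r} is empty")
        missing = [m for m in members if m not in matrix.columns]
        if missing:
            raise KeyError(f"merge group {name!r} names unknown columns {missing}")
        out[name] = matrix[members].mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)


def select_deg(matrix: pd.DataFrame, fold_threshold: float) -> list[str]:
    """Genes whose largest |log2 ratio| over conditions reaches the fold cut.

    A gene is kept iff max_c |log2 value| >= log2(fold_threshold); e.g. a
    2-fold cut keeps |log2| >= 1 and a 2.82-fold cut |log2| >= 1.5.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    cut = np.log2(fold_threshold)
    keep = matrix.abs().max(axis=1) >= cut
    return list(matrix.index[keep])


def select_no_response(matrix: pd.DataFrame, n: int = 100) -> list[str]:
    """The ``n`` least-affected genes, all below two-fold everywhere.

    Ranked by the maximum |log2 ratio| across conditions, ties broken by
    gene id so the output is deterministic.  If fewer than ``n`` genes
    fall below two-fold, all eligible genes are returned with a warning.
    """
    strength = matrix.abs().max(axis=1)
    eligible = strength[strength < 1.0]
    order = sorted(eligible.index, key=lambda g: (eligible[g], g))
    if len(order) < n:
        warnings.warn(
            f"only {len(order)} genes below two-fold everywhere; requested {n}",
            stacklevel=2,
        )
        return order
    return order[:n]


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted network.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivity k_i = sum_u a_iu (zero diagonal assumed); TOM_ii = 1.
    """
    a = np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _cut_modules(
    tree: np.ndarray, values: np.ndarray, params: ClusterParams
) -> np.ndarray:
    """Cut the dendrogram into exactly ``k_modules`` sizeable modules.

    A plain maxclust cut at k can spend modules on stray weakly
    connected genes (average linkage merges them last), so the cut is
    deepened until at least ``k_modules`` clusters reach
    ``min_module_size``; the k largest such clusters become the modules
    and every remaining gene joins the module whose expression centroid
    it correlates with best.  Module ids are renumbered 1..k in
    decreasing size order, so the result is deterministic.
    """
    n = values.shape[0]
    min_size = min(params.min_module_size, max(1, n // (2 * params.k_modules)))
    chosen = None
    for t in range(params.k_modules, min(n, params.k_modules + 50) + 1):
        cand = fcluster(tree, t=t, criterion="maxclust")
        ids, sizes = np.unique(cand, return_counts=True)
        big = ids[sizes >= min_size]
        if len(big) >= params.k_modules:
            order = big[np.argsort(-sizes[np.isin(ids, big)], kind="stable")]
            chosen = (cand, order[: params.k_modules])
            break
    if chosen is None:  # degenerate: fall back to the plain cut
        cand = fcluster(tree, t=params.k_modules, criterion="maxclust")
        ids, sizes = np.unique(cand, return_counts=True)
        chosen = (cand, ids[np.argsort(-sizes, kind="stable")][: params.k_modules])
    cand, kept = chosen
    modules = np.zeros(n, int)
    for new_id, old_id in enumerate(kept, start=1):
        modules[cand == old_id] = new_id
    leftovers = np.flatnonzero(modules == 0)
    if leftovers.size:
        centroids = np.vstack(
            [values[modules == m].mean(axis=0) for m in range(1, params.k_modules + 1)]
        )
        for i in leftovers:
            r = np.corrcoef(np.vstack([values[i], centroids]))[0, 1:]
            modules[i] = int(np.argmax(r)) + 1
    return modules


def _label_modules(centroids: pd.DataFrame, templates: pd.DataFrame) -> dict[int, str]:
    """Map module ids to template names by cosine similarity.

    Each module takes its best-matching template; if two modules claim
    the same template, the conflict is resolved by a maximum-similarity
    one-to-one assignment.
    """
    c = centroids.to_numpy(float)
    t = templates.to_numpy(float)
    cn = c / np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-12)
    tn = t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
    sim = cn @ tn.T
    best = sim.argmax(axis=1)
    if len(set(best)) < len(best) and sim.shape[0] <= sim.shape[1]:
        rows, cols = linear_sum_assignment(-sim)
        best = np.empty(sim.shape[0], int)
        best[rows] = cols
    return {
        int(mod): str(templates.index[j])
        for mod, j in zip(centroids.index, best)
    }


def cluster_regulons(
    matrix: pd.DataFrame,
    deg_genes: list[str],
    params: ClusterParams = ClusterParams(),
    no_response_genes: list[str] | None = None,
    templates: pd.DataFrame | None = None,
) -> RegulonAssignment:
    """Cluster DEG genes into regulons and label them by template match.

    Builds the signed adjacency ``((1 + r) / 2) ** beta`` on the DEG
    subset, clusters ``1 - TOM`` with average linkage, cuts the tree at
    ``k_modules`` and names each module after the class template whose
    cosine similarity to the module centroid is highest.  Genes with zero
    expression variance cannot enter a Pearson network and are dropped
    with a warning.  ``no_response_genes`` are appended with label
    ``"none"``.
    """
    if templates is None:
        templates = class_templates_default().loc[list(RESPONSIVE_CLASSES)]
    notes: list[str] = []
    deg_genes = sorted(set(deg_genes))
    sub = matrix.loc[deg_genes]
    variances = sub.to_numpy(float).var(axis=1)
    constant = [g for g, v in zip(deg_genes, variances) if v == 0.0]
    if constant:
        msg = f"excluded {len(constant)} constant-expression genes from clustering"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
        sub = sub.drop(index=constant)
    if len(sub) < params.k_modules:
        raise ValueError("fewer DEG genes than requested modules")

    values = sub.to_numpy(float)
    r = np.corrcoef(values)
    adjacency = ((1.0 + r) / 2.0) ** params.beta
    np.fill_diagonal(adjacency, 0.0)
    tom = topological_overlap(adjacency)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    tree = linkage(squareform(dist, checks=False), method=params.linkage)
    modules = _cut_modules(tree, values, params)

    centroids = (
        pd.DataFrame(values, index=sub.index, columns=sub.columns)
        .groupby(pd.Series(modules, index=sub.index))
        .mean()
    )
    label_of = _label_modules(centroids[templates.columns], templates)

    labels = pd.Series([label_of[int(m)] for m in modules], index=sub.index, name="label")
    module_ids = pd.Series(modules, index=sub.index, name="module_id")
    if no_response_genes:
        overlap = set(no_response_genes) & set(labels.index)
        if overlap:
            raise ValueError("no-response genes overlap the DEG set")
        none_labels = pd.Series("none", index=list(no_response_genes), name="label")
        labels = pd.concat([labels, none_labels])
        module_ids = pd.concat(
            [module_ids, pd.Series(0, index=list(no_response_genes), name="module_id")]
        )
    return RegulonAssignment(labels, module_ids, centroids, notes)
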
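"""Positional motif profiles around the TSS and fold-change coverage bins.

The positional profile counts, in fixed-width windows tiling a
TSS-relative span (default -3000..+2000 in 50 bp steps), the fraction of
genes with at least one motif hit starting inside each window — once for
a gene set of interest and once for all genes — and reports their ratio.
Coverage bins stratify genes by expression fold change (ratio scale) and
report the percentage of genes per bin whose scan window contains the
motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionalProfile",
    "CoverageBins",
    "DEFAULT_FOLD_EDGES",
    "positional_profile",
    "coverage_by_foldchange",
    "plot_profile",
    "plot_coverage",
]

# Fold-change bin edges on the ratio scale, from "suppressed below 0.2"
# up to "induced over 5-fold".
DEFAULT_FOLD_EDGES = (0.0, 0.2, 0.5, 0.66, 1.5, 2.0, 3.0, 5.0, np.inf)


@dataclass
class PositionalProfile:
    """Per-window hit frequencies for a gene set, all genes, and their ratio."""

    edges: np.ndarray  # window left edges, TSS-relative
    width: int
    set_freq: np.ndarray
    all_freq: np.ndarray
    relative: np.ndarray
    undefined: np.ndarray  # windows where set_freq > 0 but all_freq == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.edges,
                "window_end": self.edges + self.width,
                "set_freq": self.set_freq,
                "all_freq": self.all_freq,
                "relative": self.relative,
            }
        )


@dataclass
class CoverageBins:
    """Fold-change bins with gene counts and per-bin motif coverage %."""

    edges: np.ndarray
    counts: np.ndarray
    coverage_pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
            for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]
        return pd.DataFrame(
            {"bin": labels, "n_genes": self.counts, "coverage_pct": self.coverage_pct}
        )


def _per_gene_positions(
    hits: Iterable[tuple[str, int]] | Mapping[str, Sequence[int]],
) -> dict[str, list[int]]:
    if isinstance(hits, Mapping):
        return {g: list(p) for g, p in hits.items()}
    out: dict[str, list[int]] = {}
    for gene, pos in hits:
        out.setdefault(gene, []).append(pos)
    return out


def positional_profile(
    hits: Iterable[tuple[str, int]] | Mapping[str, Sequence[int]],
    gene_set: Iterable[str],
    all_genes: Iterable[str],
    span: tuple[int, int] = (-3000, 2000),
    width: int = 50,
) -> PositionalProfile:
    """Per-window fraction of genes with >= 1 hit, for a set and for all genes.

    ``hits`` carries TSS-relative match start positions per gene.  The
    relative profile is set_freq / all_freq with the conventions
    0/0 -> 1 and x/0 (x > 0) -> inf, flagged in ``undefined``.
    """
    lo, hi = span
    if (hi - lo) % width != 0:
        raise ValueError("window width must divide the span")
    gene_set = sorted(set(gene_set))
    all_genes = sorted(set(all_genes))
    if not gene_set:
        raise ValueError("empty gene set")
    positions = _per_gene_positions(hits)
    edges = np.arange(lo, hi, width)
    n_windows = len(edges)

    def freq(genes: list[str]) -> np.ndarray:
        counts = np.zeros(n_windows)
        for g in genes:
            if g not in positions:
                continue
            windows = {
                (p - lo) // width for p in positions[g] if lo <= p < hi
            }
            for w in windows:
                counts[w] += 1
        return counts / len(genes)

    set_freq = freq(gene_set)
    all_freq = freq(all_genes)
    relative = np.ones(n_windows)
    undefined = np.zeros(n_windows, bool)
    nonzero = all_freq > 0
    relative[nonzero] = set_freq[nonzero] / all_freq[nonzero]
    bad = (~nonzero) & (set_freq > 0)
    relative[bad] = np.inf
    undefined[bad] = True
    return PositionalProfile(edges, width, set_freq, all_freq, relative, undefined)


def coverage_by_foldchange(
    presence: pd.Series,
    expression: pd.Series,
    bins: Sequence[float] = DEFAULT_FOLD_EDGES,
) -> CoverageBins:
    """Motif coverage % of genes binned by expression fold change.

    ``presence`` is the motif's 0/1 column of a feature matrix (scan
    window -500..+150 by convention); ``expression`` the log2 ratios of
    one condition.  Fold-change bins are on the ratio scale.  A gene
    without an expression value is an error.
    """
    edges = np.asarray(bins, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    missing = [g for g in presence.index if g not in expression.index]
    if missing:
        raise ValueError(f"genes missing expression values: {missing[:5]}")
    expr = expression.loc[presence.index]
    ratios = np.power(2.0, expr.to_numpy(float))
    if ratios.min() < edges[0] or ratios.max() > edges[-1]:
        raise ValueError("bins do not cover all observed fold changes")
    which = np.clip(np.searchsorted(edges, ratios, side="right") - 1, 0, len(edges) - 2)
    counts = np.zeros(len(edges) - 1, int)
    hits = np.zeros(len(edges) - 1, int)
    pres = presence.to_numpy()
    for b, p in zip(which, pres):
        counts[b] += 1
        hits[b] += int(p > 0)
    with np.errstate(invalid="ignore"):
        coverage = np.where(counts > 0, hits / np.maximum(counts, 1) * 100.0, 0.0)
    return CoverageBins(edges, counts, coverage)


def plot_profile(profile: PositionalProfile, path: str, title: str = "") -> None:
    """Line plot of set/all frequencies and their ratio (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = profile.edges + profile.width / 2
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    ax1.plot(centers, profile.all_freq, label="all genes", color="tab:blue")
    ax1.plot(centers, profile.set_freq, label="gene set", color="tab:red")
    ax1.set_ylabel("fraction of genes with hit")
    ax1.legend()
    if title:
        ax1.set_title(title)
    finite = np.where(np.isfinite(profile.relative), profile.relative, np.nan)
    ax2.plot(centers, finite, color="black")
    ax2.axhline(1.0, ls=":", color="grey")
    ax2.set_xlabel("position relative to TSS (bp)")
    ax2.set_ylabel("set / all")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_coverage(bins: CoverageBins, path: str, title: str = "") -> None:
    """Bar plot of per-bin coverage percentages (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = bins.to_frame()
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(range(len(frame)), frame["coverage_pct"], color="tab:red")
    ax.set_xticks(range(len(frame)))
    ax.set_xticklabels(frame["bin"], rotation=45, ha="right")
    ax.set_ylabel("genes with motif (%)")
    ax.set_xlabel("expression fold change")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
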
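"""Synthetic genomes, gene models, planted promoter motifs and expression.

The generator emulates the statistical structure of a stress-response
microarray study of iron (Fe) excess in rice: five gene classes (Fe
storage, Fe uptake, metal chelator, WRKY co-expression, no response),
seven log2-ratio conditions (five Fe-excess tissues plus Fe-deficient and
Zn-deficient root), class-specific promoter motifs planted with a
TSS-proximal positional bias, and an i.i.d. background genome with
configurable base composition.

Planted motif instances overwrite background bases in place (no
insertion), so all coordinates stay aligned to the TSS.  For a fixed seed
the whole dataset — genome, gene models, expression, truth — regenerates
bit-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .seqio import GeneModel, write_fasta, write_gene_models

__all__ = [
    "CLASSES",
    "RESPONSIVE_CLASSES",
    "CONDITIONS",
    "MotifPlan",
    "SynthConfig",
    "SyntheticDataset",
    "class_templates_default",
    "default_motif_plan",
    "generate_dataset",
    "write_dataset",
]

CLASSES = ("storage", "uptake", "chelator", "wrky", "none")
RESPONSIVE_CLASSES = CLASSES[:4]
CONDITIONS = (
    "fe_excess_root",
    "fe_excess_dc",
    "fe_excess_stem",
    "fe_excess_old_leaf",
    "fe_excess_newest_leaf",
    "fe_def_root",
    "zn_def_root",
)

# Strand-pooled A/T vs C/G weights of the rice promoter background,
# normalized to probabilities.
DEFAULT_BASE_COMPOSITION = {"A": 0.26, "C": 0.24, "G": 0.24, "T": 0.26}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def class_templates_default() -> pd.DataFrame:
    """Default 5-class x 7-condition log2-ratio templates.

    Sign structure: Fe-storage genes are up under Fe excess in every
    tissue and down in the Fe-deficient root; Fe-uptake genes are the
    mirror image (suppressed under Fe excess, strongest in the root, up
    under Fe deficiency); metal-chelator genes are up under Fe excess and
    Zn deficiency; WRKY co-expression genes are up in the Fe-excess stem
    and down in the Fe-deficient root; no-response genes sit at zero.
    Magnitudes (|log2| up to ~2.5) are package choices.
    """
    rows = {
        "storage": [2.0, 2.0, 2.0, 2.0, 2.0, -2.0, 0.0],
        "uptake": [-2.0, -0.5, -0.5, -0.5, -0.5, 2.0, 0.0],
        "chelator": [1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 2.5],
        "wrky": [-1.0, 0.0, 2.5, 0.0, 0.0, -0.5, -0.5],
        "none": [0.0] * 7,
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CONDITIONS))


@dataclass(frozen=True)
class MotifPlan:
    """One motif to plant: consensus, target class, per-gene probability
    and the Normal(mean, sd) of its TSS-relative start position."""

    consensus: str
    target_class: str
    prob: float
    pos_mean: float = -150.0
    pos_sd: float = 120.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("plant probability must lie in [0, 1]")
        if self.target_class not in CLASSES:
            raise ValueError(f"unknown target class {self.target_class!r}")
        for letter in self.consensus.upper():
            if letter not in IUPAC:
                raise ValueError(f"non-IUPAC letter {letter!r} in consensus")


def default_motif_plan(prob: float = 0.7) -> list[MotifPlan]:
    """One field-named motif per responsive class, TSS-proximal bias."""
    return [
        MotifPlan("CATGCATG", "storage", prob),   # IDEF1-binding
        MotifPlan("CTACGTGC", "uptake", prob),    # bZIP/bHLH-binding
        MotifPlan("GCWGCWGC", "chelator", prob),  # novel degenerate family
        MotifPlan("CGACACGC", "wrky", prob),      # novel
    ]


@dataclass
class SynthConfig:
    """Parameters of one synthetic dataset; defaults are the study conditions."""

    n_genes: int = 1500
    class_proportions: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    promoter_span: tuple[int, int] = (-3000, 2000)
    base_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_COMPOSITION)
    )
    motif_plan: Sequence[MotifPlan] = field(default_factory=default_motif_plan)
    condition_names: Sequence[str] = CONDITIONS
    class_means: pd.DataFrame | None = None
    noise_sd: float = 0.5
    seed: int = 0
    genes_per_contig: int = 50
    gene_spacing: int = 10_000
    gene_length: int = 2000

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, float)
        if props.size != len(CLASSES) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("class_proportions must be 5 nonnegative fractions summing to 1")
        comp = np.asarray([self.base_composition[b] for b in "ACGT"], float)
        if abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("base_composition must be probabilities summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.promoter_span
        if lo >= hi:
            raise ValueError("promoter_span must be a nonempty relative interval")
        span = hi - lo
        for plan in self.motif_plan:
            if len(plan.consensus) > span:
                raise ValueError(
                    f"motif {plan.consensus!r} is wider than the promoter span"
                )
        if self.promoter_span[1] - self.promoter_span[0] > self.gene_spacing:
            raise ValueError("promoter_span exceeds the per-gene contig allowance")
        if self.class_means is None:
            self.class_means = class_templates_default()
        if list(self.class_means.columns) != list(self.condition_names):
            raise ValueError("class_means columns must match condition_names")


@dataclass
class SyntheticDataset:
    """Generated genome, gene models, expression and ground truth."""

    genome: dict[str, str]
    genes: list[GeneModel]
    expression: pd.DataFrame
    truth_labels: dict[str, str]
    truth_hits: list[tuple[str, str, int]]
    config: SynthConfig


def _assign_classes(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    props = np.asarray(config.class_proportions, float)
    counts = np.floor(props * config.n_genes).astype(int)
    # distribute the remainder by largest fractional part, ties by class order
    frac = props * config.n_genes - counts
    for idx in np.argsort(-frac, kind="stable")[: config.n_genes - counts.sum()]:
        counts[idx] += 1
    labels = np.repeat(np.arange(len(CLASSES)), counts)
    return labels[rng.permutation(config.n_genes)]


def _resolve_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        letter if letter in "ACGT" else IUPAC[letter][rng.integers(len(IUPAC[letter]))]
        for letter in consensus.upper()
    )


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset, deterministic for a fixed seed.

    Genes are laid out on contigs of ``genes_per_contig`` genes spaced
    ``gene_spacing`` bp apart, with margins so every promoter span fits
    inside its contig.  Background bases are i.i.d. from the configured
    composition; for each gene of a motif's target class, with the
    configured probability one resolved instance overwrites the
    background at a Normal-drawn, span-clipped TSS-relative position on
    the promoter strand.  Expression rows are the class template plus
    i.i.d. Normal(0, noise_sd) per condition.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.promoter_span
    margin = max(abs(lo), abs(hi), config.gene_length) + 100
    n_contigs = -(-config.n_genes // config.genes_per_contig)

    class_idx = _assign_classes(rng, config)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    strands = np.where(rng.integers(0, 2, config.n_genes) == 0, "+", "-")

    bases = np.frombuffer(b"ACGT", dtype="S1")
    probs = np.asarray([config.base_composition[b] for b in "ACGT"], float)
    probs = probs / probs.sum()

    genes: list[GeneModel] = []
    contigs: dict[str, np.ndarray] = {}
    gene_contig: list[str] = []
    gene_tss: list[int] = []
    for c in range(n_contigs):
        n_here = min(config.genes_per_contig, config.n_genes - c * config.genes_per_contig)
        length = 2 * margin + (n_here - 1) * config.gene_spacing
        contig_name = f"contig{c:03d}"
        contigs[contig_name] = rng.choice(bases, size=length, p=probs)
        for j in range(n_here):
            i = c * config.genes_per_contig + j
            tss = margin + j * config.gene_spacing
            strand = strands[i]
            tes = tss + config.gene_length - 1 if strand == "+" else tss - config.gene_length + 1
            genes.append(GeneModel(gene_ids[i], contig_name, strand, tss, tes))
            gene_contig.append(contig_name)
            gene_tss.append(tss)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    truth_hits: list[tuple[str, str, int]] = []
    for plan in config.motif_plan:
        width = len(plan.consensus)
        target = CLASSES.index(plan.target_class)
        for i in np.flatnonzero(class_idx == target):
            if rng.random() >= plan.prob:
                continue
            rel = int(round(rng.normal(plan.pos_mean, plan.pos_sd)))
            rel = min(max(rel, lo), hi - width)
            instance = _resolve_consensus(rng, plan.consensus)
            arr = contigs[gene_contig[i]]
            tss = gene_tss[i]
            if genes[i].strand == "+":
                for j, b in enumerate(instance):
                    arr[tss + rel + j] = b.encode()
            else:
                for j, b in enumerate(instance):
                    arr[tss - rel - j] = comp[b].encode()
            truth_hits.append((gene_ids[i], plan.consensus, rel))

    templates = config.class_means.to_numpy(float)
    values = templates[class_idx] + rng.normal(
        0.0, config.noise_sd, (config.n_genes, len(config.condition_names))
    )
    expression = pd.DataFrame(values, index=gene_ids, columns=list(config.condition_names))

    genome = {name: arr.tobytes().decode("ascii") for name, arr in contigs.items()}
    truth_labels = {gid: CLASSES[k] for gid, k in zip(gene_ids, class_idx)}
    return SyntheticDataset(genome, genes, expression, truth_labels, truth_hits, config)


def write_dataset(dataset: SyntheticDataset, outdir: str | os.PathLike) -> dict[str, str]:
    """Write FASTA/GFF3/BED/TSV/JSON/YAML artifacts; returns path map."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "bed": os.path.join(outdir, "genes.bed"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "config.yaml"),
    }
    write_fasta(dataset.genome, paths["genome"])
    write_gene_models(dataset.genes, paths["gff3"], "gff3")
    write_gene_models(dataset.genes, paths["bed"], "bed")
    dataset.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "labels": dataset.truth_labels,
                "hits": [list(h) for h in dataset.truth_hits],
            },
            fh,
            indent=1,
        )
    cfg = dataset.config
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "n_genes": cfg.n_genes,
                "class_proportions": [float(p) for p in cfg.class_proportions],
                "promoter_span": list(cfg.promoter_span),
                "base_composition": {k: float(v) for k, v in cfg.base_composition.items()},
                "motif_plan": [
                    {
                        "consensus": p.consensus,
                        "target_class": p.target_class,
                        "prob": p.prob,
                        "pos_mean": p.pos_mean,
                        "pos_sd": p.pos_sd,
                    }
                    for p in cfg.motif_plan
                ],
                "condition_names": list(cfg.condition_names),
                "class_means": {
                    str(k): [float(x) for x in row]
                    for k, row in cfg.class_means.iterrows()
                },
                "noise_sd": cfg.noise_sd,
                "seed": cfg.seed,
                "genes_per_contig": cfg.genes_per_contig,
                "gene_spacing": cfg.gene_spacing,
                "gene_length": cfg.gene_length,
            },
            fh,
            sort_keys=False,
        )
    return paths
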
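"""Sequence and gene-model I/O plus strand-aware promoter window extraction.

All coordinates are internally 0-based. A gene's transcription start site
(TSS) anchors every window; relative coordinates are half-open, with the
TSS base itself at relative position 0.  On the minus strand a window is
taken from the opposite genomic side and reverse-complemented so that the
returned sequence always reads 5'->3' on the promoter (sense) strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "WindowSpec",
    "PromoterWindow",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "extract_window",
    "extract_windows",
    "windows_to_fasta",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene: contig, strand and its TSS/TES (both 0-based, inclusive)."""

    gene_id: str
    contig: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )


@dataclass(frozen=True)
class WindowSpec:
    """Half-open TSS-relative interval [start_rel, end_rel).

    The TSS base sits at relative position 0, so a "-500 to +150" window
    is ``WindowSpec(-500, 150)`` and spans 650 bp including the TSS base.
    """

    start_rel: int
    end_rel: int

    def __post_init__(self) -> None:
        if self.start_rel >= self.end_rel:
            raise ValueError("WindowSpec requires start_rel < end_rel")

    def __len__(self) -> int:
        return self.end_rel - self.start_rel

    @property
    def name(self) -> str:
        return f"{self.start_rel}..{self.end_rel}"


@dataclass
class PromoterWindow:
    """Extracted promoter-strand sequence for one gene and one WindowSpec."""

    gene_id: str
    spec: WindowSpec
    sequence: str
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered dict of uppercase strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def _infer_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".gff", ".gff3")):
        return "gff3"
    if lower.endswith(".bed"):
        return "bed"
    raise ValueError(f"cannot infer gene-model format from {path!r}")


def read_gene_models(
    path: str | os.PathLike,
    format: str | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3 (gene features) or BED6.

    GFF3 1-based inclusive coordinates are converted to internal 0-based.
    On the minus strand the TSS is the feature end and the TES the feature
    start.  If ``contig_lengths`` is given, coordinates are validated and
    an out-of-contig record raises an error naming it.
    """
    fmt = format or _infer_format(str(path))
    if fmt == "gff3":
        df = pr.read_gff3(str(path)).df
        df = df[df["Feature"] == "gene"]
        ids = df["ID"].astype(str)
    elif fmt == "bed":
        df = pr.read_bed(str(path)).df
        ids = df["Name"].astype(str)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")

    models = []
    for gene_id, contig, start, end, strand in zip(
        ids, df["Chromosome"].astype(str), df["Start"], df["End"], df["Strand"]
    ):
        start, end = int(start), int(end)
        if strand == "+":
            tss, tes = start, end - 1
        elif strand == "-":
            tss, tes = end - 1, start
        else:
            raise ValueError(f"gene {gene_id!r}: unknown strand symbol {strand!r}")
        if contig_lengths is not None:
            clen = contig_lengths.get(contig)
            if clen is None:
                raise ValueError(f"gene {gene_id!r}: contig {contig!r} not in genome")
            if start < 0 or end > clen:
                raise ValueError(
                    f"gene {gene_id!r}: coordinates {start}-{end} exceed "
                    f"contig {contig!r} length {clen}"
                )
        models.append(GeneModel(gene_id, contig, strand, tss, tes))
    return models


def write_gene_models(genes: Iterable[GeneModel], path: str | os.PathLike, format: str) -> None:
    """Write gene models as GFF3 (1-based inclusive) or a BED6 mirror."""
    genes = list(genes)
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                lo, hi = sorted((g.tss, g.tes))
                fh.write(
                    f"{g.contig}\t.\tgene\t{lo + 1}\t{hi + 1}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
        elif format == "bed":
            for g in genes:
                lo, hi = sorted((g.tss, g.tes))
                fh.write(f"{g.contig}\t{lo}\t{hi + 1}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            raise ValueError(f"unknown gene-model format {format!r}")


def extract_window(
    genome: Mapping[str, str], gene: GeneModel, spec: WindowSpec
) -> PromoterWindow:
    """Extract the TSS-anchored window for one gene, promoter-strand oriented.

    Plus strand: genomic ``[tss+start_rel, tss+end_rel)``.  Minus strand:
    genomic ``(tss-end_rel, tss-start_rel]`` reverse-complemented.  Parts
    falling outside the contig are clipped (never an error) and flagged;
    a fully out-of-contig window yields an empty, clipped sequence.
    """
    if gene.contig not in genome:
        raise KeyError(f"contig {gene.contig!r} not present in genome")
    contig = genome[gene.contig]
    if gene.strand == "+":
        gstart = gene.tss + spec.start_rel
        gend = gene.tss + spec.end_rel
    else:
        gstart = gene.tss - spec.end_rel + 1
        gend = gene.tss - spec.start_rel + 1
    cstart = max(0, gstart)
    cend = min(len(contig), gend)
    clipped = (cstart != gstart) or (cend != gend)
    seq = contig[cstart:cend].upper() if cstart < cend else ""
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return PromoterWindow(gene.gene_id, spec, seq, clipped=clipped)


def extract_windows(
    genome: Mapping[str, str], genes: Iterable[GeneModel], spec: WindowSpec
) -> dict[str, PromoterWindow]:
    """Extract one window per gene, keyed by gene id."""
    return {g.gene_id: extract_window(genome, g, spec) for g in genes}


def windows_to_fasta(
    windows: Mapping[str, PromoterWindow] | Iterable[PromoterWindow],
    path: str | os.PathLike,
) -> None:
    """Export windows as FASTA with headers ``gene_id|start_rel|end_rel``."""
    if isinstance(windows, Mapping):
        windows = windows.values()
    seqs = {
        f"{w.gene_id}|{w.spec.start_rel}|{w.spec.end_rel}": w.sequence for w in windows
    }
    write_fasta(seqs, path)
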
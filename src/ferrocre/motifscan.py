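"""Catalog/PWM motif scanning and binary presence/absence feature matrices.

Two motif representations are scanned over promoter windows: degenerate
IUPAC consensi (exact set matching, overlapping hits, promoter strand by
default) and position weight matrices scored as log2-odds against a
background composition, with a hit threshold expressed as a fraction of
the PWM's maximum attainable score.  Scanning results are summarized as
gene x motif binary presence matrices — the feature representation used
by the downstream expression-type classifiers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifdisc import Motif, iupac_pattern
from .seqio import PromoterWindow

__all__ = [
    "PWM",
    "load_known_catalog",
    "read_motif_tsv",
    "write_motif_tsv",
    "read_meme",
    "write_meme",
    "pwm_logodds_scan",
    "scan_window",
    "presence_matrix",
]

# Strand-pooled promoter base weights A/T=0.52, C/G=0.48 normalized to
# probabilities (A=T=0.26, C=G=0.24).
DEFAULT_SCAN_BACKGROUND = (0.26, 0.24, 0.24, 0.26)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position weight matrix with per-position base probabilities."""

    name: str
    probabilities: np.ndarray  # width x 4, columns A,C,G,T
    background: Sequence[float] = DEFAULT_SCAN_BACKGROUND

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, float)
        bg = np.asarray(self.background, float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError("PWM probabilities must be width x 4")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if np.any((bg == 0) & (self.probabilities > 0).any(axis=0)):
            raise ValueError(
                f"PWM {self.name!r}: zero background probability for a base "
                "with nonzero column probability"
            )
        self.background = bg

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def logodds(self) -> np.ndarray:
        """log2(p / q) per position and base; zero-probability cells -> -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background[None, :])

    def max_score(self) -> float:
        return float(self.logodds().max(axis=1).sum())


def load_known_catalog() -> list[Motif]:
    """Fixture catalog of Fe-homeostasis CREs and PLACE-style motifs.

    Sources: ``known-Fe`` for elements reported from Fe/Zn nutrition
    studies (IDE1/IDE2/IDRS, IDEF1/IDEF2/OsIRO2/WRKY binding sites) and
    ``PLACE-like`` for general plant promoter elements.  Bracket-notation
    consensi are expressed as IUPAC letters (IDE2 = CAMGYHH).
    """
    known_fe = [
        ("IDE1", "CATGC"),
        ("IDE2", "CAMGYHH"),
        ("IDRS", "CCTCCAC"),
        ("IDEF1_binding", "CATGCATG"),
        ("OsIRO2_binding", "CACGTGG"),
        ("WRKY_Wbox", "TTGACY"),
        ("bZIP_bHLH", "CTACGTGC"),
        ("Zn_downstream", "ATAATGGC"),
    ]
    place_like = [
        ("DCEp1_FAM1", "AGCTAGCT"),
        ("DCEp2", "ATCGATCG"),
        ("EECCRCAH1", "GANTTNC"),
        ("CRTDREHVCBF2", "GTCGAC"),
        ("GCGC_box", "GCGCGCCA"),
        ("Myb_like", "CACCAACC"),
        ("GCWGCWGC_family", "GCWGCWGC"),
        ("CGACACGC_novel", "CGACACGC"),
        ("TATA_TBP", "CTATAAAT"),
        ("CAB2_DtRE", "CAAAACGC"),
    ]
    return [Motif(n, c, "catalog:known-Fe") for n, c in known_fe] + [
        Motif(n, c, "catalog:PLACE-like") for n, c in place_like
    ]


def read_motif_tsv(path: str | os.PathLike) -> list[Motif]:
    """Read a motif catalog TSV with columns name, consensus, source."""
    df = pd.read_csv(path, sep="\t")
    return [
        Motif(str(r["name"]), str(r["consensus"]), str(r.get("source", "catalog")))
        for _, r in df.iterrows()
    ]


def write_motif_tsv(motifs: Sequence[Motif], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("name\tconsensus\tsource\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.consensus}\t{m.source}\n")


def read_meme(path: str | os.PathLike) -> list[PWM]:
    """Read PWMs from MEME minimal format."""
    pwms: list[PWM] = []
    background = np.asarray(DEFAULT_SCAN_BACKGROUND, float)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    lines = list(lines)
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freqs = lines[i + 1].split()
            background = np.asarray([float(freqs[j]) for j in (1, 3, 5, 7)], float)
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            rows = []
            i += 1
            while i < len(lines):
                row = lines[i].strip()
                if row.startswith("letter-probability"):
                    i += 1
                    continue
                parts = row.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                    i += 1
                else:
                    break
            pwms.append(PWM(name, np.asarray(rows), background.copy()))
            continue
        i += 1
    return pwms


def write_meme(pwms: Sequence[PWM], path: str | os.PathLike) -> None:
    """Write PWMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = np.asarray(pwms[0].background, float) if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0\n"
            )
            for row in p.probabilities:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def pwm_logodds_scan(
    window: PromoterWindow | str, pwm: PWM, threshold_fraction: float = 0.8
) -> list[tuple[int, float]]:
    """All (offset, score) hits with score >= threshold_fraction * max score.

    Scores are summed per-position log2-odds; any 'N' (or other non-ACGT
    base) contributes -inf, so windows containing ambiguous bases can
    never reach the threshold at the affected offsets.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    seq = window.sequence if isinstance(window, PromoterWindow) else str(window)
    lo = pwm.logodds()
    cutoff = threshold_fraction * pwm.max_score()
    idx = np.asarray([_BASE_INDEX.get(b, -1) for b in seq.upper()], int)
    hits = []
    for offset in range(len(seq) - pwm.width + 1):
        segment = idx[offset : offset + pwm.width]
        if np.any(segment < 0):
            continue
        score = float(lo[np.arange(pwm.width), segment].sum())
        if score >= cutoff:
            hits.append((offset, score))
    return hits


def scan_window(
    window: PromoterWindow | str,
    motif: Motif | PWM,
    threshold_fraction: float = 0.8,
    both_strands: bool = False,
) -> list[int]:
    """Hit start offsets of one motif or PWM in one window.

    With ``both_strands=True`` an IUPAC motif is additionally matched as
    its reverse complement (offsets still reported on the promoter
    strand, at the match start).
    """
    seq = window.sequence if isinstance(window, PromoterWindow) else str(window)
    if isinstance(motif, PWM):
        return [off for off, _ in pwm_logodds_scan(seq, motif, threshold_fraction)]
    offsets = [m.start() for m in iupac_pattern(motif.consensus).finditer(seq)]
    if both_strands:
        rc = motif.reverse_complement()
        if rc.consensus != motif.consensus:
            offsets = sorted(
                set(offsets)
                | {m.start() for m in iupac_pattern(rc.consensus).finditer(seq)}
            )
    return offsets


def presence_matrix(
    windows: Mapping[str, PromoterWindow],
    motifs: Sequence[Motif | PWM],
    threshold_fraction: float = 0.8,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Binary gene x motif presence matrix (1 iff >= 1 hit in the window).

    Column order follows the given motif order (catalog first, then
    discovered, by convention of the callers).  Gene order is sorted for
    input-order invariance.
    """
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names in feature set")
    gene_ids = sorted(windows)
    data = np.zeros((len(gene_ids), len(motifs)), dtype=np.int8)
    for j, motif in enumerate(motifs):
        if isinstance(motif, PWM):
            for i, gid in enumerate(gene_ids):
                if pwm_logodds_scan(windows[gid], motif, threshold_fraction):
                    data[i, j] = 1
        else:
            pattern = iupac_pattern(motif.consensus)
            patterns = [pattern]
            if both_strands:
                rc = motif.reverse_complement()
                if rc.consensus != motif.consensus:
                    patterns.append(iupac_pattern(rc.consensus))
            for i, gid in enumerate(gene_ids):
                seq = windows[gid].sequence
                if any(p.search(seq) for p in patterns):
                    data[i, j] = 1
    return pd.DataFrame(data, index=gene_ids, columns=names)
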
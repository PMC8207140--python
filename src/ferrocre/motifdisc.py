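"""Regulon-enriched motif discovery with a per-length enrichment ratio
and a per-gene-presence binomial null.

A motif's enrichment is the occurrence rate per bp in the regulon's
promoter windows divided by the rate in a background window set (all
genes, or same-size random sequence).  Its p-value is the upper binomial
tail of observing at least ``k`` regulon genes carrying the motif out of
``n`` regulon genes, when the chance of a background gene carrying it is
``p``.  Discovery enumerates every exact k-mer present in the regulon
windows, scores each against the background, and ranks by p-value.
Overlapping occurrences are counted, scanning the promoter strand only.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .seqio import PromoterWindow
from .synthgen import IUPAC

__all__ = [
    "Motif",
    "EnrichmentResult",
    "iupac_pattern",
    "count_occurrences",
    "enrichment_ratio",
    "binom_pvalue",
    "score_motif",
    "discover_kmers",
    "merge_to_iupac",
    "random_background",
    "write_enrichment_tsv",
]

_BASE_TO_BITS = {b: frozenset(e) for b, e in IUPAC.items()}
_BITS_TO_BASE = {v: k for k, v in _BASE_TO_BITS.items()}


@dataclass(frozen=True)
class Motif:
    """A fixed-width motif as a (possibly degenerate) IUPAC consensus."""

    name: str
    consensus: str
    source: str = "discovered"

    def __post_init__(self) -> None:
        for letter in self.consensus.upper():
            if letter not in IUPAC:
                raise ValueError(f"non-IUPAC letter {letter!r} in consensus")

    @property
    def width(self) -> int:
        return len(self.consensus)

    def reverse_complement(self) -> "Motif":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(
            _BITS_TO_BASE[frozenset(comp[b] for b in IUPAC[letter])]
            for letter in reversed(self.consensus.upper())
        )
        return Motif(self.name + "_rc", rc, self.source)


@dataclass
class EnrichmentResult:
    """Counts, lengths, enrichment ratio and binomial p for one motif/regulon."""

    motif: Motif
    regulon: str
    k_reg: int
    L_reg: int
    k_bg: int
    L_bg: int
    enrichment: float
    genes_with_motif: int
    n_genes: int
    p_bg_gene: float
    pvalue: float
    bg_zero: bool = False


def iupac_pattern(consensus: str) -> re.Pattern:
    """Overlap-aware regex for an IUPAC consensus.

    Uses a lookahead so tandem instances (e.g. AGCTAGCTAGCT) are all
    counted.  Sequence 'N' matches no motif letter.
    """
    body = "".join(
        letter if letter in "ACGT" else "[" + IUPAC[letter.upper()] + "]"
        for letter in consensus.upper()
    )
    return re.compile(f"(?=({body}))")


def _sequences(windows: Iterable[PromoterWindow | str] | Mapping) -> list[str]:
    if isinstance(windows, Mapping):
        windows = windows.values()
    return [w.sequence if isinstance(w, PromoterWindow) else str(w) for w in windows]


def count_occurrences(
    windows: Iterable[PromoterWindow | str] | Mapping, motif: Motif | str
) -> tuple[int, int]:
    """(total overlapping occurrences, number of windows with >= 1 hit)."""
    consensus = motif.consensus if isinstance(motif, Motif) else motif
    pattern = iupac_pattern(consensus)
    total = 0
    with_hit = 0
    for seq in _sequences(windows):
        n = len(pattern.findall(seq))
        total += n
        with_hit += n > 0
    return total, with_hit


def enrichment_ratio(k_reg: int, L_reg: int, k_bg: int, L_bg: int) -> float:
    """(k_reg / L_reg) / (k_bg / L_bg); +inf when the background count is 0."""
    if min(k_reg, k_bg) < 0:
        raise ValueError("negative occurrence counts")
    if L_reg <= 0 or L_bg <= 0:
        raise ValueError("window lengths must be positive")
    if k_bg == 0:
        return float("inf")
    return (k_reg / L_reg) / (k_bg / L_bg)


def binom_pvalue(genes_with_motif: int, n_genes: int, p_bg_gene: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n_genes, p_bg_gene)."""
    if not 0 <= genes_with_motif <= n_genes:
        raise ValueError("genes_with_motif must lie in [0, n_genes]")
    if not 0.0 <= p_bg_gene <= 1.0:
        raise ValueError("p_bg_gene must lie in [0, 1]")
    if genes_with_motif == 0:
        return 1.0
    return float(binom.sf(genes_with_motif - 1, n_genes, p_bg_gene))


def score_motif(
    motif: Motif | str,
    regulon_windows: Iterable[PromoterWindow | str] | Mapping,
    background_windows: Iterable[PromoterWindow | str] | Mapping,
    regulon: str = "",
) -> EnrichmentResult:
    """Full enrichment + binomial scoring of one motif against a background."""
    if isinstance(motif, str):
        motif = Motif(motif, motif)
    reg = _sequences(regulon_windows)
    bg = _sequences(background_windows)
    if not reg:
        raise ValueError("empty regulon window set")
    L_reg = sum(len(s) for s in reg)
    L_bg = sum(len(s) for s in bg)
    if L_bg == 0:
        raise ValueError("background with zero total length")
    k_reg, genes_with = count_occurrences(reg, motif)
    k_bg, bg_with = count_occurrences(bg, motif)
    p_bg = bg_with / len(bg)
    return EnrichmentResult(
        motif=motif,
        regulon=regulon,
        k_reg=k_reg,
        L_reg=L_reg,
        k_bg=k_bg,
        L_bg=L_bg,
        enrichment=enrichment_ratio(k_reg, L_reg, k_bg, L_bg),
        genes_with_motif=genes_with,
        n_genes=len(reg),
        p_bg_gene=p_bg,
        pvalue=binom_pvalue(genes_with, len(reg), p_bg),
        bg_zero=k_bg == 0,
    )


_CODE = np.full(256, 255, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _kmer_counts(seqs: Sequence[str], k: int) -> tuple[Counter, Counter]:
    """(total occurrence counts, per-window presence counts) of exact k-mers.

    Overlapping occurrences are counted; any window k-mer containing a
    non-ACGT character is skipped.  K-mers are enumerated with a
    vectorized 2-bit encoding (k <= 12 keeps the code table in memory).
    """
    if k > 12:
        raise ValueError("k-mer enumeration supports widths up to 12")
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    all_codes: list[np.ndarray] = []
    all_unique: list[np.ndarray] = []
    for seq in seqs:
        if len(seq) < k:
            continue
        codes = _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]
        view = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (view < 4).all(axis=1)
        if not valid.any():
            continue
        kcodes = view[valid].astype(np.int64) @ powers
        all_codes.append(kcodes)
        all_unique.append(np.unique(kcodes))
    if not all_codes:
        return Counter(), Counter()
    occ_arr = np.bincount(np.concatenate(all_codes), minlength=4**k)
    pres_arr = np.bincount(np.concatenate(all_unique), minlength=4**k)
    nonzero = np.flatnonzero(occ_arr)
    occ = Counter({_decode(int(c), k): int(occ_arr[c]) for c in nonzero})
    presence = Counter({_decode(int(c), k): int(pres_arr[c]) for c in nonzero})
    return occ, presence


def discover_kmers(
    regulon_windows: Iterable[PromoterWindow | str] | Mapping,
    background_windows: Iterable[PromoterWindow | str] | Mapping,
    k: int = 8,
    top_m: int = 50,
    alpha: float = 0.001,
    correction: str | None = "bonferroni",
    regulon: str = "",
) -> list[EnrichmentResult]:
    """Enumerate, score and rank all exact k-mers present in the regulon.

    Ranking is by p-value ascending, then enrichment descending, then
    lexicographic k-mer, and only significant k-mers are returned, at
    most ``top_m`` of them.  With the default Bonferroni correction a
    k-mer is significant when pvalue <= alpha / 4**k, controlling the
    family-wise error over the full k-mer space so that a regulon drawn
    from the background yields (almost always) nothing; ``correction=None``
    applies the uncorrected per-k-mer cut ``pvalue <= alpha``.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if correction not in (None, "bonferroni"):
        raise ValueError("correction must be None or 'bonferroni'")
    cut = alpha / 4**k if correction == "bonferroni" else alpha
    reg = _sequences(regulon_windows)
    bg = _sequences(background_windows)
    if not reg:
        raise ValueError("empty regulon window set")
    L_reg = sum(len(s) for s in reg)
    L_bg = sum(len(s) for s in bg)
    if L_bg == 0:
        raise ValueError("background with zero total length")
    occ_reg, pres_reg = _kmer_counts(reg, k)
    occ_bg, pres_bg = _kmer_counts(bg, k)
    n_reg, n_bg = len(reg), len(bg)

    kmers = sorted(occ_reg)
    genes_with_arr = np.asarray([pres_reg[m] for m in kmers], int)
    p_bg_arr = np.asarray([pres_bg.get(m, 0) for m in kmers], float) / n_bg
    pvals = binom.sf(genes_with_arr - 1, n_reg, p_bg_arr)
    pvals = np.where(genes_with_arr == 0, 1.0, pvals)

    results = []
    for kmer, genes_with, p_bg, pvalue in zip(kmers, genes_with_arr, p_bg_arr, pvals):
        if pvalue > cut:
            continue
        k_reg = occ_reg[kmer]
        k_bg = occ_bg.get(kmer, 0)
        genes_with = int(genes_with)
        p_bg = float(p_bg)
        pvalue = float(pvalue)
        results.append(
            EnrichmentResult(
                motif=Motif(kmer, kmer),
                regulon=regulon,
                k_reg=k_reg,
                L_reg=L_reg,
                k_bg=k_bg,
                L_bg=L_bg,
                enrichment=enrichment_ratio(k_reg, L_reg, k_bg, L_bg),
                genes_with_motif=genes_with,
                n_genes=n_reg,
                p_bg_gene=p_bg,
                pvalue=pvalue,
                bg_zero=k_bg == 0,
            )
        )
    results.sort(key=lambda r: (r.pvalue, -r.enrichment, r.motif.consensus))
    return results[:top_m]


def _column_union(kmers: Sequence[str]) -> str:
    return "".join(
        _BITS_TO_BASE[frozenset(b for kmer in kmers for b in _BASE_TO_BITS[kmer[j]])]
        for j in range(len(kmers[0]))
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def merge_to_iupac(
    results: Sequence[EnrichmentResult],
    regulon_windows: Iterable[PromoterWindow | str] | Mapping,
    background_windows: Iterable[PromoterWindow | str] | Mapping,
    max_mismatch: int = 1,
) -> list[EnrichmentResult]:
    """Greedy single-linkage merge of equal-width motifs into IUPAC families.

    Motifs within Hamming distance ``max_mismatch`` of any group member
    join that group; each group's consensus is the per-column IUPAC union
    of observed bases.  A merged family is kept only if its re-computed
    enrichment is at least the minimum of its members'; otherwise the
    group reverts to its individual members.
    """
    if not results:
        return []
    widths = {r.motif.width for r in results}
    if len(widths) > 1:
        raise ValueError("merge requires motifs of equal width")
    groups: list[list[EnrichmentResult]] = []
    for res in results:
        joined = None
        for group in groups:
            if any(
                _hamming(res.motif.consensus, member.motif.consensus) <= max_mismatch
                for member in group
            ):
                if joined is None:
                    group.append(res)
                    joined = group
                else:  # single linkage: bridge two groups
                    joined.extend(group)
                    group.clear()
        if joined is None:
            groups.append([res])
    groups = [g for g in groups if g]

    merged: list[EnrichmentResult] = []
    for group in groups:
        if len(group) == 1:
            merged.append(group[0])
            continue
        consensus = _column_union([r.motif.consensus for r in group])
        family = score_motif(
            Motif(consensus, consensus, "discovered"),
            regulon_windows,
            background_windows,
            regulon=group[0].regulon,
        )
        if family.enrichment >= min(r.enrichment for r in group):
            merged.append(family)
        else:
            merged.extend(group)
    return merged


def random_background(
    total_length: int,
    composition: Mapping[str, float],
    window_length: int,
    seed: int = 0,
) -> list[str]:
    """Same-size random background: i.i.d. sequence cut into windows.

    Generates ``total_length`` bases from ``composition`` and partitions
    them into windows of ``window_length`` (the final window may be
    shorter).  Deterministic per seed.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    rng = np.random.default_rng(seed)
    probs = np.asarray([composition[b] for b in "ACGT"], float)
    probs = probs / probs.sum()
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=total_length, p=probs)
    seq = arr.tobytes().decode("ascii")
    return [seq[i : i + window_length] for i in range(0, total_length, window_length)]


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str) -> None:
    cols = (
        "motif\tregulon\tk_reg\tL_reg\tk_bg\tL_bg\tenrichment\t"
        "genes_with_motif\tn_genes\tp_bg_gene\tpvalue\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for r in results:
            fh.write(
                f"{r.motif.consensus}\t{r.regulon}\t{r.k_reg}\t{r.L_reg}\t{r.k_bg}\t"
                f"{r.L_bg}\t{r.enrichment:.6g}\t{r.genes_with_motif}\t{r.n_genes}\t"
                f"{r.p_bg_gene:.6g}\t{r.pvalue:.6g}\n"
            )
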
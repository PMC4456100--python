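"""Genome annotation model and gene-TE spatial relationships.

Every downstream analysis conditions on the geometry computed here: which
genes and transposable-element (TE) insertions lie in euchromatin, how far a
gene is from its nearest TE, how many TEs fall in each distance bin around a
gene, and what the local gene density and recombination rate look like.

All coordinates are internally 0-based, half-open.  GFF3 input (1-based,
closed) is converted on read and back on write.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: distance bins around a gene, half-open intervals (a, b] in bp.
#: A TE touching the gene boundary (distance 0, no overlap) counts as 0-1kb.
DISTANCE_BINS: tuple[tuple[str, int, int], ...] = (
    ("0-1kb", 0, 1_000),
    ("1-2kb", 1_000, 2_000),
    ("2-5kb", 2_000, 5_000),
    ("5-10kb", 5_000, 10_000),
)

MAX_NEIGHBORHOOD = 10_000

CATEGORIES = ("in_gene", "within_1kb", "1-2kb", "2-5kb", "5-10kb", "none_within_10kb")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance in bp; 0 if the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap_to requires intervals on the same chromosome")
        return max(other.start - self.end, self.start - other.end, 0)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class ChromSpec:
    """A chromosome arm with its euchromatin extent and locality bin size."""

    name: str
    length: int
    euchromatin: list[GenomicInterval] = field(default_factory=list)
    bin_size: int = 4_000_000

    def __post_init__(self) -> None:
        self.euchromatin = sorted(self.euchromatin, key=lambda iv: iv.start)
        prev_end = 0
        for iv in self.euchromatin:
            if iv.chrom != self.name or iv.start < prev_end or iv.end > self.length:
                raise ValueError(f"bad euchromatin interval {iv} on {self.name}")
            prev_end = iv.end

    def locality_bin(self, position: float) -> int:
        """4-Mb locality bin index of a position (used to match null segments)."""
        return int(position // self.bin_size)

    def bin_bounds(self, bin_index: int) -> tuple[int, int]:
        lo = bin_index * self.bin_size
        return lo, min(lo + self.bin_size, self.length)


@dataclass
class GeneModel:
    """A gene with the exon structure of its longest isoform."""

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for e in self.exons:
            if not self.span.contains(e) or e.start < prev_end:
                raise ValueError(f"exons of {self.gene_id} overlap or exceed span")
            prev_end = e.end

    @property
    def introns(self) -> list[GenomicInterval]:
        gaps = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                gaps.append(
                    GenomicInterval(self.span.chrom, left.end, right.start, self.span.strand)
                )
        return gaps

    @property
    def exon_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class TEInsertion:
    """An annotated transposable-element insertion."""

    te_id: str
    family: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"TE {self.te_id} has empty family label")

    @property
    def length(self) -> int:
        return self.span.length


@dataclass
class GenomeAnnotation:
    """Chromosomes, gene models, and TE insertions of one genome assembly."""

    chroms: dict[str, ChromSpec]
    genes: list[GeneModel]
    tes: list[TEInsertion]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def te(self, te_id: str) -> TEInsertion:
        for t in self.tes:
            if t.te_id == te_id:
                return t
        raise KeyError(te_id)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _in_euchromatin(iv: GenomicInterval, chrom: ChromSpec) -> bool:
    return any(eu.contains(iv) for eu in chrom.euchromatin)


def apply_euchromatic_filter(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Keep genes and TEs fully inside euchromatin; drop chromosome 4 entirely.

    Features straddling a euchromatin-heterochromatin boundary are removed.
    The small, largely heterochromatic 4th chromosome is excluded wholesale.
    """
    drop = {"4", "chr4"}
    chroms = {n: c for n, c in ann.chroms.items() if n not in drop}
    genes = [
        g
        for g in ann.genes
        if g.span.chrom in chroms and _in_euchromatin(g.span, chroms[g.span.chrom])
    ]
    tes = [
        t
        for t in ann.tes
        if t.span.chrom in chroms and _in_euchromatin(t.span, chroms[t.span.chrom])
    ]
    if not genes:
        logger.warning("euchromatic filter left no genes")
    return GenomeAnnotation(chroms=chroms, genes=genes, tes=tes)


def select_analysis_genes(
    ann: GenomeAnnotation,
    exclude_ids: Iterable[str] = (),
    flank: int = MAX_NEIGHBORHOOD,
) -> list[GeneModel]:
    """Genes eligible for the gene-level chromatin analyses.

    A gene qualifies when no TE overlaps any of its exons (TEs wholly inside
    introns are allowed) and when its +-`flank` bp neighbourhood lies entirely
    within euchromatin, so distance categories are never truncated by a
    heterochromatin boundary.  `exclude_ids` supports robustness re-analyses
    that drop externally flagged genes.
    """
    excluded = set(exclude_ids)
    out = []
    for g in ann.genes:
        if g.gene_id in excluded:
            continue
        chrom = ann.chroms[g.span.chrom]
        lo = g.span.start - flank
        hi = g.span.end + flank
        if lo < 0 or hi > chrom.length:
            continue
        window = GenomicInterval(g.span.chrom, max(lo, 0), hi)
        if not _in_euchromatin(window, chrom):
            continue
        if any(
            t.span.chrom == g.span.chrom and any(t.span.overlaps(e) for e in g.exons)
            for t in ann.tes
        ):
            continue
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# gene-TE geometry
# ---------------------------------------------------------------------------

def te_gene_distance(gene: GeneModel, te: TEInsertion) -> tuple[int, bool]:
    """(edge-to-edge distance in bp, whether the TE overlaps the gene span).

    Overlap (for analysis genes this means an intronic TE) gives distance 0.
    """
    if te.span.chrom != gene.span.chrom:
        raise ValueError("TE and gene on different chromosomes")
    if te.span.overlaps(gene.span):
        return 0, True
    return gene.span.gap_to(te.span), False


def distance_category(gene: GeneModel, tes: Sequence[TEInsertion]) -> str:
    """Distance category of a gene given its surrounding TEs.

    `in_gene` when some TE overlaps the gene span (intronic for analysis
    genes); otherwise the bin of the minimal edge distance, with a TE exactly
    at the gene boundary counting as within 1 kb; `none_within_10kb` when no
    TE lies within 10 kb.
    """
    best = None
    for te in tes:
        if te.span.chrom != gene.span.chrom:
            continue
        d, overlap = te_gene_distance(gene, te)
        if overlap:
            return "in_gene"
        if d <= MAX_NEIGHBORHOOD and (best is None or d < best):
            best = d
    if best is None:
        return "none_within_10kb"
    if best == 0:
        return "within_1kb"
    for name, lo, hi in DISTANCE_BINS:
        if lo < best <= hi:
            return "within_1kb" if name == "0-1kb" else name
    return "none_within_10kb"


def nearest_te(
    gene: GeneModel, tes: Sequence[TEInsertion]
) -> tuple[TEInsertion | None, int | None, bool]:
    """Unique nearest TE within 10 kb (or intronic).

    Returns (te, distance, tie).  When two or more TEs sit at exactly the
    same minimal bp distance the gene is excluded from nearest-TE analyses:
    (None, distance, True).  When no TE is within reach: (None, None, False).
    """
    best_d: int | None = None
    best: list[TEInsertion] = []
    for te in tes:
        if te.span.chrom != gene.span.chrom:
            continue
        d, overlap = te_gene_distance(gene, te)
        if not overlap and d > MAX_NEIGHBORHOOD:
            continue
        if best_d is None or d < best_d:
            best_d, best = d, [te]
        elif d == best_d:
            best.append(te)
    if best_d is None:
        return None, None, False
    if len(best) > 1:
        return None, best_d, True
    return best[0], best_d, False


def distance_tertiles(distances: Sequence[float]) -> np.ndarray:
    """Equal-size thirds by distance: labels 0 (short), 1 (intermediate), 2 (long).

    Cut points are recomputed from the supplied pair set, so they track the
    data rather than any fixed bp values.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(d, kind="mergesort")
    labels = np.empty(d.size, dtype=int)
    for tert, chunk in enumerate(np.array_split(order, 3)):
        labels[chunk] = tert
    return labels


def te_counts_by_bin(gene: GeneModel, tes: Sequence[TEInsertion]) -> dict[str, int]:
    """TE counts in {in_gene, 0-1kb, 1-2kb, 2-5kb, 5-10kb} around a gene.

    Each TE is counted exactly once, in the bin of its edge closest to the
    gene, so a TE spanning several bins lands in the nearest one only.
    """
    counts = {"in_gene": 0, "0-1kb": 0, "1-2kb": 0, "2-5kb": 0, "5-10kb": 0}
    for te in tes:
        if te.span.chrom != gene.span.chrom:
            continue
        d, overlap = te_gene_distance(gene, te)
        if overlap:
            counts["in_gene"] += 1
            continue
        if d > MAX_NEIGHBORHOOD:
            continue
        if d == 0:
            counts["0-1kb"] += 1
            continue
        for name, lo, hi in DISTANCE_BINS:
            if lo < d <= hi:
                counts[name] += 1
                break
    return counts


def local_context(
    gene: GeneModel,
    genes: Sequence[GeneModel],
    recomb_map: pd.DataFrame,
    window: int = 100_000,
) -> tuple[int, float]:
    """(gene density, recombination rate) at a gene.

    Gene density counts genes (including the focal one) whose midpoint falls
    in a `window`-bp window centred on the focal gene's midpoint, truncated at
    chromosome ends.  Recombination rate (cM/Mb) is linearly interpolated at
    the gene midpoint from a (chrom, pos, rate) table, clamped to the map
    range at the edges.
    """
    mid = gene.span.midpoint
    half = window / 2
    density = sum(
        1
        for g in genes
        if g.span.chrom == gene.span.chrom and mid - half <= g.span.midpoint < mid + half
    )
    sub = recomb_map[recomb_map["chrom"] == gene.span.chrom]
    if sub.empty:
        raise ValueError(f"recombination map has no entries for {gene.span.chrom}")
    sub = sub.sort_values("pos")
    rate = float(np.interp(mid, sub["pos"].to_numpy(), sub["rate"].to_numpy()))
    return density, rate


def intergenic_intervals(ann: GenomeAnnotation) -> dict[str, np.ndarray]:
    """Per-chromosome sorted (n, 2) arrays of annotated (non-intergenic) spans.

    The union of gene spans and TE spans; anything outside it is intergenic.
    Used by the decay-profile flank filter.
    """
    spans: dict[str, list[tuple[int, int]]] = {n: [] for n in ann.chroms}
    for g in ann.genes:
        spans.setdefault(g.span.chrom, []).append((g.span.start, g.span.end))
    for t in ann.tes:
        spans.setdefault(t.span.chrom, []).append((t.span.start, t.span.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in spans.items():
        if not ivs:
            merged[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def is_intergenic(mask: Mapping[str, np.ndarray], chrom: str, start: int, end: int) -> bool:
    """True when [start, end) overlaps no annotated gene or TE span."""
    ivs = mask.get(chrom)
    if ivs is None or ivs.size == 0:
        return True
    i = np.searchsorted(ivs[:, 0], end, side="left")
    return not (i > 0 and ivs[i - 1, 1] > start) and not (
        i < len(ivs) and ivs[i, 0] < end
    )
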
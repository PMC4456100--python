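"""H3K9me3 density tracks, decay profiles around TEs, and the matched null.

The central question is whether the repressive H3K9me3 mark is elevated in
sequences flanking TE insertions and decays with distance.  Densities come in
as background-subtracted step functions (reads/bp); negative values mean no
enrichment and are clamped to zero.  The decay profile averages density in
ten non-overlapping 1-kb windows on each side of every TE whose whole 10-kb
flank is intergenic.  The significance reference is an ensemble of random
"TE-size" segments matched to the real TEs in length, chromosome, and 4-Mb
locality bin.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import GeneModel, GenomeAnnotation, GenomicInterval, TEInsertion

logger = logging.getLogger(__name__)

N_WINDOWS = 10
WINDOW_BP = 1_000


@dataclass
class DensityTrack:
    """Per-chromosome step function of read density at one developmental stage.

    ``data`` maps chromosome name to ``(edges, values)`` where ``edges`` has
    length ``len(values) + 1``, starts at 0 and ends at the chromosome length,
    so the steps tile the chromosome.
    """

    stage: str
    data: dict[str, tuple[np.ndarray, np.ndarray]]

    def chrom_length(self, chrom: str) -> int:
        return int(self.data[chrom][0][-1])


def clamp_track(track: DensityTrack) -> DensityTrack:
    """Assign zero to steps with negative background-subtracted density."""
    return DensityTrack(
        stage=track.stage,
        data={
            chrom: (edges, np.maximum(values, 0.0))
            for chrom, (edges, values) in track.data.items()
        },
    )


def interval_mean_density(track: DensityTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean step density over a half-open interval."""
    if interval.chrom not in track.data:
        raise ValueError(f"no track data for chromosome {interval.chrom}")
    edges, values = track.data[interval.chrom]
    if interval.start < edges[0] or interval.end > edges[-1]:
        raise ValueError(f"interval {interval} extends beyond the track")
    i0 = int(np.searchsorted(edges, interval.start, side="right")) - 1
    i1 = int(np.searchsorted(edges, interval.end, side="left"))
    seg_lo = np.maximum(edges[i0:i1], interval.start)
    seg_hi = np.minimum(edges[i0 + 1 : i1 + 1], interval.end)
    weights = (seg_hi - seg_lo).astype(float)
    return float(np.dot(weights, values[i0:i1]) / weights.sum())


def gene_h3k9_density(track: DensityTrack, gene: GeneModel) -> float:
    """Exon-length-weighted mean density of a gene's longest isoform."""
    if not gene.exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    total = sum(e.length for e in gene.exons)
    return (
        sum(interval_mean_density(track, e) * e.length for e in gene.exons) / total
    )


@dataclass
class DecayProfile:
    """Per-window-index density observations from TE flanks.

    ``windows[i]`` holds one mean density per accepted 10-kb flank for the
    1-kb window at distance (i kb, i+1 kb] from the TE edge; left and right
    flanks are extracted separately and pooled by index.
    """

    windows: list[np.ndarray]
    n_flanks: int = 0

    @property
    def n(self) -> np.ndarray:
        return np.array([len(w) for w in self.windows])

    @property
    def median(self) -> np.ndarray:
        return np.array([np.median(w) if len(w) else np.nan for w in self.windows])

    @property
    def mean(self) -> np.ndarray:
        return np.array([np.mean(w) if len(w) else np.nan for w in self.windows])


def te_flank_decay_profile(
    tes: Sequence[TEInsertion | GenomicInterval],
    track: DensityTrack,
    intergenic_mask: Mapping[str, np.ndarray],
) -> DecayProfile:
    """Decay of density in 1-kb windows over the 10-kb flanks of TEs.

    A flank contributes (all ten windows at once) only when it lies entirely
    on-chromosome and is entirely intergenic; flanks touching any gene or TE
    annotation are dropped whole, because functional sequence is depleted of
    repressive marks and would distort the decay estimate.
    """
    from .genome import is_intergenic

    windows: list[list[float]] = [[] for _ in range(N_WINDOWS)]
    n_flanks = 0
    flank_bp = N_WINDOWS * WINDOW_BP
    for te in tes:
        span = te.span if isinstance(te, TEInsertion) else te
        if span.chrom not in track.data:
            continue
        clen = track.chrom_length(span.chrom)
        for side in ("left", "right"):
            if side == "left":
                lo, hi = span.start - flank_bp, span.start
            else:
                lo, hi = span.end, span.end + flank_bp
            if lo < 0 or hi > clen:
                continue
            if not is_intergenic(intergenic_mask, span.chrom, lo, hi):
                continue
            n_flanks += 1
            for i in range(N_WINDOWS):
                # window index 1 (list index 0) is nearest the TE edge
                if side == "left":
                    w_lo, w_hi = hi - (i + 1) * WINDOW_BP, hi - i * WINDOW_BP
                else:
                    w_lo, w_hi = lo + i * WINDOW_BP, lo + (i + 1) * WINDOW_BP
                windows[i].append(
                    interval_mean_density(track, GenomicInterval(span.chrom, w_lo, w_hi))
                )
    return DecayProfile(
        windows=[np.asarray(w, dtype=float) for w in windows], n_flanks=n_flanks
    )


@dataclass
class NullEnsemble:
    """Replicate decay profiles from random TE-size segments.

    Each replicate draws, for every template TE, one uniform-random segment
    of identical length on the same chromosome and inside the same 4-Mb
    locality bin (TE assigned to its bin by midpoint), then recomputes the
    decay profile with the same intergenic flank filter.
    """

    profiles: list[DecayProfile]
    segments: list[list[GenomicInterval]]
    seed: int
    bin_size: int = 4_000_000

    def window_percentile_band(
        self, stat: str = "median", lo: float = 2.5, hi: float = 97.5
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-window (lo, hi) percentile band of the replicate statistics."""
        mat = np.vstack([getattr(p, stat) for p in self.profiles])
        return (
            np.nanpercentile(mat, lo, axis=0),
            np.nanpercentile(mat, hi, axis=0),
        )


def matched_null_ensemble(
    tes: Sequence[TEInsertion],
    ann: GenomeAnnotation,
    track: DensityTrack,
    intergenic_mask: Mapping[str, np.ndarray],
    n_reps: int,
    seed: int,
) -> NullEnsemble:
    """Ensemble of decay profiles around random segments matched to TEs.

    Matching is on segment length, chromosome, and 4-Mb locality bin; the
    random segments themselves may fall anywhere inside the bin (including on
    genes or other TEs) — only the intergenic flank filter constrains which
    windows enter the profiles, exactly as for the real TEs.
    """
    rng = np.random.default_rng(seed)
    templates = []
    for te in tes:
        chrom = ann.chroms[te.span.chrom]
        b = chrom.locality_bin(te.span.midpoint)
        lo, hi = chrom.bin_bounds(b)
        if hi - lo < te.length:
            logger.warning(
                "TE %s longer than its locality bin; sampling whole chromosome", te.te_id
            )
            lo, hi = 0, chrom.length
        templates.append((te.span.chrom, lo, hi - te.length, te.length))
    profiles, segments = [], []
    for _ in range(n_reps):
        segs = [
            GenomicInterval(chrom, s := int(rng.integers(lo, hi_start + 1)), s + length)
            for chrom, lo, hi_start, length in templates
        ]
        segments.append(segs)
        profiles.append(te_flank_decay_profile(segs, track, intergenic_mask))
    return NullEnsemble(
        profiles=profiles,
        segments=segments,
        seed=seed,
        bin_size=next(iter(ann.chroms.values())).bin_size if ann.chroms else 4_000_000,
    )


def window_contrast(profile: DecayProfile, i: int, j: int) -> float:
    """Two-sided Mann-Whitney U p-value comparing window i vs window j (1-based).

    Used to ask whether windows near the TE carry more signal than the most
    distant (9-10 kb) window.
    """
    a, b = profile.windows[i - 1], profile.windows[j - 1]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("window contrast requires observations in both windows")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def stage_enrichment_count(
    densities: "Mapping[str, Mapping[str, float]] | 'pd.DataFrame'",
    q: float = 0.10,
    drop_low_all_stages: bool = False,
) -> "pd.Series":
    """Number of stages in which each gene is in the genome-wide top ``q``.

    ``densities`` is genes x stages (rows genes).  Per stage, a gene is
    flagged when its density is >= the (1-q) empirical quantile over genes.
    With ``drop_low_all_stages``, genes below the first quartile in every
    stage are removed before counting (they carry no enrichment signal in any
    stage and would otherwise pad the zero-count class).
    """
    import pandas as pd

    df = pd.DataFrame(densities)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if drop_low_all_stages:
        q1 = df.quantile(0.25, axis=0)
        keep = (df.ge(q1, axis=1)).any(axis=1)
        df = df.loc[keep]
    thresholds = df.quantile(1 - q, axis=0)
    flags = df.ge(thresholds, axis=1)
    return flags.sum(axis=1)
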
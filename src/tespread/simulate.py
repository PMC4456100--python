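"""Synthetic genomes, density tracks, piRNA reads, and strain panels.

The generator emulates the statistical structure the analyses assume so the
whole pipeline can run and be validated without any external download:

* a euchromatic genome with genes (exon/intron structure) and TE insertions,
  some intronic, some adjacent to genes at varied distances, and some
  standalone with clean intergenic flanks for decay profiling;
* per-TE epigenetic silencing whose probability rises with the piRNA
  abundance of the TE's family and with TE length;
* H3K9me3-like density tracks built as background noise plus an exponential
  spreading kernel A exp(-d/lambda) around each silenced TE, integrated
  exactly over the track steps;
* a piRNA read table whose family read counts scale with family abundance
  and sequence length, with correct 1/n multi-mapping across family copies;
* a population panel with a skewed TE frequency spectrum (silenced TEs
  biased toward lower frequency) and strain expression depressed for alleles
  carrying a silenced TE near the gene.

All randomness flows from a single mandatory seed through named substreams,
so every artefact is reproducible and independently regenerable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .chromatin import DensityTrack
from .expression import StrainPanel
from .genome import (
    ChromSpec,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TEInsertion,
)

STAGES = (
    "embryo_0_4h", "embryo_4_8h", "embryo_8_12h", "embryo_12_16h",
    "embryo_16_20h", "embryo_20_24h", "L1_larvae", "L2_larvae", "pupae",
)


@dataclass
class SynthConfig:
    """Tunable parameters of the synthetic study system.

    Geometry is in bp, densities in reads/bp, expression in arbitrary
    log-intensity-like units.  ``seed`` is mandatory; every generator derives
    its own substream from it.
    """

    seed: int
    # genome geometry
    n_chromosomes: int = 2
    chrom_length: int = 12_000_000
    euchromatin_margin: int = 200_000
    bin_size: int = 4_000_000
    n_genes: int = 450
    n_lone_tes: int = 100
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    n_exons_range: tuple[int, int] = (2, 4)
    block_gap_range: tuple[int, int] = (12_000, 25_000)
    te_adjacent_prob: float = 0.8
    intronic_te_prob: float = 0.12
    # TE families
    n_families: int = 12
    te_length_base_range: tuple[int, int] = (800, 6_000)
    te_length_sigma: float = 0.3
    abundance_copy_exponent: float = 1.0
    abundance_sigma: float = 0.5
    # epigenetic silencing and spreading
    silencing_intercept: float = -5.0
    silencing_abundance_coef: float = 2.0
    silencing_length_coef: float = 0.25  # per kb of TE
    amplitude: float = 0.5               # reads/bp at the TE edge
    decay_length: float = 1_000.0        # bp; the elevation is mostly gone by ~2 kb
    background: float = 0.05             # reads/bp
    noise_sd: float = 0.05               # per-step Gaussian noise (pre-clamp)
    regional_noise_sd: float = 0.05      # slowly varying chromatin-state noise
    regional_block: int = 5_000          # bp scale of the regional noise
    track_step: int = 200                # bp per track step
    stages: tuple[str, ...] = STAGES
    stage_attenuation_last: float = 0.5  # amplitude factor at the last stage
    # piRNA reads
    total_reads: int = 50_000
    read_length_range: tuple[int, int] = (23, 30)
    multimap_frac: float = 0.5
    max_multimap_hits: int = 8  # mapped positions retained per multi-mapper
    antisense_frac: float = 0.7
    genic_read_frac: float = 0.02
    # population
    n_strains: int = 21
    n_population: int = 131
    no_call_rate: float = 0.05
    freq_beta_a: float = 0.5
    freq_beta_b: float = 3.0
    silencing_freq_coupling: float = 2.5  # frequency multiplier exp(-coupling)
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 2.0
    expression_noise_sd: float = 0.5
    expression_effect: float = 1.5        # depression for silenced with-TE alleles
    expression_window: int = 10_000
    sex_baseline_sd: float = 0.3          # sex-specific baseline jitter

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SynthConfig requires an explicit seed")
        for name in ("multimap_frac", "antisense_frac", "no_call_rate",
                     "te_adjacent_prob", "intronic_te_prob", "genic_read_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("decay_length", "amplitude", "expression_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, reproducible substream of the master seed."""
        digest = int.from_bytes(stream.encode(), "big") % (2**31)
        return np.random.default_rng([self.seed, digest])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("gene_length_range", "n_exons_range", "block_gap_range",
                    "te_length_base_range", "read_length_range", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _make_exons(
    chrom: str, start: int, length: int, n_exons: int, strand: str,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    # alternate exon/intron segments summing to the gene length
    n_seg = 2 * n_exons - 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for i in range(0, n_seg, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e > s:
            exons.append(GenomicInterval(chrom, start + s, start + e, strand))
    return exons


def gen_genome(cfg: SynthConfig) -> GenomeAnnotation:
    """Place non-overlapping genes and TEs on euchromatic chromosomes.

    Features are laid out block-by-block with random inter-block gaps: gene
    blocks optionally carry an adjacent TE at a distance spread over the
    0-10 kb analysis bins (plus occasional intronic TEs), and standalone TE
    blocks are padded so their 10-kb flanks stay intergenic.  Raises when the
    requested features cannot be packed into the available euchromatin.
    """
    rng = cfg.rng("genome")
    fam_rng = cfg.rng("families")
    chrom_names = [f"chr{i + 1}L" for i in range(cfg.n_chromosomes)]
    chroms = {
        name: ChromSpec(
            name=name,
            length=cfg.chrom_length,
            euchromatin=[
                GenomicInterval(
                    name, cfg.euchromatin_margin, cfg.chrom_length - cfg.euchromatin_margin
                )
            ],
            bin_size=cfg.bin_size,
        )
        for name in chrom_names
    }
    family_names = [f"FAM{i + 1}" for i in range(cfg.n_families)]
    fam_weights = 1.0 / np.arange(1, cfg.n_families + 1)
    fam_weights /= fam_weights.sum()
    fam_base_len = fam_rng.uniform(*cfg.te_length_base_range, size=cfg.n_families)

    def draw_te_length(fam_idx: int) -> int:
        ln = fam_base_len[fam_idx] * math.exp(rng.normal(0, cfg.te_length_sigma))
        return max(150, int(ln))

    genes: list[GeneModel] = []
    tes: list[TEInsertion] = []
    te_counter = 0

    def add_te(chrom: str, start: int, length: int, fam_idx: int | None = None) -> TEInsertion:
        nonlocal te_counter
        if fam_idx is None:
            fam_idx = int(rng.choice(cfg.n_families, p=fam_weights))
        te = TEInsertion(
            te_id=f"te_{te_counter:04d}",
            family=family_names[fam_idx],
            span=GenomicInterval(chrom, start, start + length, "+" if rng.random() < 0.5 else "-"),
        )
        te_counter += 1
        tes.append(te)
        return te

    # round-robin feature queue: gene blocks and lone-TE blocks
    queue = ["gene"] * cfg.n_genes + ["lone_te"] * cfg.n_lone_tes
    rng.shuffle(queue)
    per_chrom = np.array_split(np.array(queue), cfg.n_chromosomes)
    dist_bins = [(0, 1_000), (1_000, 2_000), (2_000, 5_000), (5_000, 10_000)]
    dist_probs = [0.30, 0.20, 0.25, 0.25]

    for name, blocks in zip(chrom_names, per_chrom):
        eu = chroms[name].euchromatin[0]
        cursor = eu.start + 11_000  # headroom for upstream flanks
        limit = eu.end - 11_000
        for kind in blocks:
            cursor += int(rng.integers(*cfg.block_gap_range))
            if kind == "gene":
                glen = int(rng.integers(*cfg.gene_length_range))
                strand = "+" if rng.random() < 0.5 else "-"
                # optional upstream TE
                if rng.random() < cfg.te_adjacent_prob:
                    b = rng.choice(len(dist_bins), p=dist_probs)
                    d = int(rng.integers(dist_bins[b][0], dist_bins[b][1]))
                    fam_idx = int(rng.choice(cfg.n_families, p=fam_weights))
                    tlen = draw_te_length(fam_idx)
                    te_start = cursor
                    add_te(name, te_start, tlen, fam_idx)
                    gene_start = te_start + tlen + max(d, 1)
                else:
                    gene_start = cursor
                n_e = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
                exons = _make_exons(name, gene_start, glen, n_e, strand, rng)
                # occasional intronic TE of family-typical size: the insertion
                # expands its host intron, as real intronic TEs do
                intronic_te = None
                if len(exons) >= 2 and rng.random() < cfg.intronic_te_prob:
                    j = int(rng.integers(len(exons) - 1))
                    fam_idx = int(rng.choice(cfg.n_families, p=fam_weights))
                    tlen = draw_te_length(fam_idx)
                    pad = int(rng.integers(100, 500))
                    delta = tlen + 2 * pad
                    te_start = exons[j].end + pad
                    exons = exons[: j + 1] + [
                        GenomicInterval(name, e.start + delta, e.end + delta, strand)
                        for e in exons[j + 1 :]
                    ]
                    glen += delta
                    intronic_te = (te_start, tlen, fam_idx)
                if gene_start + glen > limit:
                    raise ValueError("infeasible packing: features exceed euchromatin")
                gene = GeneModel(
                    gene_id=f"g_{len(genes):04d}",
                    span=GenomicInterval(name, gene_start, gene_start + glen, strand),
                    exons=exons,
                )
                genes.append(gene)
                if intronic_te is not None:
                    add_te(name, intronic_te[0], intronic_te[1], intronic_te[2])
                cursor = gene_start + glen
            else:  # standalone TE with clean flanks
                cursor += 11_000
                fam_idx = int(rng.choice(cfg.n_families, p=fam_weights))
                tlen = draw_te_length(fam_idx)
                if cursor + tlen + 11_000 > limit:
                    raise ValueError("infeasible packing: features exceed euchromatin")
                add_te(name, cursor, tlen, fam_idx)
                cursor += tlen + 11_000
            if cursor > limit:
                raise ValueError("infeasible packing: features exceed euchromatin")
    return GenomeAnnotation(chroms=chroms, genes=genes, tes=tes)


def family_abundances(ann: GenomeAnnotation, cfg: SynthConfig) -> dict[str, float]:
    """Relative piRNA abundance per TE family.

    Scales with genomic copy number (the empirical driver of piRNA amount)
    raised to ``abundance_copy_exponent``, with lognormal family noise, and
    is normalised to mean 1 over families.
    """
    rng = cfg.rng("abundance")
    copies = pd.Series([t.family for t in ann.tes]).value_counts()
    fams = sorted({t.family for t in ann.tes})
    raw = {
        f: (copies.get(f, 0) ** cfg.abundance_copy_exponent)
        * math.exp(rng.normal(0, cfg.abundance_sigma))
        for f in fams
    }
    mean = np.mean(list(raw.values())) or 1.0
    return {f: v / mean for f, v in raw.items()}


def draw_silencing(
    ann: GenomeAnnotation, abundance: dict[str, float], cfg: SynthConfig
) -> set[str]:
    """Bernoulli silencing indicator per TE, shared across stages.

    The silencing probability is a logistic function rising with the family
    piRNA abundance and the TE length — longer, heavily targeted TEs are the
    likeliest heterochromatin nucleation sites.
    """
    rng = cfg.rng("silencing")
    silenced = set()
    for te in ann.tes:
        logit = (
            cfg.silencing_intercept
            + cfg.silencing_abundance_coef * math.log1p(abundance[te.family] * 10)
            + cfg.silencing_length_coef * te.length / 1_000
        )
        p = 1.0 / (1.0 + math.exp(-logit))
        if rng.random() < p:
            silenced.add(te.te_id)
    return silenced


# ---------------------------------------------------------------------------
# density tracks
# ---------------------------------------------------------------------------

def _exp_kernel_step_means(
    edges: np.ndarray, origin: float, lam: float, side: int
) -> np.ndarray:
    """Exact mean of exp(-d/lam) over each step, d measured from ``origin``
    outward in direction ``side`` (+1 right, -1 left)."""
    d0 = (edges[:-1] - origin) * side
    d1 = (edges[1:] - origin) * side
    lo = np.minimum(d0, d1)
    hi = np.maximum(d0, d1)
    return lam * (np.exp(-lo / lam) - np.exp(-hi / lam)) / (hi - lo)


def gen_density_tracks(
    ann: GenomeAnnotation,
    silenced: set[str],
    cfg: SynthConfig,
) -> list[DensityTrack]:
    """Raw (unclamped) density tracks: noise plus exponential spreading bumps.

    density(x) = background + N(0, noise_sd) per step
               + sum over silenced TEs of A_stage * exp(-dist(x, TE)/lambda),
    with the kernel integrated exactly over each step so window means match
    the closed-form integral.  Inside a silenced TE the kernel contributes
    its full amplitude.  Amplitudes attenuate geometrically from 1 at the
    first stage to ``stage_attenuation_last`` at the last.
    """
    rng = cfg.rng("tracks")
    n_stages = len(cfg.stages)
    atten = (
        np.geomspace(1.0, cfg.stage_attenuation_last, n_stages)
        if n_stages > 1
        else np.array([1.0])
    )
    lam = cfg.decay_length
    reach = int(max(10 * lam, 12_000))
    tracks = []
    # precompute per-chromosome kernel sums (stage-independent shape)
    kernel: dict[str, np.ndarray] = {}
    edges_by_chrom: dict[str, np.ndarray] = {}
    for name, chrom in ann.chroms.items():
        edges = np.arange(0, chrom.length + 1, cfg.track_step, dtype=np.int64)
        if edges[-1] != chrom.length:
            edges = np.append(edges, chrom.length)
        edges_by_chrom[name] = edges
        shape = np.zeros(len(edges) - 1)
        for te in ann.tes:
            if te.te_id not in silenced or te.span.chrom != name:
                continue
            s, e = te.span.start, te.span.end
            i0 = max(int(np.searchsorted(edges, s - reach, "right")) - 1, 0)
            i1 = min(int(np.searchsorted(edges, e + reach, "left")), len(edges) - 1)
            sub = edges[i0 : i1 + 1].astype(float)
            mids_lo = sub[:-1]
            mids_hi = sub[1:]
            contrib = np.zeros(i1 - i0)
            left = mids_hi <= s
            right = mids_lo >= e
            inside = ~(left | right)
            if left.any():
                contrib[left] = _exp_kernel_step_means(
                    np.append(mids_lo[left], mids_hi[left][-1]), s, lam, -1
                )
            if right.any():
                contrib[right] = _exp_kernel_step_means(
                    np.append(mids_lo[right], mids_hi[right][-1]), e, lam, +1
                )
            contrib[inside] = 1.0
            shape[i0:i1] += contrib
        kernel[name] = shape
    for stage_i, stage in enumerate(cfg.stages):
        data = {}
        for name in ann.chroms:
            edges = edges_by_chrom[name]
            n_steps = len(edges) - 1
            noise = rng.normal(0.0, cfg.noise_sd, size=n_steps)
            if cfg.regional_noise_sd > 0:
                per_block = max(cfg.regional_block // cfg.track_step, 1)
                n_blocks = -(-n_steps // per_block)
                regional = np.repeat(
                    rng.normal(0.0, cfg.regional_noise_sd, size=n_blocks), per_block
                )[:n_steps]
                noise = noise + regional
            values = cfg.background + noise + cfg.amplitude * atten[stage_i] * kernel[name]
            data[name] = (edges, values)
        tracks.append(DensityTrack(stage=stage, data=data))
    return tracks


# ---------------------------------------------------------------------------
# piRNA reads
# ---------------------------------------------------------------------------

def gen_pirna_reads(
    ann: GenomeAnnotation,
    abundance: dict[str, float],
    cfg: SynthConfig,
) -> pd.DataFrame:
    """Mapped piRNA read table with family-abundance-coupled counts.

    Family read totals are proportional to abundance x total family sequence
    length.  A ``multimap_frac`` of reads map at a homologous offset on every
    copy of their family (n_hits = copy number); the rest map uniquely to a
    copy chosen proportional to length.  Read strand is antisense to the TE
    with probability ``antisense_frac``.  A small fraction of reads target
    gene exons (always uniquely).
    """
    rng = cfg.rng("pirna")
    fams: dict[str, list[TEInsertion]] = {}
    for te in ann.tes:
        fams.setdefault(te.family, []).append(te)
    mass = {
        f: abundance[f] * sum(t.length for t in copies)
        for f, copies in fams.items()
    }
    total_mass = sum(mass.values()) or 1.0
    n_te_reads = int(cfg.total_reads * (1 - cfg.genic_read_frac))
    read_counter = 0
    cols: dict[str, list[np.ndarray]] = {
        "read_id": [], "chrom": [], "start": [], "end": [], "strand": [], "n_hits": []
    }

    def flip(strands: np.ndarray, sense: np.ndarray) -> np.ndarray:
        anti = np.where(strands == "+", "-", "+")
        return np.where(sense, strands, anti)

    for f, copies in fams.items():
        n_reads = int(round(n_te_reads * mass[f] / total_mass))
        if n_reads == 0:
            continue
        lengths = np.array([t.length for t in copies], dtype=np.int64)
        starts = np.array([t.span.start for t in copies], dtype=np.int64)
        strands = np.array([t.span.strand for t in copies])
        chrom_of = np.array([t.span.chrom for t in copies])
        min_len = int(lengths.min())
        L = rng.integers(cfg.read_length_range[0], cfg.read_length_range[1] + 1, n_reads)
        sense = rng.random(n_reads) >= cfg.antisense_frac
        multi = (
            (len(copies) > 1)
            & (rng.random(n_reads) < cfg.multimap_frac)
            & (min_len > L)
        )
        rids = np.array([f"r{read_counter + i:07d}" for i in range(n_reads)])
        read_counter += n_reads
        # multi-mappers: same offset on a subset of copies, n_hits = subset size
        h = min(len(copies), cfg.max_multimap_hits)
        n_multi = int(multi.sum())
        if n_multi and h > 1:
            sel = np.argpartition(rng.random((n_multi, len(copies))), h - 1, axis=1)[:, :h]
            offs = rng.integers(0, min_len - L[multi])
            for j in range(h):
                c = sel[:, j]
                cols["read_id"].append(rids[multi])
                cols["chrom"].append(chrom_of[c])
                cols["start"].append(starts[c] + offs)
                cols["end"].append(starts[c] + offs + L[multi])
                cols["strand"].append(flip(strands[c], sense[multi]))
                cols["n_hits"].append(np.full(n_multi, h))
        else:
            multi = np.zeros(n_reads, dtype=bool)
        uniq = ~multi
        n_uniq = int(uniq.sum())
        if n_uniq:
            probs = lengths / lengths.sum()
            c = rng.choice(len(copies), size=n_uniq, p=probs)
            ok = lengths[c] > L[uniq]
            c = c[ok]
            Lu = L[uniq][ok]
            offs = (rng.random(len(c)) * (lengths[c] - Lu)).astype(np.int64)
            cols["read_id"].append(rids[uniq][ok])
            cols["chrom"].append(chrom_of[c])
            cols["start"].append(starts[c] + offs)
            cols["end"].append(starts[c] + offs + Lu)
            cols["strand"].append(flip(strands[c], sense[uniq][ok]))
            cols["n_hits"].append(np.ones(len(c), dtype=np.int64))
    n_genic = cfg.total_reads - n_te_reads
    if ann.genes and n_genic > 0:
        exon_list = [(e, g.span.strand) for g in ann.genes for e in g.exons]
        elens = np.array([e.length for e, _ in exon_list], dtype=np.int64)
        estarts = np.array([e.start for e, _ in exon_list], dtype=np.int64)
        echrom = np.array([e.chrom for e, _ in exon_list])
        estrand = np.array([s for _, s in exon_list])
        idx = rng.integers(0, len(exon_list), n_genic)
        L = rng.integers(cfg.read_length_range[0], cfg.read_length_range[1] + 1, n_genic)
        ok = elens[idx] > L
        idx, L = idx[ok], L[ok]
        offs = (rng.random(len(idx)) * (elens[idx] - L)).astype(np.int64)
        sense = rng.random(len(idx)) < 0.5
        cols["read_id"].append(
            np.array([f"r{read_counter + i:07d}" for i in range(len(idx))])
        )
        read_counter += len(idx)
        cols["chrom"].append(echrom[idx])
        cols["start"].append(estarts[idx] + offs)
        cols["end"].append(estarts[idx] + offs + L)
        cols["strand"].append(flip(estrand[idx], sense))
        cols["n_hits"].append(np.ones(len(idx), dtype=np.int64))
    return pd.DataFrame(
        {k: np.concatenate(v) if v else np.array([]) for k, v in cols.items()}
    ).astype({"start": np.int64, "end": np.int64, "n_hits": np.int64}, errors="ignore")


# ---------------------------------------------------------------------------
# population panel
# ---------------------------------------------------------------------------

def gen_population_panel(
    ann: GenomeAnnotation,
    silenced: set[str],
    cfg: SynthConfig,
    expression_effect: float | None = None,
    freq_coupling: float | None = None,
    p_te: dict[str, float] | None = None,
) -> tuple[StrainPanel, pd.DataFrame]:
    """Strain panel (TE site states + expression) and TE frequency truth.

    Per TE, a true insertion frequency is drawn from a skewed Beta spectrum
    (many rare insertions) and multiplied by exp(-coupling) when the TE is
    silenced — the selection signal.  Strain genotypes are Bernoulli draws
    with no-call masking; realised population frequencies come from an
    independent sample of ``n_population`` genomes.  Strain expression is a
    gene baseline (correlated between sexes) plus noise, minus
    ``expression_effect`` when the strain carries a silenced TE within
    ``expression_window`` of the gene.  Setting effect and coupling to zero
    yields the null panel used for false-positive-rate calibration.
    """
    rng = cfg.rng("panel")
    delta = cfg.expression_effect if expression_effect is None else expression_effect
    coupling = (
        cfg.silencing_freq_coupling if freq_coupling is None else freq_coupling
    )
    strains = [f"strain_{i + 1:02d}" for i in range(cfg.n_strains)]
    te_ids = [t.te_id for t in ann.tes]
    p_true = {}
    for te in ann.tes:
        if p_te is not None:
            p = float(p_te[te.te_id])
        else:
            p = rng.beta(cfg.freq_beta_a, cfg.freq_beta_b)
            if te.te_id in silenced:
                p *= math.exp(-coupling)
        p_true[te.te_id] = p
    # population-sample frequencies (the 'observed in N genomes' classification)
    freq_rows = []
    for te in ann.tes:
        called = rng.random(cfg.n_population) >= cfg.no_call_rate
        present = (rng.random(cfg.n_population) < p_true[te.te_id]) & called
        n_called = int(called.sum())
        n_present = int(present.sum())
        freq_rows.append(
            {
                "te_id": te.te_id,
                "p_true": p_true[te.te_id],
                "n_present": n_present,
                "n_absent": n_called - n_present,
                "n_no_call": cfg.n_population - n_called,
                "frequency": n_present / n_called if n_called else np.nan,
                "observed": n_present > 0,
            }
        )
    te_frequency = pd.DataFrame(freq_rows).set_index("te_id")
    # strain genotypes with no-call masking
    geno = pd.DataFrame("absent", index=te_ids, columns=strains)
    carries = {}
    for te in ann.tes:
        present = rng.random(cfg.n_strains) < p_true[te.te_id]
        no_call = (rng.random(cfg.n_strains) < cfg.no_call_rate) & ~present
        col = np.where(present, "present", np.where(no_call, "no_call", "absent"))
        geno.loc[te.te_id] = col
        carries[te.te_id] = present
    sites = pd.DataFrame(
        {
            "site_id": te_ids,
            "chrom": [t.span.chrom for t in ann.tes],
            "start": [t.span.start for t in ann.tes],
            "end": [t.span.end for t in ann.tes],
        }
    )
    # which silenced TEs sit within the expression window of each gene
    silenced_tes = [t for t in ann.tes if t.te_id in silenced]
    gene_hit = {}
    for g in ann.genes:
        near = [
            t.te_id
            for t in silenced_tes
            if t.span.chrom == g.span.chrom
            and t.span.start < g.span.end + cfg.expression_window
            and t.span.end > g.span.start - cfg.expression_window
        ]
        gene_hit[g.gene_id] = near
    expression = {}
    gene_ids = [g.gene_id for g in ann.genes]
    base = rng.normal(
        cfg.expression_baseline_mean, cfg.expression_baseline_sd, size=len(gene_ids)
    )
    for sex in ("female", "male"):
        sex_base = base + rng.normal(0, cfg.sex_baseline_sd, size=len(gene_ids))
        mat = np.empty((len(gene_ids), cfg.n_strains))
        for gi, gid in enumerate(gene_ids):
            noise = rng.normal(0, cfg.expression_noise_sd, size=cfg.n_strains)
            hit = np.zeros(cfg.n_strains, dtype=bool)
            for tid in gene_hit[gid]:
                hit |= carries[tid]
            mat[gi] = sex_base[gi] + noise - delta * hit
        expression[sex] = pd.DataFrame(mat, index=gene_ids, columns=strains)
    panel = StrainPanel(sites=sites, states=geno, expression=expression)
    return panel, te_frequency


def gen_recomb_map(ann: GenomeAnnotation, cfg: SynthConfig) -> pd.DataFrame:
    """Smooth synthetic recombination map (cM/Mb) sampled every 1 Mb."""
    rng = cfg.rng("recomb")
    rows = []
    for name, chrom in ann.chroms.items():
        pos = np.arange(0, chrom.length + 1, 1_000_000)
        rate = np.maximum(
            0.0,
            2.5
            + 1.5 * np.sin(2 * np.pi * pos / chrom.length + rng.uniform(0, 2 * np.pi))
            + rng.normal(0, 0.2, size=len(pos)),
        )
        rows.extend((name, int(p), float(r)) for p, r in zip(pos, rate))
    return pd.DataFrame(rows, columns=["chrom", "pos", "rate"])


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SynthConfig
    annotation: GenomeAnnotation
    family_abundance: dict[str, float]
    silenced: set[str]
    tracks: list[DensityTrack]       # raw, unclamped
    reads: pd.DataFrame
    panel: StrainPanel
    te_frequency: pd.DataFrame
    recomb_map: pd.DataFrame


def simulate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Run every generator stage under one seed and bundle the results."""
    ann = gen_genome(cfg)
    abundance = family_abundances(ann, cfg)
    silenced = draw_silencing(ann, abundance, cfg)
    tracks = gen_density_tracks(ann, silenced, cfg)
    reads = gen_pirna_reads(ann, abundance, cfg)
    panel, te_frequency = gen_population_panel(ann, silenced, cfg)
    recomb = gen_recomb_map(ann, cfg)
    return SyntheticDataset(
        config=cfg,
        annotation=ann,
        family_abundance=abundance,
        silenced=silenced,
        tracks=tracks,
        reads=reads,
        panel=panel,
        te_frequency=te_frequency,
        recomb_map=recomb,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artefact as plain text; returns the path of each file."""
    from . import io as tio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_gff": out / "genes.gff3",
        "tes_bed": out / "tes.bed",
        "euchromatin_bed": out / "euchromatin.bed",
        "chrom_sizes": out / "chrom.sizes",
        "reads_tsv": out / "pirna_reads.tsv",
        "recomb_tsv": out / "recomb_map.tsv",
        "states_tsv": out / "te_states.tsv",
        "frequency_tsv": out / "te_frequency.tsv",
    }
    tio.write_gff3_genes(ds.annotation.genes, paths["genes_gff"])
    tio.write_te_bed(ds.annotation.tes, paths["tes_bed"])
    tio.write_euchromatin_bed(ds.annotation.chroms, paths["euchromatin_bed"])
    with open(paths["chrom_sizes"], "w") as fh:
        for name, chrom in ds.annotation.chroms.items():
            fh.write(f"{name}\t{chrom.length}\n")
    tio.write_mapped_reads(ds.reads, paths["reads_tsv"])
    ds.recomb_map.to_csv(paths["recomb_tsv"], sep="\t", index=False, header=False)
    states = ds.panel.sites.set_index("site_id").join(ds.panel.states)
    states.to_csv(paths["states_tsv"], sep="\t")
    ds.te_frequency.to_csv(paths["frequency_tsv"], sep="\t")
    for track in ds.tracks:
        p = out / f"track_{track.stage}.bedgraph"
        paths[f"track_{track.stage}"] = p
        tio.write_bedgraph(track, p)
    for sex, expr in ds.panel.expression.items():
        p = out / f"expression_{sex}.tsv"
        paths[f"expression_{sex}"] = p
        expr.to_csv(p, sep="\t")
    return paths


def gen_small_fixture() -> SyntheticDataset:
    """Deterministic hand-checkable miniature dataset.

    One 100-kb chromosome, 6 genes, 8 TEs (one intronic), 2 stages, and a
    12-strain panel.  Coordinates are fixed by hand (every gene keeps its
    full +-10 kb flank inside euchromatin) so tests can verify every
    pipeline stage against per-bp oracles.
    """
    cfg = SynthConfig(
        seed=0,
        n_chromosomes=1,
        chrom_length=100_000,
        euchromatin_margin=2_000,
        bin_size=4_000_000,
        stages=("stage_A", "stage_B"),
        track_step=100,
        noise_sd=0.02,
        regional_noise_sd=0.01,
        total_reads=2_000,
        n_strains=12,
        n_population=40,
        decay_length=800.0,
    )
    chrom = ChromSpec(
        name="chrS",
        length=100_000,
        euchromatin=[GenomicInterval("chrS", 2_000, 98_000)],
        bin_size=cfg.bin_size,
    )

    def gene(gid, start, end, exon_bounds, strand="+"):
        return GeneModel(
            gene_id=gid,
            span=GenomicInterval("chrS", start, end, strand),
            exons=[GenomicInterval("chrS", s, e, strand) for s, e in exon_bounds],
        )

    genes = [
        gene("gA", 12_000, 14_000, [(12_000, 12_800), (13_200, 14_000)]),
        gene("gB", 20_000, 22_500, [(20_000, 20_900), (21_600, 22_500)], "-"),
        gene("gC", 30_000, 32_600, [(30_000, 30_600), (32_000, 32_600)]),
        gene("gD", 40_000, 42_500, [(40_000, 41_000), (41_500, 42_500)]),
        gene("gE", 52_000, 54_000, [(52_000, 53_000), (53_500, 54_000)], "-"),
        gene("gF", 64_000, 66_000, [(64_000, 65_000), (65_400, 66_000)]),
    ]
    tes = [
        TEInsertion("teA", "FAM1", GenomicInterval("chrS", 14_500, 15_000, "+")),  # 500 bp from gA
        TEInsertion("teB", "FAM1", GenomicInterval("chrS", 24_000, 24_600, "-")),  # 1.5 kb from gB
        TEInsertion("teC", "FAM2", GenomicInterval("chrS", 30_900, 31_500, "+")),  # intronic in gC
        TEInsertion("teD", "FAM2", GenomicInterval("chrS", 45_700, 46_500, "+")),  # 3.2 kb from gD
        TEInsertion("teE", "FAM3", GenomicInterval("chrS", 58_600, 59_000, "-")),  # 4.6 kb from gE
        TEInsertion("teG", "FAM3", GenomicInterval("chrS", 68_000, 68_300, "+")),  # 2.0 kb from gF
        TEInsertion("teF", "FAM1", GenomicInterval("chrS", 71_800, 72_500, "+")),  # 5.8 kb from gF
        TEInsertion("teH", "FAM2", GenomicInterval("chrS", 85_000, 85_400, "-")),  # standalone
    ]
    ann = GenomeAnnotation(chroms={"chrS": chrom}, genes=genes, tes=tes)
    abundance = {"FAM1": 1.5, "FAM2": 1.0, "FAM3": 0.5}
    silenced = {"teA", "teB", "teD", "teG"}
    tracks = gen_density_tracks(ann, silenced, cfg)
    reads = gen_pirna_reads(ann, abundance, cfg)
    panel, freq = gen_population_panel(ann, silenced, cfg)
    recomb = gen_recomb_map(ann, cfg)
    return SyntheticDataset(
        config=cfg,
        annotation=ann,
        family_abundance=abundance,
        silenced=silenced,
        tracks=tracks,
        reads=reads,
        panel=panel,
        te_frequency=freq,
        recomb_map=recomb,
    )
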
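"""Readers and writers for the plain-text formats the pipeline consumes.

GFF3 (genes with isoform/exon structure), BED (TEs, euchromatin boundaries),
bedGraph and fixed-step wiggle (density tracks), and the TSV tables for
mapped small-RNA reads, recombination maps, TE state matrices and expression
matrices.  GFF3 is 1-based closed on disk and converted to the internal
0-based half-open convention; BED and bedGraph are already 0-based half-open.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import (
    ChromSpec,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TEInsertion,
)

logger = logging.getLogger(__name__)

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED6 as a DataFrame with columns chrom/start/end[/name/score/strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_te_bed(path: str | Path, chroms: Mapping[str, int] | None = None) -> list[TEInsertion]:
    """TE insertions from BED6; the name field is ``te_id|family`` (or just family)."""
    df = read_bed(path)
    tes: list[TEInsertion] = []
    for i, row in df.iterrows():
        if chroms is not None and row["chrom"] not in chroms:
            logger.warning("TE record on unknown chromosome %s skipped", row["chrom"])
            continue
        name = str(row.get("name", f"te_{i}"))
        if "|" in name:
            te_id, family = name.split("|", 1)
        else:
            te_id, family = f"te_{i}", name
        strand = str(row.get("strand", "+"))
        try:
            span = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), strand)
        except ValueError as exc:
            logger.warning("malformed TE record skipped: %s", exc)
            continue
        tes.append(TEInsertion(te_id=te_id, family=family, span=span))
    return tes


def write_te_bed(tes: Iterable[TEInsertion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tes:
            fh.write(
                f"{t.span.chrom}\t{t.span.start}\t{t.span.end}\t{t.te_id}|{t.family}\t0\t{t.span.strand}\n"
            )


def read_euchromatin_bed(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, ChromSpec]:
    df = read_bed(path)
    chroms: dict[str, ChromSpec] = {}
    for name, length in chrom_sizes.items():
        sub = df[df["chrom"] == name]
        euch = [
            GenomicInterval(name, int(r["start"]), int(r["end"]))
            for _, r in sub.iterrows()
        ]
        chroms[name] = ChromSpec(name=name, length=int(length), euchromatin=euch)
    return chroms


def write_euchromatin_bed(chroms: Mapping[str, ChromSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chroms.values():
            for iv in c.euchromatin:
                fh.write(f"{c.name}\t{iv.start}\t{iv.end}\n")


def read_gff3_genes(path: str | Path, chroms: Mapping[str, int] | None = None) -> list[GeneModel]:
    """Gene models from GFF3, keeping the longest isoform (by summed exon bp).

    Accepts gene -> mRNA/transcript -> exon hierarchies via ID/Parent
    attributes; a gene whose exons attach directly to it is treated as a
    single isoform.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=_GFF_COLS, comment="#", dtype={"seqid": str}
    )
    genes_raw: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        attrs = _gff_attrs(str(row["attributes"]))
        ftype = row["type"]
        try:
            start = int(row["start"]) - 1  # GFF3 is 1-based closed
            end = int(row["end"])
            if start < 0 or start >= end:
                raise ValueError("bad coordinates")
        except (ValueError, TypeError):
            logger.warning("malformed GFF3 record skipped: %s", row.to_dict())
            continue
        if chroms is not None and str(row["seqid"]) not in chroms:
            logger.warning("GFF3 record on unknown chromosome %s skipped", row["seqid"])
            continue
        if ftype == "gene":
            genes_raw[attrs.get("ID", f"gene_{len(genes_raw)}")] = {
                "chrom": str(row["seqid"]),
                "start": start,
                "end": end,
                "strand": str(row["strand"]),
            }
        elif ftype in ("mRNA", "transcript"):
            tx_parent[attrs["ID"]] = attrs["Parent"]
        elif ftype == "exon":
            exons.setdefault(attrs["Parent"], []).append((start, end))
    genes: list[GeneModel] = []
    for gid, info in genes_raw.items():
        isoforms = [tx for tx, parent in tx_parent.items() if parent == gid]
        candidates = [exons.get(tx, []) for tx in isoforms]
        if gid in exons:  # exons attached directly to the gene
            candidates.append(exons[gid])
        candidates = [c for c in candidates if c]
        if not candidates:
            chosen = [(info["start"], info["end"])]
        else:
            chosen = max(candidates, key=lambda c: sum(e - s for s, e in c))
        genes.append(
            GeneModel(
                gene_id=gid,
                span=GenomicInterval(info["chrom"], info["start"], info["end"], info["strand"]),
                exons=[
                    GenomicInterval(info["chrom"], s, e, info["strand"])
                    for s, e in sorted(chosen)
                ],
            )
        )
    if not genes:
        raise ValueError(f"no genes parsed from {path}")
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s = g.span
            fh.write(
                f"{s.chrom}\tsim\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\tID={g.gene_id}\n"
            )
            tx = f"{g.gene_id}.t1"
            fh.write(
                f"{s.chrom}\tsim\tmRNA\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\tID={tx};Parent={g.gene_id}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{s.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{s.strand}\t.\tParent={tx}\n"
                )


def load_annotation(
    gff_path: str | Path,
    te_bed_path: str | Path,
    euchromatin_bed_path: str | Path,
    chrom_sizes_path: str | Path,
) -> GenomeAnnotation:
    """Assemble a GenomeAnnotation from its on-disk parts."""
    sizes = read_chrom_sizes(chrom_sizes_path)
    chroms = read_euchromatin_bed(euchromatin_bed_path, sizes)
    genes = read_gff3_genes(gff_path, sizes)
    tes = read_te_bed(te_bed_path, sizes)
    return GenomeAnnotation(chroms=chroms, genes=genes, tes=tes)


# ---------------------------------------------------------------------------
# density tracks
# ---------------------------------------------------------------------------

def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], stage: str = ""
):
    """A bedGraph file as a step-function track tiling each chromosome.

    Gaps between records are filled with density 0.
    """
    from .chromatin import DensityTrack

    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    data = {}
    for name, length in chrom_sizes.items():
        sub = df[df["chrom"] == name].sort_values("start")
        edges = [0]
        values = []
        for _, r in sub.iterrows():
            s, e, v = int(r["start"]), int(r["end"]), float(r["value"])
            if s > edges[-1]:
                values.append(0.0)
                edges.append(s)
            values.append(v)
            edges.append(e)
        if edges[-1] < length:
            values.append(0.0)
            edges.append(length)
        data[name] = (np.asarray(edges, dtype=np.int64), np.asarray(values, dtype=float))
    return DensityTrack(stage=stage, data=data)


def write_bedgraph(track, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, (edges, values) in track.data.items():
            for i, v in enumerate(values):
                fh.write(f"{chrom}\t{edges[i]}\t{edges[i + 1]}\t{v:.6g}\n")


_WIG_FIXED = re.compile(r"fixedStep\s+chrom=(\S+)\s+start=(\d+)\s+step=(\d+)(?:\s+span=(\d+))?")


def read_wiggle_fixed(path: str | Path, chrom_sizes: Mapping[str, int], stage: str = ""):
    """Fixed-step wiggle (1-based starts) as a step-function track."""
    from .chromatin import DensityTrack

    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    chrom = None
    pos = step = span = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            m = _WIG_FIXED.match(line)
            if m:
                chrom = m.group(1)
                pos = int(m.group(2)) - 1
                step = int(m.group(3))
                span = int(m.group(4)) if m.group(4) else step
                continue
            if chrom is None:
                raise ValueError("wiggle data before any fixedStep header")
            per_chrom.setdefault(chrom, []).append((pos, pos + span, float(line)))
            pos += step
    data = {}
    for name, length in chrom_sizes.items():
        segs = sorted(per_chrom.get(name, []))
        edges = [0]
        values = []
        for s, e, v in segs:
            if s > edges[-1]:
                values.append(0.0)
                edges.append(s)
            values.append(v)
            edges.append(min(e, length))
        if edges[-1] < length:
            values.append(0.0)
            edges.append(length)
        data[name] = (np.asarray(edges, dtype=np.int64), np.asarray(values, dtype=float))
    return DensityTrack(stage=stage, data=data)


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_recomb_map(path: str | Path) -> pd.DataFrame:
    """3-column TSV (chrom, pos, rate in cM/Mb)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "rate"], comment="#")
    if df.empty:
        raise ValueError(f"empty recombination map: {path}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_mapped_reads(path: str | Path) -> pd.DataFrame:
    """Mapped small-RNA reads: read_id, chrom, start, end, strand, n_hits."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"read_id", "chrom", "start", "end", "strand", "n_hits"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapped-read table missing columns {required - set(df.columns)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_mapped_reads(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_sam_reads(path: str | Path) -> pd.DataFrame:
    """Mapped reads from a text SAM file; multi-mapping counts from NH tags."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            rows.append(
                {
                    "read_id": aln.query_name,
                    "chrom": aln.reference_name,
                    "start": aln.reference_start,
                    "end": aln.reference_end,
                    "strand": "-" if aln.is_reverse else "+",
                    "n_hits": int(n_hits),
                }
            )
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "strand", "n_hits"])


def read_state_matrix(path: str | Path) -> pd.DataFrame:
    """TE-site state matrix: columns site_id, chrom, start, end, then one
    column per strain with values present/absent/no_call."""
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Expression TSV: rows genes, columns ``strain:sex``; index column gene_id."""
    return pd.read_csv(path, sep="\t", index_col=0)
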
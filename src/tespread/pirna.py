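"""piRNA densities over TEs and genes with fractional multi-mapping weights.

piRNAs derived from a TE family map ambiguously across its copies.  Rather
than discarding multi-mappers (which would bias high-copy families), each of
the n genomic mappings of a read carries weight 1/n, so every read still
contributes exactly one read in total.  A feature's sense density is the
summed weight of same-strand mappings overlapping it, per bp of feature; the
antisense density likewise for the opposite strand.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, TEInsertion


@dataclass(frozen=True)
class PirnaDensity:
    feature_id: str
    sense: float
    antisense: float


def assign_mapping_weights(reads: pd.DataFrame, unique_only: bool = False) -> pd.DataFrame:
    """Attach a ``weight`` = 1/n_hits column to a mapped-read table.

    ``unique_only`` keeps reads with a single genomic hit (weight 1), the
    cross-check mode for multi-mapping-sensitive results.  Records with
    n_hits < 1 are rejected.
    """
    bad = reads["n_hits"] < 1
    if bad.any():
        reads = reads[~bad]
    out = reads.copy()
    if unique_only:
        out = out[out["n_hits"] == 1].copy()
    out["weight"] = 1.0 / out["n_hits"].astype(float)
    return out


def _feature_tuple(feature) -> tuple[str, str, int, int, str]:
    if isinstance(feature, TEInsertion):
        return feature.te_id, feature.span.chrom, feature.span.start, feature.span.end, feature.span.strand
    if isinstance(feature, GeneModel):
        return feature.gene_id, feature.span.chrom, feature.span.start, feature.span.end, feature.span.strand
    if isinstance(feature, GenomicInterval):
        return f"{feature.chrom}:{feature.start}-{feature.end}", feature.chrom, feature.start, feature.end, feature.strand
    raise TypeError(f"unsupported feature type {type(feature)!r}")


def feature_pirna_density(weighted_reads: pd.DataFrame, feature) -> PirnaDensity:
    """Sense/antisense weighted read density (reads/bp) over one feature.

    A mapping counts if it overlaps the feature by at least 1 bp; a read
    mapping twice inside the feature contributes both weighted mappings.
    """
    fid, chrom, start, end, strand = _feature_tuple(feature)
    if end <= start:
        raise ValueError(f"zero-length feature {fid}")
    if strand not in ("+", "-"):
        raise ValueError(f"feature {fid} needs a defined strand for sense/antisense")
    sub = weighted_reads[
        (weighted_reads["chrom"] == chrom)
        & (weighted_reads["start"] < end)
        & (weighted_reads["end"] > start)
    ]
    length = float(end - start)
    same = sub["strand"] == strand
    return PirnaDensity(
        feature_id=fid,
        sense=float(sub.loc[same, "weight"].sum()) / length,
        antisense=float(sub.loc[~same, "weight"].sum()) / length,
    )


def pirna_density_table(weighted_reads: pd.DataFrame, features: Sequence) -> pd.DataFrame:
    """Vectorised sense/antisense densities for many features at once."""
    rows = []
    by_chrom = {c: g for c, g in weighted_reads.groupby("chrom")}
    for feature in features:
        fid, chrom, start, end, strand = _feature_tuple(feature)
        sub = by_chrom.get(chrom)
        if sub is None:
            rows.append((fid, 0.0, 0.0))
            continue
        hit = (sub["start"].to_numpy() < end) & (sub["end"].to_numpy() > start)
        w = sub["weight"].to_numpy()[hit]
        same = (sub["strand"].to_numpy()[hit]) == strand
        length = float(end - start)
        rows.append((fid, float(w[same].sum()) / length, float(w[~same].sum()) / length))
    return pd.DataFrame(rows, columns=["feature_id", "sense", "antisense"]).set_index(
        "feature_id"
    )
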
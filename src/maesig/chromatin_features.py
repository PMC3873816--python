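"""Gene-level chromatin features: input-normalized log-ratio signal per mark.

For each gene and region (gene body, or the 2.5 kb proximal promoter upstream
of the TSS) the ChIP signal is summed over the interval and normalized to the
input/whole-cell-extract sum as a log ratio.  A pseudocount keeps the ratio
finite when either sum is zero.  The two gene-body features for H3K27me3 and
H3K36me3 are the classifier's working plane: expressed biallelic genes sit at
high K36 / low K27, genes with a silenced allele at high K27.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from maesig.genome_io import GeneModel, SignalTrack

MARKS = (
    "H3K27me3",
    "H3K36me3",
    "H3K4me2",
    "H4K20me3",
    "H3K27ac",
    "H3K4me1",
    "H3K4me3",
    "H3K9ac",
)
REGIONS = ("gene_body", "promoter")
PROMOTER_LENGTH = 2500


def feature_name(mark: str, region: str) -> str:
    """Column name for a (mark, region) feature, e.g. ``H3K27me3_gene_body``."""
    return f"{mark}_{region}"


def integrate_signal(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Sum the per-base signal over [start, end); uncovered bases add 0."""
    return track.integrate(chrom, start, end)


def promoter_interval(gene: GeneModel, length: int = PROMOTER_LENGTH) -> tuple[str, int, int]:
    """The proximal promoter: `length` bp upstream of the TSS, strand-aware,
    clipped at the chromosome start."""
    if length <= 0:
        raise ValueError("promoter length must be positive")
    if gene.strand == "+":
        return gene.chrom, max(gene.start - length, 0), gene.start
    return gene.chrom, gene.end, gene.end + length


def normalized_feature(
    mark_sum: float, input_sum: float, pseudocount: float = 1.0, base: int = 2
) -> float:
    """log_base((mark_sum + pseudocount) / (input_sum + pseudocount))."""
    if mark_sum < 0 or input_sum < 0:
        raise ValueError("signal sums must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if base not in (2, 10):
        raise ValueError("log base must be 2 or 10")
    return math.log((mark_sum + pseudocount) / (input_sum + pseudocount), base)


def build_feature_matrix(
    tracks: Mapping[str, SignalTrack],
    input_track: SignalTrack,
    genes: Sequence[GeneModel],
    regions: Iterable[str] = ("gene_body",),
    pseudocount: float = 1.0,
    base: int = 2,
    allow_extra_marks: bool = False,
) -> pd.DataFrame:
    """One row per gene, one column per (mark, region) log-ratio feature.

    A cell is missing (NaN) when both the mark and the input sum to zero over
    the region — the gene then carries no data for that feature and is later
    dropped from training.
    """
    if not tracks:
        raise ValueError("need at least one mark track")
    if not genes:
        raise ValueError("gene list is empty")
    regions = tuple(regions)
    for r in regions:
        if r not in REGIONS:
            raise ValueError(f"unknown region {r!r}; expected one of {REGIONS}")
    for mark in tracks:
        if mark not in MARKS and not allow_extra_marks:
            raise ValueError(
                f"mark {mark!r} outside the known vocabulary {MARKS}; "
                "pass allow_extra_marks=True to accept it"
            )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in gene list")

    intervals: dict[str, list[tuple[str, int, int]]] = {}
    for region in regions:
        if region == "gene_body":
            intervals[region] = [(g.chrom, g.start, g.end) for g in genes]
        else:
            intervals[region] = [promoter_interval(g) for g in genes]

    data: dict[str, np.ndarray] = {}
    for region in regions:
        triples = intervals[region]
        input_sums = input_track.integrate_many(*zip(*triples))
        for mark, track in tracks.items():
            mark_sums = track.integrate_many(*zip(*triples))
            col = np.array(
                [
                    np.nan
                    if m == 0 and s == 0
                    else normalized_feature(m, s, pseudocount, base)
                    for m, s in zip(mark_sums, input_sums)
                ]
            )
            data[feature_name(mark, region)] = col
    return pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))


def quantile_normalize(matrix: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Map each column of `matrix` onto the reference column's distribution.

    Each non-missing value is replaced by the reference column's empirical
    quantile at that value's (tie-averaged) rank, with linear interpolation
    between reference order statistics.  Missing values stay missing.
    """
    if set(matrix.columns) != set(reference.columns):
        raise ValueError("matrix and reference must share the same column set")
    out = matrix.copy()
    for col in matrix.columns:
        ref = reference[col].dropna().to_numpy(dtype=float)
        if ref.size == 0:
            raise ValueError(f"reference column {col!r} is empty")
        x = matrix[col].to_numpy(dtype=float)
        mask = np.isfinite(x)
        m = int(mask.sum())
        if m < 2:
            raise ValueError(f"column {col!r} needs >= 2 non-missing values")
        ranks = scipy.stats.rankdata(x[mask], method="average")  # 1..m, ties averaged
        q = (ranks - 1.0) / (m - 1.0)
        ref_sorted = np.sort(ref)
        if ref_sorted.size == 1:
            mapped = np.full(m, ref_sorted[0])
        else:
            ref_q = np.linspace(0.0, 1.0, ref_sorted.size)
            mapped = np.interp(q, ref_q, ref_sorted)
        col_out = np.full_like(x, np.nan)
        col_out[mask] = mapped
        out[col] = col_out
    return out
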
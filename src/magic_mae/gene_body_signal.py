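"""Per-gene gene-body signal: coverage sums, input normalization, quantile ranks.

The feature extraction pipeline integrates each coverage track over the full
genomic span of a gene's longest transcript, normalizes ChIP marks to the
matched input library (or to transcript length when no input exists), averages
replicates on the normalized scale, and converts each normalized signal to a
quantile rank in (0, 1] using average ranks for ties.  Quantile ranks are
invariant under any strictly monotone transform of the signal, which is what
lets a classifier trained on one dataset transfer to others measured on
different absolute scales.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from magic_mae.io_formats import AUTOSOME_REGEX, CoverageTrack, GeneModel, is_autosome

logger = logging.getLogger(__name__)

#: tag recorded in trained models so ranks produced here are never mixed
#: with features on another scale
QRANK_SCALE_TAG = "average-rank/n"

FEATURE_COLUMNS = [
    "gene_id",
    "chrom",
    "length_bp",
    "k27_norm",
    "k36_norm",
    "expr_norm",
    "k27_qrank",
    "k36_qrank",
    "expr_qrank",
]


def longest_transcript(gene: GeneModel):
    """Return (chrom, start, end) of the gene's longest transcript.

    Ties broken deterministically by lexicographically smallest tx_id.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    best = min(gene.transcripts, key=lambda t: (-(t.end - t.start), t.tx_id))
    return gene.chrom, best.start, best.end


def gene_body_sum(track: CoverageTrack, interval) -> float:
    """Sum per-base coverage over [start, end) of the interval.

    Equals sum over overlapping track intervals of value * overlap_length.
    A chromosome absent from the track contributes 0 (warning logged).
    """
    chrom, start, end = interval
    if start >= end:
        raise ValueError(f"invalid interval {chrom}:{start}-{end}")
    arrays = track.chrom_arrays(chrom)
    if arrays is None:
        logger.warning("chromosome %s absent from track; sum = 0", chrom)
        return 0.0
    starts, ends, values = arrays
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    if lo >= hi:
        return 0.0
    ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
    return float(np.sum(values[lo:hi] * ov))


def normalize_signal(mark_sum: float, input_sum: float | None, length_bp: int) -> float:
    """mark/input when input is available and positive, else mark/length.

    Genes with an input track but zero input signal are dropped upstream and
    never reach this function.
    """
    if input_sum is not None:
        if input_sum <= 0:
            raise ValueError("zero input signal: gene should have been dropped")
        return mark_sum / input_sum
    if length_bp <= 0:
        raise ValueError(f"non-positive gene length {length_bp}")
    return mark_sum / length_bp


def average_replicates(values) -> float:
    """Arithmetic mean of per-replicate normalized signals (pre-ranking)."""
    values = list(values)
    if not values:
        raise ValueError("no replicate values")
    return float(np.mean(values))


def quantile_rank(values) -> np.ndarray:
    """Average-rank quantile in (0, 1]: rank_i / n with average ranks on ties."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty vector")
    if np.isnan(arr).any():
        raise ValueError("missing values in quantile_rank input")
    return rankdata(arr, method="average") / arr.size


def _sum_tracks(tracks, interval):
    """Per-replicate gene-body sums for a list of tracks."""
    return [gene_body_sum(t, interval) for t in tracks]


def build_feature_table(
    genes,
    k27_tracks,
    k36_tracks,
    input_tracks=None,
    rna_tracks=None,
    abundance: pd.DataFrame | None = None,
    autosome_pattern: str = AUTOSOME_REGEX,
) -> pd.DataFrame:
    """Build the per-gene feature table used by the MAE classifier.

    Pipeline: restrict to autosomal genes -> longest transcript -> gene-body
    sum per track -> drop genes with no input signal -> normalize (to input,
    or to length when no input is given) -> average replicates -> quantile
    rank each normalized signal.  Expression comes from RNA coverage tracks
    integrated with the same pipeline (normalized to length), or from a
    supplied abundance table (columns gene_id, abundance) such as FPKM.

    Returns a DataFrame with FEATURE_COLUMNS, sorted by gene_id.
    """
    if rna_tracks is None and abundance is None:
        raise ValueError("expression requires rna_tracks or an abundance table")
    if abundance is not None:
        abun = dict(zip(abundance["gene_id"], abundance["abundance"].astype(float)))
    rows = []
    for gene in genes:
        if not is_autosome(gene.chrom, autosome_pattern):
            continue
        interval = longest_transcript(gene)
        length = interval[2] - interval[1]
        if input_tracks:
            input_sum = average_replicates(_sum_tracks(input_tracks, interval))
            if input_sum <= 0:
                logger.info("gene %s dropped: no input signal", gene.gene_id)
                continue
        else:
            input_sum = None
        k27 = average_replicates(
            [normalize_signal(s, input_sum, length) for s in _sum_tracks(k27_tracks, interval)]
        )
        k36 = average_replicates(
            [normalize_signal(s, input_sum, length) for s in _sum_tracks(k36_tracks, interval)]
        )
        if abundance is not None:
            if gene.gene_id not in abun:
                logger.warning("gene %s missing from abundance table; skipped", gene.gene_id)
                continue
            expr = abun[gene.gene_id]
        else:
            expr = average_replicates(
                [s / length for s in _sum_tracks(rna_tracks, interval)]
            )
        rows.append((gene.gene_id, gene.chrom, length, k27, k36, expr))
    if not rows:
        raise ValueError("no autosomal genes left after filtering")
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "length_bp", "k27_norm", "k36_norm", "expr_norm"]
    ).sort_values("gene_id", kind="mergesort", ignore_index=True)
    df["k27_qrank"] = quantile_rank(df["k27_norm"])
    df["k36_qrank"] = quantile_rank(df["k36_norm"])
    df["expr_qrank"] = quantile_rank(df["expr_norm"])
    return df[FEATURE_COLUMNS]
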
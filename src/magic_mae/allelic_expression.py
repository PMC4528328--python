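"""Allelic-expression calls from SNP counts, clone aggregation, benchmarking.

Per-gene maternal/paternal read counts (summed over the gene's transcribed
SNPs) are tested for allelic imbalance with an exact binomial test against
0.5, corrected across genes by Benjamini-Hochberg.  A gene is called
monoallelic when the corrected p-value is below alpha AND the major allele
carries at least a 2:1 share of reads; a gene is called biallelic when a
binomial TOST (two one-sided tests) shows the maternal fraction lies strictly
inside (1/3, 2/3); everything else — including genes with too few reads — is
indeterminate.

Chromatin-signature calls are benchmarked against these allelic calls in a
2x2 concordance table with a Fisher exact test and the sample odds ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import binom, fisher_exact
from statsmodels.stats.multitest import multipletests


def mask_reference(records, snp_positions: dict) -> list:
    """Replace the bases at SNP positions with N in each FASTA record.

    ``snp_positions`` maps record id -> iterable of 0-based positions.
    Positions outside the record raise, naming the record and position.
    """
    out = []
    for rec in records:
        seq = list(str(rec.seq))
        for pos in snp_positions.get(rec.id, ()):
            if not 0 <= pos < len(seq):
                raise ValueError(
                    f"SNP position {pos} out of range for record {rec.id} "
                    f"(length {len(seq)})"
                )
            seq[pos] = "N"
        out.append(SeqRecord(Seq("".join(seq)), id=rec.id, description=rec.description))
    return out


def aggregate_counts(snps: pd.DataFrame) -> pd.DataFrame:
    """Sum maternal and paternal counts over each gene's SNPs."""
    agg = (
        snps.groupby("gene_id", sort=True)[["maternal_count", "paternal_count"]]
        .sum()
        .reset_index()
        .rename(columns={"maternal_count": "mat", "paternal_count": "pat"})
    )
    return agg


def _binom_two_sided(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided exact binomial p vs 0.5 by doubling the smaller tail, capped at 1."""
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def call_allelic(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    bias: float = 2.0,
    min_total: int = 20,
    eq_bounds: tuple[float, float] = (1 / 3, 2 / 3),
) -> pd.DataFrame:
    """Call per-gene allelic state from aggregated maternal/paternal counts.

    Parameters
    ----------
    counts : DataFrame with columns gene_id, mat, pat.
    alpha : FDR level for the imbalance test and per-test level for the TOST.
    bias : required major:minor ratio for a monoallelic call (2.0 -> major
        fraction >= 2/3).
    min_total : genes with fewer total reads are indeterminate and excluded
        from the BH correction.
    eq_bounds : equivalence bounds on the maternal fraction for the TOST.

    Returns
    -------
    DataFrame with mat, pat, n, major_fraction, p_binom, q_value, p_eq_low,
    p_eq_high and call in {monoallelic, biallelic, indeterminate}.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    lo, hi = eq_bounds
    df = counts.copy()
    mat = df["mat"].to_numpy(np.int64)
    pat = df["pat"].to_numpy(np.int64)
    if (mat < 0).any() or (pat < 0).any():
        raise ValueError("negative allele counts")
    n = mat + pat
    df["n"] = n
    with np.errstate(invalid="ignore"):
        df["major_fraction"] = np.where(n > 0, np.maximum(mat, pat) / n, np.nan)
    tested = n >= min_total

    p_binom = np.full(len(df), np.nan)
    p_binom[tested] = _binom_two_sided(mat[tested], n[tested])
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested] = multipletests(p_binom[tested], method="fdr_bh")[1]
    # TOST: reject "fraction <= lo" and "fraction >= hi"
    p_eq_low = np.full(len(df), np.nan)
    p_eq_high = np.full(len(df), np.nan)
    p_eq_low[tested] = binom.cdf(mat[tested], n[tested], hi)
    p_eq_high[tested] = binom.sf(mat[tested] - 1, n[tested], lo)

    major_thresh = bias / (bias + 1.0)
    mono = tested & (q < alpha) & (df["major_fraction"].to_numpy() >= major_thresh)
    bi = tested & ~mono & (p_eq_low < alpha) & (p_eq_high < alpha)
    df["p_binom"] = p_binom
    df["q_value"] = q
    df["p_eq_low"] = p_eq_low
    df["p_eq_high"] = p_eq_high
    df["call"] = np.where(mono, "monoallelic", np.where(bi, "biallelic", "indeterminate"))
    return df


def aggregate_clones(clone_calls: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-clone allelic calls into one benchmark call per gene.

    A gene is MAE if monoallelic in at least one clone; otherwise BAE if
    biallelic in at least one clone; otherwise indeterminate.  (Opposite
    allelic biases in different clones of a nonclonal population cancel in
    bulk RNA-Seq, so multiple clones jointly approximate the population.)
    """
    if not clone_calls:
        raise ValueError("at least one clone required")
    stacked = pd.concat(
        [c[["gene_id", "call"]] for c in clone_calls], ignore_index=True
    )
    def combine(calls):
        if (calls == "monoallelic").any():
            return "MAE"
        if (calls == "biallelic").any():
            return "BAE"
        return "indeterminate"

    out = stacked.groupby("gene_id", sort=True)["call"].apply(combine).reset_index()
    return out.rename(columns={"call": "benchmark_call"})


def concordance(magic_calls: pd.DataFrame, benchmark: pd.DataFrame) -> dict:
    """2x2 concordance of chromatin-signature calls vs allelic benchmark.

    Restricted to genes with a determinate call on both sides.  Returns the
    table counts, two-sided Fisher exact p, the sample odds ratio
    (tp*tn)/(fp*fn) (nan when undefined by a zero margin), and per-class
    confirmation rates tp/(tp+fp) and tn/(tn+fn).
    """
    merged = magic_calls.merge(benchmark, on="gene_id")
    merged = merged[
        merged["final_call"].isin(["MAE", "BAE"])
        & merged["benchmark_call"].isin(["MAE", "BAE"])
    ]
    m = merged["final_call"] == "MAE"
    b = merged["benchmark_call"] == "MAE"
    tp = int((m & b).sum())
    fp = int((m & ~b).sum())
    fn = int((~m & b).sum())
    tn = int((~m & ~b).sum())
    _, fisher_p = fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
    if fp > 0 and fn > 0:
        odds_ratio = (tp * tn) / (fp * fn)
    else:
        odds_ratio = np.inf if tp * tn > 0 else np.nan
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "fisher_p": float(fisher_p),
        "odds_ratio": float(odds_ratio),
        "mae_confirmation": tp / (tp + fp) if tp + fp else np.nan,
        "bae_confirmation": tn / (tn + fn) if tn + fn else np.nan,
    }
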
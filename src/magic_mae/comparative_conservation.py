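"""Cross-species conservation of MAE over one-to-one orthologs.

Given N ortholog pairs with a determinate MAE/BAE call in both species, K of
which are MAE in species A and n in species B, the number of pairs MAE in
both species is hypergeometric under independence.  Conservation is measured
by the inclusive upper tail P(X >= observed), computed by log-space summation
of the pmf (the tails of interest are far below double underflow), and by
the expected overlap p_A * p_B * N = K * n / N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass
class ConservationResult:
    n_pairs: int
    n_mae_a: int
    n_mae_b: int
    observed_overlap: int
    p_a: float
    p_b: float
    expected_overlap: float
    log10_hyper_p: float

    @property
    def hyper_p(self) -> float:
        return 10.0 ** self.log10_hyper_p


def restrict_one_to_one(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop every ortholog pair involving a gene mapped more than once.

    Input columns: gene_a, gene_b.  A gene appearing in more than one row on
    either side is ambiguous; all its pairs are removed.
    """
    counts_a = pairs["gene_a"].value_counts()
    counts_b = pairs["gene_b"].value_counts()
    keep = pairs["gene_a"].map(counts_a).eq(1) & pairs["gene_b"].map(counts_b).eq(1)
    return pairs[keep].reset_index(drop=True)


def hypergeom_upper_tail_log10(N: int, K: int, n: int, observed: int) -> float:
    """log10 of the inclusive upper tail P(X >= observed), X ~ HG(N, K, n).

    Summed in log space over the support [observed, min(K, n)]; exact down to
    tails of order 1e-300 and far beyond.
    """
    upper = min(K, n)
    if observed <= max(0, K + n - N):
        return 0.0
    ks = np.arange(observed, upper + 1)
    if ks.size == 0:
        return -np.inf
    logp = hypergeom.logpmf(ks, N, K, n)
    return float(logsumexp(logp) / np.log(10.0))


def conservation_test(
    pairs: pd.DataFrame,
    calls_a: dict | pd.Series,
    calls_b: dict | pd.Series,
) -> ConservationResult:
    """Test conservation of MAE between two species over one-to-one orthologs.

    ``calls_a``/``calls_b`` map gene id -> call; only pairs with a determinate
    MAE/BAE call in BOTH species enter the universe N.
    """
    calls_a = dict(calls_a)
    calls_b = dict(calls_b)
    det = {"MAE", "BAE"}
    mask = pairs.apply(
        lambda r: calls_a.get(r["gene_a"]) in det and calls_b.get(r["gene_b"]) in det,
        axis=1,
    )
    usable = pairs[mask] if len(pairs) else pairs
    N = len(usable)
    if N == 0:
        raise ValueError("no ortholog pairs with determinate calls in both species")
    mae_a = usable["gene_a"].map(calls_a).eq("MAE")
    mae_b = usable["gene_b"].map(calls_b).eq("MAE")
    K = int(mae_a.sum())
    n = int(mae_b.sum())
    observed = int((mae_a & mae_b).sum())
    return ConservationResult(
        n_pairs=N,
        n_mae_a=K,
        n_mae_b=n,
        observed_overlap=observed,
        p_a=K / N,
        p_b=n / N,
        expected_overlap=K * n / N,
        log10_hyper_p=hypergeom_upper_tail_log10(N, K, n, observed),
    )
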
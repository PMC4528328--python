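"""MAE-profile comparison across samples: Gower distance, UPGMA, binning.

An MAE profile matrix holds genes x samples entries in {1 (MAE), 0 (BAE),
NaN (missing / not assessed)}.  Pairwise sample dissimilarity is the Gower
distance, which on symmetric binary traits reduces to the mismatch fraction
over genes informative (non-missing) in both samples.  Samples are clustered
by UPGMA (average linkage, size-weighted) with deterministic lexicographic
tie-breaks, and the tree is exportable as Newick with branch lengths derived
from merge heights (height = distance / 2, so cophenetic distance between
two leaves equals the average-linkage distance at their join).

``specificity_bins`` reproduces the tissue-specificity analysis: genes are
binned by the number of samples in which they are expressed, and the MAE
proportion per (bin, sample) is computed among expressed, determinate genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Merge:
    left: str  # cluster labels (smallest leaf name in the cluster)
    right: str
    height: float
    size: int


@dataclass
class Dendrogram:
    """Binary merge tree over sample names, UPGMA heights (ultrametric)."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def to_newick(self) -> str:
        node: dict[str, tuple[str, float]] = {
            leaf: (leaf, 0.0) for leaf in self.leaves
        }
        for m in self.merges:
            ls, lh = node.pop(m.left)
            rs, rh = node.pop(m.right)
            label = min(m.left, m.right)
            node[label] = (
                f"({ls}:{m.height - lh:g},{rs}:{m.height - rh:g})",
                m.height,
            )
        (tree, _), = node.values()
        return tree + ";"

    def cophenetic(self) -> pd.DataFrame:
        """Leaf x leaf matrix of 2 * merge height of the lowest common cluster."""
        members: dict[str, set[str]] = {leaf: {leaf} for leaf in self.leaves}
        coph = pd.DataFrame(0.0, index=list(self.leaves), columns=list(self.leaves))
        for m in self.merges:
            left, right = members.pop(m.left), members.pop(m.right)
            for a in left:
                for b in right:
                    coph.loc[a, b] = coph.loc[b, a] = 2.0 * m.height
            members[min(m.left, m.right)] = left | right
        return coph


def gower_distance(profile_a, profile_b) -> float:
    """Mismatch fraction over genes non-missing in both profiles.

    Gower's coefficient on symmetric binary variables with pairwise deletion;
    similarity is 1 - distance.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    shared = ~np.isnan(a) & ~np.isnan(b)
    if not shared.any():
        raise ValueError("no genes informative in both samples")
    return float(np.mean(a[shared] != b[shared]))


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA (size-weighted average linkage) with lexicographic tie-breaks.

    ``dist`` is a symmetric sample x sample distance matrix with zero
    diagonal.  At each step the closest cluster pair is merged at height
    d/2; the distance from the merged cluster to any other is the
    size-weighted average of the members' distances.  Ties in the minimum
    distance are broken by the lexicographically smallest (left, right)
    cluster-label pair, labels being the smallest leaf name in each cluster.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValueError("UPGMA requires at least 2 samples")
    if list(dist.columns) != labels:
        raise ValueError("distance matrix index and columns must match")
    d = {
        (min(a, b), max(a, b)): float(dist.loc[a, b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    sizes = {lab: 1 for lab in labels}
    merges = []
    active = sorted(labels)
    while len(active) > 1:
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (left, right), dist_lr = best
        height = dist_lr / 2.0
        new_label = min(left, right)
        merges.append(Merge(left=left, right=right, height=height, size=sizes[left] + sizes[right]))
        for other in active:
            if other in (left, right):
                continue
            d_lo = d.pop((min(left, other), max(left, other)))
            d_ro = d.pop((min(right, other), max(right, other)))
            new_d = (sizes[left] * d_lo + sizes[right] * d_ro) / (
                sizes[left] + sizes[right]
            )
            d[(min(new_label, other), max(new_label, other))] = new_d
        del d[(left, right)]
        new_size = sizes.pop(left) + sizes.pop(right)
        sizes[new_label] = new_size
        active = [x for x in active if x not in (left, right)]
        active.append(new_label)
        active.sort()
    return Dendrogram(leaves=tuple(sorted(labels)), merges=tuple(merges))


def pairwise_distances(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Gower distance between sample columns of a profile matrix."""
    samples = list(profiles.columns)
    d = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            try:
                dd = gower_distance(profiles[a], profiles[b])
            except ValueError as exc:
                raise ValueError(f"samples {a!r} and {b!r}: {exc}") from exc
            d.loc[a, b] = d.loc[b, a] = dd
    return d


def cluster_profiles(profiles: pd.DataFrame) -> tuple[Dendrogram, pd.DataFrame]:
    """Cluster samples by MAE-profile similarity.

    Returns the UPGMA dendrogram and the pairwise similarity table
    (1 - Gower distance) for heat-map plotting.
    """
    if profiles.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    dist = pairwise_distances(profiles)
    return upgma(dist), 1.0 - dist


def specificity_bins(profiles: pd.DataFrame, expressed: pd.DataFrame) -> pd.DataFrame:
    """MAE proportion per (number of expressing samples, sample).

    Genes are grouped by how many samples express them; within each bin, the
    proportion of MAE genes among expressed, determinate genes is computed
    per sample.  Returns a long-form table (bin, sample, n_genes, proportion)
    plus per-bin quartiles of the per-sample proportions for box plotting;
    empty (bin, sample) cells are omitted.
    """
    if not profiles.index.equals(expressed.index) or list(profiles.columns) != list(
        expressed.columns
    ):
        raise ValueError("profiles and expressed must share genes and samples")
    nbins = expressed.sum(axis=1).astype(int)
    rows = []
    for b in sorted(nbins.unique()):
        genes = nbins[nbins == b].index
        for sample in profiles.columns:
            mask = expressed.loc[genes, sample].to_numpy(bool)
            calls = profiles.loc[genes, sample].to_numpy(float)[mask]
            calls = calls[~np.isnan(calls)]
            if calls.size == 0:
                continue
            rows.append((int(b), sample, int(calls.size), float(np.mean(calls == 1))))
    long = pd.DataFrame(rows, columns=["bin", "sample", "n_genes", "mae_proportion"])
    quart = (
        long.groupby("bin")["mae_proportion"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
        .reset_index()
    )
    return long.merge(quart, on="bin")
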
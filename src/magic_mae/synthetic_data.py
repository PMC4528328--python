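"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the population-level biology behind the chromatin
signature rather than read-level sequencing.  Genes fall into three classes:

* MAE — in each cell one allele is silenced (H3K27me3) and one active
  (H3K36me3), so the cell population shows BOTH marks over the gene body at
  roughly half dosage each, and intermediate RNA abundance;
* BAE-expressed — high H3K36me3, low H3K27me3, high RNA;
* silent — high H3K27me3, low H3K36me3, low RNA.

Per-gene mean enrichments are lognormal around class-specific levels, with
Poisson quantization noise on top; the input control is near-uniform.  These
tracks reproduce the four-quadrant geometry the classifier exploits (MAE
genes in the high-K27/high-K36 corner).  Allele counts, multi-tissue MAE
profiles evolving on a lineage tree, and ortholog tables with planted
conservation cover the downstream modules.

Every generator is a pure function of its configuration and seed: one global
seed fans out to fixed per-generator substreams, so each data type can be
regenerated independently and reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from magic_mae.io_formats import CoverageTrack, GeneModel, Transcript

# fixed substream ids: regenerating one data type never disturbs the others
_STREAMS = {
    "annotation": 11,
    "labels": 12,
    "tracks": 13,
    "alleles": 14,
    "profiles": 15,
    "orthologs": 16,
    "training": 17,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


DEFAULT_TREE = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Defaults: 2000 genes of which 15% are MAE (the upper bound reported for
    mammalian autosomal genes) and 30% silent; lognormal mark enrichment with
    a ~17-fold high/low separation (exp(mu_high)/exp(mu_low) = 5/0.3) and
    sigma = 0.5 within-class spread; MAE alleles at 0.5 dosage per mark and
    0.7 RNA dosage; clone-fixed major-allele fraction 0.95 at ~100 reads per
    gene; 6-leaf lineage tree with 5% per-branch MAE switching.
    """

    n_genes: int = 2000
    mae_fraction: float = 0.15
    silent_fraction: float = 0.30
    chrom_layout: tuple = (
        ("chr1", 40_000_000),
        ("chr2", 40_000_000),
        ("chr3", 40_000_000),
        ("chrX", 4_000_000),
    )
    n_x_genes: int = 20
    mu_high: float = math.log(5.0)
    mu_low: float = math.log(0.3)
    sigma: float = 0.5
    mae_mark_dosage: float = 0.5
    mae_rna_dosage: float = 0.7
    short_gene_fraction: float = 0.10
    allele_depth: int = 100
    mono_fraction: float = 0.95
    lineage_tree: str = DEFAULT_TREE
    switch_prob: float = 0.05
    seed: int = 0


# ---------------------------------------------------------------------------
# annotation and labels


def simulate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping gene models, 1-3 transcripts each, ~10% under 2.5 kb.

    Autosomal genes are laid across the autosomes of ``chrom_layout``;
    ``n_x_genes`` extra genes land on chrX to exercise the autosome
    restriction.  Raises when the layout cannot accommodate the genes.
    """
    rng = _rng(config.seed, "annotation")
    autosomes = [(c, l) for c, l in config.chrom_layout if c != "chrX"]
    x_chroms = [(c, l) for c, l in config.chrom_layout if c == "chrX"]
    genes: list[GeneModel] = []

    def place(n, chroms, prefix):
        placed = 0
        cursors = {c: 1000 for c, _ in chroms}
        lengths = dict(chroms)
        order = [c for c, _ in chroms]
        ci = 0
        while placed < n:
            if rng.random() < config.short_gene_fraction:
                length = int(rng.integers(1000, 2500))
            else:
                length = int(np.exp(rng.uniform(np.log(2500), np.log(50_000))))
            gap = int(rng.integers(500, 5000))
            tries = 0
            while cursors[order[ci]] + length + gap > lengths[order[ci]]:
                ci = (ci + 1) % len(order)
                tries += 1
                if tries > len(order):
                    raise ValueError(
                        f"chromosome layout too small for {n} genes"
                    )
            chrom = order[ci]
            start = cursors[chrom]
            end = start + length
            cursors[chrom] = end + gap
            gene_id = f"{prefix}{placed:05d}"
            n_tx = int(rng.integers(1, 4))
            txs = [Transcript(f"{gene_id}.t1", start, end)]
            for t in range(2, n_tx + 1):
                s = int(rng.integers(start, end - 100))
                e = int(rng.integers(s + 100, end + 1))
                txs.append(Transcript(f"{gene_id}.t{t}", s, e))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_id, chrom, strand, tuple(txs)))
            placed += 1
            ci = (ci + 1) % len(order)

    place(config.n_genes, autosomes, "gene")
    if x_chroms and config.n_x_genes:
        place(config.n_x_genes, x_chroms, "xgene")
    return genes


def simulate_labels(config: SimulationConfig) -> pd.Series:
    """Per-autosomal-gene class in {MAE, BAE-expressed, silent}."""
    rng = _rng(config.seed, "labels")
    classes = rng.choice(
        ["MAE", "BAE-expressed", "silent"],
        size=config.n_genes,
        p=[
            config.mae_fraction,
            1.0 - config.mae_fraction - config.silent_fraction,
            config.silent_fraction,
        ],
    )
    return pd.Series(classes, index=[f"gene{i:05d}" for i in range(config.n_genes)])


# ---------------------------------------------------------------------------
# coverage tracks


def simulate_tracks(
    models: list[GeneModel], labels: pd.Series, config: SimulationConfig
) -> dict[str, CoverageTrack]:
    """bedGraph-style coverage for k27, k36, input and rna.

    Each gene gets a constant per-base coverage over its span, drawn from the
    class mixture, with Poisson quantization (depth 64) as base-level noise.
    """
    rng = _rng(config.seed, "tracks")
    mu_h, mu_l, sig = config.mu_high, config.mu_low, config.sigma
    intervals: dict[str, list] = {"k27": [], "k36": [], "input": [], "rna": []}
    for gene in sorted(models, key=lambda g: g.gene_id):
        label = labels.get(gene.gene_id, "BAE-expressed")
        if label == "MAE":
            k27 = config.mae_mark_dosage * np.exp(rng.normal(mu_h, sig))
            k36 = config.mae_mark_dosage * np.exp(rng.normal(mu_h, sig))
            rna = config.mae_rna_dosage * np.exp(rng.normal(mu_h, sig))
        elif label == "silent":
            k27 = np.exp(rng.normal(mu_h, sig))
            k36 = np.exp(rng.normal(mu_l, sig))
            rna = np.exp(rng.normal(mu_l, sig))
        else:
            k27 = np.exp(rng.normal(mu_l, sig))
            k36 = np.exp(rng.normal(mu_h, sig))
            rna = np.exp(rng.normal(mu_h, sig))
        inp = np.exp(rng.normal(0.0, 0.2))
        span = (gene.chrom, min(t.start for t in gene.transcripts),
                max(t.end for t in gene.transcripts))
        for name, rate in (("k27", k27), ("k36", k36), ("input", inp), ("rna", rna)):
            value = rng.poisson(rate * 64) / 64.0
            intervals[name].append((span[0], span[1], span[2], value))
    return {name: CoverageTrack(ivals) for name, ivals in intervals.items()}


# ---------------------------------------------------------------------------
# allele counts


def simulate_allele_counts(
    models: list[GeneModel], labels: pd.Series, config: SimulationConfig
) -> pd.DataFrame:
    """Per-SNP maternal/paternal counts for expressed genes.

    MAE genes express one clone-fixed allele at ``mono_fraction``; BAE genes
    are balanced at 0.5.  Silent genes yield no reads and are absent.  Each
    gene carries 1-20 SNPs; per-SNP depth is Poisson with gene total depth
    around ``allele_depth``.
    """
    if config.allele_depth < 1:
        raise ValueError("allele_depth must be >= 1")
    rng = _rng(config.seed, "alleles")
    rows = []
    for gene in sorted(models, key=lambda g: g.gene_id):
        label = labels.get(gene.gene_id)
        if label not in ("MAE", "BAE-expressed"):
            continue
        if label == "MAE":
            f = config.mono_fraction if rng.random() < 0.5 else 1 - config.mono_fraction
        else:
            f = 0.5
        n_snps = int(rng.integers(1, 21))
        start = min(t.start for t in gene.transcripts)
        end = max(t.end for t in gene.transcripts)
        positions = np.sort(
            rng.choice(np.arange(start, end), size=min(n_snps, end - start), replace=False)
        )
        for pos in positions:
            depth = rng.poisson(config.allele_depth / n_snps)
            m = rng.binomial(depth, f)
            rows.append((gene.gene_id, gene.chrom, int(pos), int(m), int(depth - m)))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "pos", "maternal_count", "paternal_count"]
    )


# ---------------------------------------------------------------------------
# profiles on a lineage tree


def simulate_profiles(
    lineage_tree: str | None = None,
    n_genes: int = 2000,
    mae_fraction: float = 0.15,
    switch_prob: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """MAE profiles evolving on a lineage tree; leaves become samples.

    Each gene starts MAE at the root with probability ``mae_fraction`` and
    flips state independently along every branch with probability
    ``switch_prob``.  Returns the genes x leaves 0/1 matrix and the Newick
    string of the generating tree.
    """
    newick = lineage_tree or DEFAULT_TREE
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("lineage tree needs at least 3 leaves")
    rng = _rng(seed, "profiles")
    states = {}
    root = tree.seed_node
    states[root] = rng.random(n_genes) < mae_fraction
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        flip = rng.random(n_genes) < switch_prob
        states[node] = states[node.parent_node] ^ flip
    data = {
        lf.taxon.label: states[lf].astype(int) for lf in tree.leaf_node_iter()
    }
    profiles = pd.DataFrame(
        data, index=[f"gene{i:05d}" for i in range(n_genes)]
    ).astype(float)
    return profiles, newick


# ---------------------------------------------------------------------------
# orthologs with planted conservation


def simulate_orthologs(
    n_pairs: int,
    p_a: float,
    p_b: float,
    n_conserved: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict, dict]:
    """One-to-one ortholog pairs with exactly ``n_conserved`` shared-MAE pairs.

    ``round(p_a * n_pairs)`` genes are MAE in species A and likewise for B;
    the first ``n_conserved`` of each are the same pairs, the rest disjoint
    where possible.  Returns (pairs, calls_a, calls_b).
    """
    rng = _rng(seed, "orthologs")
    n_mae_a = round(p_a * n_pairs)
    n_mae_b = round(p_b * n_pairs)
    if n_conserved > min(n_mae_a, n_mae_b):
        raise ValueError(
            f"cannot plant {n_conserved} conserved pairs with "
            f"{n_mae_a} and {n_mae_b} MAE genes"
        )
    if n_mae_a + n_mae_b - n_conserved > n_pairs:
        raise ValueError("MAE sets do not fit disjointly in the universe")
    order = rng.permutation(n_pairs)
    mae_a_idx = set(order[:n_mae_a])
    mae_b_idx = set(order[:n_conserved]) | set(
        order[n_mae_a : n_mae_a + n_mae_b - n_conserved]
    )
    pairs = pd.DataFrame(
        {
            "gene_a": [f"mmu{i:05d}" for i in range(n_pairs)],
            "gene_b": [f"hsa{i:05d}" for i in range(n_pairs)],
        }
    )
    calls_a = {
        f"mmu{i:05d}": "MAE" if i in mae_a_idx else "BAE" for i in range(n_pairs)
    }
    calls_b = {
        f"hsa{i:05d}": "MAE" if i in mae_b_idx else "BAE" for i in range(n_pairs)
    }
    return pairs, calls_a, calls_b


# ---------------------------------------------------------------------------
# classifier training sets


def simulate_training_table(
    n: int = 2000,
    rule_threshold: float = 0.6,
    label_noise: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled qrank table under the planted rule "MAE iff both qranks high".

    Features are uniform on (0, 1]; the true label is MAE exactly when both
    quantile ranks exceed ``rule_threshold`` (the high-K27/high-K36 corner);
    labels are then flipped with probability ``label_noise``.
    """
    rng = _rng(seed, "training")
    k27 = rng.uniform(0, 1, n) + 1e-12
    k36 = rng.uniform(0, 1, n) + 1e-12
    truth = (k27 > rule_threshold) & (k36 > rule_threshold)
    flip = rng.random(n) < label_noise
    labels = np.where(truth ^ flip, "MAE", "BAE")
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "k27_qrank": k27,
            "k36_qrank": k36,
            "label": labels,
            "truth": np.where(truth, "MAE", "BAE"),
        }
    )
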
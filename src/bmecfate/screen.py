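"""Pooled barcoded TF-overexpression screen analysis.

Four steps: (1) genotype deconvolution assigns each cell the lentiviral
TF barcodes it carries from barcode UMI counts (UMI floor plus a
dominance-fraction rule); (2) cells are clustered by PCA on scaled
highly-variable genes, a shared-nearest-neighbor (Jaccard) graph, and
seeded modularity community detection; (3) one-vs-rest Wilcoxon cluster
markers; (4) a permutation test asks whether a genotype is over- or
under-represented in a cluster, reporting the log2 fold difference of
proportions with a bootstrap confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .markers import de_wilcoxon
from .types import ExpressionDataset, ValidationError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# genotype deconvolution
# --------------------------------------------------------------------------

@dataclass
class GenotypeAssignment:
    """Per-cell barcode calls: genotypes, supporting UMIs, and status."""

    cell_ids: list[str]
    genotypes: list[frozenset[str]]
    supporting_umis: list[dict]
    status: list[str]  # untransduced | single | multiple | ambiguous

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cell_ids,
                "genotype": ["+".join(sorted(g)) for g in self.genotypes],
                "n_barcodes": [len(g) for g in self.genotypes],
                "status": self.status,
            }
        ).set_index("cell")


def assign_genotypes(
    barcode_umis: pd.DataFrame,
    min_umis: int = 5,
    dominance_fraction: float = 0.5,
    max_multiplicity: int = 3,
) -> GenotypeAssignment:
    """Call TF barcodes per cell from a cell x barcode UMI table.

    A barcode is called when its UMI count reaches ``min_umis`` AND at
    least ``dominance_fraction`` of the cell's top barcode count — the
    dominance rule separates real co-transduction from ambient
    contamination, which sits orders of magnitude below genuine signal.
    Cells with more than ``max_multiplicity`` calls are ambiguous and
    carry no assignment.
    """
    counts = barcode_umis.to_numpy()
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValidationError("barcode UMIs must be non-negative integers")
    cells = list(barcode_umis.index)
    barcodes = np.array(barcode_umis.columns)
    genotypes, support, status = [], [], []
    for i in range(len(cells)):
        row = counts[i]
        top = row.max()
        called = (row >= min_umis) & (row >= dominance_fraction * top)
        called &= row > 0
        names = barcodes[called]
        if len(names) == 0:
            genotypes.append(frozenset())
            status.append("untransduced")
        elif len(names) > max_multiplicity:
            genotypes.append(frozenset())
            status.append("ambiguous")
        else:
            genotypes.append(frozenset(names))
            status.append("single" if len(names) == 1 else "multiple")
        support.append({b: int(row[j]) for j, b in enumerate(barcodes) if called[j]})
    return GenotypeAssignment(cells, genotypes, support, status)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def _highly_variable_genes(values: np.ndarray, n_top: int) -> np.ndarray:
    """Top genes by variance-stabilized dispersion (variance / mean on the
    linear scale, binned z-scored by mean)."""
    linear = np.expm1(values)
    mean = linear.mean(axis=1)
    var = linear.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    # z-score dispersion within 20 mean bins
    order = np.argsort(mean)
    n_bins = 20
    z = np.zeros_like(dispersion)
    bins = np.array_split(order, n_bins)
    for b in bins:
        d = dispersion[b]
        s = d.std()
        z[b] = (d - d.mean()) / s if s > 0 else 0.0
    n_top = min(n_top, len(z))
    return np.sort(np.argsort(-z)[:n_top])


def snn_graph(
    coords: np.ndarray, k_neighbors: int = 20
) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Two cells are connected when they appear in each other's k-NN
    neighborhood union; the weight is the Jaccard index of their
    neighbor sets (each set includes the cell itself, Seurat-style).
    Edges with zero Jaccard are dropped.
    """
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_sets = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    g.simplify(combine_edges="max")
    return g


def cluster_cells(
    dataset: ExpressionDataset,
    n_pcs_computed: int = 50,
    n_pcs_used: int = 15,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    n_hvg: int = 2000,
    scale_clip: float = 10.0,
) -> np.ndarray:
    """PCA -> SNN graph -> seeded modularity communities.

    Expects log-normalized data; genes are restricted to the top
    ``n_hvg`` highly-variable genes, scaled to zero mean / unit variance
    and clipped at ``±scale_clip``; ``n_pcs_computed`` components are
    computed and the first ``n_pcs_used`` feed the k-NN graph.  Leiden
    community detection (RB-configuration modularity at ``resolution``)
    runs with a fixed seed; labels are 0..K-1 by decreasing cluster size.
    """
    if dataset.n_samples < k_neighbors:
        raise ValidationError(
            f"{dataset.n_samples} cells < k_neighbors={k_neighbors}"
        )
    hvg = _highly_variable_genes(dataset.values, n_hvg)
    x = dataset.values[hvg, :].T.copy()  # cells x genes
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    np.clip(x, -scale_clip, scale_clip, out=x)
    n_comp = min(n_pcs_computed, min(x.shape) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)[:, : min(n_pcs_used, n_comp)]
    graph = snn_graph(coords, k_neighbors=k_neighbors)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.array(partition.membership)
    # relabel by decreasing size, ties by original label for determinism
    sizes = np.bincount(labels)
    new_order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(new_order)
    remap[new_order] = np.arange(len(new_order))
    return remap[labels]


def cluster_markers(
    dataset: ExpressionDataset,
    labels: np.ndarray,
    min_pct: float = 0.01,
    logfc_min: float = 0.25,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per cluster with the screen's gates.

    Keeps rows with average log2 fold change above ``logfc_min`` and
    p below ``p_max``; clusters with fewer than 3 cells are skipped.
    """
    table = de_wilcoxon(
        dataset,
        [f"c{l}" for l in labels],
        min_pct=min_pct,
        fc_threshold=1.0,
        min_group_size=3,
    )
    keep = (table["log2_fold_change"] > logfc_min) & (table["p_value"] < p_max)
    return table.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# proportion permutation test
# --------------------------------------------------------------------------

def _log2fd(n_gc, n_g, n_oc, n_o):
    """log2 of genotype vs non-genotype proportions in one cluster,
    with a pseudocount of one cell on each numerator.  Vectorized over
    cluster counts."""
    return np.log2(((np.asarray(n_gc) + 1) / n_g) / ((np.asarray(n_oc) + 1) / n_o))


def proportion_permutation_test(
    labels: np.ndarray,
    genotypes: list[frozenset[str]] | pd.Series,
    n_permutations: int = 1000,
    log2fd_threshold: float = float(np.log2(1.275)),
    alpha: float = 0.05,
    seed: int = 0,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Genotype-proportion shifts per cluster with a permutation null.

    For every (cluster, genotype) pair the observed log2 fold difference
    compares the genotype's share of the cluster with all other cells'
    share.  The null distribution permutes genotype membership across
    cells ``n_permutations`` times (two-sided p with the +1 correction);
    the confidence interval is an empirical bootstrap (cells resampled
    with replacement, ``n_permutations`` draws).  A pair is significant
    when the CI lies entirely outside ``±log2fd_threshold`` AND the
    permutation p-value is below ``alpha``.  Genotypes with fewer than
    ``min_cells`` cells are skipped.
    """
    labels = np.asarray(labels)
    if isinstance(genotypes, pd.Series):
        genotype_sets = [
            frozenset(g.split("+")) if g else frozenset() for g in genotypes
        ]
    else:
        genotype_sets = list(genotypes)
    n = len(labels)
    if n != len(genotype_sets):
        raise ValidationError("labels and genotypes length mismatch")
    all_genotypes = sorted({g for gs in genotype_sets for g in gs})
    clusters, label_idx = np.unique(labels, return_inverse=True)
    n_clusters = len(clusters)
    rng = np.random.default_rng(seed)
    rows = []
    for g in all_genotypes:
        is_g = np.array([g in gs for gs in genotype_sets])
        n_g = int(is_g.sum())
        n_o = n - n_g
        if n_g < min_cells:
            log.warning("genotype %s has %d cells (< %d); skipped", g, n_g, min_cells)
            continue
        obs_gc = np.bincount(label_idx[is_g], minlength=n_clusters)
        cluster_sizes = np.bincount(label_idx, minlength=n_clusters)
        obs = _log2fd(obs_gc, n_g, cluster_sizes - obs_gc, n_o)
        # permutation null: shuffle genotype membership across cells
        perm_fd = np.empty((n_permutations, n_clusters))
        for p in range(n_permutations):
            chosen = rng.choice(n, size=n_g, replace=False)
            n_gc = np.bincount(label_idx[chosen], minlength=n_clusters)
            perm_fd[p] = _log2fd(n_gc, n_g, cluster_sizes - n_gc, n_o)
        # bootstrap CI of the observed FD (cells resampled with replacement)
        boot_fd = np.full((n_permutations, n_clusters), np.nan)
        for p in range(n_permutations):
            take = rng.integers(0, n, size=n)
            bg = is_g[take]
            n_gb = int(bg.sum())
            if n_gb == 0 or n_gb == n:
                continue
            bl = label_idx[take]
            n_gc = np.bincount(bl[bg], minlength=n_clusters)
            n_c = np.bincount(bl, minlength=n_clusters)
            boot_fd[p] = _log2fd(n_gc, n_gb, n_c - n_gc, n - n_gb)
        null_center = perm_fd.mean(axis=0)
        for ci, c in enumerate(clusters):
            null = perm_fd[:, ci]
            p_val = (
                1
                + np.sum(np.abs(null - null_center[ci]) >= abs(obs[ci] - null_center[ci]))
            ) / (n_permutations + 1)
            boots = boot_fd[:, ci]
            boots = boots[~np.isnan(boots)]
            lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
            significant = bool(
                (lo > log2fd_threshold or hi < -log2fd_threshold) and p_val < alpha
            )
            rows.append(
                {
                    "cluster": int(c),
                    "genotype": g,
                    "n_genotype_cells": n_g,
                    "observed_log2fd": float(obs[ci]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p_value": float(p_val),
                    "significant": significant,
                    "n_permutations": n_permutations,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "genotype",
            "n_genotype_cells",
            "observed_log2fd",
            "ci_low",
            "ci_high",
            "p_value",
            "significant",
            "n_permutations",
        ],
    )
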
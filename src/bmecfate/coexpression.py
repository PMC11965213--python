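"""Signed co-expression module detection and motif-recovery enrichment.

Genes are connected by a signed soft-thresholded correlation adjacency
``a_ij = ((1 + cor_ij) / 2) ** power``; the topological overlap measure
(TOM) turns shared neighborhoods into a similarity, average-linkage
clustering on ``1 - TOM`` yields a dendrogram, and a static height cut
with a minimum module size produces modules, which are then merged while
their eigengenes are closer than a dissimilarity threshold.  A
single-sample rank-based enrichment score summarizes module activity per
sample, and a motif-ranking table provides per-TF recovery AUCs whose
z-scores (NES) flag candidate regulators of each module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .types import ExpressionDataset, ValidationError

log = logging.getLogger(__name__)


@dataclass
class CoexpressionModule:
    module_id: str
    genes: list[str]
    eigengene: np.ndarray  # per-sample, sign-oriented


# --------------------------------------------------------------------------
# soft power
# --------------------------------------------------------------------------

def _signed_adjacency(values: np.ndarray, power: float) -> np.ndarray:
    """Signed adjacency from a gene x sample matrix."""
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0][:10]
        raise ValidationError(f"constant gene rows at positions {bad.tolist()}")
    cor = np.corrcoef(values)
    np.clip(cor, -1.0, 1.0, out=cor)
    return ((1.0 + cor) / 2.0) ** power


def scale_free_fit(adjacency: np.ndarray, n_breaks: int = 10) -> float:
    """Signed scale-free topology fit index of a network.

    Connectivities are binned, the log-log frequency/connectivity
    relation is fit by least squares, and the squared correlation is
    signed by the negative of the slope (a scale-free network has a
    decreasing log-log frequency curve).
    """
    k = adjacency.sum(axis=1) - np.diag(adjacency)
    k = k[k > 0]
    if len(k) < n_breaks:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_breaks + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_breaks - 1)
    log_k, log_p = [], []
    for b in range(n_breaks):
        mask = which == b
        if mask.sum() == 0:
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_p.append(np.log10(mask.mean()))
    if len(log_k) < 3:
        return 0.0
    log_k, log_p = np.array(log_k), np.array(log_p)
    slope, _ = np.polyfit(log_k, log_p, 1)
    r = np.corrcoef(log_k, log_p)[0, 1]
    return float(-np.sign(slope) * r * r)


def pick_soft_power(
    dataset: ExpressionDataset,
    powers: range = range(1, 31),
    r2_target: float = 0.8,
) -> int:
    """Smallest power whose scale-free fit reaches ``r2_target``.

    Falls back (with a warning) to the power maximizing the fit when no
    power reaches the target.
    """
    if dataset.n_samples < 3:
        raise ValidationError("need >= 3 samples for a correlation network")
    fits = {}
    for p in powers:
        fits[p] = scale_free_fit(_signed_adjacency(dataset.values, p))
        if fits[p] >= r2_target:
            return p
    best = max(fits, key=lambda p: fits[p])
    log.warning(
        "no power in %s reaches fit %.2f; using power %d (fit %.3f)",
        list(powers)[:1] + ["..."] + list(powers)[-1:],
        r2_target,
        best,
        fits[best],
    )
    return best


# --------------------------------------------------------------------------
# module detection
# --------------------------------------------------------------------------

def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Diagonal treated as 1; symmetric; values in [0, 1].
    """
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    k_min = np.minimum.outer(k, k)
    tom = (l + a) / (k_min + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(values: np.ndarray) -> np.ndarray:
    """First principal component across samples, sign-oriented to
    correlate positively with the module's mean expression."""
    centered = values - values.mean(axis=1, keepdims=True)
    # genes x samples: PC over samples = first right singular vector
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    eig = vt[0]
    mean_expr = centered.mean(axis=0)
    if np.dot(eig, mean_expr) < 0:
        eig = -eig
    return eig


def _cut_clusters(
    linkage: np.ndarray, heights: np.ndarray, cut_height: float | str, min_size: int
) -> np.ndarray:
    if isinstance(cut_height, (int, float)):
        return sch.fcluster(linkage, t=float(cut_height), criterion="distance")
    if cut_height != "auto":
        raise ValueError(f"unknown cut_height {cut_height!r}")
    # static cut chosen once per dendrogram: scan midpoints between
    # consecutive merge heights and keep the highest cut maximizing the
    # number of clusters that reach min_size (the highest such cut pulls
    # stragglers into their module without collapsing distinct modules,
    # which would reduce the count)
    hs = np.unique(heights)
    candidates = (hs[:-1] + hs[1:]) / 2 if len(hs) > 1 else hs
    best_labels, best_score, best_h = None, -1, None
    for h in candidates:
        labels = sch.fcluster(linkage, t=h, criterion="distance")
        sizes = np.bincount(labels)
        score = int((sizes >= min_size).sum())
        if score >= best_score:
            best_labels, best_score, best_h = labels, score, h
    log.info("auto cut height %.4f -> %d modules >= min_size", best_h, best_score)
    return best_labels


def detect_modules(
    dataset: ExpressionDataset,
    power: int,
    min_size: int = 30,
    merge_dissim: float = 0.3,
    cut_height: float | str = "auto",
) -> list[CoexpressionModule]:
    """TOM-based module detection with eigengene merging.

    Average-linkage hierarchical clustering on ``1 - TOM`` is cut at a
    static height (``"auto"`` scans merge heights for the cut yielding
    the most modules of at least ``min_size``); clusters below
    ``min_size`` fall into an ``unassigned`` pool.  Modules whose
    eigengene dissimilarity ``1 - cor`` is below ``merge_dissim`` are
    merged iteratively until stable.  Ties in the linkage are broken by
    lexicographic gene order (genes are sorted before clustering), so
    detection is deterministic given the matrix.
    """
    genes = sorted(dataset.gene_ids)
    d = dataset.subset(genes=genes)
    if d.n_genes < min_size:
        return [
            CoexpressionModule("unassigned", genes, np.zeros(d.n_samples))
        ]
    adjacency = _signed_adjacency(d.values, power)
    tom = topological_overlap(adjacency)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    labels = _cut_clusters(linkage, linkage[:, 2], cut_height, min_size)

    # collect clusters of sufficient size; the rest is unassigned
    assignments: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        assignments.setdefault(int(lab), []).append(i)
    module_members = [idx for idx in assignments.values() if len(idx) >= min_size]
    unassigned = sorted(
        i for idx in assignments.values() if len(idx) < min_size for i in idx
    )

    # iterative eigengene merging
    while True:
        if len(module_members) < 2:
            break
        eigs = np.array([_eigengene(d.values[idx, :]) for idx in module_members])
        cor = np.corrcoef(eigs)
        dissim = 1.0 - cor
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(np.argmin(dissim), dissim.shape)
        if dissim[i, j] >= merge_dissim:
            break
        a, b = sorted((i, j))
        merged = sorted(module_members[a] + module_members[b])
        module_members = [
            m for t, m in enumerate(module_members) if t not in (a, b)
        ] + [merged]

    module_members.sort(key=lambda idx: (-len(idx), idx[0]))
    modules = [
        CoexpressionModule(
            module_id=f"M{t + 1:02d}",
            genes=[genes[i] for i in idx],
            eigengene=_eigengene(d.values[idx, :]),
        )
        for t, idx in enumerate(module_members)
    ]
    if unassigned:
        modules.append(
            CoexpressionModule(
                "unassigned",
                [genes[i] for i in unassigned],
                np.zeros(d.n_samples),
            )
        )
    return modules


# --------------------------------------------------------------------------
# single-sample module activity
# --------------------------------------------------------------------------

def score_module_activity(
    dataset: ExpressionDataset,
    module_genes,
    weight: float = 0.25,
    min_overlap: int = 5,
) -> np.ndarray:
    """Single-sample rank-based enrichment score of a gene set.

    Per sample, genes are ranked by decreasing expression; a weighted
    running sum accumulates in-set genes with weight
    ``(n - position + 1) ** weight`` (normalized) and out-set genes with
    ``1 / n_out``.  The score is the maximum positive deviation minus the
    maximum negative deviation of the running difference, in [-1, 1].
    A set covering every gene carries no ranking information and scores 0.
    Scores are comparable across samples of one dataset only.
    """
    module_genes = set(module_genes)
    overlap = [g for g in dataset.gene_ids if g in module_genes]
    if len(overlap) < min_overlap and len(overlap) < dataset.n_genes:
        raise ValidationError(
            f"module overlaps dataset by {len(overlap)} genes (< {min_overlap})"
        )
    n = dataset.n_genes
    in_set = np.array([g in module_genes for g in dataset.gene_ids])
    n_out = n - int(in_set.sum())
    scores = np.zeros(dataset.n_samples)
    if n_out == 0:
        return scores
    w_by_pos = (np.arange(n, 0, -1)) ** weight  # weight of position 1..n
    for j in range(dataset.n_samples):
        order = np.argsort(-dataset.values[:, j], kind="stable")
        hits = in_set[order]
        w = np.where(hits, w_by_pos, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~hits) / n_out
        run = p_in - p_out
        scores[j] = max(run.max(), 0.0) + min(run.min(), 0.0)
    return scores


# --------------------------------------------------------------------------
# motif-recovery NES
# --------------------------------------------------------------------------

def recovery_auc(
    ranking: np.ndarray, gene_set_mask: np.ndarray, top_fraction: float = 0.05
) -> float:
    """Normalized recovery AUC of a gene set down one TF's genome ranking.

    ``ranking`` holds 1-based ranks per gene; the step recovery curve over
    the first ``ceil(top_fraction * n)`` positions is integrated and
    divided by the maximum achievable area.
    """
    n = len(ranking)
    k = max(1, int(np.ceil(top_fraction * n)))
    t = int(gene_set_mask.sum())
    if t == 0:
        raise ValueError("empty gene set on ranking universe")
    ranks = ranking[gene_set_mask]
    area = float(np.maximum(0, k - ranks + 1).sum())
    t_eff = min(t, k)
    max_area = t_eff * (t_eff + 1) / 2 + (k - t_eff) * t_eff
    return area / max_area


def motif_enrichment_nes(
    module_genes,
    motif_rankings: pd.DataFrame,
    top_fraction: float = 0.05,
    nes_min: float = 3.0,
) -> pd.DataFrame:
    """Per-TF recovery AUC of a module and its NES across TFs.

    ``motif_rankings``: TFs x genes table of 1-based genome ranks.  The
    NES is the z-score of a TF's AUC over all TFs for this module
    (population standard deviation), and rows with ``nes > nes_min`` are
    flagged as candidate regulators.
    """
    universe = list(motif_rankings.columns)
    mask = np.array([g in set(module_genes) for g in universe])
    if not mask.any():
        raise ValidationError("module has no gene in the motif-ranking universe")
    aucs = np.array(
        [
            recovery_auc(motif_rankings.loc[tf].to_numpy(), mask, top_fraction)
            for tf in motif_rankings.index
        ]
    )
    sd = aucs.std()  # ddof=0 so that NES has unit sd by construction
    nes = (aucs - aucs.mean()) / sd if sd > 0 else np.zeros_like(aucs)
    return pd.DataFrame(
        {
            "tf": motif_rankings.index,
            "recovery_auc": aucs,
            "nes": nes,
            "flagged": nes > nes_min,
        }
    ).set_index("tf")
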
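"""Ranking-based regulon activity (AUC) and its summaries.

A regulon's activity in a sample is the area under the recovery curve of
its target genes within the top fraction of that sample's expression
ranking, normalized to the maximum achievable area (all targets at the
very top).  Only ranks matter, so the score is invariant to monotone
transforms of expression.  A *reversed* context inverts every ranking so
that the same AUC scores under-representation — used to select regulons
that are inactive in non-brain endothelial cells.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ActivityMatrix, ExpressionDataset, RankingContext, Regulon, RegulonSet

log = logging.getLogger(__name__)


def build_ranking(
    dataset: ExpressionDataset,
    direction: str = "forward",
    tie_seed: int = 0,
    context_id: str | None = None,
) -> RankingContext:
    """Per-sample gene rankings by decreasing expression.

    Ties are broken by a uniform random permutation drawn from
    ``tie_seed`` (ties are ubiquitous in sparse count data, and a fixed
    deterministic tie-break would bias every zero-inflated regulon the
    same way).  ``direction="reversed"`` inverts the final order.
    """
    if direction not in ("forward", "reversed"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(tie_seed)
    n_g, n_s = dataset.values.shape
    # random tie-break key per (gene, sample); lexsort: primary -values,
    # secondary random key
    noise = rng.random((n_g, n_s))
    order = np.empty((n_g, n_s), dtype=np.int64)
    for j in range(n_s):
        order[:, j] = np.lexsort((noise[:, j], -dataset.values[:, j]))
    if direction == "reversed":
        order = order[::-1, :]
    return RankingContext(
        context_id=context_id or f"{dataset.dataset_id}_{direction}",
        dataset_id=dataset.dataset_id,
        direction=direction,
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        order=order,
        tie_seed=tie_seed,
    )


def _auc_window(n_genes: int, top_fraction: float) -> int:
    k = math.ceil(top_fraction * n_genes)
    return max(1, min(k, n_genes))


def _max_area(n_targets: int, window: int) -> float:
    """Area when all targets occupy the very top of the ranking."""
    t = min(n_targets, window)
    return t * (t + 1) / 2 + (window - t) * t


def compute_auc(
    ctx: RankingContext, regulon: Regulon, top_fraction: float = 0.05
) -> np.ndarray:
    """Per-sample recovery AUC of a regulon's targets.

    The step recovery curve counts targets found at each of the first
    ``ceil(top_fraction * n_genes)`` ranks; its integral equals
    ``sum_j max(0, window - rank_j + 1)`` over target ranks, which is
    divided by the maximum achievable area.  Returns 0 for a sample in
    which no target falls inside the window.
    """
    universe = set(ctx.gene_ids)
    targets = sorted(regulon.targets & universe)
    if not targets:
        raise ValueError(
            f"regulon {regulon.tf}: no target in ranking universe of "
            f"{ctx.context_id}"
        )
    k = _auc_window(len(ctx.gene_ids), top_fraction)
    pos = {g: i for i, g in enumerate(ctx.gene_ids)}
    rows = np.array([pos[g] for g in targets], dtype=int)
    ranks = ctx.ranks[rows, :]  # (n_targets, n_samples), 1-based
    area = np.maximum(0, k - ranks + 1).sum(axis=0).astype(float)
    return area / _max_area(len(targets), k)


def compute_activity_matrix(
    ctx: RankingContext,
    regulons: RegulonSet,
    top_fraction: float = 0.05,
    skip_missing: bool = True,
) -> ActivityMatrix:
    """AUC of every regulon in every sample of one context.

    Regulons with no target in the context's universe are skipped with a
    log entry when ``skip_missing`` (they cannot be scored there).
    """
    universe = set(ctx.gene_ids)
    pos = {g: i for i, g in enumerate(ctx.gene_ids)}
    k = _auc_window(len(ctx.gene_ids), top_fraction)
    ranks = ctx.ranks
    kept: list[str] = []
    rows: list[np.ndarray] = []
    for reg in regulons:
        targets = sorted(reg.targets & universe)
        if not targets:
            if not skip_missing:
                raise ValueError(
                    f"regulon {reg.tf}: no target in universe of {ctx.context_id}"
                )
            log.info("%s: regulon %s has no target in universe", ctx.context_id, reg.tf)
            continue
        idx = np.array([pos[g] for g in targets], dtype=int)
        area = np.maximum(0, k - ranks[idx, :] + 1).sum(axis=0).astype(float)
        kept.append(reg.tf)
        rows.append(area / _max_area(len(targets), k))
    values = np.vstack(rows) if rows else np.empty((0, len(ctx.sample_ids)))
    return ActivityMatrix(
        context_id=ctx.context_id,
        regulon_ids=kept,
        sample_ids=list(ctx.sample_ids),
        values=values,
        top_fraction=top_fraction,
    )


def aggregate_activity(
    am: ActivityMatrix,
    groups: Mapping[str, Sequence[str]],
    stat: str = "median",
) -> pd.DataFrame:
    """Per-regulon group summaries of AUC.

    ``stat="median"`` is the 0.5 quantile with linear interpolation;
    ``stat="mean"`` the arithmetic mean.  Returns a regulon x group frame.
    """
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    frame = am.to_frame()
    out = {}
    for group, samples in groups.items():
        samples = list(samples)
        if not samples:
            raise ValueError(f"group {group!r} is empty")
        missing = [s for s in samples if s not in frame.columns]
        if missing:
            raise ValueError(f"group {group!r} references unknown samples {missing[:5]}")
        sub = frame[samples].to_numpy()
        if stat == "median":
            out[group] = np.quantile(sub, 0.5, axis=1)
        else:
            out[group] = sub.mean(axis=1)
    return pd.DataFrame(out, index=frame.index)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins.

    Implemented on the rank scale (stable order for ties) so that bin
    occupancies differ by at most one sample.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def mutual_information(
    auc: np.ndarray,
    labels: Sequence[str],
    n_bins: int = 0,
) -> float:
    """Plug-in mutual information (nats) between AUC and a categorical label.

    The continuous AUC vector is discretized into ``n_bins``
    equal-frequency bins (default ``ceil(N ** (1/3))``), then MI is read
    off the joint contingency table with natural logs.  A constant AUC
    vector carries no information and returns 0 (with a warning).
    """
    auc = np.asarray(auc, dtype=float)
    labels = np.asarray(labels)
    if auc.shape[0] != labels.shape[0]:
        raise ValueError("auc and labels length mismatch")
    n = auc.shape[0]
    cats, y = np.unique(labels, return_inverse=True)
    if len(cats) < 2:
        raise ValueError("need >= 2 label categories")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("every label category needs >= 2 samples")
    if np.allclose(auc, auc[0]):
        log.warning("constant AUC vector: MI = 0")
        return 0.0
    if n_bins <= 0:
        n_bins = math.ceil(n ** (1 / 3))
    n_bins = min(n_bins, n)
    x = _equal_frequency_bins(auc, n_bins)
    joint = np.zeros((n_bins, len(cats)))
    np.add.at(joint, (x, y), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def transformed_mi(mi: float, epsilon: float = 1e-6) -> float:
    """log10(MI + eps): the scale on which the funnel's MI floor applies.

    Raw plug-in MI is non-negative, so a threshold of -1.3 can only act
    on a log scale; ``log10(MI + 1e-6) > -1.3`` keeps regulons with
    MI above roughly 0.05 nats.
    """
    return math.log10(mi + epsilon)
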
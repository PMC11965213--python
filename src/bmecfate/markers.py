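"""Differential-expression marker detection and the four brain-EC marker sets.

Marker genes come from one-vs-rest Wilcoxon rank-sum tests on
log-normalized data (Seurat-style gates: min.pct and a fold-change
threshold).  The four criteria-defined brain-EC marker sets combine
(1, 2) murine brain-EC vs other-EC fold changes at 4x / 2x with a cap on
90th-percentile expression in human non-brain ECs, (3) 4x brain-EC vs
other-brain-cell enrichment in the designated single-cell datasets, and
(4) the 2x murine criterion plus strictly positive capillary-vs-large
log fold change.  Every set records the full predicate it applied so a
membership can be replayed from the stored inputs.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .types import ExpressionDataset, MarkerSet, ValidationError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum DE
# --------------------------------------------------------------------------

def _ranksum_pvalues(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p-values, one gene per row.

    Normal approximation with tie correction (the standard large-sample
    route for cluster markers); exactness is checked against the
    brute-force U statistic in the test suite.
    """
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    n = n1 + n2
    ranks = scipy.stats.rankdata(values, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    # tie correction per gene
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mu) / sigma
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    p[sigma == 0] = 1.0  # all-tied gene: no evidence
    return np.clip(p, 0.0, 1.0), u


def de_wilcoxon(
    dataset: ExpressionDataset,
    group_labels: Sequence[str],
    min_pct: float = 0.25,
    fc_threshold: float = 1.2,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per group.

    Genes are tested only when detected in at least ``min_pct`` of either
    side and when the fold change (group means on the ``expm1`` scale,
    pseudocount 1) is at least ``fc_threshold`` in either direction.
    Returns a MarkerTable frame with columns gene, group,
    log2_fold_change, p_value, p_adj (Bonferroni over tested rows),
    pct_in_group, pct_out_group, dataset_id.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != dataset.n_samples:
        raise ValidationError("group_labels length != n_samples")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups for one-vs-rest DE")
    if dataset.unit == "log_normalized":
        linear = np.expm1(dataset.values)
    else:
        linear = dataset.values
    rows: list[dict] = []
    for group in groups:
        in_group = labels == group
        if in_group.sum() < min_group_size:
            log.warning("group %s has < %d samples; skipped", group, min_group_size)
            continue
        pct_in = (dataset.values[:, in_group] > 0).mean(axis=1)
        pct_out = (dataset.values[:, ~in_group] > 0).mean(axis=1)
        mean_in = linear[:, in_group].mean(axis=1)
        mean_out = linear[:, ~in_group].mean(axis=1)
        fold = (mean_in + 1.0) / (mean_out + 1.0)
        testable = (np.maximum(pct_in, pct_out) >= min_pct) & (
            np.maximum(fold, 1.0 / fold) >= fc_threshold
        )
        if not testable.any():
            continue
        idx = np.where(testable)[0]
        p, _ = _ranksum_pvalues(dataset.values[idx, :], in_group)
        for i, pi in zip(idx, p):
            rows.append(
                {
                    "gene": dataset.gene_ids[i],
                    "group": group,
                    "log2_fold_change": float(np.log2(fold[i])),
                    "p_value": float(pi),
                    "pct_in_group": float(pct_in[i]),
                    "pct_out_group": float(pct_out[i]),
                    "dataset_id": dataset.dataset_id,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "group",
            "log2_fold_change",
            "p_value",
            "pct_in_group",
            "pct_out_group",
            "dataset_id",
        ],
    )
    n_tests = len(table)
    table["p_adj"] = np.minimum(table["p_value"] * max(n_tests, 1), 1.0)
    return table


def group_fold_change(
    dataset: ExpressionDataset,
    in_samples: Sequence[str],
    out_samples: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene linear fold change between two sample groups.

    Means are taken on the linear scale (``expm1`` applied first when the
    dataset is log-normalized) with a pseudocount on both sides.
    """
    values = dataset.values
    if dataset.unit == "log_normalized":
        values = np.expm1(values)
    si = {s: i for i, s in enumerate(dataset.sample_ids)}
    a = values[:, [si[s] for s in in_samples]].mean(axis=1)
    b = values[:, [si[s] for s in out_samples]].mean(axis=1)
    return pd.Series(
        (a + pseudocount) / (b + pseudocount), index=dataset.gene_ids, name="fold"
    )


# --------------------------------------------------------------------------
# percentile cross filter
# --------------------------------------------------------------------------

def percentile_cross_filter(
    brain_expr: pd.DataFrame | ExpressionDataset,
    nonbrain_expr: pd.DataFrame | ExpressionDataset,
    q: float = 0.9,
    max_fold: float = 7.0,
) -> pd.Series:
    """Genes not over-expressed in non-brain ECs.

    A gene passes iff ``(quantile_q(nonbrain) + 1) / (mean(brain) + 1)
    < max_fold``.  Genes absent from either summary fail with a logged
    reason.  Inputs may be gene x sample frames or datasets on a common
    positive scale.
    """

    def _frame(x):
        if isinstance(x, ExpressionDataset):
            v = np.expm1(x.values) if x.unit == "log_normalized" else x.values
            return pd.DataFrame(v, index=x.gene_ids, columns=x.sample_ids)
        return x

    brain = _frame(brain_expr)
    nonbrain = _frame(nonbrain_expr)
    union = brain.index.union(nonbrain.index, sort=False)
    result = pd.Series(False, index=union, name="passes")
    common = brain.index.intersection(nonbrain.index)
    absent = union.difference(common)
    if len(absent):
        log.info("%d genes absent from one summary fail the percentile filter", len(absent))
    q_nb = nonbrain.loc[common].quantile(q, axis=1)
    mean_brain = brain.loc[common].mean(axis=1)
    result.loc[common] = ((q_nb + 1.0) / (mean_brain + 1.0) < max_fold).to_numpy()
    return result


# --------------------------------------------------------------------------
# the four marker sets
# --------------------------------------------------------------------------

def _positive_markers(table: pd.DataFrame, min_fold: float, p_max: float = 0.05) -> set[str]:
    """Genes up in the focal group at the given linear fold floor."""
    sel = (table["log2_fold_change"] >= np.log2(min_fold)) & (table["p_value"] < p_max)
    return set(table.loc[sel, "gene"])


def build_marker_sets(
    murine_table: pd.DataFrame,
    sc_tables: Mapping[str, pd.DataFrame],
    zonated_table: pd.DataFrame,
    brain_summary: pd.DataFrame,
    nonbrain_summary: pd.DataFrame,
    fold_strict: float = 4.0,
    fold_lenient: float = 2.0,
    percentile_q: float = 0.9,
    percentile_fold_strict: float = 7.0,
    percentile_fold_lenient: float = 7.5,
    set3_mode: str = "all",
    p_max: float = 0.05,
) -> dict[str, MarkerSet]:
    """Construct the four criteria-defined brain-EC marker sets.

    Inputs
    ------
    murine_table:
        MarkerTable of the murine array contrast, ``brain_ec`` group rows
        giving brain-EC vs other-EC fold changes.
    sc_tables:
        Per designated single-cell dataset, MarkerTable whose
        ``brain_ec`` rows give brain-EC vs other-brain-cell folds.
    zonated_table:
        MarkerTable with a ``capillary`` group (capillary vs large
        vessels contrast).
    brain_summary, nonbrain_summary:
        Gene x sample linear-scale expression frames for the percentile
        cross filter.
    set3_mode:
        ``"all"`` requires the 4x single-cell criterion in every
        designated dataset; ``"any"`` in at least one.

    The candidate universe for every set is the union of positive
    single-cell brain-EC markers: the murine fold and percentile criteria
    then rank that universe.
    """
    if set3_mode not in ("all", "any"):
        raise ValidationError("set3_mode must be 'all' or 'any'")
    for name, table in [("murine", murine_table), ("zonated", zonated_table)]:
        if table is None:
            raise ValidationError(f"marker-set construction blocked: {name} table missing")
    if not sc_tables:
        raise ValidationError("marker-set construction blocked: no sc tables (sets 1-4)")

    murine_brain = murine_table[murine_table["group"] == "brain_ec"]
    sc_brain = {k: t[t["group"] == "brain_ec"] for k, t in sc_tables.items()}
    capillary = zonated_table[zonated_table["group"] == "capillary"]

    universe: set[str] = set()
    for t in sc_brain.values():
        universe |= _positive_markers(t, min_fold=1.0, p_max=p_max)

    murine_4 = _positive_markers(murine_brain, fold_strict, p_max) & universe
    murine_2 = _positive_markers(murine_brain, fold_lenient, p_max) & universe

    pct_strict = percentile_cross_filter(
        brain_summary, nonbrain_summary, q=percentile_q, max_fold=percentile_fold_strict
    )
    pct_lenient = percentile_cross_filter(
        brain_summary, nonbrain_summary, q=percentile_q, max_fold=percentile_fold_lenient
    )
    pass_strict = set(pct_strict.index[pct_strict])
    pass_lenient = set(pct_lenient.index[pct_lenient])

    sc_4_per_ds = [_positive_markers(t, fold_strict, p_max) for t in sc_brain.values()]
    combine = set.intersection if set3_mode == "all" else set.union
    sc_4 = combine(*sc_4_per_ds) if sc_4_per_ds else set()

    cap_up = set(
        capillary.loc[
            (capillary["log2_fold_change"] > 0) & (capillary["p_value"] < p_max),
            "gene",
        ]
    )

    set1 = murine_4 & pass_strict
    set2 = murine_2 & pass_lenient
    set3 = sc_4 & universe
    set4 = murine_2 & pass_lenient & cap_up

    base = {
        "percentile_q": percentile_q,
        "sc_datasets": sorted(sc_tables),
        "p_max": p_max,
    }
    sets = {
        "set1": MarkerSet(
            "set1",
            frozenset(set1),
            {
                **base,
                "murine_min_fold": fold_strict,
                "percentile_max_fold": percentile_fold_strict,
            },
        ),
        "set2": MarkerSet(
            "set2",
            frozenset(set2),
            {
                **base,
                "murine_min_fold": fold_lenient,
                "percentile_max_fold": percentile_fold_lenient,
            },
        ),
        "set3": MarkerSet(
            "set3",
            frozenset(set3),
            {**base, "sc_min_fold": fold_strict, "mode": set3_mode},
        ),
        "set4": MarkerSet(
            "set4",
            frozenset(set4),
            {
                **base,
                "murine_min_fold": fold_lenient,
                "percentile_max_fold": percentile_fold_lenient,
                "capillary_logfc_above": 0.0,
            },
        ),
    }
    if not sets["set1"].genes <= sets["set2"].genes:
        raise AssertionError("marker-set nesting violated: set1 must be within set2")
    return sets
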
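"""End-to-end orchestration of the prioritization funnel and the screen.

``run_funnel`` takes a meta-cohort (expression datasets with class /
zonation metadata), a regulon collection, a motif-ranking table and a
recipient-cell TPM table, and drives every stage: lift-over, per-dataset
preprocessing, activity scoring under the four ranking contexts, module
detection with motif NES, marker-set construction, and the staged TF
filter — returning the per-TF FunnelRecords plus all intermediate tables.
``run_screen`` drives the barcode-screen analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import activity, coexpression, funnel, markers, preprocess, screen
from .config import RunConfig
from .io import apply_ortholog_map
from .types import ExpressionDataset, MarkerSet, RegulonSet, ValidationError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# dataset roles
# --------------------------------------------------------------------------

def classify_dataset(d: ExpressionDataset) -> str:
    """Infer a dataset's role in the funnel from its metadata.

    ``zonated``: carries real vascular-bed labels; ``nonbrain_array``:
    only non-brain ECs; ``murine_array``: brain vs other-organ ECs;
    ``sc``: brain ECs among other brain cells.
    """
    beds = set(d.metadata["vascular_bed"]) - {"na"}
    classes = set(d.metadata["cell_class"])
    if beds:
        return "zonated"
    if classes == {"nonbrain_ec"}:
        return "nonbrain_array"
    if "other_ec" in classes:
        return "murine_array"
    if "other_brain_cell" in classes:
        return "sc"
    raise ValidationError(f"{d.dataset_id}: cannot infer dataset role from {classes}")


@dataclass
class FunnelResult:
    """Everything a funnel run produces, for auditing and export."""

    records: dict  # tf -> FunnelRecord
    shortlist: list[str]
    summaries: pd.DataFrame
    capillary_summaries: pd.DataFrame
    mi_values: dict
    marker_sets: dict  # set_id -> MarkerSet
    counter_sets: dict
    sens_spec: pd.DataFrame
    module_nes: dict = field(default_factory=dict)  # module_id -> NES frame
    module_memberships: dict = field(default_factory=dict)

    @property
    def stage_counts(self) -> dict:
        """TFs surviving up to and including each stage (forced passes count)."""
        counts = {"input": len(self.records)}
        for k, stage in enumerate(funnel.STAGES):
            allowed = set(funnel.STAGES[: k + 1])
            survivors = 0
            for r in self.records.values():
                verdicts = [v for v in r.verdicts if v["stage"] in allowed]
                if len(verdicts) < k + 1:
                    continue  # never reached this stage
                if all(v["passed"] or v.get("force_included") for v in verdicts):
                    survivors += 1
            counts[stage] = survivors
        counts["final"] = len(self.shortlist)
        return counts


def _prepare_datasets(
    datasets: Sequence[ExpressionDataset],
    ortholog_map: Mapping[str, str] | None,
    count_floors: Mapping[str, int],
) -> dict:
    """Lift-over, gene filtering and normalization per dataset role."""
    roles: dict[str, list[ExpressionDataset]] = {
        "sc": [],
        "murine_array": [],
        "zonated": [],
        "nonbrain_array": [],
    }
    for d in datasets:
        role = classify_dataset(d)
        if d.species == "mouse":
            if ortholog_map is None:
                raise ValidationError(
                    f"{d.dataset_id} is murine but no ortholog map was given"
                )
            d = apply_ortholog_map(d, ortholog_map)
        if d.unit == "raw_counts":
            floor = count_floors.get(d.dataset_id, 10)
            d, _ = preprocess.filter_genes_by_counts(d, min_total_counts=floor)
            d = preprocess.normalize_log(d)
        roles[role].append(d)
    for role in ("sc", "murine_array", "zonated", "nonbrain_array"):
        if not roles[role]:
            raise ValidationError(f"funnel needs at least one {role} dataset")
    return roles


def run_funnel(
    datasets: Sequence[ExpressionDataset],
    regulons: RegulonSet,
    motif_rankings: pd.DataFrame | None,
    recipient_tpm: pd.Series,
    config: RunConfig | None = None,
    ortholog_map: Mapping[str, str] | None = None,
    fetal_expression: Mapping[str, bool] | None = None,
    count_floors: Mapping[str, int] | None = None,
    compute_modules: bool = True,
    n_module_genes: int = 400,
) -> FunnelResult:
    """Run the full candidate-TF funnel over a meta-cohort."""
    config = config or RunConfig()
    roles = _prepare_datasets(datasets, ortholog_map, count_floors or {})
    tie_seed = config.seed

    # --- activity contexts ---
    top = config.auc_top_fraction
    brain_aucs: list[pd.DataFrame] = []
    for d in roles["sc"]:
        brain = d.subset(samples=d.samples_where(cell_class="brain_ec"))
        ctx = activity.build_ranking(brain, "forward", tie_seed)
        am = activity.compute_activity_matrix(ctx, regulons, top)
        brain_aucs.append(am.to_frame())

    murine = roles["murine_array"][0]
    ctx_m = activity.build_ranking(murine, "forward", tie_seed)
    am_m = activity.compute_activity_matrix(ctx_m, regulons, top)
    groups_m = {
        "brain_ec": murine.samples_where(cell_class="brain_ec"),
        "other_ec": murine.samples_where(cell_class="other_ec"),
    }
    mean_m = activity.aggregate_activity(am_m, groups_m, stat="mean")

    nonbrain = roles["nonbrain_array"][0]
    ctx_nb = activity.build_ranking(nonbrain, "reversed", tie_seed)
    am_nb = activity.compute_activity_matrix(ctx_nb, regulons, top)
    median_nb = activity.aggregate_activity(
        am_nb, {"nonbrain_ec": list(nonbrain.sample_ids)}, stat="median"
    )

    zonated = roles["zonated"][0]
    ctx_z = activity.build_ranking(zonated, "forward", tie_seed)
    am_z = activity.compute_activity_matrix(ctx_z, regulons, top)
    beds = zonated.metadata["vascular_bed"].to_numpy()
    cap_samples = zonated.samples_where(vascular_bed="capillary")
    cap_median = activity.aggregate_activity(
        am_z, {"capillary": cap_samples}, stat="median"
    )
    is_cap = np.where(beds == "capillary", "capillary", "other_bed")

    all_tfs = sorted(set(regulons.tfs))
    mi_values: dict[str, float] = {}
    cap_mi: dict[str, float] = {}
    frame_z = am_z.to_frame()
    for tf in frame_z.index:
        auc = frame_z.loc[tf].to_numpy()
        mi_values[tf] = activity.mutual_information(auc, beds, config.mi_n_bins)
        cap_mi[tf] = activity.mutual_information(auc, is_cap, config.mi_n_bins)

    pooled_brain = pd.concat(brain_aucs, axis=1)
    eps = 1e-9
    summaries = pd.DataFrame(
        {
            "median_auc_brain": pooled_brain.quantile(0.5, axis=1),
            "murine_relative_activity": (mean_m["brain_ec"] + eps)
            / (mean_m["other_ec"] + eps),
            "median_auc_nonbrain_reversed": median_nb["nonbrain_ec"],
        }
    )
    capillary_summaries = pd.DataFrame(
        {
            "capillary_median_auc": cap_median["capillary"],
            "capillary_mi": pd.Series(cap_mi),
        }
    ).fillna(0.0)

    # --- modules and motif NES (annotation layer) ---
    module_nes: dict[str, pd.DataFrame] = {}
    module_memberships: dict[str, list[str]] = {}
    if compute_modules and motif_rankings is not None:
        log_vals = np.log1p(murine.values)
        variances = np.var(log_vals, axis=1)
        order = np.argsort(-variances, kind="stable")[:n_module_genes]
        top_idx = sorted(order)
        # correlation work happens on the log scale
        sub = ExpressionDataset(
            murine.dataset_id,
            murine.species,
            [murine.gene_ids[i] for i in top_idx],
            list(murine.sample_ids),
            log_vals[top_idx, :],
            "log_normalized",
            murine.metadata,
        )
        power = coexpression.pick_soft_power(sub, r2_target=config.soft_power_r2_target)
        modules = coexpression.detect_modules(
            sub,
            power,
            min_size=config.min_module_size,
            merge_dissim=config.merge_dissimilarity,
        )
        for mod in modules:
            if mod.module_id == "unassigned":
                continue
            in_universe = [g for g in mod.genes if g in motif_rankings.columns]
            if not in_universe:
                continue
            nes = coexpression.motif_enrichment_nes(
                in_universe,
                motif_rankings,
                top_fraction=top,
                nes_min=config.nes_min,
            )
            module_nes[mod.module_id] = nes
            for tf in nes.index[nes["flagged"]]:
                module_memberships.setdefault(tf, []).append(mod.module_id)

    # --- marker sets ---
    marker_sets, counter_sets = compute_cohort_marker_sets(roles, config)

    # --- the staged funnel ---
    records = {tf: funnel.FunnelRecord(tf) for tf in all_tfs}
    candidates = funnel.initial_candidate_screen(summaries, config, records)
    scores = funnel.score_tf_sens_spec(regulons, marker_sets, counter_sets)
    candidates = funnel.apply_sens_spec_mi_filter(
        scores, mi_values, config, records, candidates
    )
    candidates = funnel.recipient_expression_filter(
        candidates, recipient_tpm, config, records
    )
    shortlist = funnel.capillary_and_context_filter(
        candidates,
        capillary_summaries,
        config,
        records,
        module_memberships=module_memberships,
        fetal_expression=fetal_expression,
    )
    return FunnelResult(
        records=records,
        shortlist=shortlist,
        summaries=summaries,
        capillary_summaries=capillary_summaries,
        mi_values=mi_values,
        marker_sets=marker_sets,
        counter_sets=counter_sets,
        sens_spec=scores,
        module_nes=module_nes,
        module_memberships=module_memberships,
    )


def compute_cohort_marker_sets(
    roles: Mapping[str, Sequence[ExpressionDataset]],
    config: RunConfig,
) -> tuple[dict[str, MarkerSet], dict[str, frozenset[str]]]:
    """Marker tables and the four marker sets (plus counter sets) for a
    prepared cohort (see ``_prepare_datasets`` for the role layout)."""
    murine = roles["murine_array"][0]
    nonbrain = roles["nonbrain_array"][0]
    zonated = roles["zonated"][0]
    murine_table = markers.de_wilcoxon(
        murine,
        murine.metadata["cell_class"].tolist(),
        min_pct=config.de_min_pct,
        fc_threshold=config.de_fc_threshold,
    )
    sc_tables = {}
    for d in roles["sc"]:
        sc_tables[d.dataset_id] = markers.de_wilcoxon(
            d,
            d.metadata["cell_class"].tolist(),
            min_pct=config.de_min_pct,
            fc_threshold=config.de_fc_threshold,
        )
    beds = zonated.metadata["vascular_bed"].to_numpy()
    zon_cap_large = zonated.subset(
        samples=[
            s for s, b in zip(zonated.sample_ids, beds) if b in ("capillary", "large")
        ]
    )
    zonated_table = markers.de_wilcoxon(
        zon_cap_large,
        zon_cap_large.metadata["vascular_bed"].tolist(),
        min_pct=config.de_min_pct,
        fc_threshold=1.0,
    )
    brain_summary = _linear_frame(murine, murine.samples_where(cell_class="brain_ec"))
    nonbrain_summary = _linear_frame(nonbrain, list(nonbrain.sample_ids))
    marker_sets = markers.build_marker_sets(
        murine_table,
        sc_tables,
        zonated_table,
        brain_summary,
        nonbrain_summary,
        fold_strict=config.marker_fold_strict,
        fold_lenient=config.marker_fold_lenient,
        percentile_q=config.percentile_q,
        percentile_fold_strict=config.percentile_fold_strict,
        percentile_fold_lenient=config.percentile_fold_lenient,
        set3_mode=config.set3_mode,
    )
    counter_sets = build_counter_sets(
        murine_table,
        sc_tables,
        fold_lenient=config.marker_fold_lenient,
        fold_strict=config.marker_fold_strict,
    )
    return marker_sets, counter_sets


def prepare_cohort(
    datasets: Sequence[ExpressionDataset],
    ortholog_map: Mapping[str, str] | None = None,
    count_floors: Mapping[str, int] | None = None,
) -> dict:
    """Public wrapper around the lift-over / filter / normalize step."""
    return _prepare_datasets(datasets, ortholog_map, count_floors or {})


def _linear_frame(d: ExpressionDataset, samples: list[str]) -> pd.DataFrame:
    values = d.values
    if d.unit == "log_normalized":
        values = np.expm1(values)
    si = {s: i for i, s in enumerate(d.sample_ids)}
    cols = [si[s] for s in samples]
    return pd.DataFrame(values[:, cols], index=d.gene_ids, columns=samples)


def build_counter_sets(
    murine_table: pd.DataFrame,
    sc_tables: Mapping[str, pd.DataFrame],
    fold_lenient: float = 2.0,
    fold_strict: float = 4.0,
    p_max: float = 0.05,
) -> dict[str, frozenset[str]]:
    """Markers of the flipped contrasts: non-brain ECs and other brain cells.

    These are the genes a brain-EC-specific TF should NOT regulate; the
    specificity score counts a TF's marker-overlapping targets against
    them.
    """
    out: dict[str, frozenset[str]] = {}
    other_ec = murine_table[murine_table["group"] == "other_ec"]
    sel = (other_ec["log2_fold_change"] >= np.log2(fold_lenient)) & (
        other_ec["p_value"] < p_max
    )
    out["counter_other_ec"] = frozenset(other_ec.loc[sel, "gene"])
    counter_sc: set[str] = set()
    for t in sc_tables.values():
        rows = t[t["group"] == "other_brain_cell"]
        sel = (rows["log2_fold_change"] >= np.log2(fold_strict)) & (
            rows["p_value"] < p_max
        )
        counter_sc |= set(rows.loc[sel, "gene"])
    out["counter_other_brain"] = frozenset(counter_sc)
    return out


# --------------------------------------------------------------------------
# screen analysis
# --------------------------------------------------------------------------

@dataclass
class ScreenResult:
    genotype_assignment: screen.GenotypeAssignment
    cell_ids: list[str]  # cells surviving QC, aligned with cluster_labels
    cluster_labels: np.ndarray
    cluster_marker_table: pd.DataFrame
    proportion_tests: pd.DataFrame


def run_screen(
    counts: ExpressionDataset,
    barcode_umis: pd.DataFrame,
    config: RunConfig | None = None,
) -> ScreenResult:
    """Genotype deconvolution, clustering, markers and proportion tests."""
    config = config or RunConfig()
    assignment = screen.assign_genotypes(
        barcode_umis,
        min_umis=config.genotype_min_umis,
        dominance_fraction=config.genotype_dominance_fraction,
        max_multiplicity=config.genotype_max_multiplicity,
    )
    qc, _ = preprocess.qc_filter_cells(counts, min_genes=200, min_cells_per_gene=3)
    normalized = preprocess.normalize_log(qc)
    labels = screen.cluster_cells(
        normalized,
        n_pcs_computed=config.n_pcs_computed,
        n_pcs_used=config.n_pcs_used,
        k_neighbors=config.k_neighbors,
        resolution=config.clustering_resolution,
        seed=config.seed,
        n_hvg=config.n_hvg,
        scale_clip=config.scale_clip,
    )
    marker_table = screen.cluster_markers(
        normalized,
        labels,
        min_pct=config.screen_min_pct,
        logfc_min=config.screen_logfc_min,
        p_max=config.screen_p_max,
    )
    geno_by_cell = dict(zip(assignment.cell_ids, assignment.genotypes))
    kept_genotypes = [geno_by_cell.get(c, frozenset()) for c in normalized.sample_ids]
    tests = screen.proportion_permutation_test(
        labels,
        kept_genotypes,
        n_permutations=config.permutations,
        log2fd_threshold=config.log2fd_threshold,
        alpha=config.proportion_alpha,
        seed=config.seed,
        min_cells=config.min_cells_per_genotype,
    )
    return ScreenResult(assignment, list(normalized.sample_ids), labels, marker_table, tests)
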
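"""The staged candidate-TF funnel with a complete audit trail.

Stage 1 screens regulons on activity summaries (brain-EC median AUC and
murine brain-vs-other relative activity).  Stage 2 scores each surviving
TF's sensitivity (fraction of a brain-EC marker set inside its regulon)
and specificity (fraction of its marker-overlapping targets that are
brain-EC rather than counter markers) and applies the sensitivity >
0.1 / specificity > 0.8 / MI > -1.3 filter.  Stage 3 drops TFs already
expressed in the recipient cells (TPM >= 2), with a force-include list.
Stage 4 keeps TFs with capillary median AUC > 0.08 and capillary MI >
0.05 and ranks the survivors.  Every per-TF decision, with the exact
threshold applied, is kept in a FunnelRecord that can be replayed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .activity import transformed_mi
from .config import RunConfig
from .types import MarkerSet, RegulonSet, ValidationError

log = logging.getLogger(__name__)

STAGES = (
    "initial_screen",
    "sens_spec_mi",
    "recipient_expression",
    "capillary_context",
)


@dataclass
class FunnelRecord:
    """Per-TF ledger of every score and verdict through the funnel."""

    tf: str
    inputs: dict = field(default_factory=dict)
    verdicts: list[dict] = field(default_factory=list)
    final_status: str = "pending"
    rank: int | None = None

    def record(self, stage: str, passed: bool, thresholds: dict, **extra) -> None:
        self.verdicts.append(
            {"stage": stage, "passed": bool(passed), "thresholds": thresholds, **extra}
        )
        if not passed and self.final_status == "pending":
            self.final_status = f"dropped_at_{stage}"

    def to_dict(self) -> dict:
        return {
            "tf": self.tf,
            "inputs": self.inputs,
            "verdicts": self.verdicts,
            "final_status": self.final_status,
            "rank": self.rank,
        }


def replay_record(record: FunnelRecord) -> str:
    """Recompute a record's final status from its stored verdicts.

    A retained TF passed every stage or carries a force-include verdict;
    otherwise the status names the first failed stage.
    """
    status = "pending"
    for v in record.verdicts:
        if v.get("force_included") and not v["passed"]:
            continue  # overridden failure
        if not v["passed"] and status == "pending":
            status = f"dropped_at_{v['stage']}"
    if status == "pending":
        status = (
            "force_included"
            if any(v.get("force_included") for v in record.verdicts)
            else "retained"
        )
    return status


# --------------------------------------------------------------------------
# stage 1: initial activity screen
# --------------------------------------------------------------------------

def initial_candidate_screen(
    summaries: pd.DataFrame,
    config: RunConfig,
    records: Mapping[str, FunnelRecord],
) -> list[str]:
    """Permissive first cut on activity summaries.

    ``summaries`` is a TF-indexed frame with columns
    ``median_auc_brain`` and ``murine_relative_activity`` (brain mean AUC
    over other-EC mean AUC).  Floors default to 0 and 1 — the published
    funnel reports a large initial list without stating its cutoffs, so
    stage 1 errs toward recall.
    """
    retained = []
    thresholds = {
        "brain_auc_floor": config.brain_auc_floor,
        "murine_relative_activity_floor": config.murine_relative_activity_floor,
    }
    for tf, rec in records.items():
        if tf not in summaries.index:
            log.info("TF %s has no activity summary; dropped", tf)
            rec.record("initial_screen", False, thresholds, reason="no_activity_entry")
            continue
        row = summaries.loc[tf]
        rec.inputs["median_auc_brain"] = float(row["median_auc_brain"])
        rec.inputs["murine_relative_activity"] = float(row["murine_relative_activity"])
        passed = (
            row["median_auc_brain"] > config.brain_auc_floor
            and row["murine_relative_activity"] > config.murine_relative_activity_floor
        )
        rec.record("initial_screen", passed, thresholds)
        if passed:
            retained.append(tf)
    return retained


# --------------------------------------------------------------------------
# stage 2: sensitivity / specificity / MI
# --------------------------------------------------------------------------

def score_tf_sens_spec(
    regulons: RegulonSet,
    marker_sets: Mapping[str, MarkerSet],
    counter_marker_sets: Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """Per-TF sensitivity per marker set and overall specificity.

    sensitivity(T, S) = |targets(T) ∩ S| / |S|.
    specificity(T) = |targets(T) ∩ B| / |targets(T) ∩ (B ∪ C)| with B the
    union of brain marker sets and C the union of counter-marker sets;
    NaN (treated downstream as a fail) when the denominator is empty.
    """
    for sid, ms in marker_sets.items():
        if not ms.genes:
            raise ValidationError(f"marker set {sid} is empty")
    brain_union = frozenset().union(*(ms.genes for ms in marker_sets.values()))
    counter_union = (
        frozenset().union(*counter_marker_sets.values())
        if counter_marker_sets
        else frozenset()
    )
    rows = []
    for reg in regulons:
        targets = reg.targets
        row: dict = {"tf": reg.tf}
        for sid, ms in marker_sets.items():
            row[f"sensitivity_{sid}"] = len(targets & ms.genes) / len(ms.genes)
        n_brain = len(targets & brain_union)
        n_any = len(targets & (brain_union | counter_union))
        row["specificity"] = n_brain / n_any if n_any else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("tf")


def apply_sens_spec_mi_filter(
    scores: pd.DataFrame,
    mi_values: Mapping[str, float],
    config: RunConfig,
    records: Mapping[str, FunnelRecord],
    candidates: Sequence[str],
) -> list[str]:
    """Retain TFs passing the sensitivity / specificity / MI floors.

    Sensitivity must exceed ``sensitivity_min`` for at least one marker
    set (``sensitivity_mode="any"``, the default) or for every set
    (``"all"``); specificity must exceed ``specificity_min`` strictly;
    the zonation MI enters as ``log10(MI + eps)`` and must exceed
    ``mi_min``.
    """
    sens_cols = [c for c in scores.columns if c.startswith("sensitivity_")]
    thresholds = {
        "sensitivity_min": config.sensitivity_min,
        "specificity_min": config.specificity_min,
        "mi_min": config.mi_min,
        "mi_epsilon": config.mi_epsilon,
        "sensitivity_mode": config.sensitivity_mode,
    }
    retained = []
    for tf in candidates:
        rec = records[tf]
        row = scores.loc[tf]
        sens = {c: float(row[c]) for c in sens_cols}
        spec = float(row["specificity"])
        raw_mi = float(mi_values.get(tf, 0.0))
        tmi = transformed_mi(raw_mi, config.mi_epsilon)
        rec.inputs.update(
            {**sens, "specificity": spec, "mi_zonation": raw_mi, "mi_transformed": tmi}
        )
        passes = [v > config.sensitivity_min for v in sens.values()]
        sens_ok = all(passes) if config.sensitivity_mode == "all" else any(passes)
        spec_ok = (not math.isnan(spec)) and spec > config.specificity_min
        mi_ok = tmi > config.mi_min
        passed = sens_ok and spec_ok and mi_ok
        rec.record(
            "sens_spec_mi",
            passed,
            thresholds,
            sensitivity_ok=sens_ok,
            specificity_ok=spec_ok,
            mi_ok=mi_ok,
        )
        if passed:
            retained.append(tf)
    return retained


# --------------------------------------------------------------------------
# stage 3: recipient expression
# --------------------------------------------------------------------------

def recipient_expression_filter(
    tfs: Sequence[str],
    recipient_tpm: pd.Series,
    config: RunConfig,
    records: Mapping[str, FunnelRecord],
) -> list[str]:
    """Keep TFs silent in the recipient cells (TPM < ``tpm_max``).

    A TF absent from the table is taken as not expressed (TPM 0, with a
    warning).  Members of ``force_include`` are retained regardless and
    marked as such.
    """
    thresholds = {"tpm_max": config.tpm_max, "force_include": list(config.force_include)}
    retained = []
    for tf in tfs:
        rec = records[tf]
        if tf in recipient_tpm.index:
            tpm = float(recipient_tpm.loc[tf])
        else:
            tpm = 0.0
            log.warning("TF %s missing from recipient TPM table; assuming 0", tf)
        rec.inputs["recipient_tpm"] = tpm
        passed = tpm < config.tpm_max
        forced = (not passed) and tf in config.force_include
        rec.record(
            "recipient_expression", passed, thresholds, force_included=forced
        )
        if forced:
            rec.final_status = "pending"  # the failure is overridden
        if passed or forced:
            retained.append(tf)
    return retained


# --------------------------------------------------------------------------
# stage 4: capillary activity and context
# --------------------------------------------------------------------------

def capillary_and_context_filter(
    tfs: Sequence[str],
    capillary_summaries: pd.DataFrame,
    config: RunConfig,
    records: Mapping[str, FunnelRecord],
    module_memberships: Mapping[str, Sequence[str]] | None = None,
    fetal_expression: Mapping[str, bool] | None = None,
) -> list[str]:
    """Final filter and ranking on capillary-bed activity.

    ``capillary_summaries``: TF-indexed frame with
    ``capillary_median_auc`` and ``capillary_mi``.  Retains TFs with
    capillary median AUC strictly above ``capillary_auc_min`` and
    capillary MI strictly above ``capillary_mi_min``.  Module
    membership (count of modules in which the TF's NES was flagged) and
    a fetal-expression annotation are soft boosts by default —
    configurable hard filters — since the published final step mixed
    quantitative and judgment criteria.  Survivors are ranked by
    descending capillary AUC, then best sensitivity, then module count.
    """
    module_memberships = module_memberships or {}
    fetal_expression = fetal_expression or {}
    thresholds = {
        "capillary_auc_min": config.capillary_auc_min,
        "capillary_mi_min": config.capillary_mi_min,
        "module_filter_hard": config.module_filter_hard,
        "fetal_filter_hard": config.fetal_filter_hard,
    }
    survivors = []
    for tf in tfs:
        rec = records[tf]
        if tf in capillary_summaries.index:
            cap_auc = float(capillary_summaries.loc[tf, "capillary_median_auc"])
            cap_mi = float(capillary_summaries.loc[tf, "capillary_mi"])
        else:
            cap_auc, cap_mi = 0.0, 0.0
        modules = sorted(module_memberships.get(tf, []))
        fetal = bool(fetal_expression.get(tf, False))
        rec.inputs.update(
            {
                "capillary_median_auc": cap_auc,
                "capillary_mi": cap_mi,
                "module_memberships": modules,
                "fetal_expression_flag": fetal,
            }
        )
        passed = cap_auc > config.capillary_auc_min and cap_mi > config.capillary_mi_min
        if config.module_filter_hard:
            passed = passed and bool(modules)
        if config.fetal_filter_hard:
            passed = passed and fetal
        rec.record("capillary_context", passed, thresholds)
        if passed:
            survivors.append(tf)

    def sort_key(tf: str):
        rec = records[tf]
        sens = max(
            (v for k, v in rec.inputs.items() if k.startswith("sensitivity_")),
            default=0.0,
        )
        return (
            -rec.inputs.get("capillary_median_auc", 0.0),
            -sens,
            -len(rec.inputs.get("module_memberships", [])),
            tf,
        )

    ranked = sorted(survivors, key=sort_key)
    for i, tf in enumerate(ranked, start=1):
        records[tf].rank = i
        if records[tf].final_status == "pending":
            forced = any(v.get("force_included") for v in records[tf].verdicts)
            records[tf].final_status = "force_included" if forced else "retained"
    return ranked
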
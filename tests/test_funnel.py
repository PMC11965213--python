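"""Sensitivity/specificity scoring and the staged funnel's verdict logic."""

import math

import numpy as np
import pandas as pd
import pytest

from bmecfate.config import RunConfig
from bmecfate.funnel import (
    FunnelRecord,
    apply_sens_spec_mi_filter,
    capillary_and_context_filter,
    initial_candidate_screen,
    recipient_expression_filter,
    replay_record,
    score_tf_sens_spec,
)
from bmecfate.types import MarkerSet, Regulon, RegulonSet, ValidationError


def _marker_sets(sets: dict) -> dict:
    return {
        sid: MarkerSet(sid, frozenset(genes), {}) for sid, genes in sets.items()
    }


class TestSensSpec:
    def test_full_coverage_gives_sensitivity_one(self):
        genes = {f"m{i}" for i in range(8)}
        regs = RegulonSet([Regulon("TF", frozenset(genes | {"x"}))])
        scores = score_tf_sens_spec(regs, _marker_sets({"set1": genes}), {})
        assert scores.loc["TF", "sensitivity_set1"] == pytest.approx(1.0)

    def test_partial_coverage_arithmetic(self):
        markers = {f"m{i}" for i in range(32)}
        hit = {f"m{i}" for i in range(4)}
        regs = RegulonSet([Regulon("TF", frozenset(hit | {"x", "y"}))])
        scores = score_tf_sens_spec(regs, _marker_sets({"set2": markers}), {})
        assert scores.loc["TF", "sensitivity_set2"] == pytest.approx(0.125)

    def test_specificity_counts_counter_marker_hits(self):
        brain = {"b1", "b2", "b3"}
        counter = {"c1", "c2"}
        regs = RegulonSet([Regulon("TF", frozenset({"b1", "b2", "c1", "z"}))])
        scores = score_tf_sens_spec(
            regs, _marker_sets({"set1": brain}), {"ctr": frozenset(counter)}
        )
        assert scores.loc["TF", "specificity"] == pytest.approx(2 / 3)

    def test_no_marker_overlap_gives_nan_specificity(self):
        regs = RegulonSet([Regulon("TF", frozenset({"z1", "z2"}))])
        scores = score_tf_sens_spec(regs, _marker_sets({"set1": {"b1"}}), {})
        assert math.isnan(scores.loc["TF", "specificity"])

    def test_matches_exhaustive_set_intersections(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(200)]
        sets = {
            "set1": set(rng.choice(universe, 20, replace=False)),
            "set2": set(rng.choice(universe, 40, replace=False)),
        }
        counter = {"ctr": frozenset(rng.choice(universe, 30, replace=False))}
        regs = RegulonSet(
            [
                Regulon(f"TF{k}", frozenset(rng.choice(universe, 25, replace=False)))
                for k in range(20)
            ]
        )
        scores = score_tf_sens_spec(regs, _marker_sets(sets), counter)
        brain_union = sets["set1"] | sets["set2"]
        for reg in regs:
            for sid, s in sets.items():
                assert scores.loc[reg.tf, f"sensitivity_{sid}"] == pytest.approx(
                    len(reg.targets & s) / len(s)
                )
            n_b = len(reg.targets & brain_union)
            n_all = len(reg.targets & (brain_union | counter["ctr"]))
            if n_all:
                assert scores.loc[reg.tf, "specificity"] == pytest.approx(n_b / n_all)

    def test_empty_marker_set_is_error(self):
        regs = RegulonSet([Regulon("TF", frozenset({"a"}))])
        with pytest.raises(ValidationError, match="empty"):
            score_tf_sens_spec(regs, _marker_sets({"set1": set()}), {})


class TestStageFilters:
    def _records(self, tfs):
        return {tf: FunnelRecord(tf) for tf in tfs}

    def test_initial_screen_predicates(self):
        summaries = pd.DataFrame(
            {
                "median_auc_brain": [0.2, 0.0, 0.3],
                "murine_relative_activity": [1.5, 1.5, 0.5],
            },
            index=["brainy", "silent", "peripheral"],
        )
        records = self._records(["brainy", "silent", "peripheral", "absent"])
        out = initial_candidate_screen(summaries, RunConfig(), records)
        assert out == ["brainy"]
        assert records["absent"].final_status == "dropped_at_initial_screen"

    def test_sens_spec_mi_filter_thresholds(self):
        scores = pd.DataFrame(
            {
                "sensitivity_set1": [0.15, 0.15, 0.15],
                "specificity": [0.85, 0.8, 0.85],
            },
            index=["keep", "boundary_spec", "low_mi"],
        )
        mi = {"keep": 0.1, "boundary_spec": 0.1, "low_mi": 0.0}
        records = self._records(scores.index)
        out = apply_sens_spec_mi_filter(
            scores, mi, RunConfig(), records, list(scores.index)
        )
        # transformed MI of 0.1 is log10(0.1) = -1 > -1.3; of 0 is -6
        assert out == ["keep"]
        # specificity of exactly 0.8 fails the strict inequality
        assert records["boundary_spec"].final_status == "dropped_at_sens_spec_mi"

    def test_retained_example_from_stated_thresholds(self):
        scores = pd.DataFrame(
            {"sensitivity_set1": [0.15], "specificity": [0.85]}, index=["tf"]
        )
        # transformed MI of -1.0 corresponds to raw MI of 0.1
        records = self._records(["tf"])
        out = apply_sens_spec_mi_filter(scores, {"tf": 0.1}, RunConfig(), records, ["tf"])
        assert out == ["tf"]

    def test_recipient_filter_drops_expressed_tfs(self):
        tpm = pd.Series({"hot": 5.0, "cold": 0.5})
        records = self._records(["hot", "cold"])
        out = recipient_expression_filter(["hot", "cold"], tpm, RunConfig(), records)
        assert out == ["cold"]

    def test_force_include_overrides_tpm(self):
        tpm = pd.Series({"ZIC3": 5.0})
        records = self._records(["ZIC3"])
        out = recipient_expression_filter(["ZIC3"], tpm, RunConfig(), records)
        assert out == ["ZIC3"]
        verdict = records["ZIC3"].verdicts[-1]
        assert verdict["force_included"] and not verdict["passed"]

    def test_missing_tf_treated_as_unexpressed(self, caplog):
        records = self._records(["ghost"])
        with caplog.at_level("WARNING"):
            out = recipient_expression_filter(
                ["ghost"], pd.Series(dtype=float), RunConfig(), records
            )
        assert out == ["ghost"]

    def test_mixed_fixture_equals_threshold_scan_plus_force_union(self):
        rng = np.random.default_rng(8)
        tfs = [f"T{i}" for i in range(30)]
        tpm = pd.Series(rng.uniform(0, 6, 30), index=tfs)
        cfg = RunConfig(force_include=["T3", "T4"])
        records = self._records(tfs)
        out = recipient_expression_filter(tfs, tpm, cfg, records)
        expected = [t for t in tfs if tpm[t] < 2.0 or t in ("T3", "T4")]
        assert out == expected

    def test_capillary_filter_boundaries(self):
        caps = pd.DataFrame(
            {
                "capillary_median_auc": [0.10, 0.08, 0.10],
                "capillary_mi": [0.06, 0.06, 0.04],
            },
            index=["keep", "auc_boundary", "low_mi"],
        )
        records = self._records(caps.index)
        out = capillary_and_context_filter(list(caps.index), caps, RunConfig(), records)
        assert out == ["keep"]
        assert records["auc_boundary"].final_status == "dropped_at_capillary_context"

    def test_ranking_orders_by_capillary_auc_then_sensitivity(self):
        caps = pd.DataFrame(
            {
                "capillary_median_auc": [0.2, 0.3, 0.2],
                "capillary_mi": [0.1, 0.1, 0.1],
            },
            index=["midA", "top", "midB"],
        )
        records = self._records(caps.index)
        records["midA"].inputs["sensitivity_set1"] = 0.5
        records["midB"].inputs["sensitivity_set1"] = 0.2
        out = capillary_and_context_filter(list(caps.index), caps, RunConfig(), records)
        assert out == ["top", "midA", "midB"]
        assert records["top"].rank == 1


class TestReplayAndMonotonicity:
    def test_replay_reproduces_final_status(self, default_cohort, default_rankings):
        from bmecfate.pipeline import run_funnel

        datasets, truth = default_cohort
        result = run_funnel(
            datasets,
            truth.regulons,
            default_rankings,
            truth.recipient_tpm,
            RunConfig(seed=1),
            ortholog_map=truth.ortholog_map,
            compute_modules=False,
        )
        for tf, rec in result.records.items():
            assert replay_record(rec) == rec.final_status

    def test_relaxing_a_threshold_never_removes_a_retained_tf(
        self, default_cohort, default_rankings
    ):
        from bmecfate.pipeline import run_funnel

        datasets, truth = default_cohort
        strict = RunConfig(seed=1)
        relaxed = strict.replace(sensitivity_min=0.05, capillary_auc_min=0.04)
        kw = dict(
            ortholog_map=truth.ortholog_map,
            compute_modules=False,
        )
        a = run_funnel(
            datasets, truth.regulons, default_rankings, truth.recipient_tpm, strict, **kw
        )
        b = run_funnel(
            datasets, truth.regulons, default_rankings, truth.recipient_tpm, relaxed, **kw
        )
        assert set(a.shortlist) <= set(b.shortlist)
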
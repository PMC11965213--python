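"""Wilcoxon DE gates, the percentile cross filter, and marker-set logic."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from bmecfate.markers import (
    build_marker_sets,
    de_wilcoxon,
    group_fold_change,
    percentile_cross_filter,
)
from bmecfate.types import ValidationError
from conftest import make_dataset


class TestDeWilcoxon:
    def test_low_pct_gene_not_tested(self):
        rng = np.random.default_rng(0)
        values = np.zeros((2, 40))
        # gene0 detected in 10% of both sides; gene1 strongly DE
        values[0, [0, 1, 20, 21]] = 5.0
        values[1, :20] = 5.0 + rng.random(20)
        d = make_dataset(values, unit="log_normalized")
        labels = ["a"] * 20 + ["b"] * 20
        table = de_wilcoxon(d, labels, min_pct=0.25)
        assert "g0" not in set(table["gene"])
        assert "g1" in set(table["gene"])

    def test_identical_distributions_fail_fold_gate(self):
        pattern = np.concatenate([np.linspace(1, 2, 20), np.linspace(1, 2, 20)])
        values = np.tile(pattern, (3, 1))  # both groups see the same values
        d = make_dataset(values, unit="log_normalized")
        table = de_wilcoxon(d, ["a"] * 20 + ["b"] * 20, fc_threshold=1.2)
        assert table.empty

    def test_pvalues_match_scipy_on_two_group_fixture(self):
        rng = np.random.default_rng(1)
        values = rng.random((15, 40)) * 3
        values[:5, :20] += 1.0
        d = make_dataset(values, unit="log_normalized")
        labels = np.array(["a"] * 20 + ["b"] * 20)
        table = de_wilcoxon(d, labels, min_pct=0.0, fc_threshold=1.0)
        sub = table[table["group"] == "a"].set_index("gene")
        for gene in sub.index:
            i = d.gene_ids.index(gene)
            ref = scipy.stats.mannwhitneyu(
                values[i, :20], values[i, 20:], alternative="two-sided",
                method="asymptotic", use_continuity=False,
            )
            assert sub.loc[gene, "p_value"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_u_statistic_matches_exhaustive_pairwise_count(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 6, size=40).astype(float)  # many ties
        in_group = np.zeros(40, dtype=bool)
        in_group[:18] = True
        from bmecfate.markers import _ranksum_pvalues

        _, u = _ranksum_pvalues(x[None, :], in_group)
        brute = sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in x[in_group]
            for b in x[~in_group]
        )
        assert u[0] == pytest.approx(brute, abs=1e-9)

    def test_small_group_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        d = make_dataset(rng.random((5, 10)), unit="log_normalized")
        labels = ["a"] * 8 + ["b"] * 2
        with caplog.at_level("WARNING"):
            table = de_wilcoxon(d, labels)
        assert "b" not in set(table["group"])


class TestPercentileFilter:
    def _frames(self, brain, nonbrain):
        genes = [f"g{i}" for i in range(len(brain))]
        return (
            pd.DataFrame(np.asarray(brain), index=genes),
            pd.DataFrame(np.asarray(nonbrain), index=genes),
        )

    def test_silent_in_nonbrain_always_passes(self):
        brain, nonbrain = self._frames([[10, 12, 8]], [[0, 0, 0]])
        out = percentile_cross_filter(brain, nonbrain, max_fold=1.01)
        assert bool(out.iloc[0])

    def test_pass_set_equals_direct_inequality(self):
        rng = np.random.default_rng(4)
        brain = rng.random((10, 6)) * 20
        nonbrain = rng.random((10, 8)) * 40
        bf, nf = self._frames(brain, nonbrain)
        out = percentile_cross_filter(bf, nf, q=0.9, max_fold=7.0)
        for i in range(10):
            expected = (np.quantile(nonbrain[i], 0.9) + 1) / (brain[i].mean() + 1) < 7.0
            assert bool(out.iloc[i]) == expected

    def test_gene_absent_from_one_summary_fails(self):
        brain = pd.DataFrame([[1.0]], index=["gA"])
        nonbrain = pd.DataFrame([[1.0]], index=["gB"])
        out = percentile_cross_filter(brain, nonbrain)
        assert not out.loc["gA"] and not out.loc["gB"]


class TestGroupFoldChange:
    def test_additive_pseudocount_fold(self):
        d = make_dataset([[9.0, 9.0, 4.0, 4.0]], unit="tpm")
        fold = group_fold_change(d, ["s0", "s1"], ["s2", "s3"])
        assert fold.iloc[0] == pytest.approx(10.0 / 5.0)


def _marker_inputs():
    """Hand-built tables with one dominant marker and assorted decoys."""

    def table(rows, dataset_id):
        return pd.DataFrame(
            rows,
            columns=["gene", "group", "log2_fold_change", "p_value",
                     "pct_in_group", "pct_out_group", "dataset_id"],
        )

    lf = np.log2
    murine = pd.DataFrame(
        {
            "gene": ["hero", "weak", "flat", "caponly"],
            "group": "brain_ec",
            "log2_fold_change": [lf(5.0), lf(2.5), 0.1, lf(4.5)],
            "p_value": [1e-6, 1e-4, 0.8, 1e-5],
            "pct_in_group": 1.0,
            "pct_out_group": 0.2,
            "dataset_id": "murine",
        }
    )
    sc = pd.DataFrame(
        {
            "gene": ["hero", "weak", "flat", "caponly"],
            "group": "brain_ec",
            "log2_fold_change": [lf(6.0), lf(4.2), lf(4.1), lf(5.0)],
            "p_value": [1e-8, 1e-6, 1e-6, 1e-6],
            "pct_in_group": 1.0,
            "pct_out_group": 0.1,
            "dataset_id": "sc1",
        }
    )
    zonated = pd.DataFrame(
        {
            "gene": ["hero", "weak", "caponly", "flat"],
            "group": "capillary",
            "log2_fold_change": [1.2, -0.4, 2.0, 0.0],
            "p_value": [1e-4, 0.3, 1e-5, 0.9],
            "pct_in_group": 1.0,
            "pct_out_group": 0.5,
            "dataset_id": "zonated",
        }
    )
    genes = ["hero", "weak", "flat", "caponly"]
    brain_summary = pd.DataFrame(
        np.array([[30.0], [10.0], [5.0], [25.0]]), index=genes
    )
    nonbrain_summary = pd.DataFrame(
        np.array([[0.5], [1.0], [5.0], [0.2]]), index=genes
    )
    return murine, {"sc1": sc}, zonated, brain_summary, nonbrain_summary


class TestBuildMarkerSets:
    def test_dominant_marker_appears_in_all_four_sets(self):
        sets = build_marker_sets(*_marker_inputs())
        for sid in ("set1", "set2", "set3", "set4"):
            assert "hero" in sets[sid].genes

    def test_set4_requires_strictly_positive_capillary_logfc(self):
        sets = build_marker_sets(*_marker_inputs())
        assert "weak" in sets["set2"].genes  # 2.5-fold murine, quiet non-brain
        assert "weak" not in sets["set4"].genes  # capillary logFC < 0

    def test_set1_nested_in_set2(self):
        sets = build_marker_sets(*_marker_inputs())
        assert sets["set1"].genes <= sets["set2"].genes

    def test_members_replay_their_recorded_predicates(self):
        murine, sc, zonated, brain, nonbrain = _marker_inputs()
        sets = build_marker_sets(murine, sc, zonated, brain, nonbrain)
        mb = murine.set_index("gene")
        for sid in ("set1", "set2", "set4"):
            ms = sets[sid]
            for gene in ms.genes:
                fold = 2 ** mb.loc[gene, "log2_fold_change"]
                assert fold >= ms.criteria["murine_min_fold"]
                q = np.quantile(nonbrain.loc[gene], ms.criteria["percentile_q"])
                assert (q + 1) / (brain.loc[gene].mean() + 1) < ms.criteria[
                    "percentile_max_fold"
                ]
        zb = zonated.set_index("gene")
        for gene in sets["set4"].genes:
            assert zb.loc[gene, "log2_fold_change"] > 0

    def test_missing_input_blocks_with_named_error(self):
        murine, sc, zonated, brain, nonbrain = _marker_inputs()
        with pytest.raises(ValidationError, match="sc"):
            build_marker_sets(murine, {}, zonated, brain, nonbrain)
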
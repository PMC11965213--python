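"""Soft power selection, TOM module detection, module scoring and NES."""

import inspect

import numpy as np
import pytest

from bmecfate import coexpression as cx
from bmecfate.types import ValidationError
from conftest import make_dataset


def two_block_dataset(rho_between=0.0, seed=0, n_samples=60, loading=0.95, noise=0.3):
    """Two 40-gene blocks driven by latent factors with a configurable
    between-factor correlation."""
    rng = np.random.default_rng(seed)
    fa = rng.normal(size=n_samples)
    fb = rho_between * fa + np.sqrt(1 - rho_between**2) * rng.normal(size=n_samples)
    block_a = loading * fa[None, :] + noise * rng.normal(size=(40, n_samples))
    block_b = loading * fb[None, :] + noise * rng.normal(size=(40, n_samples))
    genes = [f"a{i}" for i in range(40)] + [f"b{i}" for i in range(40)]
    return make_dataset(
        np.vstack([block_a, block_b]) + 5.0, gene_ids=genes, unit="log_normalized"
    )


class TestSoftPower:
    def test_perfectly_correlated_pair_has_adjacency_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        adj = cx._signed_adjacency(np.vstack([x, 2 * x + 1]), power=1)
        assert adj[0, 1] == pytest.approx(1.0)

    def test_default_sweep_is_one_to_thirty(self):
        sig = inspect.signature(cx.pick_soft_power)
        assert list(sig.parameters["powers"].default) == list(range(1, 31))

    def test_recovers_scale_free_fit_on_hub_network(self):
        # sparse latent-factor loadings yield a hubby, heavy-tailed network
        rng = np.random.default_rng(0)
        n_g, n_s = 150, 60
        hubs = rng.normal(size=(5, n_s))
        load = rng.dirichlet(np.ones(5) * 0.3, size=n_g)
        noise_sd = rng.uniform(0.3, 2.0, n_g)
        values = load @ hubs + noise_sd[:, None] * rng.normal(size=(n_g, n_s))
        d = make_dataset(values + 10, unit="log_normalized")
        power = cx.pick_soft_power(d)
        fit = cx.scale_free_fit(cx._signed_adjacency(d.values, power))
        assert fit >= 0.8

    def test_constant_gene_rows_raise(self):
        d = make_dataset(np.vstack([np.ones(10), np.arange(10)]), unit="log_normalized")
        with pytest.raises(ValidationError, match="constant"):
            cx.pick_soft_power(d)


class TestTom:
    def test_tom_invariants(self):
        rng = np.random.default_rng(2)
        adj = cx._signed_adjacency(rng.normal(size=(30, 40)), power=6)
        tom = cx.topological_overlap(adj)
        assert np.all(tom >= 0) and np.all(tom <= 1)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestDetectModules:
    def test_two_orthogonal_blocks_are_block_pure(self):
        d = two_block_dataset(rho_between=0.0)
        mods = [m for m in cx.detect_modules(d, power=6) if m.module_id != "unassigned"]
        assert len(mods) == 2
        prefixes = sorted("".join(sorted({g[0] for g in m.genes})) for m in mods)
        assert prefixes == ["a", "b"]

    def test_eigengene_dissimilarity_below_threshold_merges(self):
        # factor correlation 0.9 -> eigengene dissimilarity ~0.1 < 0.3
        d = two_block_dataset(rho_between=0.9)
        mods = [m for m in cx.detect_modules(d, power=6) if m.module_id != "unassigned"]
        assert len(mods) == 1
        assert len(mods[0].genes) == 80

    def test_merge_threshold_zero_keeps_blocks_apart(self):
        d = two_block_dataset(rho_between=0.9)
        mods = [
            m
            for m in cx.detect_modules(d, power=6, merge_dissim=0.0)
            if m.module_id != "unassigned"
        ]
        assert len(mods) == 2

    def test_detection_is_deterministic(self):
        d = two_block_dataset(rho_between=0.3, seed=5)
        a = cx.detect_modules(d, power=6)
        b = cx.detect_modules(d, power=6)
        assert [(m.module_id, m.genes) for m in a] == [(m.module_id, m.genes) for m in b]

    def test_tiny_dataset_falls_to_unassigned_pool(self):
        rng = np.random.default_rng(6)
        d = make_dataset(rng.normal(size=(10, 20)) + 5, unit="log_normalized")
        mods = cx.detect_modules(d, power=6, min_size=30)
        assert [m.module_id for m in mods] == ["unassigned"]


class TestModuleActivity:
    def test_module_on_top_has_maximal_score(self):
        rng = np.random.default_rng(7)
        values = rng.random((30, 8))
        values[:6, 0] += 10.0  # sample 0 puts the whole module on top
        d = make_dataset(values, unit="log_normalized")
        scores = cx.score_module_activity(d, [f"g{i}" for i in range(6)])
        assert np.argmax(scores) == 0

    def test_all_gene_module_scores_zero(self):
        rng = np.random.default_rng(8)
        d = make_dataset(rng.random((20, 4)), unit="log_normalized")
        scores = cx.score_module_activity(d, [f"g{i}" for i in range(20)])
        np.testing.assert_array_equal(scores, 0.0)

    def test_matches_brute_force_running_sum(self):
        rng = np.random.default_rng(9)
        values = rng.random((30, 8))
        d = make_dataset(values, unit="log_normalized")
        module = [f"g{i}" for i in [2, 5, 11, 17, 23, 29]]
        got = cx.score_module_activity(d, module, weight=0.25)
        # independent re-implementation, gene by gene
        in_set = np.array([g in set(module) for g in d.gene_ids])
        for j in range(8):
            order = np.argsort(-values[:, j], kind="stable")
            run, p_in, p_out = [], 0.0, 0.0
            w_tot = sum(
                (30 - pos) ** 0.25 for pos, gi in enumerate(order) if in_set[gi]
            )
            n_out = 30 - in_set.sum()
            for pos, gi in enumerate(order):
                if in_set[gi]:
                    p_in += (30 - pos) ** 0.25 / w_tot
                else:
                    p_out += 1.0 / n_out
                run.append(p_in - p_out)
            expected = max(max(run), 0.0) + min(min(run), 0.0)
            assert got[j] == pytest.approx(expected, abs=1e-9)

    def test_insufficient_overlap_raises(self):
        rng = np.random.default_rng(10)
        d = make_dataset(rng.random((30, 4)), unit="log_normalized")
        with pytest.raises(ValidationError, match="overlap"):
            cx.score_module_activity(d, ["g0", "absent1", "absent2"])


class TestMotifNes:
    def _rankings(self, n_tfs=40, n_genes=100, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n_genes)]
        rows = {}
        for t in range(n_tfs):
            rows[f"TF{t}"] = rng.permutation(n_genes) + 1
        return pd.DataFrame.from_dict(rows, orient="index", columns=genes)

    def test_targets_on_top_give_recovery_auc_one(self):
        rankings = self._rankings()
        module = list(rankings.columns[:5])
        # craft TF0 to rank the module genes 1..5
        ranks = np.arange(1, 101)
        rankings.loc["TF0"] = ranks
        out = cx.motif_enrichment_nes(module, rankings, top_fraction=0.2)
        assert out.loc["TF0", "recovery_auc"] == pytest.approx(1.0)

    def test_nes_equals_direct_zscore(self):
        rankings = self._rankings(seed=3)
        module = list(rankings.columns[10:25])
        out = cx.motif_enrichment_nes(module, rankings, top_fraction=0.1)
        aucs = out["recovery_auc"].to_numpy()
        expected = (aucs - aucs.mean()) / aucs.std()
        np.testing.assert_allclose(out["nes"].to_numpy(), expected, atol=1e-12)
        assert out["nes"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["nes"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_flagging_uses_nes_floor_of_three(self):
        rankings = self._rankings(seed=4)
        module = list(rankings.columns[:8])
        rankings.loc["TF0"] = np.arange(1, 101)  # perfect recovery
        out = cx.motif_enrichment_nes(module, rankings)
        assert bool(out.loc["TF0", "flagged"]) == (out.loc["TF0", "nes"] > 3)

    def test_disjoint_module_raises(self):
        rankings = self._rankings()
        with pytest.raises(ValidationError, match="universe"):
            cx.motif_enrichment_nes(["absent"], rankings)
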
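import numpy as np
import pandas as pd
import pytest
from scipy import stats

import varcon
from varcon.data_io import GeneSetCollection

from conftest import make_design, make_norm


def brute_force_f(values, labels):
    """Sums-of-squares one-way ANOVA, computed the long way."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    ssb = sum(
        (labels == g).sum() * (values[labels == g].mean() - grand) ** 2
        for g in np.unique(labels)
    )
    ssw = sum(
        ((values[labels == g] - values[labels == g].mean()) ** 2).sum()
        for g in np.unique(labels)
    )
    dfb = len(np.unique(labels)) - 1
    dfw = len(values) - len(np.unique(labels))
    return (ssb / dfb) / (ssw / dfw)


class TestGeneFstat:
    def test_hand_anova(self):
        norm = make_norm([[1.0, 2.0, 3.0, 4.0]])
        classes = pd.Series(["A", "A", "B", "B"], index=norm.matrix.columns)
        table = varcon.gene_fstat(norm, classes)
        assert table.loc["g0", "f_statistic"] == pytest.approx(8.0)
        assert table.loc["g0", "df_between"] == 1
        assert table.loc["g0", "df_within"] == 2
        assert table.loc["g0", "p_value"] == pytest.approx(stats.f.sf(8.0, 1, 2))

    def test_equal_class_means_f_near_zero(self):
        norm = make_norm([[1.0, 3.0, 1.0, 3.0]])
        classes = pd.Series(["A", "A", "B", "B"], index=norm.matrix.columns)
        table = varcon.gene_fstat(norm, classes)
        assert table.loc["g0", "f_statistic"] == pytest.approx(0.0)

    def test_permutation_within_class_invariant(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(5, 8))
        samples = [f"s{i}" for i in range(8)]
        classes = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
        f1 = varcon.gene_fstat(make_norm(arr, samples=samples), classes)["f_statistic"]
        perm = [1, 0, 3, 2, 7, 6, 5, 4]  # permutes within classes
        f2 = varcon.gene_fstat(
            make_norm(arr[:, perm], samples=[samples[i] for i in perm]), classes
        )["f_statistic"]
        np.testing.assert_allclose(np.sort(f1), np.sort(f2))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(6, 12)
            k = rng.integers(2, 4)
            labels = np.repeat([f"c{j}" for j in range(k)], 3)[:n]
            while len(labels) < n:
                labels = np.append(labels, "c0")
            arr = rng.normal(size=(3, n))
            samples = [f"s{i}" for i in range(n)]
            table = varcon.gene_fstat(
                make_norm(arr, samples=samples), pd.Series(labels, index=samples)
            )
            for g in range(3):
                assert table["f_statistic"].iloc[g] == pytest.approx(
                    brute_force_f(arr[g], labels), abs=1e-10, rel=1e-10
                )

    def test_small_class_rejected(self):
        norm = make_norm([[1.0, 2.0, 3.0]])
        classes = pd.Series(["A", "A", "B"], index=norm.matrix.columns)
        with pytest.raises(ValueError, match="< 2 samples"):
            varcon.gene_fstat(norm, classes)


def anova_table(f_values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(f_values))]
    f = np.asarray(f_values, dtype=float)
    return pd.DataFrame(
        {
            "f_statistic": f,
            "df_between": 1,
            "df_within": 10,
            "p_value": stats.f.sf(f, 1, 10),
        },
        index=genes,
    )


def collection(sets, universe):
    return GeneSetCollection(
        sets={k: list(v) for k, v in sets.items()}, universe=list(universe)
    )


class TestFindCorePathways:
    def test_null_set_not_retained(self):
        rng = np.random.default_rng(2)
        f = rng.chisquare(1, size=200)
        anova = anova_table(f)
        sets = collection({"S": list(anova.index[:50])}, anova.index)
        # in-set genes drawn from the same F distribution as the background
        table = varcon.find_core_pathways(anova, sets, alpha=0.05)
        assert len(table) == 0 or table["adjusted_p"].iloc[0] > 0.05

    def test_enriched_set_retained(self):
        rng = np.random.default_rng(3)
        f = rng.chisquare(1, size=2000)
        f[:100] *= 8.0
        anova = anova_table(f)
        sets = collection({"hot": list(anova.index[:100])}, anova.index)
        table = varcon.find_core_pathways(anova, sets)
        assert list(table["set_name"]) == ["hot"]
        assert table["adjusted_p"].iloc[0] < 0.05

    def test_ranking_by_detected_probe_count(self):
        rng = np.random.default_rng(4)
        f = rng.chisquare(1, size=2000)
        f[:235] *= 20.0
        f[300:493] *= 20.0
        anova = anova_table(f)
        sets = collection(
            {"big": list(anova.index[:235]), "small": list(anova.index[300:493])},
            anova.index,
        )
        table = varcon.find_core_pathways(anova, sets)
        assert list(table["n_detected_probes"]) == [235, 193]
        assert list(table["rank"]) == [1, 2]

    def test_small_set_skipped(self):
        anova = anova_table(np.ones(20))
        sets = collection({"tiny": list(anova.index[:3])}, anova.index)
        table = varcon.find_core_pathways(anova, sets, min_size=5)
        assert len(table) == 0

    def test_null_fdr_control(self):
        """Under a global null, sets are retained at most ~alpha of the time."""
        retained = 0
        n_sim = 100
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            f = rng.chisquare(1, size=300)
            anova = anova_table(f)
            members = list(rng.choice(anova.index, size=40, replace=False))
            sets = collection({"S": members}, anova.index)
            retained += len(varcon.find_core_pathways(anova, sets)) > 0
        assert retained / n_sim <= 0.05 + 0.05  # alpha + Monte-Carlo slack


def block_profiles(n_samples=12, noise=0.01, seed=0):
    """Two anti-correlated blocks of 5 genes each."""
    rng = np.random.default_rng(seed)
    base = np.sin(np.linspace(0, 3 * np.pi, n_samples))
    up = np.tile(base, (5, 1)) + rng.normal(0, noise, (5, n_samples))
    down = np.tile(-base, (5, 1)) + rng.normal(0, noise, (5, n_samples))
    return np.vstack([up, down])


class TestSynexpression:
    def test_single_profile_one_group(self):
        arr = np.tile(np.linspace(0, 1, 8), (6, 1)) + np.random.default_rng(0).normal(
            0, 1e-6, (6, 8)
        )
        norm = make_norm(arr)
        genes = list(norm.matrix.index)
        groups = varcon.synexpression_groups(norm, genes, genes)
        assert len(groups) == 1
        assert sorted(groups[0].members) == sorted(genes)

    def test_anticorrelated_blocks_split_in_two(self):
        norm = make_norm(block_profiles())
        genes = list(norm.matrix.index)
        groups = varcon.synexpression_groups(norm, genes, genes, min_corr=0.85)
        assert len(groups) == 2
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [5, 5]
        for g in groups:
            assert g.mean_within_corr >= 0.85

    def test_impossible_floor_caps_at_max_groups(self):
        rng = np.random.default_rng(5)
        norm = make_norm(rng.normal(size=(20, 10)))
        genes = list(norm.matrix.index)
        groups = varcon.synexpression_groups(norm, genes, genes, min_corr=1.0, max_groups=4)
        assert 1 <= len(groups) <= 4

    def test_under_three_genes_trivial_group(self):
        norm = make_norm(np.random.default_rng(6).normal(size=(5, 6)))
        genes = list(norm.matrix.index)
        groups = varcon.synexpression_groups(norm, genes[:2], genes)
        assert len(groups) == 1 and len(groups[0].members) == 2

    def test_no_eligible_genes_rejected(self):
        norm = make_norm(np.ones((3, 4)))
        with pytest.raises(ValueError):
            varcon.synexpression_groups(norm, ["g0"], ["gX"])


class TestExpand:
    def _setup(self):
        norm = make_norm(block_profiles(seed=1))
        genes = list(norm.matrix.index)
        groups = varcon.synexpression_groups(norm, genes[:5], genes)
        return norm, groups[0]

    def test_identical_gene_included(self):
        norm, group = self._setup()
        expanded = varcon.expand_synexpression(norm, group)
        assert set(group.members) <= set(expanded)

    def test_anticorrelated_gene_excluded(self):
        """Threshold applies to signed r: the mirrored block never enters."""
        norm, group = self._setup()
        expanded = varcon.expand_synexpression(norm, group, corr_threshold=0.8)
        mirrored = {f"g{i}" for i in range(5, 10)}
        assert not (set(expanded) & mirrored)

    def test_threshold_one_returns_members_only(self):
        norm, group = self._setup()
        expanded = varcon.expand_synexpression(norm, group, corr_threshold=1.0)
        assert set(expanded) == set(group.members) or set(expanded) <= set(
            norm.matrix.index[:5]
        )

    def test_lowering_threshold_is_monotone(self):
        norm, group = self._setup()
        prev: set = set()
        for thr in (0.99, 0.9, 0.5, 0.0, -1.0):
            cur = set(varcon.expand_synexpression(norm, group, corr_threshold=thr))
            assert prev <= cur
            prev = cur


class TestRunAttract:
    def test_planted_pathway_recovered_end_to_end(self, disease_dataset):
        cfg, bundle, sets, _ = disease_dataset
        norm = varcon.normalize(bundle, "log2_quantile")
        table, modules = varcon.run_attract(norm, bundle.design["cell_type"], sets)
        assert "shifted" in set(table["set_name"])
        assert "flat" not in set(table["set_name"])
        for groups in modules.values():
            for g in groups:
                assert set(g.members) <= set(g.expanded)
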
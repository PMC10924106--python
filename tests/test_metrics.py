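"""Density/prevalence metrics, correlations, phylogenetic depth,
stepwise selection and habitat comparisons."""

import dendropy
import numpy as np
import pytest

from defensome.metrics import (
    DefensomeProfile,
    density,
    family_prevalence,
    habitat_compare,
    phylo_depth,
    size_correlation,
    stepwise_regression,
)

from oracles import spearman_no_ties, vcv_diagonal_mean


def profile(mag_id, fams_complete, fams_any=None, size=5_000_000, habitat="soil"):
    fams_any = fams_any if fams_any is not None else fams_complete
    return DefensomeProfile(
        mag_id=mag_id, habitat=habitat, size_bp=size,
        n_systems=len(fams_complete), n_systems_any=len(fams_any),
        n_defense_genes=len(fams_any),
        families_complete=frozenset(fams_complete),
        families_any=frozenset(fams_any),
    )


class TestDensity:
    @pytest.mark.parametrize(
        "count,size,expected",
        [(10, 5_000_000, 2e-3), (0, 5_000_000, 0.0), (7, 3_500_000, 2e-3)],
    )
    def test_known_values(self, count, size, expected):
        assert density(count, size) == pytest.approx(expected)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            density(1, 0)


class TestPrevalence:
    def test_fraction_of_mags(self):
        profiles = [profile(f"m{i}", ["RM"]) for i in range(3)] + [
            profile("m3", ["CBASS"])
        ]
        prev = family_prevalence(profiles)
        assert prev["RM"] == pytest.approx(75.0)
        assert prev["CBASS"] == pytest.approx(25.0)

    def test_any_gene_mode_differs(self):
        profiles = [profile("m0", [], fams_any=["RM"]), profile("m1", ["RM"])]
        assert family_prevalence(profiles)["RM"] == pytest.approx(50.0)
        assert family_prevalence(profiles, complete_only=False)["RM"] == pytest.approx(100.0)

    def test_bounds_on_random_cohorts(self):
        rng = np.random.default_rng(0)
        profiles = [
            profile(f"m{i}", rng.choice(["RM", "CBASS", "Gabija"], size=rng.integers(0, 3), replace=False).tolist())
            for i in range(50)
        ]
        assert all(0 <= v <= 100 for v in family_prevalence(profiles).values())


class TestSizeCorrelation:
    def test_monotone_gives_extreme_rho(self):
        sizes = [1e6, 2e6, 3e6, 4e6, 5e6]
        counts = [1, 2, 3, 4, 5]
        rho, p = size_correlation(sizes, counts)
        assert rho == pytest.approx(1.0)
        dens = [c / s for c, s in zip([3] * 5, sizes)]
        rho_d, _ = size_correlation(sizes, dens)
        assert rho_d == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(1)
        sizes = rng.permutation(6).astype(float)  # distinct, no ties
        counts = rng.permutation(6).astype(float)
        rho, _ = size_correlation(sizes, counts)
        assert rho == pytest.approx(spearman_no_ties(sizes, counts), abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = size_correlation([1e6, 2e6, 3e6, 4e6], [2, 2, 2, 2])
        assert np.isnan(rho)


class TestPhyloDepth:
    def test_two_leaf_mean(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.3);", schema="newick")
        assert phylo_depth(tree) == pytest.approx(0.2)

    def test_ultrametric_depth(self):
        tree = dendropy.Tree.get(
            data="((A:0.2,B:0.2):0.3,(C:0.4,D:0.4):0.1);", schema="newick"
        )
        assert phylo_depth(tree) == pytest.approx(0.5)

    def test_unrooted_rejected_without_flag(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.2,C:0.3);", schema="newick")
        with pytest.raises(ValueError, match="unrooted"):
            phylo_depth(tree)
        assert phylo_depth(tree, midpoint_root=True) > 0

    @staticmethod
    def random_tree(rng, n_leaves=10):
        """Random rooted binary tree via recursive newick construction."""

        def build(labels):
            if len(labels) == 1:
                return f"{labels[0]}:{rng.uniform(0.01, 0.5):.6f}"
            k = int(rng.integers(1, len(labels)))
            left, right = labels[:k], labels[k:]
            return (
                f"({build(left)},{build(right)}):{rng.uniform(0.01, 0.5):.6f}"
            )

        labels = [f"t{i}" for i in range(n_leaves)]
        newick = f"({build(labels[: n_leaves // 2])},{build(labels[n_leaves // 2 :])});"
        return dendropy.Tree.get(data=newick, schema="newick")

    @pytest.mark.parametrize("seed", range(5))
    def test_path_sum_equals_vcv_diagonal(self, seed):
        tree = self.random_tree(np.random.default_rng(seed))
        assert phylo_depth(tree) == pytest.approx(vcv_diagonal_mean(tree), abs=1e-9)


class TestStepwise:
    def test_pure_size_signal_selects_size_only(self):
        rng = np.random.default_rng(0)
        n = 60
        size = rng.normal(size=n)
        depth = rng.normal(size=n)
        y = 2.0 * size  # noiseless
        res = stepwise_regression(y, {"size": size, "phylo_depth": depth})
        assert res["selected"] == ["size"]
        assert res["coefficients"]["size"] == pytest.approx(2.0 * size.std(ddof=0), rel=1e-6)

    def test_null_response_selects_nothing_usually(self):
        # under pure noise, AIC keeps the intercept-only model with
        # probability ~ (1 - P(chi2_1 > 2))^2 ~ 0.7 for two candidates
        picks = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=30)
            res = stepwise_regression(
                y, {"size": rng.normal(size=30), "phylo_depth": rng.normal(size=30)}
            )
            if res["selected"] == []:
                picks += 1
        assert 50 <= picks <= 85

    def test_two_strong_signals_select_both(self):
        rng = np.random.default_rng(3)
        n = 100
        size = rng.normal(size=n)
        depth = rng.normal(size=n)
        y = size + depth + rng.normal(scale=0.1, size=n)
        res = stepwise_regression(y, {"size": size, "phylo_depth": depth})
        assert sorted(res["selected"]) == ["phylo_depth", "size"]
        assert all(v > 0 for v in res["partial_r2"].values())

    def test_collinear_predictors_warn(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        with pytest.warns(UserWarning, match="collinear"):
            stepwise_regression(x * 3, {"a": x, "b": x * 1.0000001})


class TestHabitatCompare:
    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0, 1, 20))
        res = habitat_compare({"soil": vals, "marine": vals})
        assert res["tests"][0]["p"] >= 0.99

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        res = habitat_compare({"soil": a, "marine": a + 10})
        assert res["tests"][0]["p"] < 1e-3

    def test_u_statistic_identity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(size=12)
        from scipy.stats import mannwhitneyu

        u1 = mannwhitneyu(a, b, alternative="two-sided").statistic
        u2 = mannwhitneyu(b, a, alternative="two-sided").statistic
        assert u1 + u2 == pytest.approx(len(a) * len(b))

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = habitat_compare(
                {"soil": [1, 2, 3, 4], "marine": [2, 3, 4, 5], "gut": [1.0]}
            )
        assert set(res["groups"]) == {"soil", "marine"}
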
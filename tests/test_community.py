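"""Diversity indices, Bray-Curtis, Domin conversion and marginal PERMANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from firetraits.community import (
    AliasedTermsError,
    CoverTable,
    DOMIN_MIDPOINTS,
    bray_curtis,
    diversity,
    domin_to_cover,
    permanova_marginal,
)
from firetraits.phylo import MissingTaxonError, Phylogeny


def _cover(matrix, index, columns):
    tax = pd.DataFrame(
        {"genus": "g", "family": "f", "functional_group": "x"},
        index=pd.Index(columns, name="species"),
    )
    return CoverTable(
        matrix=pd.DataFrame(matrix, index=index, columns=columns), taxonomy=tax
    )


class TestDomin:
    def test_default_midpoint_of_50_to_75_class(self):
        assert domin_to_cover(8) == 62.5

    def test_absent_species_map_to_zero(self):
        assert domin_to_cover(0) == 0.0
        assert domin_to_cover(float("nan")) == 0.0

    def test_custom_mapping_used_verbatim(self):
        mapping = {1: 3.0, 2: 12.0}
        s = pd.Series([1, 2, 1])
        out = domin_to_cover(s, mapping)
        assert list(out) == [3.0, 12.0, 3.0]

    def test_unmapped_code_named_in_error(self):
        with pytest.raises(ValueError, match="11"):
            domin_to_cover(11)

    def test_dataframe_conversion(self):
        df = pd.DataFrame({"s1": [8, 0], "s2": [3, 10]})
        out = domin_to_cover(df)
        assert out.loc[0, "s1"] == 62.5
        assert out.loc[1, "s2"] == DOMIN_MIDPOINTS[10]


class TestDiversity:
    def test_equal_covers_give_max_entropy_and_evenness(self, star5):
        cov = _cover([[2.0] * 5], ["p1"], list("abcde"))
        out = diversity(cov, star5)
        assert out.loc["p1", "richness"] == 5
        assert out.loc["p1", "shannon"] == pytest.approx(math.log(5))
        assert out.loc["p1", "pielou"] == pytest.approx(1.0)

    def test_two_species_closed_form(self):
        cov = _cover([[70.0, 30.0]], ["p1"], ["a", "b"])
        out = diversity(cov)
        expect = -0.7 * math.log(0.7) - 0.3 * math.log(0.3)
        assert out.loc["p1", "shannon"] == pytest.approx(expect)

    def test_full_community_pd_is_total_branch_length(self, tree20):
        sp = tree20.tip_labels
        cov = _cover([[1.0] * len(sp)], ["p1"], sp)
        out = diversity(cov, tree20)
        assert out.loc["p1", "faith_pd"] == pytest.approx(
            tree20.total_branch_length()
        )

    def test_zero_cover_plot_flagged_not_zero(self):
        cov = _cover([[1.0, 1.0], [0.0, 0.0]], ["p1", "p2"], ["a", "b"])
        with pytest.warns(UserWarning, match="zero total cover"):
            out = diversity(cov)
        assert np.isnan(out.loc["p2", "shannon"])

    def test_species_missing_from_tree_is_error(self, star5):
        cov = _cover([[1.0, 1.0]], ["p1"], ["a", "zz"])
        with pytest.raises(MissingTaxonError, match="zz"):
            diversity(cov, star5)

    def test_indices_invariant_to_uniform_rescaling_and_column_order(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 20, (3, 6))
        sp = [f"s{i}" for i in range(6)]
        a = diversity(_cover(X, list("pqr"), sp))
        b = diversity(_cover(X[:, ::-1] * 7.3, list("pqr"), sp[::-1]))
        for col in ("richness", "shannon", "pielou"):
            assert np.allclose(a[col], b[col])


class TestFaithPD:
    @staticmethod
    def brute_force_pd(tree: Phylogeny, tips) -> float:
        """Oracle: sum lengths of the union of root-to-tip path edges."""
        dtree = tree.tree
        edges = set()
        for leaf in dtree.leaf_node_iter():
            if leaf.taxon.label not in tips:
                continue
            cur = leaf
            while cur.parent_node is not None:
                edges.add(cur)
                cur = cur.parent_node
        return sum(float(nd.edge.length) for nd in edges)

    def test_matches_brute_force_on_random_subsets(self, tree20):
        rng = np.random.default_rng(9)
        labels = tree20.tip_labels
        for _ in range(25):
            k = rng.integers(1, len(labels) + 1)
            subset = list(rng.choice(labels, size=k, replace=False))
            assert tree20.faith_pd(subset) == pytest.approx(
                self.brute_force_pd(tree20, set(subset))
            )

    def test_monotone_in_species_set(self, tree20):
        rng = np.random.default_rng(2)
        labels = tree20.tip_labels
        subset = list(rng.choice(labels, size=5, replace=False))
        base = tree20.faith_pd(subset)
        for extra in set(labels) - set(subset):
            assert tree20.faith_pd(subset + [extra]) >= base - 1e-12


class TestBrayCurtis:
    def test_identical_plots_give_zero(self):
        d = bray_curtis(_cover([[1, 2, 3], [1, 2, 3]], ["a", "b"], list("xyz")))
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_plots_give_one(self):
        d = bray_curtis(_cover([[1, 1, 0, 0], [0, 0, 2, 5]], ["a", "b"],
                               list("wxyz")))
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # |1-0|+|2-2|+|0-4| over (1+0)+(2+2)+(0+4) = 5/9
        d = bray_curtis(_cover([[1, 2, 0], [0, 2, 4]], ["a", "b"], list("xyz")))
        assert d.loc["a", "b"] == pytest.approx(5 / 9)

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 10, (4, 5))
        sp = [f"s{i}" for i in range(5)]
        a = bray_curtis(_cover(X, list("pqrs"), sp))
        b = bray_curtis(_cover(X * 3.7, list("pqrs"), sp))
        assert np.allclose(a, b)

    def test_all_zero_pair_flagged(self):
        with pytest.warns(UserWarning, match="zero total cover"):
            d = bray_curtis(_cover([[0, 0], [0, 0], [1, 1]], list("abc"),
                                   ["x", "y"]))
        assert np.isnan(d.loc["a", "b"])


def oneway_permanova_oracle(D: np.ndarray, labels: np.ndarray):
    """Independent route: Anderson's within/between group distance formula."""
    n = len(D)
    groups = np.unique(labels)
    ss_total = np.sum(D[np.triu_indices(n, 1)] ** 2) / n
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        sub = D[np.ix_(idx, idx)]
        ss_within += np.sum(sub[np.triu_indices(len(idx), 1)] ** 2) / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.X = rng.uniform(0, 10, (4, 6))
        self.X[:2] += 4.0  # group signal
        self.sp = [f"s{i}" for i in range(6)]
        self.cov = _cover(self.X, list("abcd"), self.sp)
        self.d = bray_curtis(self.cov)

    def test_single_term_marginal_equals_sequential(self):
        # with one predictor, marginal SS is the full-model SS by definition
        pred = pd.DataFrame({"g": [0, 0, 1, 1.0]}, index=self.d.index)
        res = permanova_marginal(self.d, pred, n_perm=99, seed=0)
        ss_model = res.table.loc["Total", "ss"] - res.table.loc["Residual", "ss"]
        assert res.table.loc["g", "ss"] == pytest.approx(ss_model)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        labels = np.array([0, 0, 1, 1])
        pred = pd.DataFrame({"g": labels.astype(float)}, index=self.d.index)
        res = permanova_marginal(self.d, pred, exhaustive=True)
        D = np.asarray(self.d)
        f_obs = oneway_permanova_oracle(D, labels)
        assert res.table.loc["g", "pseudo_f"] == pytest.approx(f_obs)
        count = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            if oneway_permanova_oracle(D, labels[list(p)]) >= f_obs - 1e-12:
                count += 1
        assert res.table.loc["g", "p_value"] == pytest.approx(count / len(perms))

    def test_aliased_terms_listed(self):
        pred = pd.DataFrame(
            {"a": [0, 1, 2, 3.0], "b": [0, 2, 4, 6.0]}, index=self.d.index
        )
        with pytest.raises(AliasedTermsError, match="a.*b|b.*a"):
            permanova_marginal(self.d, pred, n_perm=99, seed=0)

    def test_r2_components_sum_to_one_for_single_term(self):
        pred = pd.DataFrame({"g": [0, 0, 1, 1.0]}, index=self.d.index)
        res = permanova_marginal(self.d, pred, n_perm=99, seed=0)
        assert res.table.loc["g", "r2"] + res.table.loc["Residual", "r2"] == (
            pytest.approx(1.0)
        )

    def test_frozen_cross_implementation_values(self):
        # values verified against an independent marginal-SS implementation
        # (vegan::adonis2, by='margin') on this exact fixture
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 10, (8, 5)).round(3)
        fire = rng.uniform(0, 1, 8).round(3)
        light = rng.uniform(0, 1, 8).round(3)
        cov = _cover(X, [f"p{i}" for i in range(8)], [f"s{i}" for i in range(5)])
        d = bray_curtis(cov)
        pred = pd.DataFrame({"fire": fire, "light": light}, index=d.index)
        res = permanova_marginal(d, pred, n_perm=99, seed=1)
        assert res.table.loc["fire", "ss"] == pytest.approx(0.01438, abs=2e-5)
        assert res.table.loc["fire", "r2"] == pytest.approx(0.03203, abs=2e-5)
        assert res.table.loc["fire", "pseudo_f"] == pytest.approx(0.1737, abs=2e-4)
        assert res.table.loc["light", "ss"] == pytest.approx(0.01984, abs=2e-5)
        assert res.table.loc["Residual", "ss"] == pytest.approx(0.41406, abs=2e-5)
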
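"""Trait models, phylogenetic/geographic distances, dissimilarity regressions."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from condclim.comparative import (
    concordance_vs_phylo,
    dissimilarity_pairs,
    distance_dissimilarity_regression,
    fit_trait_model,
    geo_distance,
    phylo_distance,
)


def _estimates(n_species=10, n_sites=8, gap=0.0, noise=0.3, seed=0):
    """Site-level estimates with an optional wet/dry habitat gap."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_species):
        for j in range(n_sites):
            hab = "wet" if j % 2 == 0 else "dry"
            mu = gap if hab == "wet" else 0.0
            rows.append(
                {
                    "species": f"sp{i}",
                    "site": f"s{j}",
                    "estimate": mu + rng.normal(0, noise),
                    "se": 0.1,
                    "habitat": hab,
                    "noise_trait": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestTraitModels:
    def test_planted_habitat_gap_detected(self):
        hits = 0
        for seed in range(20):
            df = _estimates(gap=1.2, noise=0.3, seed=seed)  # 4x residual SD
            r = fit_trait_model(df, "habitat", level="site")
            hits += r.delta_aicc < -2
        assert hits >= 18

    def test_null_trait_keeps_null_competitive(self):
        hits = 0
        for seed in range(20):
            df = _estimates(gap=0.0, noise=0.3, seed=seed)
            r = fit_trait_model(df, "noise_trait", level="site")
            hits += r.delta_aicc >= -2
        assert hits >= 18

    def test_identical_estimates_give_zero_coefficient(self):
        df = _estimates(seed=1)
        df["estimate"] = 0.7
        r = fit_trait_model(df, "noise_trait", level="species")
        assert r.coef[1] == pytest.approx(0.0, abs=1e-8)
        assert r.delta_aicc > 0  # null favoured

    def test_delta_aicc_invariant_to_constant_shift(self):
        df = _estimates(gap=0.8, seed=2)
        r1 = fit_trait_model(df, "habitat", level="site")
        r2 = fit_trait_model(df.assign(estimate=df["estimate"] + 5.0), "habitat",
                             level="site")
        assert r1.delta_aicc == pytest.approx(r2.delta_aicc, abs=1e-6)

    def test_single_trait_level_rejected(self):
        df = _estimates(seed=3)
        df["habitat"] = "wet"
        with pytest.raises(ValueError, match="single level"):
            fit_trait_model(df, "habitat", level="site")


class TestPhyloDistance:
    def test_three_taxon_tree_path_lengths(self):
        tree = dendropy.Tree.get(data="((A:2,B:2):3,C:5);", schema="newick")
        d = phylo_distance(tree).set_index(["a", "b"])["distance"]
        assert d.loc[("A", "B")] == pytest.approx(2.0)
        assert d.loc[("A", "C")] == pytest.approx(5.0)
        assert d.loc[("B", "C")] == pytest.approx(5.0)

    def test_sister_tips_divergence_equals_depth(self):
        tree = dendropy.Tree.get(data="((A:5,B:5):1,C:6);", schema="newick")
        d = phylo_distance(tree).set_index(["a", "b"])["distance"]
        assert d.loc[("A", "B")] == pytest.approx(5.0)

    def test_missing_tip_named_in_error(self):
        tree = dendropy.Tree.get(data="((A:2,B:2):3,C:5);", schema="newick")
        with pytest.raises(ValueError, match="ghost"):
            phylo_distance(tree, species=["A", "B", "ghost"])

    def test_pair_count(self):
        tree = dendropy.Tree.get(data="(((A:1,B:1):1,C:2):1,(D:2,E:2):1);",
                                 schema="newick")
        assert len(phylo_distance(tree)) == 5 * 4 // 2


class TestGeoDistance:
    SITES = pd.DataFrame(
        {"site": ["a", "b", "c"], "lat": [52.0, 52.0, 53.0], "lon": [5.0, 5.0, 5.0]}
    )

    def test_identical_coordinates_zero(self):
        d = geo_distance(self.SITES).set_index(["a", "b"])["distance"]
        assert d.loc[("a", "b")] == 0.0

    def test_one_degree_latitude(self):
        d = geo_distance(self.SITES).set_index(["a", "b"])["distance"]
        assert d.loc[("a", "c")] == pytest.approx(111.2, abs=0.3)

    def test_missing_coordinates_rejected(self):
        bad = self.SITES.copy()
        bad.loc[1, "lat"] = np.nan
        with pytest.raises(ValueError, match="coordinates"):
            geo_distance(bad)


class TestDistanceDissimilarity:
    def _gradient_pairs(self, seed, noise=0.02):
        """Sites on a line with a smooth estimate gradient."""
        rng = np.random.default_rng(seed)
        sites = pd.DataFrame(
            {"site": [f"s{i}" for i in range(8)],
             "lat": 52.0 + 0.1 * np.arange(8), "lon": 5.0}
        )
        est = pd.DataFrame(
            {"site": sites["site"],
             "estimate": 0.1 * np.arange(8) + rng.normal(0, noise, 8)}
        )
        return dissimilarity_pairs(est, "site", geo_distance(sites))

    def test_equal_estimates_give_exactly_zero_slope(self):
        sites = pd.DataFrame(
            {"site": ["a", "b", "c"], "lat": [52.0, 52.3, 52.9], "lon": [5.0] * 3}
        )
        est = pd.DataFrame({"site": ["a", "b", "c"], "estimate": [0.4] * 3})
        pairs = dissimilarity_pairs(est, "site", geo_distance(sites))
        r = distance_dissimilarity_regression(pairs)
        assert r.slope == 0.0

    def test_spatial_gradient_flagged_positive(self):
        hits = sum(
            distance_dissimilarity_regression(self._gradient_pairs(s)).significant_positive
            for s in range(10)
        )
        assert hits >= 8

    def test_permutation_null_rate_near_alpha(self):
        """With distances permuted against dissimilarities, the OLS flag fires
        at roughly the nominal rate (pair pseudo-replication makes it only
        approximate, which is the point of the Mantel diagnostic)."""
        rng = np.random.default_rng(5)
        flags = 0
        n_rep = 40
        for s in range(n_rep):
            pairs = self._gradient_pairs(s, noise=0.5)
            pairs = pairs.assign(
                dissimilarity=rng.permutation(pairs["dissimilarity"].to_numpy())
            )
            flags += distance_dissimilarity_regression(pairs).significant_positive
        assert flags <= 8  # ~binomial upper bound for p<=0.1ish on 40 draws

    def test_mantel_diagnostic_small_for_true_gradient(self):
        r = distance_dissimilarity_regression(self._gradient_pairs(0), n_perm=99, seed=1)
        assert r.mantel_p is not None and r.mantel_p < 0.2

    def test_zero_variance_distance_rejected(self):
        pairs = pd.DataFrame(
            {"a": ["x"] * 3, "b": ["y"] * 3, "distance": [1.0] * 3,
             "dissimilarity": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError, match="zero-variance"):
            distance_dissimilarity_regression(pairs)

    def test_symmetry_and_zero_diagonal_of_dissimilarity(self):
        pairs = self._gradient_pairs(2)
        est = pairs.set_index(["a", "b"])["dissimilarity"]
        assert (pairs["dissimilarity"] >= 0).all()


class TestConcordance:
    def _balanced_tree(self):
        return dendropy.Tree.get(
            data="(((A:1,B:1):4,(C:1,D:1):4):5,((E:1,F:1):4,(G:1,H:1):4):5);",
            schema="newick",
        )

    def test_clade_clustered_flags_give_negative_slope(self):
        # one clade almost entirely affected, the other almost entirely not:
        # close pairs are mostly concordant, distant pairs mostly discordant
        tree = self._balanced_tree()
        flags = pd.DataFrame(
            {"species": list("ABCDEFGH"),
             "affected": [True, True, True, False, False, False, False, True]}
        )
        r = concordance_vs_phylo(flags, phylo_distance(tree))
        assert not r.separation
        assert r.slope < 0

    def test_perfectly_clustered_flags_trigger_separation(self):
        tree = self._balanced_tree()
        flags = pd.DataFrame(
            {"species": list("ABCDEFGH"), "affected": [True] * 4 + [False] * 4}
        )
        r = concordance_vs_phylo(flags, phylo_distance(tree))
        assert r.separation

    def test_identical_flags_trigger_separation_path(self):
        tree = self._balanced_tree()
        flags = pd.DataFrame({"species": list("ABCDEFGH"), "affected": [True] * 8})
        r = concordance_vs_phylo(flags, phylo_distance(tree))
        assert r.separation and r.slope is None

    def test_tree_independent_flags_usually_cover_zero(self):
        tree = self._balanced_tree()
        rng = np.random.default_rng(9)
        covered = 0
        runs = 0
        for _ in range(30):
            flags = pd.DataFrame(
                {"species": list("ABCDEFGH"),
                 "affected": rng.random(8) < 0.5}
            )
            r = concordance_vs_phylo(flags, phylo_distance(tree))
            if r.separation:
                continue
            runs += 1
            covered += abs(r.slope) < 1.96 * r.se
        assert runs > 0 and covered / runs >= 0.8
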
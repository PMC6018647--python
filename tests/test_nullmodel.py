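import numpy as np
import pandas as pd
import pytest

from traitdisp.dissimilarity import DistanceMatrix, jaccard_dissimilarity
from traitdisp.io_validation import BinaryTraitMatrix
from traitdisp.nullmodel import (
    mean_within_plot_distance,
    median_difference_test,
    null_replicate,
    run_all_trait_tests,
)
from traitdisp.synthetic import SyntheticConfig, generate_dataset

from conftest import make_distance, make_occurrence
from oracles import exact_calibrated_p, exact_zero_threshold_p


class TestMeanWithinPlotDistance:
    def test_single_pair(self):
        occ = make_occurrence({"p1": ["a", "b"], "p2": ["a", "b"]}, ["a", "b"])
        d = make_distance(["a", "b"], {("a", "b"): 0.4})
        obs = mean_within_plot_distance(occ, d)
        assert obs["p1"] == pytest.approx(0.4)

    def test_three_pair_average(self):
        occ = make_occurrence({"p1": ["a", "b", "c"], "p2": ["a", "b"]}, ["a", "b", "c"])
        d = make_distance(
            ["a", "b", "c"], {("a", "b"): 0.2, ("a", "c"): 0.4, ("b", "c"): 0.6}
        )
        assert mean_within_plot_distance(occ, d)["p1"] == pytest.approx(0.4)

    def test_identical_profiles_all_zero(self):
        sm = BinaryTraitMatrix(
            pd.DataFrame([[1, 1, 0]] * 3, index=list("abc"), columns=["m1", "m2", "m3"])
        )
        d = jaccard_dissimilarity(sm)
        occ = make_occurrence({"p1": ["a", "b"], "p2": ["b", "c"]}, list("abc"))
        assert (mean_within_plot_distance(occ, d) == 0).all()

    def test_thin_plot_excluded_with_warning(self):
        occ = make_occurrence({"p1": ["a", "b"], "p2": ["c"]}, ["a", "b", "c"])
        d = make_distance(["a", "b"], {("a", "b"): 0.4})
        with pytest.warns(UserWarning, match="p2"):
            obs = mean_within_plot_distance(occ, d)
        assert list(obs.index) == ["p1"]


class TestNullReplicate:
    def test_pool_of_one_degenerate_multiset(self, rng):
        occ = make_occurrence({"p1": ["a", "b"], "p2": ["a", "c"]}, ["a", "b", "c"])
        rep = null_replicate(occ, ["a"], rng, variant="multiset")
        assert rep == {"p1": ["a", "a"], "p2": ["a", "a"]}

    def test_subset_variant_rejects_overrich_plot(self, rng):
        occ = make_occurrence({"p1": ["a", "b"]}, ["a", "b"])
        with pytest.raises(ValueError, match="richer than the pool"):
            null_replicate(occ, ["a"], rng, variant="subset")

    def test_cardinality_preserved(self, rng):
        occ = make_occurrence({"p1": ["a", "b", "c"], "p2": ["a", "b"]}, ["a", "b", "c"])
        pool = [f"s{i}" for i in range(27)]
        rep = null_replicate(occ, pool, rng)
        assert len(rep["p1"]) == 3 and len(rep["p2"]) == 2
        assert set(rep["p1"]) <= set(pool)

    def test_seed_determinism(self):
        occ = make_occurrence({"p1": ["a", "b", "c"], "p2": ["a", "b"]}, ["a", "b", "c"])
        pool = list("abc")
        r1 = null_replicate(occ, pool, np.random.default_rng(5))
        r2 = null_replicate(occ, pool, np.random.default_rng(5))
        assert r1 == r2

    def test_subset_variant_draws_distinct_species(self, rng):
        occ = make_occurrence({"p1": ["a", "b", "c"]}, ["a", "b", "c"])
        rep = null_replicate(occ, list("abcde"), rng, variant="subset")
        assert len(set(rep["p1"])) == 3


def _toy_setup():
    """2 plots x 3-species pool with generic (collision-free) distances."""
    species = ["a", "b", "c"]
    occ = make_occurrence({"p1": ["a", "b"], "p2": ["a", "c"]}, species)
    d = make_distance(species, {("a", "b"): 0.93, ("a", "c"): 0.47, ("b", "c"): 0.11})
    return occ, d, species


class TestMedianDifferenceTest:
    @pytest.mark.parametrize("variant", ["subset", "multiset"])
    @pytest.mark.parametrize("alternative", ["divergence", "convergence"])
    def test_p_matches_exhaustive_enumeration(self, variant, alternative):
        occ, d, pool = _toy_setup()
        obs = mean_within_plot_distance(occ, d)
        res = median_difference_test(
            occ, d, pool, R=40_000, alternative=alternative, seed=9, variant=variant
        )
        p_cal = exact_calibrated_p(obs.to_numpy(), [2, 2], d.values, alternative, variant)
        se = np.sqrt(p_cal * (1 - p_cal) / res.R)
        assert abs(res.p - p_cal) <= 3 * se + 1 / res.R
        p_zero = exact_zero_threshold_p(obs.to_numpy(), [2, 2], d.values, alternative, variant)
        se = np.sqrt(p_zero * (1 - p_zero) / res.R)
        assert abs(res.p_zero_threshold - p_zero) <= 3 * se + 1 / res.R

    def test_multiset_three_species_plot_enumeration(self):
        # a 3-species plot exercises richness > 2 multisets
        species = ["a", "b", "c", "d"]
        occ = make_occurrence({"p1": ["a", "b", "c"], "p2": ["b", "d"]}, species)
        d = make_distance(
            species,
            {("a", "b"): 0.91, ("a", "c"): 0.53, ("a", "d"): 0.29,
             ("b", "c"): 0.13, ("b", "d"): 0.71, ("c", "d"): 0.61},
        )
        obs = mean_within_plot_distance(occ, d)
        res = median_difference_test(
            occ, d, species, R=40_000, alternative="divergence", seed=4, variant="multiset"
        )
        p_cal = exact_calibrated_p(obs.to_numpy(), [3, 2], d.values, "divergence", "multiset")
        se = np.sqrt(p_cal * (1 - p_cal) / res.R)
        assert abs(res.p - p_cal) <= 3 * se + 1 / res.R

    def test_zero_distance_world_nonsignificant(self):
        species = list("abc")
        occ = make_occurrence({"p1": ["a", "b"], "p2": ["b", "c"]}, species)
        d = DistanceMatrix(species, np.zeros((3, 3)), "jaccard")
        for alt in ("divergence", "convergence"):
            res = median_difference_test(occ, d, species, R=500, alternative=alt, seed=1)
            assert res.mean == 0.0
            assert res.p == 1.0

    def test_seed_reproducibility_and_summary_consistency(self):
        occ, d, pool = _toy_setup()
        r1 = median_difference_test(occ, d, pool, R=300, alternative="divergence", seed=7)
        r2 = median_difference_test(occ, d, pool, R=300, alternative="divergence", seed=7)
        assert np.array_equal(r1.replicate_medians, r2.replicate_medians)
        assert r1.p == r2.p
        assert r1.mean == pytest.approx(np.mean(r1.replicate_medians), abs=1e-12)
        assert len(r1.replicate_medians) == 300
        assert 0 < r1.p <= 1

    def test_p_varies_across_seeds_within_mc_error(self):
        occ, d, pool = _toy_setup()
        ps = [
            median_difference_test(occ, d, pool, R=2000, alternative="divergence", seed=s).p
            for s in range(5)
        ]
        assert len(set(ps)) > 1  # genuinely random
        assert max(ps) - min(ps) < 0.1

    def test_multiset_conspecific_pairs_count_zero(self):
        # pool of 1: every draw is conspecific, expected distance 0,
        # so O - E equals the observed mean exactly
        species = ["a", "b"]
        occ = make_occurrence({"p1": ["a", "b"], "p2": ["a", "b"]}, species)
        d = make_distance(species, {("a", "b"): 0.8})
        res = median_difference_test(
            occ, d, ["a"], R=50, alternative="divergence", seed=3, variant="multiset"
        )
        assert np.allclose(res.replicate_medians, 0.8)

    def test_multiset_variant_biased_toward_divergence(self):
        # documented bias: duplicate-zero pairs shrink expected distances
        occ, d, pool = _toy_setup()
        sub = median_difference_test(occ, d, pool, R=4000, alternative="divergence",
                                     seed=8, variant="subset")
        mult = median_difference_test(occ, d, pool, R=4000, alternative="divergence",
                                      seed=8, variant="multiset")
        assert mult.mean > sub.mean

    def test_invalid_args(self):
        occ, d, pool = _toy_setup()
        with pytest.raises(ValueError):
            median_difference_test(occ, d, pool, R=0, alternative="divergence")
        with pytest.raises(ValueError):
            median_difference_test(occ, d, pool, R=10, alternative="both")
        with pytest.raises(ValueError):
            median_difference_test(occ, d, pool + ["ghost"], R=10, alternative="divergence")

    def test_outlier_control_variant_runs(self):
        occ, d, pool = _toy_setup()
        res = median_difference_test(
            occ, d, pool, R=200, alternative="divergence", seed=2, outlier_control=True
        )
        assert 0 < res.p <= 1


class TestRunAllTraitTests:
    def test_synthetic_strong_effects_recovered(self):
        cfg = SyntheticConfig(sigma_filt=0.4, lambda_div=60.0, seed=21)
        ds = generate_dataset(cfg)
        assemblages = {"rut_axis1": ds.bundle.rut.trait_ids[:7]}
        results = run_all_trait_tests(ds.bundle, assemblages, R=300, seed=5)
        assert results["sm"].alternative == "divergence"
        assert results["sm"].p < 0.05
        assert results["rut_axis1"].alternative == "convergence"
        assert results["rut_axis1"].p < 0.05

    def test_neutral_rates_not_degenerate(self):
        # light calibration check; the full 500-dataset band lives in
        # the acceptance suite
        hits = 0
        n = 60
        for s in range(n):
            ds = generate_dataset(
                SyntheticConfig(n_plots=8, n_species=12, n_metabolites=50,
                                mean_richness=5.0, seed=1000 + s)
            )
            res = run_all_trait_tests(ds.bundle, {}, R=100, seed=s)["sm"]
            hits += res.p <= 0.05
        assert hits <= 12  # ~binomial(60, 0.05) upper tail, generous

    def test_divergence_monotonicity_in_generator_strength(self):
        # stronger divergence never makes the SM test less significant (grid)
        grid = [0.0, 8.0, 20.0]
        rates = []
        for lam in grid:
            sig = 0
            for s in range(25):
                ds = generate_dataset(
                    SyntheticConfig(lambda_div=lam, n_plots=10, n_species=15,
                                    n_metabolites=60, mean_richness=5.0,
                                    seed=3000 + s)
                )
                res = run_all_trait_tests(ds.bundle, {}, R=120, seed=s)["sm"]
                sig += res.p <= 0.05
            rates.append(sig / 25)
        assert rates[0] <= rates[1] + 0.15
        assert rates[1] <= rates[2] + 0.15
        assert rates[2] > rates[0]
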
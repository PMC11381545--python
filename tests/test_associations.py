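import itertools
import math

import numpy as np
import pandas as pd
import pytest

from microflux import (
    AbundanceMatrix,
    SimulationConfig,
    coabundance_network,
    differential_abundance,
    function_enrichment,
    mixed_model_association,
    overlap_enrichment,
    per_species_association,
    simulate_case_control,
)

from conftest import make_metadata


def hypergeom_upper_tail_by_enumeration(n_universe, class_size, n_hits, k):
    """Oracle: enumerate every possible hit set and count the tail."""
    universe = range(n_universe)
    cls = set(range(class_size))
    total = hits_at_least = 0
    for hit_set in itertools.combinations(universe, n_hits):
        total += 1
        if len(cls.intersection(hit_set)) >= k:
            hits_at_least += 1
    return hits_at_least / total


class TestOverlapEnrichment:
    def test_worked_exact_example(self):
        # universe 10, class 4, all 3 hits inside the class: C(4,3)/C(10,3) = 1/30
        universe = [f"sp{i}" for i in range(10)]
        result = overlap_enrichment(universe[:3], universe[:4], universe)
        assert result.hypergeom_p == pytest.approx(1 / 30)
        assert result.direction == "over"

    def test_disjoint_hit_set_upper_tail_is_one(self):
        universe = [f"sp{i}" for i in range(10)]
        result = overlap_enrichment(universe[5:8], universe[:4], universe)
        assert result.hypergeom_p == pytest.approx(1.0)

    def test_hits_equal_universe_carry_no_signal(self):
        universe = [f"sp{i}" for i in range(12)]
        result = overlap_enrichment(universe, universe[:5], universe)
        assert result.hypergeom_p == pytest.approx(1.0)
        assert result.table[0, 0] == 5

    def test_margins_partition_universe(self):
        universe = [f"sp{i}" for i in range(20)]
        result = overlap_enrichment(universe[:7], universe[4:12], universe)
        assert result.table.sum() == 20
        assert result.table[0].sum() == 7
        assert result.table[:, 0].sum() == 8

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            overlap_enrichment([], [], [])

    def test_matches_exhaustive_enumeration_on_small_universes(self):
        # spot the full grid at N<=9 plus boundary draws at N in {12, 15}
        for n_universe in range(1, 10):
            for class_size in range(n_universe + 1):
                for n_hits in range(n_universe + 1):
                    universe = [f"sp{i}" for i in range(n_universe)]
                    result = overlap_enrichment(
                        universe[:n_hits], universe[:class_size], universe
                    )
                    k = len(set(universe[:n_hits]) & set(universe[:class_size]))
                    expected = hypergeom_upper_tail_by_enumeration(
                        n_universe, class_size, n_hits, k
                    )
                    assert result.hypergeom_p == pytest.approx(expected, abs=1e-12)
        for n_universe, class_size, n_hits in [(12, 5, 6), (15, 7, 4), (15, 15, 8)]:
            universe = [f"sp{i}" for i in range(n_universe)]
            result = overlap_enrichment(universe[:n_hits], universe[:class_size], universe)
            k = min(n_hits, class_size)
            expected = hypergeom_upper_tail_by_enumeration(n_universe, class_size, n_hits, k)
            assert result.hypergeom_p == pytest.approx(expected, abs=1e-12)

    def test_chi_square_agrees_in_direction_on_strong_signal(self):
        universe = [f"sp{i}" for i in range(100)]
        result = overlap_enrichment(universe[:30], universe[:35], universe)
        assert result.direction == "over"
        assert result.chi2_p < 0.01 and result.hypergeom_p < 0.01


class TestCoabundanceNetwork:
    def _abundance(self, arr, labels):
        md = make_metadata(arr.shape[1], 1)
        values = pd.DataFrame(
            arr, index=[f"sp{i}" for i in range(arr.shape[0])], columns=md.index
        )
        return AbundanceMatrix(values, md), pd.Series(labels, index=values.index)

    def test_duplicated_species_perfect_positive_edge(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(1, 10, 12)
        ab, labels = self._abundance(np.vstack([row, row]), ["PCS", "TCS"])
        edges = coabundance_network(ab, labels, p_adj_threshold=0.05)
        assert len(edges) == 1 and edges.loc[0, "rho"] == pytest.approx(1.0)
        assert edges.loc[0, "sign"] == "+"

    def test_anti_monotone_pair_negative_edge(self):
        x = np.arange(12.0) + 1
        ab, labels = self._abundance(np.vstack([x, x[::-1]]), ["PCS", "TCS"])
        edges = coabundance_network(ab, labels, p_adj_threshold=0.05)
        assert edges.loc[0, "rho"] == pytest.approx(-1.0)
        assert edges.loc[0, "sign"] == "-"

    def test_null_false_edge_rate_near_alpha_for_raw_p(self):
        # independent species: raw-p edge calls should run at about alpha
        rng = np.random.default_rng(42)
        n_sp, n_samp = 40, 30
        ab, labels = self._abundance(
            rng.uniform(0, 5, (n_sp, n_samp)), ["PCS", "TCS"] * (n_sp // 2)
        )
        edges = coabundance_network(ab, labels, p_adj_threshold=1.1)  # keep all
        rate = (edges["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 0.03
        # after BH correction on an exact null, few or no edges survive
        assert (edges["p_adj"] < 0.05).mean() < 0.02


class TestFunctionEnrichment:
    def _flux(self, score):
        return pd.DataFrame(
            {"inflow": score, "outflow": 1 - score},
            index=[f"sp{i}" for i in range(len(score))],
        )

    def test_constant_annotation_skipped(self):
        rng = np.random.default_rng(0)
        flux = self._flux(rng.uniform(0, 1, 20))
        ann = pd.DataFrame({"fun": np.ones(20, int)}, index=flux.index)
        assert len(function_enrichment(flux, ann)) == 0

    def test_coefficient_is_group_mean_difference(self):
        rng = np.random.default_rng(1)
        score = rng.uniform(0, 1, 30)
        flux = self._flux(score)
        x = (np.arange(30) < 12).astype(int)
        ann = pd.DataFrame({"fun": x}, index=flux.index)
        table = function_enrichment(flux, ann)
        expected = score[x == 1].mean() - score[x == 0].mean()
        assert table.loc["fun", "coefficient"] == pytest.approx(expected)

    def test_constructed_effect_recovered_at_scale(self):
        rng = np.random.default_rng(2)
        n = 500
        x = rng.integers(0, 2, n)
        score = np.clip(0.3 * x + rng.normal(0.3, 0.08, n), 0, 1)
        flux = self._flux(score)
        ann = pd.DataFrame(
            {"signal": x, **{f"null{i}": rng.integers(0, 2, n) for i in range(20)}},
            index=flux.index,
        )
        table = function_enrichment(flux, ann)
        assert bool(table.loc["signal", "enriched"])
        assert table.loc["signal", "p_adj"] < 1e-3
        assert not table.drop(index="signal")["enriched"].any()


class TestDifferentialAbundance:
    def test_null_calibration(self):
        config = SimulationConfig(n_subjects=50, n_species=200, n_visits=1, seed=11)
        ab, truth = simulate_case_control(config, effect_on_tcs=0.0)
        table = differential_abundance(ab, p_threshold=0.01)
        assert truth.shifted_species == [] or truth.shifted_species  # truth recorded
        # expect about alpha * n_tested false calls
        assert table["significant"].sum() <= 10

    def test_constructed_shift_recovered(self):
        config = SimulationConfig(n_subjects=50, n_species=120, n_visits=1, seed=12)
        shifted = [f"msp_{i:04d}" for i in range(30)]
        ab, truth = simulate_case_control(config, effect_on_tcs=3.0, shifted_species=shifted)
        table = differential_abundance(ab, p_threshold=0.01)
        hits = set(table.index[table["significant"] & (table["direction"] == "enriched")])
        assert len(hits & set(shifted)) >= 27
        result = overlap_enrichment(hits, shifted, list(ab.species))
        assert result.hypergeom_p < 0.01

    def test_group_requirements(self, toy_abundance):
        with pytest.raises(ValueError, match="two groups"):
            differential_abundance(toy_abundance)


class TestMixedModel:
    def _scores_phenotype(self, n_subjects=86, n_visits=4, re_sd=0.5, seed=5):
        rng = np.random.default_rng(seed)
        md = make_metadata(n_subjects, n_visits)
        scores = pd.DataFrame(
            rng.standard_normal((len(md), 2)), index=md.index, columns=["Z_PCS", "Z_TCS"]
        )
        u = pd.Series(
            rng.normal(0, re_sd, n_subjects), index=[f"S{i}" for i in range(n_subjects)]
        )
        y = (
            0.5 * scores["Z_PCS"]
            - 0.5 * scores["Z_TCS"]
            + u.loc[md["subject_id"]].to_numpy()
            + rng.normal(0, 1.0, len(md))
        )
        return scores, pd.Series(y, index=md.index), md

    def test_reduces_to_ols_with_one_sample_per_subject(self):
        import statsmodels.api as sm

        scores, y, md = self._scores_phenotype(n_subjects=120, n_visits=1)
        res = mixed_model_association(scores, y, md)
        ols = sm.OLS(y, sm.add_constant(scores[["Z_PCS", "Z_TCS"]])).fit()
        assert res.coefficients["Z_PCS"] == pytest.approx(ols.params["Z_PCS"], abs=1e-6)
        assert res.coefficients["Z_TCS"] == pytest.approx(ols.params["Z_TCS"], abs=1e-6)
        assert res.random_intercept_var == 0.0

    def test_recovers_generating_coefficients(self):
        scores, y, md = self._scores_phenotype()
        res = mixed_model_association(scores, y, md)
        se = 2.5 / math.sqrt(len(y))  # generous CI half-width bound
        assert abs(res.coefficients["Z_PCS"] - 0.5) < 4 * se
        assert abs(res.coefficients["Z_TCS"] + 0.5) < 4 * se
        assert res.p_values["Z_PCS"] < 0.05 and res.p_values["Z_TCS"] < 0.05
        assert res.random_intercept_var > 0

    def test_null_phenotype_not_significant_on_average(self):
        rng = np.random.default_rng(9)
        hits = 0
        for seed in range(10):
            scores, _, md = self._scores_phenotype(n_subjects=40, n_visits=3, seed=seed)
            y = pd.Series(rng.standard_normal(len(scores)), index=scores.index)
            res = mixed_model_association(scores, y, md)
            hits += res.p_values["Z_PCS"] < 0.05
        assert hits <= 3


class TestPerSpeciesAssociation:
    def _abundance(self, n_subjects=30, n_visits=3, seed=6):
        rng = np.random.default_rng(seed)
        md = make_metadata(n_subjects, n_visits)
        values = pd.DataFrame(
            rng.uniform(0, 10, (4, len(md))),
            index=[f"sp{i}" for i in range(4)],
            columns=md.index,
        )
        return AbundanceMatrix(values, md)

    def test_phenotype_equal_to_abundance_retained(self):
        ab = self._abundance()
        phenotype = ab.values.loc["sp0"]
        table = per_species_association(ab, phenotype)
        assert table.loc["sp0", "explained_variance"] > 0.9
        assert bool(table.loc["sp0", "retained"])

    def test_independent_phenotype_dropped(self):
        rng = np.random.default_rng(8)
        ab = self._abundance()
        phenotype = pd.Series(rng.standard_normal(len(ab.samples)), index=ab.samples)
        table = per_species_association(ab, phenotype)
        assert not table["retained"].any()

    def test_constructed_variance_share_above_threshold(self):
        # fixed-effect variance tuned to ~0.2 of the total
        rng = np.random.default_rng(10)
        ab = self._abundance(n_subjects=60)
        a = ab.values.loc["sp1"]
        beta = np.sqrt(0.2 / 0.8) / a.std(ddof=0)
        phenotype = beta * a + rng.normal(0, 1.0, len(a))
        table = per_species_association(ab, pd.Series(phenotype, index=a.index))
        assert 0.08 < table.loc["sp1", "explained_variance"] < 0.4
        assert bool(table.loc["sp1", "retained"])
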
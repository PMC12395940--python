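import numpy as np
import pandas as pd
import pytest

from arealna import (
    SyntheticScenario,
    generate_confounder,
    generate_counts,
    generate_exposure,
    generate_graph,
    morans_i,
    preset_scenario,
    simulate,
)
from arealna.areas import STRATA, validate_area_table


class TestScenarioValidation:
    def test_grid_needs_nine_units(self):
        with pytest.raises(ValueError, match="n_units >= 9"):
            SyntheticScenario(n_units=6, graph_kind="grid")

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SyntheticScenario(confounder_sd=-1.0)

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            SyntheticScenario(exposure_confounding_weight=1.5)

    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError, match="rates"):
            SyntheticScenario(stratum_rates=(0.1, 0.2, 0.3, 1.5))

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            preset_scenario("bogus")


class TestGenerateGraph:
    def test_3x3_lattice_structure(self):
        W = generate_graph(SyntheticScenario(n_units=9, graph_kind="grid"))
        degs = sorted(W.degrees.tolist())
        assert degs == [2, 2, 2, 2, 3, 3, 3, 3, 4]
        assert W.s0 == 24  # 12 undirected rook edges

    def test_prime_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            generate_graph(SyntheticScenario(n_units=13, graph_kind="grid"))

    def test_random_planar_deterministic(self):
        scen = SyntheticScenario(n_units=50, graph_kind="random_planar", seed=1)
        W1, W2 = generate_graph(scen), generate_graph(scen)
        assert W1.to_edge_list() == W2.to_edge_list()

    def test_random_planar_connected(self):
        scen = SyntheticScenario(n_units=356, graph_kind="random_planar", seed=5)
        assert generate_graph(scen).is_connected


class TestGenerateConfounder:
    def test_k0_is_iid_noise(self, grid10x10):
        scen = SyntheticScenario(
            n_units=100, confounder_smoothing_steps=0, confounder_sd=1.0, seed=3
        )
        U = generate_confounder(grid10x10, scen)
        assert U.mean() == pytest.approx(0.0, abs=1e-12)
        assert U.std() == pytest.approx(1.0)
        # unsmoothed noise shows no spatial structure
        assert abs(morans_i(U, grid10x10) - (-1 / 99)) < 0.15

    def test_smoothing_increases_moran(self, grid10x10):
        base = SyntheticScenario(n_units=100, confounder_sd=1.0, seed=7)
        scen0 = SyntheticScenario(
            n_units=100, confounder_sd=1.0, seed=7, confounder_smoothing_steps=0
        )
        scen8 = SyntheticScenario(
            n_units=100, confounder_sd=1.0, seed=7, confounder_smoothing_steps=8
        )
        i0 = morans_i(generate_confounder(grid10x10, scen0), grid10x10)
        i8 = morans_i(generate_confounder(grid10x10, scen8), grid10x10)
        assert i8 > i0

    def test_zero_scale_gives_zero_field(self, grid10x10):
        scen = SyntheticScenario(n_units=100, confounder_sd=0.0)
        assert not generate_confounder(grid10x10, scen).any()


class TestGenerateExposure:
    def test_unconfounded_uncorrelated(self):
        scen = SyntheticScenario(
            n_units=400,
            graph_kind="grid",
            exposure_confounding_weight=0.0,
            confounder_sd=1.0,
            seed=2,
        )
        W = generate_graph(scen)
        U = generate_confounder(W, scen)
        x = generate_exposure(U, W, scen)
        assert abs(np.corrcoef(x, U)[0, 1]) < 0.2

    def test_pure_confounding_is_affine(self, grid10x10):
        scen = SyntheticScenario(
            n_units=100,
            exposure_confounding_weight=1.0,
            exposure_noise_sd=0.0,
            exposure_smoothing_steps=0,
            confounder_sd=1.0,
            seed=4,
        )
        U = generate_confounder(grid10x10, scen)
        x = generate_exposure(U, grid10x10, scen)
        assert abs(np.corrcoef(x, U)[0, 1]) == pytest.approx(1.0)

    def test_partial_confounding_correlation(self, grid10x10):
        scen = SyntheticScenario(
            n_units=100,
            exposure_confounding_weight=0.6,
            confounder_sd=1.0,
            seed=3,
        )
        U = generate_confounder(grid10x10, scen)
        x = generate_exposure(U, grid10x10, scen)
        assert np.corrcoef(x, U)[0, 1] > 0.3

    def test_nonnegative_percentage_points(self, grid10x10):
        scen = SyntheticScenario(n_units=100, seed=5, exposure_sd_pp=10.0)
        U = generate_confounder(grid10x10, scen)
        x = generate_exposure(U, grid10x10, scen)
        assert (x >= 0).all()

    def test_exposure_must_be_rougher_than_confounder(self, grid10x10):
        scen = SyntheticScenario(
            n_units=100,
            exposure_confounding_weight=0.5,
            confounder_smoothing_steps=2,
            exposure_smoothing_steps=4,
        )
        U = generate_confounder(grid10x10, scen)
        with pytest.raises(ValueError, match="shallower"):
            generate_exposure(U, grid10x10, scen)


class TestGenerateCounts:
    def test_null_aggregate_rate(self):
        # beta0 = beta_x = gamma = 0, U = 0: empirical aggregate rate matches
        # sum(pop_s * r_s) / sum(pop) within 3 Poisson standard errors
        scen = preset_scenario("null", seed=6, confounder_sd=0.0)
        areas, _ = simulate(scen)
        y = areas[[f"y_inc_{s}" for s in STRATA]].to_numpy().sum()
        expected = sum(
            areas[f"pop_{s}"].sum() * r for s, r in zip(STRATA, scen.stratum_rates)
        )
        assert abs(y - expected) < 3 * np.sqrt(expected)

    def test_counts_bounded_by_population(self):
        scen = preset_scenario("confounded", seed=1)
        areas, _ = simulate(scen)
        for prefix in ("y_inc", "y_mort"):
            for s in STRATA:
                assert (areas[f"{prefix}_{s}"] <= areas[f"pop_{s}"]).all()
                assert (areas[f"{prefix}_{s}"] >= 0).all()

    def test_zero_population_rejected(self, grid10x10):
        scen = SyntheticScenario(n_units=100, seed=1)
        areas, _ = simulate(scen)
        bad = areas.copy()
        bad.loc[0, "pop_F_lt65"] = 0
        with pytest.raises(ValueError, match="positive"):
            generate_counts(bad, np.zeros(100), scen)

    def test_link_closed_form(self):
        # shifting x by +1 everywhere scales every Poisson mean by
        # exp(beta_x); with huge populations the empirical ratio converges
        scen = SyntheticScenario(
            n_units=100,
            beta_x=-0.03,
            pop_low=500_000,
            pop_high=500_000,
            seed=8,
        )
        areas, _ = simulate(scen)
        shifted = areas.copy()
        shifted["x"] = shifted["x"] + 1.0
        U = areas["u_true"].to_numpy()
        y1 = generate_counts(areas, U, scen)
        y2 = generate_counts(shifted, U, scen)
        tot1 = y1[[f"y_inc_{s}" for s in STRATA]].to_numpy().sum()
        tot2 = y2[[f"y_inc_{s}" for s in STRATA]].to_numpy().sum()
        assert tot2 / tot1 == pytest.approx(np.exp(-0.03), rel=2e-3)

    def test_gamma_length_checked(self, grid10x10):
        scen = SyntheticScenario(n_units=100, gamma=(0.1, 0.2))
        with pytest.raises(ValueError):
            simulate(scen)


class TestSimulate:
    def test_bit_for_bit_determinism(self):
        scen = preset_scenario("confounded", seed=123)
        a1, W1 = simulate(scen)
        a2, W2 = simulate(scen)
        pd.testing.assert_frame_equal(a1, a2)
        assert W1.to_edge_list() == W2.to_edge_list()

    def test_different_seeds_differ(self):
        a1, _ = simulate(preset_scenario("null", seed=1))
        a2, _ = simulate(preset_scenario("null", seed=2))
        assert not a1.equals(a2)

    def test_valid_schema(self, unconfounded_data):
        areas, W = unconfounded_data
        validate_area_table(areas)
        assert len(areas) == W.n
        assert "u_true" in areas.columns

    def test_covariate_magnitudes(self, confounded_data):
        areas, _ = confounded_data
        # medians in the observed municipal ranges
        assert 0.2 < areas["rurality"].median() < 0.8
        assert 0.5 < areas["pcp_density"].median() < 2.0
        assert 250 < areas["income"].median() < 600
        assert 0.02 < areas["immigrants"].median() < 0.3

    def test_scenario_from_dict_preset_override(self):
        from arealna.synthetic import scenario_from_dict

        scen = scenario_from_dict({"preset": "null", "n_units": 64, "seed": 9})
        assert scen.n_units == 64
        assert scen.seed == 9
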
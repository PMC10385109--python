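import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ladderflow as lf
from oracles import bisect_root


class TestInletPositions:
    def test_uniform_when_kappa_is_one(self):
        rng = np.random.default_rng(5)
        x = lf.sample_inlet_positions(20000, 1.0, rng)
        assert stats.kstest(x, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("kappa", [1.0, 3.0, 8.0])
    def test_variance_matches_beta_family(self, kappa):
        rng = np.random.default_rng(6)
        x = lf.sample_inlet_positions(200000, kappa, rng)
        expected = 1.0 / (4.0 * (2.0 * kappa + 1.0))
        assert x.var() == pytest.approx(expected, rel=0.05)
        assert x.mean() == pytest.approx(0.5, abs=0.01)

    def test_seeded_determinism(self):
        a = lf.sample_inlet_positions(100, 4.0, np.random.default_rng(42))
        b = lf.sample_inlet_positions(100, 4.0, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_wall_concentration_rejected(self):
        with pytest.raises(lf.SimulationError):
            lf.sample_inlet_positions(10, 0.5, np.random.default_rng(0))


class TestSeparatingFraction:
    @pytest.mark.parametrize("q", [0.0, 0.3, 0.5, 1.0])
    def test_plug_profile_is_identity(self, q):
        assert lf.separating_fraction(q, "plug") == pytest.approx(q, abs=1e-15)

    def test_parabolic_symmetry(self):
        assert lf.separating_fraction(0.5, "parabolic_plate") == pytest.approx(
            0.5, abs=1e-10)

    @pytest.mark.parametrize("q", [0.05, 0.2, 0.8])
    def test_parabolic_matches_bisection_oracle(self, q):
        want = bisect_root(lambda x: 3 * x**2 - 2 * x**3 - q, 0.0, 1.0)
        got = lf.separating_fraction(q, "parabolic_plate")
        assert got == pytest.approx(want, abs=1e-10)

    def test_domain_error(self):
        with pytest.raises(lf.SimulationError):
            lf.separating_fraction(1.2)


class TestRelaxation:
    def test_zero_distance_never_redraws(self):
        x = np.linspace(0.01, 0.99, 500)
        out = lf.relax_positions(x, 0.0, 50.0, 4.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)

    def test_infinite_migration_length_never_redraws(self):
        x = np.linspace(0.01, 0.99, 500)
        out = lf.relax_positions(x, 1e6, math.inf, 4.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)

    def test_redraw_frequency_at_one_migration_length(self):
        n = 40000
        x = np.full(n, 0.123456)
        out = lf.relax_positions(x, 50.0, 50.0, 1.0, np.random.default_rng(3))
        p = 1.0 - math.exp(-1.0)
        frac = np.mean(out != x)
        assert abs(frac - p) < 3.0 * math.sqrt(p * (1 - p) / n)


class TestSimulator:
    def test_flux_conservation_null_limit(self, case1, case1_solution):
        """With a uniform profile, plug flow and no migration, transit
        fractions reproduce the flow fractions (no phase separation)."""
        config = lf.SimulationConfig(target_parent_hematocrit=0.10,
                                     profile_concentration=1.0,
                                     migration_length=math.inf,
                                     frames_per_set=150, n_sets=1)
        _, truth = lf.simulate_transits(case1, case1_solution, config,
                                        rng=lf.set_rng(21, 0))
        n = truth.branch_counts.sum()
        assert n >= 2000
        fractions = truth.branch_counts / n
        q = case1_solution.fractional_ratios
        sigma = np.sqrt(q * (1 - q) / n)
        assert (np.abs(fractions - q) <= 3.0 * sigma).all()

    def test_exit_probabilities_reduce_to_flow_fractions_in_null_limit(
            self, case1, case1_solution):
        config = lf.SimulationConfig(target_parent_hematocrit=0.10,
                                     profile_concentration=1.0,
                                     migration_length=math.inf)
        probs = lf.junction_exit_probabilities(case1, case1_solution, config)
        np.testing.assert_allclose(probs, case1_solution.fractional_ratios, atol=1e-9)

    def test_exit_probabilities_match_simulation(self, case1, case1_solution):
        config = lf.SimulationConfig(target_parent_hematocrit=0.10,
                                     profile_concentration=8.0,
                                     migration_length=200.0,
                                     frames_per_set=150, n_sets=1)
        _, truth = lf.simulate_transits(case1, case1_solution, config,
                                        rng=lf.set_rng(22, 0))
        n = truth.branch_counts.sum()
        p = truth.exit_probabilities
        sigma = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        assert (np.abs(truth.branch_counts / n - p) <= 4.0 * sigma + 1e-4).all()

    def test_center_concentration_biases_first_branches(self, case1, case1_solution):
        base = lf.SimulationConfig(target_parent_hematocrit=0.10,
                                   profile_concentration=1.0,
                                   migration_length=math.inf)
        peaked = lf.SimulationConfig(target_parent_hematocrit=0.10,
                                     profile_concentration=8.0,
                                     migration_length=200.0)
        p0 = lf.junction_exit_probabilities(case1, case1_solution, base)
        p1 = lf.junction_exit_probabilities(case1, case1_solution, peaked)
        assert p1[0] + p1[1] > p0[0] + p0[1]

    def test_heterogeneity_decreases_with_branch_spacing(self):
        """Short inter-branch distance leaves no room for lateral migration,
        so the transit split is more uneven at L_D = 30 than 90 than 150 um."""
        hets = []
        for case in ("case1", "case4", "case5"):  # L_D = 30, 90, 150 um
            g = lf.build_case(case)
            sol = lf.solve_flows(lf.assemble_network(g))
            config = lf.SimulationConfig(target_parent_hematocrit=0.10,
                                         profile_concentration=8.0,
                                         migration_length=200.0)
            p = lf.junction_exit_probabilities(g, sol, config)
            hets.append(p.max() / p.min())
        assert hets[0] >= hets[1] >= hets[2]

    def test_cell_conservation_and_single_channel_per_frame(self, small_sim):
        _, table, truth = small_sim
        per_frame = table.groupby(["frame", "cell"]).size()
        assert (per_frame == 1).all()
        assert truth.branch_counts.sum() <= truth.n_cells_injected

    def test_seeded_determinism(self, case1, case1_solution):
        config = lf.SimulationConfig(target_parent_hematocrit=0.05,
                                     frames_per_set=50, n_sets=1, rng_seed=9)
        t1, _ = lf.simulate_transits(case1, case1_solution, config)
        t2, _ = lf.simulate_transits(case1, case1_solution, config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_lateral_positions_in_unit_interval(self, small_sim):
        _, table, _ = small_sim
        assert table["lateral"].between(0.0, 1.0).all()
        assert (table["frame"] < 100).all() and (table["frame"] >= 0).all()

    def test_flux_counting_matches_ground_truth_exactly(self, small_sim):
        _, table, truth = small_sim
        flux = lf.fractional_rbc_flux(table, n_branches=6)
        np.testing.assert_array_equal(flux.counts, truth.branch_counts)

    def test_mismatched_solution_rejected(self, case1_solution):
        g3 = lf.LadderGeometry(parent_width=10, branch_width=10, branch_spacing=30,
                               branch_length=90, n_branches=3)
        config = lf.SimulationConfig(target_parent_hematocrit=0.10)
        with pytest.raises(lf.SimulationError):
            lf.simulate_transits(g3, case1_solution, config)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"target_parent_hematocrit": 0.0},
        {"target_parent_hematocrit": 0.1, "profile_concentration": 0.9},
        {"target_parent_hematocrit": 0.1, "migration_length": -3.0},
        {"target_parent_hematocrit": 0.1, "frames_per_set": 0},
        {"target_parent_hematocrit": 0.1, "velocity_profile": "cubic"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(lf.SimulationError):
            lf.SimulationConfig(**kwargs)


class TestDetectionIO:
    def test_round_trip(self, small_sim, tmp_path):
        _, table, _ = small_sim
        path = tmp_path / "detections.csv"
        lf.write_detections(table, path)
        back = lf.read_detections(path)
        assert list(back.columns) == lf.DETECTION_COLUMNS
        assert len(back) == len(table)
        np.testing.assert_array_equal(back["cell"], table["cell"])
        np.testing.assert_allclose(back["axial_um"], table["axial_um"], rtol=1e-12)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"frame": [0]}).to_csv(path, index=False)
        with pytest.raises(lf.SimulationError):
            lf.read_detections(path)
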
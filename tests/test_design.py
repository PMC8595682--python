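import numpy as np
import pytest
from scipy import stats

from scpower.data_model import CostModel, DesignPoint, ExpressionThreshold
from scpower.design import (
    celltype_detection_probability,
    doublet_adjust,
    experiment_cost,
    make_cell_type_context,
    min_cells_for_detection,
    optimize_design,
    sample_size_for_budget,
)
from scpower.detection import overall_detection_power
from scpower.simulate import simulate_de_priors
from tests.conftest import make_prior


class TestDoubletAdjust:
    def test_overloading_cap(self, cost_model):
        # 20,000 cells per lane -> doublet rate <= 15.34% for any feasible split
        rates = []
        for n_c in range(100, 20_001, 100):
            adj = doublet_adjust(n_c, cost_model, 10_000)
            rates.append(adj.doublet_rate)
        assert max(rates) <= 7.67e-6 * 20_000 + 1e-12
        assert max(rates) == pytest.approx(0.1534, abs=1e-4)

    def test_no_doublets_identity(self):
        cm = CostModel(doublet_slope=None, doublet_rate_constant=0.0)
        adj = doublet_adjust(1000, cm, 10_000)
        assert adj.n_u == 1000
        assert adj.r_s == pytest.approx(10_000)
        assert adj.r_m == pytest.approx(8_000)

    def test_worked_example(self, cost_model):
        # n_c=1000 -> n_sl=20, d=0.1534, r=10,000, f_d=1.8
        adj = doublet_adjust(1000, cost_model, 10_000)
        assert adj.n_sl == 20
        assert adj.doublet_rate == pytest.approx(0.1534)
        assert adj.n_u == pytest.approx(846.6)
        assert adj.r_s == pytest.approx(1e7 / (846.6 + 1.8 * 153.4), rel=1e-9)
        assert adj.r_m == pytest.approx(0.8 * adj.r_s, rel=1e-12)

    def test_read_conservation(self, cost_model, rng):
        # r_s * (n_u + f_d (n_c - n_u)) == r * n_c exactly
        for _ in range(100):
            n_c = int(rng.integers(50, 20_000))
            r = float(rng.uniform(1_000, 100_000))
            adj = doublet_adjust(n_c, cost_model, r)
            lhs = adj.r_s * (adj.n_u + cost_model.doublet_read_factor * (n_c - adj.n_u))
            assert lhs == pytest.approx(r * n_c, rel=1e-12)

    def test_lane_capacity_error(self, cost_model):
        with pytest.raises(ValueError, match="lane capacity"):
            doublet_adjust(30_000, cost_model, 10_000)

    def test_context_infeasible_below_one_cell(self, cost_model):
        design = DesignPoint(n_s=4, n_c=100, r=10_000)
        with pytest.raises(ValueError, match="infeasible"):
            make_cell_type_context(design, 0.001, cost_model)


class TestExperimentCost:
    COST = CostModel(
        kit_cost=6_000, flowcell_cost=1_000, reads_per_flowcell=4.1e8,
        cells_loaded_per_lane=4_999,  # forces n_sl = 4 at n_c = 1000
    )

    def test_worked_example(self):
        cost = experiment_cost(DesignPoint(n_s=24, n_c=1000, r=10_000), self.COST)
        assert cost == 7_000  # 1 kit + 1 flow cell

    def test_zero_samples(self):
        assert experiment_cost(DesignPoint(n_s=1, n_c=10, r=1) , self.COST) > 0
        # n_s = 0 handled through the dataclass floor; emulate directly
        from dataclasses import replace
        d = DesignPoint(n_s=1, n_c=10, r=1)
        object.__setattr__(d, "n_s", 0)
        assert experiment_cost(d, self.COST) == 0.0

    def test_monotone(self):
        base = experiment_cost(DesignPoint(24, 1000, 10_000), self.COST)
        assert experiment_cost(DesignPoint(48, 1000, 10_000), self.COST) >= base
        assert experiment_cost(DesignPoint(24, 2000, 10_000), self.COST) >= base
        assert experiment_cost(DesignPoint(24, 1000, 50_000), self.COST) >= base

    def test_per_cell_mode(self):
        cm = CostModel(
            per_cell_library_cost=0.1, doublet_rate_constant=0.05, doublet_slope=None,
            flowcell_cost=1_000, reads_per_flowcell=4.1e8,
        )
        cost = experiment_cost(DesignPoint(10, 500, 10_000), cm)
        assert cost == pytest.approx(0.1 * 10 * 500 + np.ceil(10 * 500 * 10_000 / 4.1e8) * 1_000)


class TestSampleSizeForBudget:
    def test_worked_example(self):
        # per-sample cost 250 + 24.39 -> floor(10000 / 274.39) = 36
        n_s = sample_size_for_budget(10_000, 1_000, 10_000, TestExperimentCost.COST)
        assert n_s == 36

    def test_zero_budget(self):
        assert sample_size_for_budget(0, 1_000, 10_000, TestExperimentCost.COST) == 0

    def test_floor_consistency(self, rng):
        cm = TestExperimentCost.COST
        for _ in range(20):
            budget = float(rng.uniform(1_000, 100_000))
            n_c = int(rng.integers(100, 4_000))
            r = float(rng.uniform(5_000, 50_000))
            n_s = sample_size_for_budget(budget, n_c, r, cm)
            per = cm.kit_cost / (cm.lanes_per_kit * (cm.cells_loaded_per_lane // n_c)) + (
                n_c * r * cm.flowcell_cost / cm.reads_per_flowcell
            )
            assert n_s * per <= budget + 1e-9
            assert (n_s + 1) * per > budget


class TestCellTypeDetection:
    def test_certain_type(self):
        assert celltype_detection_probability(10, 5, 1.0, 3) == 1.0

    def test_binomial_tail_identity(self, rng):
        # NB CDF formulation equals P(Bin(n_c, f_c) >= n_cs) exactly
        for _ in range(50):
            n_c = int(rng.integers(5, 500))
            n_cs = int(rng.integers(1, min(n_c, 20) + 1))
            f_c = float(rng.uniform(0.01, 1.0))
            ours = celltype_detection_probability(n_c, n_cs, f_c, 1)
            binom_tail = float(stats.binom.sf(n_cs - 1, n_c, f_c))
            assert ours == pytest.approx(binom_tail, abs=1e-12)

    def test_worked_example(self):
        # P(Bin(10, 0.2) >= 2) = 1 - 0.8^10 - 10*0.2*0.8^9
        expected = 1 - 0.8**10 - 10 * 0.2 * 0.8**9
        assert celltype_detection_probability(10, 2, 0.2, 1) == pytest.approx(expected, abs=1e-12)

    def test_independent_individuals(self):
        single = celltype_detection_probability(100, 5, 0.1, 1)
        assert celltype_detection_probability(100, 5, 0.1, 7) == pytest.approx(single**7)

    def test_more_cells_needed_than_captured(self):
        assert celltype_detection_probability(5, 10, 0.5, 1) == 0.0

    def test_monotonicity(self):
        probs = [celltype_detection_probability(n_c, 10, 0.05, 4) for n_c in (200, 400, 800)]
        assert probs == sorted(probs)
        probs = [celltype_detection_probability(400, 10, 0.05, n_s) for n_s in (1, 4, 16)]
        assert probs == sorted(probs, reverse=True)


class TestMinCells:
    def test_certain_frequency(self):
        assert min_cells_for_detection(1.0, 10, 5, 0.99) == 10

    def test_minimality_contract(self):
        n_c = min_cells_for_detection(0.05, 10, 4, 0.9)
        assert celltype_detection_probability(n_c, 10, 0.05, 4) >= 0.9
        assert celltype_detection_probability(n_c - 1, 10, 0.05, 4) < 0.9

    def test_brute_force_agreement(self):
        f_c, n_cs, n_s, target = 0.3, 3, 2, 0.95
        expected = next(
            n_c for n_c in range(n_cs, 10_000)
            if celltype_detection_probability(n_c, n_cs, f_c, n_s) >= target
        )
        assert min_cells_for_detection(f_c, n_cs, n_s, target) == expected

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            min_cells_for_detection(0.1, 5, 2, 1.0)


class TestOptimizeDesign:
    @pytest.fixture
    def opt_args(self, cost_model, default_threshold):
        return dict(
            prior=make_prior(),
            effects=simulate_de_priors(n_genes=40, lfc_mean=1.0, lfc_sd=0.3, rank_max=8_000, seed=5),
            f_c=0.2,
            threshold=default_threshold,
            cost_model=cost_model,
            mt="fwer",
        )

    def test_single_point_consistency(self, opt_args, cost_model, default_threshold):
        table = optimize_design(
            20_000, cells_grid=[1_000], reads_grid=[10_000.0], **opt_args
        )
        assert len(table) == 1
        row = table.iloc[0]
        design = DesignPoint(n_s=int(row.n_s), n_c=1_000, r=10_000.0)
        ctx = make_cell_type_context(design, 0.2, cost_model)
        direct = overall_detection_power(
            opt_args["prior"], opt_args["effects"], ctx, design, default_threshold, mt="fwer"
        )
        assert row.overall_power == pytest.approx(direct.overall_power, rel=1e-12)

    def test_optimum_is_table_max(self, opt_args):
        table = optimize_design(
            15_000,
            cells_grid=[500, 1_000, 2_000],
            reads_grid=[5_000.0, 15_000.0, 30_000.0],
            **opt_args,
        )
        assert table.iloc[0].overall_power == table.overall_power.max()

    def test_budget_coupling_monotone(self, cost_model):
        # for fixed budget, increasing n_c weakly decreases the derived n_s
        n_cs = [500, 1_000, 2_000, 4_000]
        n_ss = [sample_size_for_budget(50_000, n_c, 20_000, cost_model) for n_c in n_cs]
        assert n_ss == sorted(n_ss, reverse=True)

    def test_infeasible_grid(self, opt_args):
        with pytest.raises(ValueError, match="feasible"):
            optimize_design(10.0, cells_grid=[1_000], reads_grid=[10_000.0], **opt_args)

    def test_samples_cells_grid_mode(self, opt_args):
        table = optimize_design(
            30_000,
            cells_grid=[1_000, 2_000],
            reads_grid=None,
            samples_grid=[8, 16],
            **opt_args,
        )
        assert set(table.n_s) <= {8, 16}
        assert np.all(table.r > 0)
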
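"""Space-use metrics: utilization distributions, isopleth areas, Hellinger
distances, site fidelity, distances and the behaviour-table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pentrack as pt
from conftest import make_trajectory
from pentrack.metrics import MetricsConfig, unit_behaviours
from pentrack.preprocess import segment_into_units


def uniform_ud(n_cells: int, cell_size: float = 1.0):
    mass = np.full((n_cells, 1), 1.0 / n_cells)
    return pt.UtilizationDistribution((0.0, 0.0), cell_size, mass)


class TestTotalDistance:
    def test_stationary_zero(self):
        tr = make_trajectory(np.ones(10), np.ones(10))
        assert pt.total_distance(tr) == 0.0

    def test_three_four_five(self):
        tr = make_trajectory([0, 3], [0, 4])
        assert pt.total_distance(tr) == pytest.approx(5.0)

    def test_square_path(self):
        tr = make_trajectory([0, 0, 1, 1, 0], [0, 1, 1, 0, 0])
        assert pt.total_distance(tr) == pytest.approx(4.0)

    def test_gap_steps_excluded(self):
        t = np.array([0.0, 1.0, 100.0, 101.0])
        tr = make_trajectory([0, 1, 5, 6], [0, 0, 0, 0], t=t)
        assert pt.total_distance(tr, gap_threshold_s=10) == pytest.approx(2.0)


class TestUD:
    def test_mass_conserved_and_nonnegative(self, pen):
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0], [6, 10], size=(500, 2))
        ud = pt.estimate_ud(pts, pen)
        assert abs(ud.mass.sum() - 1.0) < 1e-9
        assert (ud.mass >= 0).all()

    def test_point_mass_concentrates(self, pen):
        pts = np.tile([[3.0, 5.0]], (100, 1))
        ud = pt.estimate_ud(pts, pen, bandwidth_rule=0.2)
        core = pt.area_at_isopleth(ud, 0.5)
        assert core < 1.0  # tightly concentrated around one spot
        ud_wide = pt.estimate_ud(pts, pen, bandwidth_rule=0.6)
        assert pt.area_at_isopleth(ud_wide, 0.5) > core

    def test_uniform_points_give_near_uniform_ud(self, pen):
        # oracle: with a tiny bandwidth the UD is the normalized histogram
        rng = np.random.default_rng(1)
        pts = rng.uniform([0, 0], [6, 10], size=(200_000, 2))
        ud = pt.estimate_ud(pts, pen, cell_size=0.5, bandwidth_rule=0.01,
                            buffer_m=0.0)
        hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[12, 20],
                                    range=[[0, 6], [0, 10]])
        assert np.abs(ud.mass - hist / hist.sum()).max() < 1e-12
        occupied = ud.mass[ud.mass > 0]
        assert occupied.max() / occupied.min() < 1.5

    def test_mirror_symmetry(self, pen):
        rng = np.random.default_rng(2)
        half = rng.uniform([0.5, 1], [2.5, 4], size=(400, 2))
        mirrored = np.column_stack([6 - half[:, 0], 10 - half[:, 1]])
        pts = np.vstack([half, mirrored])
        ud = pt.estimate_ud(pts, pen, cell_size=0.5, bandwidth_rule=0.3,
                            buffer_m=0.0)
        assert np.allclose(ud.mass, ud.mass[::-1, ::-1], atol=1e-12)

    def test_too_few_points_rejected(self, pen):
        with pytest.raises(ValueError, match="at least"):
            pt.estimate_ud(np.zeros((3, 2)), pen)


class TestIsopleth:
    def test_uniform_ud_level_times_area(self):
        ud = uniform_ud(60)
        assert pt.area_at_isopleth(ud, 0.95) == pytest.approx(57.0)
        assert pt.area_at_isopleth(ud, 0.50) == pytest.approx(30.0)

    def test_cumulative_sum_example(self):
        ud = pt.UtilizationDistribution((0, 0), 1.0,
                                        np.array([[0.6, 0.3, 0.1]]))
        assert pt.area_at_isopleth(ud, 0.5) == pytest.approx(1.0)
        assert pt.area_at_isopleth(ud, 0.95) == pytest.approx(3.0)

    def test_level_validation(self):
        ud = uniform_ud(4)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                pt.area_at_isopleth(ud, bad)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 40), st.integers(0, 10_000))
    def test_monotone_in_level_and_core_below_total(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(n)).reshape(-1, 1)
        ud = pt.UtilizationDistribution((0, 0), 0.5, m)
        levels = [0.1, 0.3, 0.5, 0.8, 0.95]
        areas = [pt.area_at_isopleth(ud, lv) for lv in levels]
        assert all(a <= b for a, b in zip(areas, areas[1:]))


class TestHellinger:
    def test_identical_zero(self):
        ud = uniform_ud(10)
        assert pt.hellinger_distance(ud, ud) == pytest.approx(0.0, abs=1e-7)

    def test_disjoint_one(self):
        a = pt.UtilizationDistribution((0, 0), 1.0, np.array([[1.0, 0.0]]))
        b = pt.UtilizationDistribution((0, 0), 1.0, np.array([[0.0, 1.0]]))
        assert pt.hellinger_distance(a, b) == pytest.approx(1.0)

    def test_half_half_versus_point(self):
        a = pt.UtilizationDistribution((0, 0), 1.0, np.array([[0.5, 0.5]]))
        b = pt.UtilizationDistribution((0, 0), 1.0, np.array([[1.0, 0.0]]))
        assert pt.hellinger_distance(a, b) == pytest.approx(
            np.sqrt(1 - np.sqrt(0.5)), abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = uniform_ud(4)
        b = uniform_ud(5)
        with pytest.raises(ValueError):
            pt.hellinger_distance(a, b)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 10_000))
    def test_symmetry_range_and_identity(self, n, seed):
        rng = np.random.default_rng(seed)
        p = pt.UtilizationDistribution((0, 0), 1.0,
                                       rng.dirichlet(np.ones(n)).reshape(-1, 1))
        q = pt.UtilizationDistribution((0, 0), 1.0,
                                       rng.dirichlet(np.ones(n)).reshape(-1, 1))
        h = pt.hellinger_distance(p, q)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(pt.hellinger_distance(q, p))
        assert pt.hellinger_distance(p, p) == pytest.approx(0.0, abs=1e-7)


class TestSiteFidelity:
    def test_identical_days_full_similarity(self):
        ud = uniform_ud(6)
        assert pt.site_fidelity([ud, ud, ud]) == pytest.approx(1.0, abs=1e-7)

    def test_hand_mean_over_pairs(self):
        # three daily UDs engineered to have H12=x, H13=y, H23=z; the
        # similarity is 1 - mean(H) over the C(3,2) pairs
        a = pt.UtilizationDistribution((0, 0), 1.0, np.array([[1.0, 0, 0]]))
        b = pt.UtilizationDistribution((0, 0), 1.0, np.array([[0.0, 1, 0]]))
        c = pt.UtilizationDistribution((0, 0), 1.0, np.array([[0.5, 0.5, 0]]))
        h_ab = 1.0
        h_ac = np.sqrt(1 - np.sqrt(0.5))
        h_bc = np.sqrt(1 - np.sqrt(0.5))
        expected = 1 - np.mean([h_ab, h_ac, h_bc])
        assert pt.site_fidelity([a, b, c]) == pytest.approx(expected)
        assert pt.site_fidelity([a, b, c], "distance") == pytest.approx(
            1 - expected)

    def test_needs_two_days(self):
        with pytest.raises(ValueError):
            pt.site_fidelity([uniform_ud(3)])


class TestFeederTime:
    def test_no_points_inside(self, pen):
        tr = make_trajectory(np.full(50, 5.0), np.full(50, 9.0))
        assert pt.feeder_time(tr, pen) == 0.0

    def test_counts_seconds_at_one_hz(self, pen):
        x = np.concatenate([np.full(120, 1.0), np.full(60, 5.0)])
        y = np.concatenate([np.full(120, 1.0), np.full(60, 9.0)])
        tr = make_trajectory(x, y)
        assert pt.feeder_time(tr, pen) == pytest.approx(2.0)

    def test_frequency_scaling(self, pen):
        x = np.full(120, 1.0)
        tr = make_trajectory(x, x, hz=2.0)
        assert pt.feeder_time(tr, pen) == pytest.approx(1.0)

    def test_boundary_points_count_as_inside(self, pen):
        tr = make_trajectory([1.5, 0.0], [3.0, 0.0])  # on the feeder edge
        assert pt.feeder_time(tr, pen) == pytest.approx(2 / 60)


@pytest.fixture(scope="module")
def tiny_bundle(pen):
    cfg = pt.TrajectorySimConfig(n_individuals=4, days=9, hz=0.02, seed=42)
    trajs = pt.simulate_trajectories(cfg)
    cov = pd.DataFrame({
        "individual_id": [t.individual_id for t in trajs],
        "cohort": [1, 1, 2, 2],
        "sex": ["F", "M", "F", "F"],
        "breed": ["HF", "HF", "HFxBB", "HF"],
        "birth_day": [-30, -40, -25, -35],
        "step_down_day": [6, 6, np.nan, 6],
        "weaned_day": [8, 8, np.nan, 8],
        "treatment_days": [np.nan, "2", np.nan, "-2"],
    })
    temp = pd.DataFrame({"day": np.arange(10),
                         "temperature_C": np.linspace(8, 12, 10)})
    mcfg = MetricsConfig(drop_first_day=True, cell_size=0.25,
                         min_points=5, daily_coverage_min=0.1,
                         unit_coverage_min=0.1)
    return trajs, cov, temp, mcfg


class TestBehaviourTable:
    def test_row_count_and_columns(self, pen, tiny_bundle):
        trajs, cov, temp, mcfg = tiny_bundle
        table = pt.build_behaviour_table(trajs, cov, pen, temp, mcfg)
        # 9 days, first dropped -> 2 complete 4-day units per individual
        assert len(table) == 8
        for col in pt.BEHAVIOURS:
            assert col in table.columns
        assert (table["core_area_m2"] <= table["total_area_m2"] + 1e-9).all()
        assert table["site_fidelity"].between(0, 1).all()
        assert (table["distance_m"] >= 0).all()

    def test_health_status_coding(self, pen, tiny_bundle):
        trajs, cov, temp, mcfg = tiny_bundle
        table = pt.build_behaviour_table(trajs, cov, pen, temp, mcfg)
        by = table.set_index(["individual_id", "unit_index"])
        # treatment on day 2 (unit 0 = days 1-4) -> sick during unit 0
        assert by.loc[("calf_002", 0), "health_status"] == "sick"
        # treatment on day -2: days -2..0 precede unit 0, days +1..+3
        # reach day 1 -> convalescent in unit 0
        assert by.loc[("calf_004", 0), "health_status"] == "convalescent"
        assert by.loc[("calf_001", 0), "health_status"] == "healthy"

    def test_weaning_stage_coding(self, pen, tiny_bundle):
        trajs, cov, temp, mcfg = tiny_bundle
        table = pt.build_behaviour_table(trajs, cov, pen, temp, mcfg)
        by = table.set_index(["individual_id", "unit_index"])
        assert by.loc[("calf_001", 0), "weaning_stage"] == "not_weaning"
        # unit 1 = days 5-8: step-down from day 6, weaned day 8
        assert by.loc[("calf_001", 1), "weaning_stage"] == "step_down"
        assert by.loc[("calf_003", 1), "weaning_stage"] == "not_weaning"

    def test_missing_covariates_dropped(self, pen, tiny_bundle):
        trajs, cov, temp, mcfg = tiny_bundle
        table = pt.build_behaviour_table(trajs, cov.iloc[:2], pen, temp, mcfg)
        assert set(table["individual_id"]) == {"calf_001", "calf_002"}

    def test_low_coverage_day_skips_site_fidelity(self, pen):
        # one day with almost no samples must not enter the daily UDs
        rng = np.random.default_rng(3)
        t = np.concatenate([np.arange(0, 4 * 86400, 600.0),
                            np.array([4 * 86400 + 10.0])])
        x = rng.uniform(0.5, 5.5, len(t))
        y = rng.uniform(0.5, 9.5, len(t))
        tr = pt.Trajectory("c", t, x, y, nominal_hz=1 / 600)
        (unit,) = segment_into_units(tr, 5)
        rec = unit_behaviours(unit, pt.PenGeometry.default(),
                              MetricsConfig(min_points=5,
                                            daily_coverage_min=0.5))
        assert np.isfinite(rec["site_fidelity"])  # 4 good days remain
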
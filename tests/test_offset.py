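"""Offset engines: RONA closed forms, gradient-forest turnover recovery
and invariants, GDM fitting/self-consistency, and the brute-force
forward/reverse oracle with spherical geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from landgen.distmat import DistanceMatrix
from landgen.envtable import EnvTable
from landgen.grids import ClimateGrid, haversine_km
from landgen.offset import (
    GFModel,
    gdm_fit,
    gdm_offsets,
    gf_fit,
    gf_offset,
    gf_rgb_map,
    offset_rgb,
    predict_dissimilarity,
    rona,
)
from landgen.offset.gf import TurnoverFunction
from landgen.offset.gdm import ispline_basis
from landgen.popgen import frequency_distance
from landgen.synthdata import (
    SimulationConfig,
    individual_env_table,
    population_env_table,
    simulate_scenario,
)


def pop_env_tables(g, cur, fut, truth):
    env = population_env_table(g, cur, truth)
    delta = fut.layers[:, 0, 0] - cur.layers[:, 0, 0]
    fenv = EnvTable(env.data + delta, dict(env.categories), scaled=True)
    return env, fenv


# ----------------------------------------------------------------- RONA


class TestRona:
    def test_zero_delta_gives_zero(self, small_scenario):
        _, g, truth, cur, fut = small_scenario
        env = population_env_table(g, cur, truth)
        res = rona(g, env, env, {"env1": truth.adaptive_locus_ids})
        assert np.all(res.rona.to_numpy() == 0.0)

    def test_single_locus_closed_form(self, small_scenario):
        _, g, truth, cur, fut = small_scenario
        env, fenv = pop_env_tables(g, cur, fut, truth)
        lid = truth.adaptive_locus_ids[0]
        res = rona(g, env, fenv, {"env1": [lid]})
        slope = res.per_locus.loc[("env1", lid), "slope"]
        delta = (fenv.data["env1"] - env.data["env1"]).to_numpy()
        np.testing.assert_allclose(
            res.rona["env1"].to_numpy(), np.abs(slope) * np.abs(delta), atol=1e-12
        )

    def test_weights_sum_to_one_per_variable(self, small_scenario):
        _, g, truth, cur, fut = small_scenario
        env, fenv = pop_env_tables(g, cur, fut, truth)
        res = rona(g, env, fenv, {"env1": truth.adaptive_locus_ids})
        assert res.weights.groupby("variable")["weight"].sum()["env1"] == pytest.approx(1.0)

    def test_matches_ground_truth_mean_frequency_change(self):
        """Weighted RONA for the driving variable tracks the generator's
        true mean |delta p| at the population cells within +-20%."""
        ratios = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            g, truth, cur, fut = simulate_scenario(cfg)
            env, fenv = pop_env_tables(g, cur, fut, truth)
            res = rona(g, env, fenv, {"env1": truth.adaptive_locus_ids})
            est = res.rona["env1"].mean()
            true = truth.true_cell_offset.ravel()[np.array(truth.pop_cells)].mean()
            ratios.append(est / true)
        assert all(0.8 <= r <= 1.2 for r in ratios)

    def test_variable_without_loci_excluded(self, small_scenario):
        _, g, truth, cur, fut = small_scenario
        env, fenv = pop_env_tables(g, cur, fut, truth)
        with pytest.warns(UserWarning, match="env2"):
            res = rona(g, env, fenv, {"env1": truth.adaptive_locus_ids[:3], "env2": []})
        assert list(res.rona.columns) == ["env1"]

    def test_top_variables_ranked_by_locus_count(self, small_scenario):
        _, g, truth, cur, fut = small_scenario
        env, fenv = pop_env_tables(g, cur, fut, truth)
        sig = {"env1": truth.adaptive_locus_ids, "env2": truth.adaptive_locus_ids[:2]}
        res = rona(g, env, fenv, sig)
        assert res.top_variables[0] == "env1"


# ------------------------------------------------------- gradient forest


@pytest.fixture(scope="module")
def gf_scenario():
    cfg = SimulationConfig(grid_rows=20, grid_cols=20, n_pops=16, n_ind_per_pop=8,
                           n_neutral=100, n_adaptive=25, beta=2.0, seed=8)
    g, truth, cur, fut = simulate_scenario(cfg)
    ga = g.subset_loci(np.arange(100, 125))
    env = individual_env_table(g, cur, truth)
    model = gf_fit(ga, env, n_trees=100, seed=8)
    return g, ga, truth, cur, fut, env, model


class TestGradientForest:
    def test_driving_variable_dominates_importance(self, gf_scenario):
        *_, model = gf_scenario
        assert model.importance["env1"] >= 0.5
        assert model.importance.idxmax() == "env1"

    def test_turnover_non_decreasing_and_bounded(self, gf_scenario):
        *_, model = gf_scenario
        xs = np.linspace(-4, 4, 200)
        for v in model.variables:
            f = model.turnover[v](xs)
            assert np.all(np.diff(f) >= -1e-12)
            assert f[0] == 0.0 and f[-1] <= model.turnover[v].total + 1e-12

    def test_permuted_environment_destroys_signal(self, gf_scenario):
        g, ga, truth, cur, fut, env, model = gf_scenario
        rng = np.random.default_rng(0)
        shuffled = EnvTable(
            pd.DataFrame(rng.permutation(env.values()), index=env.data.index,
                         columns=env.variables), dict(env.categories), env.scaled)
        total = model.locus_r2.sum()
        try:
            perm_model = gf_fit(ga, shuffled, n_trees=100, seed=8)
            perm_total = perm_model.locus_r2.sum()
        except RuntimeError:  # every locus below the R^2 floor
            perm_total = 0.0
        assert total >= 5.0 * max(perm_total, 1e-12) or perm_total == 0.0

    def test_offset_zero_when_future_equals_current(self, gf_scenario):
        *_, cur, fut, env, model = gf_scenario[2:]
        off = gf_offset(model, cur, cur.copy(scenario="future"))
        assert np.all(off[cur.mask] == 0.0)

    def test_offset_monotone_in_shift_of_top_variable(self, gf_scenario):
        g, ga, truth, cur, fut, env, model = gf_scenario
        top = int(np.argmax([model.importance[v] for v in model.variables]))
        prev = np.zeros(cur.shape)[cur.mask]
        for delta in (0.5, 1.0, 2.0):
            shifted = cur.copy(scenario="future")
            shifted.layers[top] = shifted.layers[top] + delta
            off = gf_offset(model, cur, shifted)[cur.mask]
            assert np.all(off >= prev - 1e-12)
            prev = off

    def test_toy_turnover_hand_computed(self):
        """3x3 grid with hand-specified step turnover functions: offsets
        must equal hand-computed Euclidean distances."""
        t1 = TurnoverFunction(np.array([0.5]), np.array([0.3]))  # 0 below 0.5, then 0.3
        t2 = TurnoverFunction(np.array([1.0, 2.0]), np.array([0.1, 0.25]))
        model = GFModel(["a", "b"], {"a": t1, "b": t2}, pd.Series({"a": 0.6, "b": 0.4}),
                        pd.Series(dtype=float), n_trees=1, max_depth=1)
        cur_a = np.array([[0.0, 0.4, 0.6], [0.0, 0.6, 0.6], [0.4, 0.4, 0.6]])
        cur_b = np.array([[0.5, 1.5, 2.5], [0.5, 0.5, 1.5], [2.5, 2.5, 0.5]])
        fut_a = cur_a + 0.2
        fut_b = cur_b + 1.0
        cur = ClimateGrid(["a", "b"], np.stack([cur_a, cur_b]))
        fut = ClimateGrid(["a", "b"], np.stack([fut_a, fut_b]), scenario="future")
        off = gf_offset(model, cur, fut)
        for i in range(3):
            for j in range(3):
                da = t1(np.array([fut_a[i, j]]))[0] - t1(np.array([cur_a[i, j]]))[0]
                db = t2(np.array([fut_b[i, j]]))[0] - t2(np.array([cur_b[i, j]]))[0]
                assert off[i, j] == pytest.approx(np.hypot(da, db), abs=1e-12)

    def test_rgb_map_channels(self, gf_scenario):
        *_, cur, fut, env, model = gf_scenario[2:]
        rgb = gf_rgb_map(model, cur)
        vals = rgb[cur.mask]
        assert rgb.shape == cur.shape + (3,)
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0

    def test_rgb_constant_grid_single_color(self):
        t = TurnoverFunction(np.array([0.0]), np.array([1.0]))
        model = GFModel(["a", "b", "c"], {"a": t, "b": t, "c": t},
                        pd.Series({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}),
                        pd.Series(dtype=float), 1, 1)
        grid = ClimateGrid(["a", "b", "c"], np.ones((3, 4, 4)))
        with pytest.warns(UserWarning):
            rgb = gf_rgb_map(model, grid)
        for ch in range(3):
            plane = rgb[..., ch]
            assert np.nanstd(plane) == pytest.approx(0.0, abs=1e-12)

    def test_offset_tracks_ground_truth(self, gf_scenario):
        g, ga, truth, cur, fut, env, model = gf_scenario
        off = gf_offset(model, cur, fut)
        rho = stats.spearmanr(off[cur.mask], truth.true_cell_offset[cur.mask]).statistic
        assert rho >= 0.5


# ------------------------------------------------------------------ GDM


class TestIsplineBasis:
    def test_monotone_zero_to_one(self):
        knots = np.array([0.0, 0.4, 1.0])
        xs = np.linspace(0, 1, 101)
        basis = ispline_basis(xs, knots, 3)
        assert basis.shape == (101, 3)
        assert np.all(np.diff(basis, axis=0) >= -1e-12)
        np.testing.assert_allclose(basis[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(basis[-1], 1.0, atol=1e-12)

    def test_out_of_range_clamped(self):
        knots = np.array([0.0, 0.5, 1.0])
        basis = ispline_basis(np.array([-5.0, 5.0]), knots, 3)
        np.testing.assert_allclose(basis[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(basis[1], 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def gdm_scenario():
    cfg = SimulationConfig(grid_rows=15, grid_cols=15, n_pops=16, n_ind_per_pop=8,
                           n_neutral=100, n_adaptive=30, beta=1.5, seed=4)
    g, truth, cur, fut = simulate_scenario(cfg)
    gen = frequency_distance(g, truth.adaptive_locus_ids)
    env = population_env_table(g, cur, truth)
    model = gdm_fit(gen, env, g.population_coords())
    return g, truth, cur, fut, gen, env, model


class TestGdm:
    def test_identical_environments_give_constant_prediction(self, rng):
        n = 8
        labels = [f"s{i}" for i in range(n)]
        env = EnvTable(pd.DataFrame({"v": np.ones(n)}, index=labels))
        vals = np.abs(rng.normal(0.2, 0.05, (n, n)))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        model = gdm_fit(DistanceMatrix(labels, vals), env, coords=None)
        assert np.all(model.coefs["v"] == 0.0)
        pred = predict_dissimilarity(model, np.ones((3, 1)), np.ones((3, 1)))
        np.testing.assert_allclose(pred, 1 - np.exp(-model.intercept), atol=1e-12)

    def test_coefficients_nonnegative(self, gdm_scenario):
        *_, model = gdm_scenario
        assert model.intercept >= 0.0
        for v, c in model.coefs.items():
            assert np.all(c >= 0.0)

    def test_prediction_monotone_in_site_difference(self, gdm_scenario):
        *_, model = gdm_scenario
        base = np.zeros((1, 5))
        prev = -1.0
        for step in np.linspace(0.0, 2.0, 9):
            other = base.copy()
            other[0, 0] = step
            d = predict_dissimilarity(model, base, other)[0]
            assert d >= prev - 1e-12
            prev = d

    def test_self_consistency_recovery(self, rng):
        """Dissimilarities generated from a known single-predictor GDM are
        recovered: deviance explained >= 95% and RMSE <= 0.02."""
        n = 14
        labels = [f"s{i}" for i in range(n)]
        x = np.sort(rng.uniform(0, 10, n))
        env = EnvTable(pd.DataFrame({"v": x}, index=labels))
        knots = np.quantile(x, [0, 0.5, 1])
        basis = ispline_basis(x, knots, 3)
        coef = np.array([0.4, 0.8, 0.3])
        iu = np.triu_indices(n, 1)
        eta = 0.05 + np.abs(basis[iu[0]] - basis[iu[1]]) @ coef
        y = 1 - np.exp(-eta)
        vals = np.zeros((n, n))
        vals[iu] = y
        vals += vals.T
        model = gdm_fit(DistanceMatrix(labels, vals), env, coords=None)
        pred = predict_dissimilarity(model, x[iu[0]][:, None], x[iu[1]][:, None])
        assert model.deviance_explained >= 0.95
        assert np.sqrt(((pred - y) ** 2).mean()) <= 0.02

    def test_negative_dissimilarity_rejected(self, rng):
        labels = [f"s{i}" for i in range(6)]
        vals = np.zeros((6, 6))
        vals[0, 1] = vals[1, 0] = -0.1
        env = EnvTable(pd.DataFrame({"v": rng.normal(size=6)}, index=labels))
        with pytest.raises(ValueError):
            gdm_fit(DistanceMatrix(labels, vals), env, coords=None)

    def test_too_few_sites_rejected(self, rng):
        labels = [f"s{i}" for i in range(4)]
        vals = np.abs(rng.normal(0.2, 0.02, (4, 4)))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        env = EnvTable(pd.DataFrame({"v": rng.normal(size=4)}, index=labels))
        with pytest.raises(ValueError):
            gdm_fit(DistanceMatrix(labels, vals), env, coords=None)


class TestGdmOffsets:
    def test_null_scenario_all_zero(self, gdm_scenario):
        g, truth, cur, fut, gen, env, model = gdm_scenario
        surf = gdm_offsets(model, cur, cur.copy(scenario="future"))
        m = cur.mask
        assert np.all(surf.local[m] == 0.0)
        assert np.all(surf.forward[m] == 0.0)
        assert np.all(surf.reverse[m] == 0.0)
        assert np.all(surf.distance_km[m] == 0.0)

    def test_forward_and_reverse_bounded_by_local(self, gdm_scenario):
        g, truth, cur, fut, gen, env, model = gdm_scenario
        surf = gdm_offsets(model, cur, fut)
        m = cur.mask
        assert np.all(surf.forward[m] <= surf.local[m] + 1e-12)
        assert np.all(surf.reverse[m] <= surf.local[m] + 1e-12)
        # distance is zero iff the focal cell is its own best target
        stay = surf.forward_target[m] == np.flatnonzero(m.ravel())
        assert np.array_equal(surf.distance_km[m] == 0.0, stay)

    def test_matches_exhaustive_double_loop_oracle(self, gdm_scenario):
        *_, model = gdm_scenario
        rng = np.random.default_rng(2)
        cur = ClimateGrid([f"env{i+1}" for i in range(5)], rng.normal(size=(5, 3, 3)),
                          lat0=24.0, lon0=121.0, cell_size=0.1)
        fut = ClimateGrid(cur.variables, cur.layers + rng.normal(0.5, 0.3, size=(5, 3, 3)),
                          lat0=24.0, lon0=121.0, cell_size=0.1, scenario="future")
        surf = gdm_offsets(model, cur, fut)
        t_cur = model.transform_env(cur.env_at_cells(np.arange(9)))
        t_fut = model.transform_env(fut.env_at_cells(np.arange(9)))
        for i in range(9):
            fwd = min(1 - np.exp(-np.abs(t_cur[i] - t_fut[j]).sum()) for j in range(9))
            rev = min(1 - np.exp(-np.abs(t_fut[i] - t_cur[j]).sum()) for j in range(9))
            r, c = divmod(i, 3)
            assert surf.forward[r, c] == pytest.approx(fwd, abs=1e-12)
            assert surf.reverse[r, c] == pytest.approx(rev, abs=1e-12)

    def test_bearing_due_north_target(self, gdm_scenario):
        """A forced move to the cell due north must report bearing ~0."""
        *_, model = gdm_scenario
        # 2x1 grid: focal cell is the southern one, target the northern one
        cur_layers = np.zeros((5, 2, 1))
        fut_layers = np.full((5, 2, 1), 3.0)
        fut_layers[:, 0, 0] = 0.0  # northern cell keeps the current climate
        cur = ClimateGrid([f"env{i+1}" for i in range(5)], cur_layers, lat0=24.0,
                          lon0=121.0, cell_size=0.1)
        fut = ClimateGrid(cur.variables, fut_layers, lat0=24.0, lon0=121.0,
                          cell_size=0.1, scenario="future")
        surf = gdm_offsets(model, cur, fut)
        assert surf.forward_target[1, 0] == 0  # flat index of the northern cell
        assert surf.bearing_deg[1, 0] == pytest.approx(0.0, abs=0.5)
        expected_km = haversine_km(23.9, 121.0, 24.0, 121.0)
        assert surf.distance_km[1, 0] == pytest.approx(expected_km, rel=1e-6)

    def test_local_offset_tracks_ground_truth(self, gdm_scenario):
        g, truth, cur, fut, gen, env, model = gdm_scenario
        surf = gdm_offsets(model, cur, fut)
        rho = stats.spearmanr(surf.local[cur.mask], truth.true_cell_offset[cur.mask]).statistic
        assert rho >= 0.5

    def test_offset_monotone_in_delta(self, gdm_scenario):
        g, truth, cur, fut, gen, env, model = gdm_scenario
        prev = np.zeros(cur.shape)[cur.mask]
        for delta in (0.5, 1.0, 2.0):
            shifted = cur.copy(scenario="future")
            shifted.layers[0] = shifted.layers[0] + delta
            surf = gdm_offsets(model, cur, shifted)
            off = surf.local[cur.mask]
            assert np.all(off >= prev - 1e-12)
            prev = off

    def test_rgb_composite_in_unit_range(self, gdm_scenario):
        g, truth, cur, fut, gen, env, model = gdm_scenario
        surf = gdm_offsets(model, cur, fut)
        rgb = offset_rgb(surf)
        vals = rgb[cur.mask]
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0

    def test_table_export_roundtrip(self, gdm_scenario, tmp_path):
        g, truth, cur, fut, gen, env, model = gdm_scenario
        surf = gdm_offsets(model, cur, fut)
        surf.write(tmp_path)
        table = pd.read_csv(tmp_path / "offset_table.csv")
        assert len(table) == int(cur.mask.sum())
        assert {"local", "forward", "reverse", "distance_km", "bearing_deg"} <= set(table.columns)
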
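"""RFTI / RFDTI: thresholds, stopping rule, person-fit index, grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfdti.dina_core import QMatrix, ResponseMatrix, fit_dina_em
from rfdti.rf_threshold_imputation import (
    RFConfig,
    ThresholdGrid,
    ThresholdPair,
    _StoppingReplay,
    delta,
    initial_impute,
    iterate_impute,
    order_variables,
    rci_c_mean,
    rci_c_person,
    rci_c_report,
    rfdti,
    rfti,
    select_thresholds,
    threshold_map,
)

RF_FAST = RFConfig(n_trees=25)


class TestInitialImpute:
    def test_item_mean_rounding(self):
        values = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 0], [1, 0], [np.nan, np.nan]], dtype=float
        )
        out = initial_impute(ResponseMatrix(values))
        assert out[5, 0] == 1.0  # observed mean 1.0
        assert out[5, 1] == 0.0  # observed mean 0.2
        assert not np.isnan(out).any()

    def test_complete_matrix_unchanged(self):
        values = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.array_equal(initial_impute(ResponseMatrix(values)), values)

    def test_all_na_column_rejected(self):
        with pytest.raises(ValueError):
            initial_impute(ResponseMatrix(np.array([[np.nan, 1.0], [np.nan, 0.0]])))


class TestOrderVariables:
    def test_ascending_with_ties_and_skips(self):
        values = np.ones((5, 3))
        values[:3, 0] = np.nan  # 3 NA
        values[0, 2] = np.nan  # 1 NA; item 1 complete
        order = order_variables(ResponseMatrix(values))
        assert order.tolist() == [2, 0]

    def test_no_missing_items_empty(self):
        assert order_variables(ResponseMatrix(np.ones((3, 2)))).size == 0


class TestThresholdMap:
    @pytest.mark.parametrize(
        "p, tau_l, tau_u, expected",
        [
            (0.97, 0.30, 0.95, 1.0),
            (0.50, 0.30, 0.70, np.nan),
            (0.50, 0.50, 0.70, 0.0),  # RFTI branch: p <= 0.5 -> 0
            (0.50, 0.30, 0.50, 1.0),  # upper boundary is >=
        ],
    )
    def test_boundaries(self, p, tau_l, tau_u, expected):
        got = threshold_map(p, ThresholdPair(tau_l, tau_u))
        assert np.isnan(got) if np.isnan(expected) else got == expected

    def test_brute_force_over_dense_grid(self):
        p = np.linspace(0.0, 1.0, 201)
        for pair in ThresholdGrid(step=0.05, mode="RFDTI").pairs:
            mapped = threshold_map(p, pair)
            for pi, mi in zip(p, mapped):
                if pi >= pair.tau_u:
                    assert mi == 1.0
                elif pi <= pair.tau_l:
                    assert mi == 0.0
                else:
                    assert np.isnan(mi)

    def test_raising_tau_u_never_imputes_more_ones(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        for tau_l in (0.1, 0.3, 0.5):
            ones = [
                np.nansum(threshold_map(p, ThresholdPair(tau_l, tu)) == 1.0)
                for tu in (0.5, 0.6, 0.7, 0.8, 0.9)
            ]
            assert (np.diff(ones) <= 0).all()


class TestThresholdGrid:
    def test_rfti_grid_fixes_lower_threshold(self):
        grid = ThresholdGrid(step=0.05, mode="RFTI")
        assert all(pair.tau_l == 0.5 for pair in grid.pairs)
        assert grid.tau_u_values[0] == 0.5 and grid.tau_u_values[-1] < 1.0

    def test_rfdti_grid_ranges(self):
        grid = ThresholdGrid(step=0.05, mode="RFDTI")
        assert grid.tau_l_values.min() == pytest.approx(0.05)
        assert grid.tau_l_values.max() < 0.5
        assert len(grid.pairs) == 9 * 10


class TestDelta:
    def test_hand_counts(self):
        mask = np.zeros((2, 5), dtype=bool)
        mask[0, :5] = True
        mask[1, :5] = True
        old = np.zeros((2, 5))
        new = old.copy()
        assert delta(new, old, mask) == 0.0
        new[0, 0] = 1.0
        assert delta(new, old, mask) == pytest.approx(0.1)
        assert delta(1 - old, old, mask) == 1.0

    def test_na_transition_counts_as_change(self):
        mask = np.array([[True, True]])
        old = np.array([[0.0, 1.0]])
        new = np.array([[np.nan, 1.0]])
        assert delta(new, old, mask) == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            delta(np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_on_random_state_matrices(self, seed):
        rng = np.random.default_rng(seed)
        shape = (6, 7)
        mask = rng.random(shape) < 0.5
        if not mask.any():
            mask[0, 0] = True
        draw = lambda: rng.choice([0.0, 1.0, np.nan], size=shape)
        old, new = draw(), draw()
        brute = sum(
            1
            for i in range(shape[0])
            for j in range(shape[1])
            if mask[i, j]
            and (
                np.isnan(new[i, j]) != np.isnan(old[i, j])
                or (not np.isnan(new[i, j]) and new[i, j] != old[i, j])
            )
        )
        assert delta(new, old, mask) == pytest.approx(brute / mask.sum())


class TestStoppingRule:
    def _matrix(self):
        values = np.ones((4, 3))
        values[0, 0] = values[1, 1] = values[2, 2] = values[3, 0] = 0.0
        values[0, 1] = values[1, 0] = np.nan
        return ResponseMatrix(values)

    def test_delta_increase_returns_previous_candidate(self):
        # initial item-mean fill puts (1, 0) at the two masked cells
        x = self._matrix()
        replay = _StoppingReplay(x, ThresholdPair(0.3, 0.7))
        mask = x.mask.astype(bool)
        probs = np.full(x.values.shape, np.nan)
        probs[mask] = [0.9, 0.9]  # candidate 1 = (1, 1): delta 0.5
        assert not replay.feed(probs)
        cand1 = replay.prev.copy()
        probs[mask] = [0.1, 0.1]  # candidate 2 = (0, 0): delta 1.0 > 0.5 -> revert
        assert replay.feed(probs)
        assert replay.delta_trace == [0.5, 1.0]
        assert np.array_equal(replay.finalize(), cand1)

    def test_zero_delta_stops_and_returns_current(self):
        x = self._matrix()
        replay = _StoppingReplay(x, ThresholdPair(0.3, 0.7))
        mask = x.mask.astype(bool)
        probs = np.full(x.values.shape, np.nan)
        probs[mask] = [0.9, 0.9]  # delta 0.5
        assert not replay.feed(probs)
        probs[mask] = [0.9, 0.1]  # delta 0.5 (equal, not an increase)
        assert not replay.feed(probs)
        assert replay.feed(probs)  # identical again -> delta 0, stop
        assert replay.delta_trace == [0.5, 0.5, 0.0]
        out = replay.finalize()
        assert out[mask].tolist() == [1.0, 0.0]


class TestIterateImpute:
    def test_invariants_and_determinism(self, wide_complete):
        data, q, *_ = wide_complete
        from rfdti.missingness import apply_mcar, select_subsample

        sub = select_subsample(data.n_examinees, 0.8, seed=1)
        missing = apply_mcar(data, 0.2, sub, seed=2)
        pair = ThresholdPair(0.3, 0.7)
        out1 = iterate_impute(missing, pair, RF_FAST, seed=3)
        out2 = iterate_impute(missing, pair, RF_FAST, seed=3)
        assert np.array_equal(out1.values, out2.values, equal_nan=True)
        # observed cells unchanged; NA only where originally missing
        obs = ~np.isnan(missing.values)
        assert np.array_equal(out1.values[obs], missing.values[obs])
        assert not (np.isnan(out1.values) & obs).any()

    def test_requires_missing_cells(self, wide_complete):
        data, *_ = wide_complete
        with pytest.raises(ValueError):
            iterate_impute(data, ThresholdPair(0.3, 0.7), RF_FAST, seed=4)


class TestRciC:
    def test_consistent_rows_score_zero(self, identifiable_q):
        profile = np.array([1, 1, 1])
        eta = np.ones(identifiable_q.n_items)
        s = np.full(identifiable_q.n_items, 0.1)
        g = np.full(identifiable_q.n_items, 0.2)
        assert rci_c_person(eta, profile, identifiable_q, s, g) == 0.0

    def test_hand_computed_single_item_cases(self):
        q = QMatrix(np.array([[1]]))
        # Y=1 while the profile's ideal response is 0, P = g = 0.2
        val = rci_c_person(np.array([1.0]), np.array([0]), q, np.array([0.1]), np.array([0.2]))
        assert val == pytest.approx(np.log(4), abs=1e-9)
        # Y=0 while the ideal response is 1, P = 1 - s = 0.9
        val = rci_c_person(np.array([0.0]), np.array([1]), q, np.array([0.1]), np.array([0.2]))
        assert val == pytest.approx(np.log(9), abs=1e-9)

    def test_missing_items_excluded_from_m_i(self):
        q = QMatrix(np.array([[1], [1]]))
        row = np.array([1.0, np.nan])
        val = rci_c_person(row, np.array([0]), q, np.array([0.1, 0.1]), np.array([0.2, 0.2]))
        assert val == pytest.approx(np.log(4))  # m_i = 1

    def test_mean_definition(self):
        assert rci_c_mean(np.array([0.0, np.log(4)])) == pytest.approx(np.log(4) / 2)
        with pytest.raises(ValueError):
            rci_c_mean(np.array([np.nan]))

    def test_report_matches_per_person_loop(self, small_missing):
        data, q, *_ = small_missing
        fit = fit_dina_em(data, q)
        report = rci_c_report(
            data.values, fit.map_profiles, q, fit.item_params.s, fit.item_params.g
        )
        for i in range(0, data.n_examinees, 17):
            expected = rci_c_person(
                data.values[i], fit.map_profiles[i], q, fit.item_params.s, fit.item_params.g
            )
            assert report.rci_per_person[i] == pytest.approx(expected)
        assert report.rci_mean == pytest.approx(rci_c_mean(report.rci_per_person))


@pytest.fixture(scope="module")
def missing_30(wide_complete):
    data, q, *_ = wide_complete
    from rfdti.missingness import apply_mcar, select_subsample

    sub = select_subsample(data.n_examinees, 0.8, seed=40)
    return apply_mcar(data, 0.2, sub, seed=41), q


class TestSelectThresholds:
    def test_single_combination_grid(self, missing_30):
        missing, q = missing_30
        grid = ThresholdGrid(step=0.45, mode="RFTI")  # tau_u values {0.5, 0.95}
        result = select_thresholds(missing, q, grid, RF_FAST, seed=42)
        assert result.thresholds in [p for p in grid.pairs]
        assert len(result.grid_table) == len(grid.pairs)

    def test_rci_mean_is_grid_minimum_and_self_consistent(self, missing_30):
        missing, q = missing_30
        result = rfti(missing, q, stepV=0.1, rf_config=RF_FAST, seed=43)
        ok = result.grid_table[result.grid_table["ok"]]
        assert result.rci_mean == pytest.approx(ok["rci_mean"].min())
        # recomputing RCI from the returned matrix and a fresh fit agrees
        refit = fit_dina_em(result.imputed, q)
        report = rci_c_report(
            result.imputed.values, refit.map_profiles, q,
            refit.item_params.s, refit.item_params.g,
        )
        assert report.rci_mean == pytest.approx(result.rci_mean, abs=1e-9)

    def test_rfdti_with_fixed_lower_equals_rfti_bit_exact(self, missing_30):
        missing, q = missing_30
        a = rfti(missing, q, stepV=0.1, rf_config=RF_FAST, seed=44)
        b = select_thresholds(
            missing, q, ThresholdGrid(step=0.1, mode="RFTI"), RF_FAST, seed=44
        )
        assert a.thresholds == b.thresholds
        assert np.array_equal(a.imputed.values, b.imputed.values, equal_nan=True)
        assert a.rci_mean == b.rci_mean

    def test_iterate_impute_agrees_with_shared_trace(self, missing_30):
        # the grid search replays the same trace each pair would see alone
        missing, q = missing_30
        result = rfdti(missing, q, stepV=0.2, rf_config=RF_FAST, seed=45)
        alone = iterate_impute(missing, result.thresholds, RF_FAST, seed=45)
        assert np.array_equal(result.imputed.values, alone.values, equal_nan=True)

    def test_observed_cells_never_altered(self, missing_30):
        missing, q = missing_30
        result = rfdti(missing, q, stepV=0.2, rf_config=RF_FAST, seed=46)
        obs = ~np.isnan(missing.values)
        assert np.array_equal(result.imputed.values[obs], missing.values[obs])

    def test_multi_grid_matches_separate_runs(self, missing_30):
        # both grids against one shared trace == two independent grid searches
        from rfdti.rf_threshold_imputation import select_thresholds_multi

        missing, q = missing_30
        grids = {
            "rfdti": ThresholdGrid(step=0.2, mode="RFDTI"),
            "rfti": ThresholdGrid(step=0.2, mode="RFTI"),
        }
        both = select_thresholds_multi(missing, q, grids, RF_FAST, seed=47)
        for name, grid in grids.items():
            alone = select_thresholds(missing, q, grid, RF_FAST, seed=47)
            assert both[name].thresholds == alone.thresholds
            assert np.array_equal(
                both[name].imputed.values, alone.imputed.values, equal_nan=True
            )
            assert both[name].rci_mean == alone.rci_mean
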
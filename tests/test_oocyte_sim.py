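"""Unit and property tests of the oocyte replication simulator."""

import numpy as np
import pytest
from scipy import stats as sps

from mthet.errors import (
    EmptyInputError,
    ExtinctCellError,
    InvalidParameterError,
)
from mthet.oocyte_sim import (
    CellState,
    SimParams,
    predict_transmission_curve,
    simulate_cell,
    simulate_cohort,
    step,
)

from conftest import scaled_params


def neutral(**kw):
    return scaled_params(H=4, **kw)


class TestParamValidation:
    def test_neutral_models_force_equal_rates(self):
        with pytest.raises(InvalidParameterError):
            SimParams(lambda_m=0.6, lambda_w=0.4, R0=50, H=4)
        with pytest.raises(InvalidParameterError):
            SimParams(lambda_m=0.6, lambda_w=0.4, R0=50, H=1)

    def test_h5_threshold_ordering(self):
        with pytest.raises(InvalidParameterError):
            SimParams(lambda_m=0.6, lambda_w=0.4, R0=50, H=5,
                      h_th1=0.8, h_th2=0.5)

    @pytest.mark.parametrize("bad", [
        dict(lambda_m=1.5, lambda_w=0.5),
        dict(lambda_m=0.5, lambda_w=-0.1),
        dict(R0=0),
        dict(H=6),
        dict(h_th=0.0),
        dict(T=-1),
    ])
    def test_out_of_range_parameters(self, bad):
        kw = dict(lambda_m=0.5, lambda_w=0.5, R0=50, H=0)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            SimParams(**kw)

    def test_negative_copy_numbers_rejected(self):
        with pytest.raises(InvalidParameterError):
            CellState(-1, 10)


class TestStep:
    def test_no_mutants_created_de_novo(self, rng):
        params = scaled_params(H=0, lam_m=0.9, lam_w=0.5)
        s = CellState(0, 100)
        for t in range(50):
            s = step(s, params, t, rng)
        assert s.m == 0
        assert s.w > 100

    def test_zero_birth_probability_freezes_state(self, rng):
        params = scaled_params(H=4, lam_m=0.0, lam_w=0.0)
        s = step(CellState(50, 50), params, 0, rng)
        assert (s.m, s.w) == (50, 50)

    def test_h5_low_wildtype_regime_suppresses_mutants(self, rng):
        # w < w_th and h > h_th1: mutant births must never occur
        params = scaled_params(H=5, lam_m=0.9, lam_w=0.5, h_th1=0.5,
                               h_th2=0.9, w_th=1000)
        for _ in range(50):
            s = step(CellState(90, 10), params, 0, rng)
            assert s.m == 90

    def test_h5_high_wildtype_regime_uses_upper_threshold(self, rng):
        # w >= w_th so the cap is h_th2=0.9 > h=0.6: mutants may replicate
        params = scaled_params(H=5, lam_m=1.0, lam_w=0.5, h_th1=0.5,
                               h_th2=0.9, w_th=100)
        grew = any(step(CellState(300, 200), params, 0, rng).m > 300
                   for _ in range(20))
        assert grew

    def test_extinct_cell_raises(self, rng):
        with pytest.raises(ExtinctCellError):
            step(CellState(0, 0), neutral(), 0, rng)

    def test_counts_never_decrease(self, rng):
        params = scaled_params(H=0, lam_m=0.7, lam_w=0.3, h_th=0.6)
        s = CellState(5, 7)
        for t in range(200):
            s2 = step(s, params, t, rng)
            assert s2.m >= s.m and s2.w >= s.w
            s = s2

    def test_birth_counts_match_per_molecule_bernoulli_oracle(self, rng):
        # with R0 >= m+w and no thresholds every molecule gets a slot,
        # so one iteration's mutant births are exactly Binomial(m, lam)
        from _oracles import binomial_pmf

        m, w, lam = 7, 5, 0.4
        params = scaled_params(H=3, lam_m=lam, lam_w=lam, R0=50, T=0)
        draws = np.array([step(CellState(m, w), params, 1, rng).m - m
                          for _ in range(10_000)])
        ks = np.arange(m + 1)
        expected = binomial_pmf(ks, m, lam) * draws.size
        observed = np.bincount(draws, minlength=m + 1)
        chi2, p = sps.chisquare(observed, expected)
        assert p > 1e-3


class TestSimulateCell:
    def test_pure_wildtype_cell_stays_homoplasmic(self, rng):
        traj = simulate_cell(CellState(0, 300), neutral(), rng)
        assert traj.final.m == 0
        assert traj.final.h == 0.0

    def test_h0_heteroplasmy_nonincreasing_above_threshold(self, rng):
        params = scaled_params(H=0, lam_m=0.6, lam_w=0.4, h_th=0.8,
                               N_final=3000)
        traj = simulate_cell(CellState(950, 50), params, rng)
        hs = np.array([s.h for s in traj.states])
        above = hs[:-1] > 0.8
        assert np.all(hs[1:][above] <= hs[:-1][above])

    def test_copy_number_monotone_and_terminal(self, rng):
        traj = simulate_cell(CellState(150, 150), neutral(), rng)
        totals = np.array([s.n for s in traj.states])
        assert np.all(np.diff(totals) >= 0)
        assert traj.complete and totals[-1] >= traj.params.N_final

    def test_incomplete_flag_at_t_max(self, rng):
        params = scaled_params(H=4, lam_m=0.1, lam_w=0.1, R0=5, t_max=20)
        traj = simulate_cell(CellState(50, 50), params, rng)
        assert not traj.complete
        assert traj.t_end == 20

    def test_checkpoints_ordered_by_stage_milestone(self, rng):
        traj = simulate_cell(CellState(150, 150), neutral(),
                             rng, milestones={"primary": 500, "secondary": 2000})
        cp = traj.checkpoints
        assert cp["primordial"].n <= cp["primary"].n <= cp["secondary"].n
        assert cp["antral"].n >= traj.params.N_final

    def test_initial_above_target_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            simulate_cell(CellState(4000, 4000), neutral(), rng)


class TestCohort:
    def test_seed_determinism(self):
        initials = [CellState(100, 200)] * 10
        a = simulate_cohort(initials, neutral(), np.random.default_rng(99))
        b = simulate_cohort(initials, neutral(), np.random.default_rng(99))
        for ta, tb in zip(a, b):
            assert ta.seed == tb.seed
            assert [(s.m, s.w) for s in ta.states] == [(s.m, s.w) for s in tb.states]

    def test_fixed_cohort_stays_fixed(self, rng):
        trajs = simulate_cohort([CellState(200, 0)] * 5,
                                scaled_params(H=5, lam_m=0.7, lam_w=0.4),
                                rng, record="checkpoints")
        assert all(t.final.h == 1.0 for t in trajs)

    def test_empty_cohort_raises(self, rng):
        with pytest.raises(EmptyInputError):
            simulate_cohort([], neutral(), rng)

    def test_neutral_mean_preserved(self, rng):
        # drift martingale at moderate n; the full-scale version is an
        # acceptance check
        trajs = simulate_cohort([CellState(150, 150)] * 400, neutral(),
                                rng, record="checkpoints")
        hs = np.array([t.final.h for t in trajs])
        se = hs.std() / np.sqrt(hs.size)
        assert abs(hs.mean() - 0.5) < 3.5 * se

    def test_h5_selection_raises_low_heteroplasmy(self, rng):
        # paired against the same-seed neutral run
        sel = scaled_params(H=5, lam_m=0.6, lam_w=0.4, h_th1=0.5,
                            h_th2=0.8, w_th=500)
        initials = [CellState(60, 240)] * 200
        t_sel = simulate_cohort(initials, sel, np.random.default_rng(7),
                                record="checkpoints")
        t_neu = simulate_cohort(initials, neutral(), np.random.default_rng(7),
                                record="checkpoints")
        h_sel = np.mean([t.final.h for t in t_sel])
        h_neu = np.mean([t.final.h for t in t_neu])
        assert h_sel > h_neu + 0.05
        assert h_sel > 0.25  # above the initial heteroplasmy 0.2


class TestPredictionCurve:
    def test_neutral_curve_is_identity(self, rng):
        curve = predict_transmission_curve([neutral()], [0.2, 0.5, 0.8],
                                           n_cells=150, rng=rng)
        assert np.allclose(curve["mean_final_h"], curve["initial_h"], atol=0.03)

    def test_degenerate_grid_values_dropped(self, rng):
        with pytest.warns(UserWarning):
            curve = predict_transmission_curve([neutral()], [0.0, 0.5, 1.0],
                                               n_cells=20, rng=rng)
        assert list(curve["initial_h"]) == [0.5]

    def test_empty_params_set_raises(self, rng):
        with pytest.raises(EmptyInputError):
            predict_transmission_curve([], [0.5], 10, rng)

    def test_mixed_models_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            predict_transmission_curve(
                [neutral(), scaled_params(H=0, lam_m=0.6, lam_w=0.4)],
                [0.5], 10, rng)
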
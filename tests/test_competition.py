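"""Competition model: reparametrization, analytic phase states, and the
piecewise ODE simulation."""

import math

import numpy as np
import pytest

from esrkit import competition as cm

LN2 = math.log(2.0)


def closed_form_critical_m(alpha: float, beta: float, ratio: float) -> float:
    """Independent oracle: invert the State III threshold for m analytically.

    threshold(m) = (1 - 1/alpha) beta ln2 / ln(1-m) - 1/alpha = ratio
    =>  m = 1 - exp((1 - 1/alpha) beta ln2 / (ratio + 1/alpha)).
    """
    return 1.0 - math.exp((1.0 - 1.0 / alpha) * beta * LN2 / (ratio + 1.0 / alpha))


class TestReduceParams:
    def test_definitional_round_trip(self):
        # growth window of 50 doubling times, kill tuned to m = 0.8
        stress_dur = 10.0
        p = cm.CompetitionParams(
            r_wt=0.9,
            r_null=1.0,
            stress_period=50 * LN2 + stress_dur,
            growth_fraction=50 * LN2 / (50 * LN2 + stress_dur),
            death_rate=-math.log(0.2) / stress_dur,
        )
        rp = cm.reduce_params(p)
        assert rp.alpha == pytest.approx(0.9)
        assert rp.beta == pytest.approx(50.0)
        assert rp.death_fraction == pytest.approx(0.8)

    def test_equal_rates_give_alpha_one_and_no_kill_gives_zero_m(self):
        p = cm.CompetitionParams(r_wt=1.0, r_null=1.0, death_rate=0.0)
        rp = cm.reduce_params(p)
        assert rp.alpha == 1.0
        assert rp.death_fraction == 0.0

    def test_zero_r_null_is_an_error(self):
        p = cm.CompetitionParams(r_wt=0.9, r_null=0.0)
        with pytest.raises(cm.CompetitionError, match="relative fitness"):
            cm.reduce_params(p)

    def test_expand_inverts_reduce(self):
        rp = cm.ReducedParams(0.9, 12.0, 0.4)
        assert cm.reduce_params(cm.expand_params(rp)).death_fraction == pytest.approx(
            0.4
        )
        assert cm.reduce_params(cm.expand_params(rp)).beta == pytest.approx(12.0)


class TestClassifyState:
    @pytest.mark.parametrize(
        "alpha, beta, m, label",
        [
            (1.0, 10.0, 0.5, cm.WT_ALWAYS_WINS),  # State II bound is 0 at alpha=1
            (0.9, 5.0, 0.999, cm.MUTANT_NONVIABLE),  # above 1 - 2^-5 = 0.96875
            (0.9, 50.0, 0.9, cm.RATIO_DEPENDENT),
        ],
    )
    def test_examples(self, alpha, beta, m, label):
        assert cm.classify_state(cm.ReducedParams(alpha, beta, m)).label == label

    def test_state_three_threshold_value(self):
        ps = cm.classify_state(cm.ReducedParams(0.9, 50.0, 0.9))
        # direct evaluation: (1 - 1/0.9)*50*ln2 / ln(0.1) - 1/0.9
        expected = (1 - 1 / 0.9) * 50 * LN2 / math.log(0.1) - 1 / 0.9
        assert ps.threshold_ratio == pytest.approx(expected)
        assert ps.threshold_ratio == pytest.approx(0.5613, abs=1e-4)

    def test_boundary_ordering_on_grid(self):
        for alpha in (0.5, 0.8, 0.95):
            for beta in np.linspace(0.5, 100, 40):
                assert cm.state_one_bound(beta) >= cm.state_two_bound(alpha, beta)

    def test_zero_kill_threshold_is_infinite_for_slow_wt(self):
        ps = cm.classify_state(cm.ReducedParams(0.9, 10.0, 0.0))
        assert ps.label == cm.RATIO_DEPENDENT
        assert ps.threshold_ratio == math.inf

    def test_alpha_to_one_limit_threshold_negative(self):
        # as alpha -> 1-, any positive ratio exceeds the threshold
        thr = cm.threshold_ratio(1.0 - 1e-9, 20.0, 0.5)
        assert thr < 0


class TestThresholdMonotonicity:
    def test_threshold_increases_with_beta(self):
        thrs = [cm.threshold_ratio(0.9, b, 0.5) for b in np.linspace(5, 80, 12)]
        assert np.all(np.diff(thrs) > 0)

    def test_threshold_decreases_with_m(self):
        thrs = [cm.threshold_ratio(0.9, 30.0, m) for m in np.linspace(0.05, 0.95, 12)]
        assert np.all(np.diff(thrs) < 0)

    def test_critical_m_decreases_with_start_ratio(self):
        ms = [cm.critical_death_fraction(0.9, 50.0, r) for r in (0.5, 1, 5, 25)]
        assert np.all(np.diff(ms) < 0)


class TestCriticalDeathFraction:
    @pytest.mark.parametrize(
        "alpha, beta, ratio",
        [(0.9, 50.0, 1.0), (0.9, 100.0, 25.0), (0.8, 30.0, 5.0), (0.95, 10.0, 0.5)],
    )
    def test_bisection_matches_closed_form(self, alpha, beta, ratio):
        m = cm.critical_death_fraction(alpha, beta, ratio)
        assert m == pytest.approx(closed_form_critical_m(alpha, beta, ratio), abs=1e-6)

    def test_worked_one_to_one_case(self):
        assert cm.critical_death_fraction(0.9, 50.0, 1.0) == pytest.approx(
            0.8386, abs=1e-3
        )

    def test_worked_25_to_one_case(self):
        assert cm.critical_death_fraction(0.9, 100.0, 25.0) == pytest.approx(
            0.2554, abs=1e-3
        )

    def test_equal_rates_need_no_killing(self):
        assert cm.critical_death_fraction(1.0, 20.0, 1.0) == 0.0

    def test_root_classifies_as_dominance_flip(self):
        m = cm.critical_death_fraction(0.9, 50.0, 1.0)
        above = cm.classify_state(cm.ReducedParams(0.9, 50.0, m + 1e-4))
        below = cm.classify_state(cm.ReducedParams(0.9, 50.0, m - 1e-4))
        assert above.threshold_ratio < 1.0 < below.threshold_ratio


class TestSimulation:
    def test_wt_frozen_during_stress_and_conservation(self):
        p = cm.expand_params(cm.ReducedParams(0.9, 3.0, 0.5), carrying_capacity=1.0)
        init = cm.PopulationState(0.0, 0.025, 0.025)
        traj = cm.simulate_competition(p, init, 12)
        t, w, n = traj.times, traj.n_wt, traj.n_null
        assert np.all(w + n <= 1.0 * (1 + 1e-6))
        assert np.all(w >= 0) and np.all(n >= 0)
        # stress occupies the first (1-phi)*omega of each cycle: wt constant there
        for c in range(12):
            mask = (t >= c * p.stress_period) & (
                t <= c * p.stress_period + p.stress_duration
            )
            assert np.ptp(w[mask]) <= 1e-8 * max(w[mask].max(), 1e-30)

    def test_no_killing_freezes_at_saturation(self):
        p = cm.expand_params(cm.ReducedParams(0.9, 5.0, 0.0))
        traj = cm.simulate_competition(p, cm.PopulationState(0.0, 0.02, 0.03), 12)
        assert cm.winner(traj) == cm.COEXIST_FROZEN
        # both strains persist
        assert traj.n_null[-1] > 0.02 and traj.n_wt[-1] > 0.01

    def test_equal_rates_with_killing_wt_gains_every_cycle(self):
        p = cm.expand_params(cm.ReducedParams(1.0, 5.0, 0.3))
        traj = cm.simulate_competition(p, cm.PopulationState(0.0, 0.025, 0.025), 12)
        assert np.all(np.asarray(traj.cycle_log_ratio_changes) > 0)
        assert cm.winner(traj) == cm.WT

    def test_mutant_extinct_above_state_one_bound(self):
        # beta=2: bound = 1 - 2^-2 = 0.75; m = 0.9 kills faster than regrowth
        traj = cm.simulate_reduced(
            cm.ReducedParams(0.9, 2.0, 0.9), start_ratio=1.0, n_cycles=30
        )
        assert cm.winner(traj) == cm.MUTANT_EXTINCT

    def test_wt_wins_in_state_two(self):
        # beta=5: II bound 0.293, I bound 0.969; m=0.6 is squarely State II
        traj = cm.simulate_reduced(
            cm.ReducedParams(0.9, 5.0, 0.6), start_ratio=1.0, n_cycles=20
        )
        assert cm.winner(traj) == cm.WT

    def test_wt_ratchet_at_saturation_in_state_three(self):
        # In the saturating ODE every kill frees capacity the never-dying
        # wild-type absorbs, so it gains per cycle even where the dilute-phase
        # analysis is ratio-dependent (see docs/methods.md).
        traj = cm.simulate_reduced(
            cm.ReducedParams(0.9, 10.0, 0.2), start_ratio=1.0, n_cycles=20
        )
        assert cm.classify_state(cm.ReducedParams(0.9, 10.0, 0.2)).label == (
            cm.RATIO_DEPENDENT
        )
        assert cm.winner(traj) == cm.WT

    def test_winner_needs_ten_cycles(self):
        traj = cm.simulate_reduced(cm.ReducedParams(0.9, 5.0, 0.5), n_cycles=5)
        with pytest.raises(cm.CompetitionError, match="10 cycles"):
            cm.winner(traj)


class TestPhaseMap:
    def test_layout_and_zero_kill_column(self):
        pm = cm.phase_map(
            0.9, np.linspace(2, 50, 8), [0.0, 0.2, 0.5, 0.9, 0.99], ratios=[1, 5, 25]
        )
        # m=0 row: all ratio-dependent with infinite threshold
        assert all(s == cm.RATIO_DEPENDENT for s in pm["states"][0])
        assert np.all(np.isinf(pm["threshold_ratios"][0]))
        # severity ordering within each beta column: states never go back from
        # nonviable to ratio-dependent as m rises
        rank = {cm.RATIO_DEPENDENT: 0, cm.WT_ALWAYS_WINS: 1, cm.MUTANT_NONVIABLE: 2}
        for j in range(pm["states"].shape[1]):
            ranks = [rank[s] for s in pm["states"][:, j]]
            assert ranks == sorted(ranks)

    def test_higher_ratio_contours_lie_lower(self):
        pm = cm.phase_map(0.9, np.linspace(10, 80, 6), [0.1, 0.5], ratios=[1, 5, 25])
        c1, c5, c25 = (pm["contours"][r] for r in (1, 5, 25))
        assert np.all(c5 < c1) and np.all(c25 < c5)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(cm.CompetitionError, match="sorted"):
            cm.phase_map(0.9, [5, 2], [0.1])
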
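"""Concession arithmetic, band filtering, offer selection, termination."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcan import (
    AgentState,
    CandidatePool,
    DesireFunctions,
    Outcome,
    StateVector,
    StrategyParams,
    check_termination,
    concession_step,
    feasible_set,
    generate_offer,
    internal_state,
    offer_distance,
    prospective_set,
    responsive_state,
    time_pressure,
)
from fcan.engine import DeadlineExceededError

from conftest import ASTHMA_AGREEMENT, brute_force_asv_band, make_profile, unit_issue

IDENTITY_DESIRES = DesireFunctions(delta=lambda d: d)


def make_state(profile, omega=1.0, epsilon=1.0, reservation=0.0):
    pool = CandidatePool.support_box(profile)
    params = StrategyParams(omega=omega, omega1=1.0, omega2=1.0)
    return AgentState(
        profile=profile, params=params, pool=pool,
        epsilon=epsilon, reservation=reservation,
    )


class TestOfferDistance:
    def test_identical_offers(self):
        schema = [unit_issue("a"), unit_issue("b")]
        a = np.array([0.3, 0.7])
        assert offer_distance(a, a, schema) == 0.0

    def test_single_issue_full_span(self):
        from fcan import IssueSchema

        schema = [IssueSchema(name="a", units="", domain_lo=0, domain_hi=10,
                              grid_step=1)]
        assert offer_distance([0.0], [10.0], schema) == pytest.approx(1.0)

    def test_two_issue_hand_value(self):
        schema = [unit_issue("a"), unit_issue("b")]
        # scaled per-issue distances 0.6 and 0.8
        assert offer_distance([0.0, 0.1], [0.6, 0.9], schema) == pytest.approx(0.5)


class TestResponsiveState:
    def test_first_round_no_movement(self):
        schema = [unit_issue("a")]
        A0, B0 = np.array([0.0]), np.array([1.0])
        sigma, flag = responsive_state(A0, B0, A0, B0, schema)
        assert sigma == pytest.approx(1.0)
        assert not flag

    def test_half_gap_closed(self):
        schema = [unit_issue("a")]
        sigma, _ = responsive_state([0.0], [0.5], [0.0], [0.25], schema)
        assert sigma == pytest.approx(0.5)

    def test_converged_and_immediate_agreement(self):
        schema = [unit_issue("a")]
        sigma, _ = responsive_state([0.0], [1.0], [0.5], [0.5], schema)
        assert sigma == 0.0
        sigma, flag = responsive_state([0.3], [0.3], [0.3], [0.3], schema)
        assert sigma == 0.0 and flag


class TestInternalState:
    def test_zero_slack_gives_full_tightness(self):
        p = make_profile([(0, 0.2, 0.4, 0.6)])
        s = make_state(p, epsilon=0.6)
        s.rho = 0.6
        rho, delta = internal_state(s)
        assert (rho, delta) == (0.6, 1.0)

    def test_slack_reduces_tightness(self):
        p = make_profile([(0, 0.2, 0.4, 0.6)])
        s = make_state(p, epsilon=0.6)
        s.rho = 0.9
        assert internal_state(s)[1] == pytest.approx(0.7)

    def test_opening_offer_has_unit_satisfaction(self):
        p = make_profile([(0, 0.2, 0.4, 0.6)])
        s = make_state(p)
        assert internal_state(s)[0] == 1.0


class TestTimePressure:
    def test_deadline_and_start(self):
        assert time_pressure(15, 15, 0.1, 0.5) == pytest.approx(1.0)
        assert time_pressure(0, 15, 0.1, 0.5) == pytest.approx(0.1)

    def test_hand_value(self):
        assert time_pressure(1, 4, 0.0, 0.5) == pytest.approx(0.5)

    def test_monotone_in_round(self):
        vals = [time_pressure(r, 10, 0.2, 0.7) for r in range(11)]
        assert np.all(np.diff(vals) >= 0)

    def test_past_deadline_signals(self):
        with pytest.raises(DeadlineExceededError):
            time_pressure(16, 15, 0.1, 0.5)


class TestConcessionStep:
    @pytest.fixture()
    def profile(self):
        return make_profile([(0, 0.2, 0.4, 0.6)])

    def test_zero_desire_blocks_concession(self, profile):
        s = make_state(profile, omega=1.0)
        sv = StateVector(sigma=0.0, rho=0.9, delta=0.2, t=0.5)
        deps, eps_new = concession_step(s, sv, IDENTITY_DESIRES)
        assert deps == 0.0 and eps_new == s.epsilon

    def test_min_conjunction(self, profile):
        s = make_state(profile, omega=1.0)
        sv = StateVector(sigma=0.6, rho=0.4, delta=0.9, t=0.8)
        deps, _ = concession_step(s, sv, IDENTITY_DESIRES)
        assert deps == pytest.approx(0.4)

    def test_competitive_exponent_shrinks_concession(self, profile):
        s = make_state(profile, omega=2.0)
        sv = StateVector(sigma=0.6, rho=0.4, delta=0.9, t=0.8)
        deps, _ = concession_step(s, sv, IDENTITY_DESIRES)
        assert deps == pytest.approx(0.16)

    def test_product_tnorm_option(self, profile):
        s = make_state(profile, omega=1.0)
        sv = StateVector(sigma=0.5, rho=0.5, delta=1.0, t=0.5)
        deps, _ = concession_step(s, sv, IDENTITY_DESIRES, tnorm="product")
        assert deps == pytest.approx(0.125)

    @given(
        mus=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    )
    @settings(max_examples=100, deadline=None)
    def test_strategy_exponent_ordering(self, mus):
        # identical states: competitive <= win-win <= collaborative concession
        p = make_profile([(0, 0.2, 0.4, 0.6)])
        sv = StateVector(sigma=mus[0], rho=mus[1], delta=mus[2], t=mus[3])
        deps = {}
        for name, omega in [("collaborative", 0.8), ("win_win", 1.0),
                            ("competitive", 1.2)]:
            s = make_state(p, omega=omega)
            deps[name], _ = concession_step(s, sv, IDENTITY_DESIRES)
        assert deps["competitive"] <= deps["win_win"] + 1e-12
        assert deps["win_win"] <= deps["collaborative"] + 1e-12


class TestFeasibleSet:
    def test_unit_band_keeps_only_core_offers(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)], step=0.2)
        pool = CandidatePool.support_box(p)
        P = feasible_set(pool, 1.0, 1.0)
        assert np.allclose(p.asv(P), 1.0)
        assert sorted(P[:, 0]) == [0.4, 0.6]

    def test_hand_band(self):
        # grid {0, 0.5, 1} with degrees {0, 0.5, 1}
        p = make_profile([(0, 1, 1, 1)], step=0.5)
        pool = CandidatePool.support_box(p)
        P = feasible_set(pool, 0.9, 0.4)
        assert P[:, 0].tolist() == [0.5]

    def test_band_above_one_is_empty(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)], step=0.2)
        pool = CandidatePool.support_box(p)
        assert len(feasible_set(pool, 1.2, 1.1)) == 0

    def test_inverted_band_rejected(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)], step=0.2)
        pool = CandidatePool.support_box(p)
        with pytest.raises(ValueError):
            feasible_set(pool, 0.4, 0.9)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(1, 3)
            quads = [tuple(np.sort(rng.uniform(0, 1, 4))) for _ in range(n)]
            p = make_profile(quads, step=0.125)
            pool = CandidatePool.support_box(p)
            lo, hi = np.sort(rng.uniform(0, 1, 2))
            got = feasible_set(pool, hi, lo)
            expected = brute_force_asv_band(p, pool.offers, lo, hi)
            got_s = got[np.lexsort(got.T[::-1])] if len(got) else got
            exp_s = expected[np.lexsort(expected.T[::-1])] if len(expected) else expected
            assert np.array_equal(got_s, exp_s)


class TestProspectiveSet:
    def test_ideal_counteroffer_is_the_unique_maximizer(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)], step=0.2)
        s = make_state(p)
        P = np.array([[0.0], [0.4], [0.8]])
        B = np.array([0.4])  # in P, core membership, zero distance
        S = prospective_set(s, P, B)
        assert S.tolist() == [[0.4]]

    def test_hand_computed_utility_ranking(self):
        # two issues; H(S1) = sqrt(0.68)/2 > H(S2) = sqrt(0.52)/2
        p = make_profile([(0, 0.2, 0.2, 1.0), (0, 0.4, 0.4, 1.0)])
        s = make_state(p)
        S1, S2 = [0.2, 0.8], [0.6, 0.4]
        P = np.array([S1, S2])
        B = np.array([0.0, 0.0])
        S = prospective_set(s, P, B)
        assert S.tolist() == [S1]

    def test_symmetric_ties_are_kept(self):
        p = make_profile([(0, 0.5, 0.5, 1.0)], step=0.25)
        s = make_state(p)
        P = np.array([[0.25], [0.75]])  # same degree, same distance to B
        B = np.array([0.5])
        assert len(prospective_set(s, P, B)) == 2

    def test_empty_feasible_set_is_an_error(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)])
        s = make_state(p)
        with pytest.raises(ValueError):
            prospective_set(s, np.empty((0, 1)), np.array([0.5]))


class TestGenerateOffer:
    def test_counteroffer_itself_wins(self):
        schema = [unit_issue("a")]
        S = np.array([[0.2], [0.5], [0.9]])
        out = generate_offer(S, np.array([0.5]), 1.0, schema)
        assert out.tolist() == [0.5]

    def test_similarity_argmax(self):
        schema = [unit_issue("a")]
        S = np.array([[0.2], [0.9]])
        out = generate_offer(S, np.array([1.0]), 1.0, schema)
        assert out.tolist() == [0.9]

    def test_vanishing_kernel_falls_back_to_lexicographic(self):
        schema = [unit_issue("a"), unit_issue("b")]
        S = np.array([[0.9, 0.1], [0.1, 0.9]])
        out = generate_offer(S, np.array([0.5, 0.5]), 1e-12, schema)
        assert out.tolist() == [0.1, 0.9]

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(23)
        schema = [unit_issue("a"), unit_issue("b")]
        for _ in range(50):
            S = rng.uniform(0, 1, size=(rng.integers(1, 40), 2))
            B = rng.uniform(0, 1, 2)
            k = rng.uniform(0.2, 3.0)
            got = generate_offer(S, B, k, schema)
            sims = np.exp(-k * np.abs(S - B)).mean(axis=1)
            best = sims.max()
            cands = S[sims >= best - 1e-9]
            expected = cands[np.lexsort(cands[:, ::-1].T)][0]
            assert np.allclose(got, expected)


class TestTermination:
    def test_patient_accepts_final_asthma_offer(self, pa_profile):
        pool = CandidatePool.support_box(pa_profile, cap=1000,
                                         rng=np.random.default_rng(0))
        s = AgentState(
            profile=pa_profile,
            params=StrategyParams.preset("collaborative"),
            pool=pool, epsilon=0.59,
        )
        out = check_termination(s, ASTHMA_AGREEMENT, np.empty((0, 5)), 7, 15)
        assert out == Outcome.AGREE  # ASV 0.7730 >= 0.59

    def test_threshold_floor(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)])
        s = make_state(p, epsilon=-0.01)
        assert check_termination(s, None, None, 3, 15) == Outcome.FAIL_THRESHOLD

    def test_empty_feasible_set(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)])
        s = make_state(p, epsilon=0.5)
        out = check_termination(s, np.array([0.0]), np.empty((0, 1)), 3, 15)
        assert out == Outcome.FAIL_EMPTY

    def test_deadline(self):
        p = make_profile([(0, 0.4, 0.6, 1.0)])
        s = make_state(p)
        assert check_termination(s, None, None, 16, 15) == Outcome.FAIL_DEADLINE


class TestStrategyParams:
    def test_presets_respect_their_regimes(self):
        for name in ("collaborative", "win_win", "competitive"):
            StrategyParams.preset(name)

    def test_regime_violations_rejected(self):
        with pytest.raises(ValueError):
            StrategyParams(omega=1.2, omega1=0.8, omega2=1.0,
                           strategy_name="collaborative")
        with pytest.raises(ValueError):
            StrategyParams(omega=1.0, omega1=0.9, omega2=1.0,
                           strategy_name="win_win")

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            StrategyParams.preset("aggressive")


class TestCandidatePool:
    def test_exhaustive_when_small(self):
        p = make_profile([(0, 0.2, 0.6, 1.0)], step=0.1)
        pool = CandidatePool.support_box(p)
        assert pool.exhaustive
        assert len(pool) == 11

    def test_sampled_pool_is_capped_and_contains_corners(self):
        p = make_profile([(0, 0.2, 0.6, 1.0)] * 4, step=0.01)
        pool = CandidatePool.support_box(p, cap=500,
                                         rng=np.random.default_rng(3))
        assert not pool.exhaustive
        assert len(pool) <= 500 + 2 ** 4
        corner = np.array([0.2, 0.2, 0.2, 0.2])
        assert (pool.offers == corner).all(axis=1).any()
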
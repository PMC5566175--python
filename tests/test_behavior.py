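"""Willingness, ability, readiness curves and the conception decision flow."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from srbsim import (
    FEMALE,
    AgentState,
    ConceptionEvent,
    DiffusionCurve,
    ParameterSet,
    SonPreferenceCurve,
    ability_probability,
    conception_event_distribution,
    conception_step,
    fit_son_preference,
    readiness_probability,
    son_preference_probability,
    update_tech_access,
)


def woman(age=30, sp=0, parity=0, sons=0, tech=False):
    return AgentState(
        id=1, sex=FEMALE, birth_year=1970, age=age, sp=sp, parity=parity,
        sons=sons, tech_access=tech,
    )


def logit(p):
    return math.log(p / (1 - p))


class TestSonPreferenceCurve:
    def test_curve_through_survey_anchors(self):
        # stated son preference: 48 % in 1985 falling to 26 % in 1994
        curve = SonPreferenceCurve.from_anchors(1985, 0.48, 1994, 0.26)
        assert son_preference_probability(curve, 1985) == pytest.approx(0.48, abs=1e-9)
        assert son_preference_probability(curve, 1994) == pytest.approx(0.26, abs=1e-9)
        assert curve.delta1 == pytest.approx((logit(0.26) - logit(0.48)) / 9, abs=1e-12)

    def test_zero_slope_is_constant(self):
        curve = SonPreferenceCurve(delta0=0.3, delta1=0.0)
        vals = [son_preference_probability(curve, y) for y in (1980, 2000, 2050)]
        assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_negative_slope_strictly_decreasing(self):
        curve = SonPreferenceCurve.from_anchors(1985, 0.48, 1994, 0.26)
        years = np.arange(1980, 2051)
        vals = [son_preference_probability(curve, y) for y in years]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)


class TestFitSonPreference:
    def test_two_point_fit_is_exact(self):
        curve = fit_son_preference([(1985, 0.48), (1994, 0.26)])
        assert son_preference_probability(curve, 1985) == pytest.approx(0.48, abs=1e-9)
        assert son_preference_probability(curve, 1994) == pytest.approx(0.26, abs=1e-9)

    def test_equal_proportions_give_zero_slope(self):
        curve = fit_son_preference([(1985, 0.3), (1995, 0.3)])
        assert curve.delta1 == 0.0

    def test_collinear_logit_points_interpolated_exactly(self):
        base = SonPreferenceCurve(delta0=0.2, delta1=-0.08, reference_year=1980)
        obs = [(y, son_preference_probability(base, y)) for y in (1982, 1990, 1999, 2004)]
        curve = fit_son_preference(obs)
        for y, p in obs:
            assert son_preference_probability(curve, y) == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize(
        "obs", [[(1985, 0.4)], [(1985, 0.0), (1990, 0.5)], [(1985, 0.5), (1990, 1.0)]]
    )
    def test_degenerate_observations_rejected(self, obs):
        with pytest.raises(ValueError):
            fit_son_preference(obs)


class TestAbility:
    def test_half_at_inflection(self):
        assert ability_probability(DiffusionCurve(rho=0.7, phi=9), 9) == 0.5

    def test_degenerate_slope_stays_half(self):
        curve = DiffusionCurve(rho=0.0, phi=7)
        assert all(ability_probability(curve, t) == 0.5 for t in range(0, 31))

    def test_direct_evaluation(self):
        val = ability_probability(DiffusionCurve(rho=0.5, phi=7), 0)
        assert val == pytest.approx(1 / (1 + math.exp(3.5)), abs=1e-12)

    @given(rho=st.floats(0.01, 2.0), phi=st.floats(0.0, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_cdf_shape(self, rho, phi):
        curve = DiffusionCurve(rho=rho, phi=phi)
        ts = np.linspace(-50, 100, 200)
        vals = [ability_probability(curve, t) for t in ts]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert ability_probability(curve, phi) == pytest.approx(0.5)
        assert ability_probability(curve, phi - 2000 / rho) < 1e-6
        assert ability_probability(curve, phi + 2000 / rho) > 1 - 1e-6


class TestUpdateTechAccess:
    def test_saturated_diffusion_grants_access(self):
        curve = DiffusionCurve(rho=2.0, phi=0.0)
        agent = update_tech_access(woman(), curve, t=500, rng=np.random.default_rng(0))
        assert agent.tech_access

    def test_absorbing_state_persists(self):
        curve = DiffusionCurve(rho=2.0, phi=1000.0)  # ability ~ 0
        agent = update_tech_access(
            woman(tech=True), curve, t=0, rng=np.random.default_rng(0)
        )
        assert agent.tech_access

    def test_population_fraction_tracks_ability(self):
        curve = DiffusionCurve(rho=0.5, phi=7)
        t = 5
        p = ability_probability(curve, t)
        rng = np.random.default_rng(11)
        n = 30_000
        got = sum(
            update_tech_access(woman(), curve, t, rng).tech_access for _ in range(n)
        )
        se = np.sqrt(p * (1 - p) / n)
        assert got / n == pytest.approx(p, abs=3 * se)


class TestReadiness:
    def test_parity_one_coefficient_at_tfr_3(self):
        # transition from first to second parity at TFR 3: 0.33... x sigma
        p = ParameterSet(sigma=1.0)
        assert readiness_probability(1, 3.0, p) == pytest.approx(1 / 3, abs=1e-12)

    def test_parity_one_coefficient_at_tfr_2_5(self):
        p = ParameterSet(sigma=1.0)
        assert readiness_probability(1, 2.5, p) == pytest.approx(0.4, abs=1e-12)

    def test_sigma_scales_linearly(self):
        p = ParameterSet(sigma=1.7)
        assert readiness_probability(1, 2.5, p) == pytest.approx(0.4 * 1.7, abs=1e-12)

    def test_capped_at_one(self):
        p = ParameterSet(sigma=1.0)
        assert readiness_probability(3, 2.0, p) == 1.0

    def test_parity_zero_uses_beta(self):
        p = ParameterSet(beta=0.2)
        assert readiness_probability(0, 2.0, p) == pytest.approx(0.1, abs=1e-12)

    def test_nonpositive_tfr_rejected(self, params):
        with pytest.raises(ValueError):
            readiness_probability(1, 0.0, params)

    @given(
        par=st.integers(0, 6),
        par2=st.integers(0, 6),
        tfr=st.floats(0.5, 6.0),
        tfr2=st.floats(0.5, 6.0),
        sigma=st.floats(0, 2.5),
        beta=st.floats(0, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity_and_bounds(self, par, par2, tfr, tfr2, sigma, beta):
        p = ParameterSet(sigma=sigma, beta=beta)
        r = readiness_probability(par, tfr, p)
        assert 0.0 <= r <= 1.0
        # non-decreasing in parity (for parity >= 1 branch continuity at 0
        # is not claimed: beta may exceed sigma-scaled squeeze)
        if par >= 1 and par2 >= par:
            assert readiness_probability(par2, tfr, p) >= r
        # non-increasing in prevailing TFR
        if tfr2 >= tfr:
            assert readiness_probability(par, tfr2, p) <= r


class TestConceptionStep:
    def test_zero_base_rate_never_conceives(self, params):
        rng = np.random.default_rng(0)
        for _ in range(200):
            event, _ = conception_step(woman(sp=1, tech=True), 0.0, 2.0, params, rng)
            assert event is ConceptionEvent.NO_CONCEPTION

    def test_no_readiness_means_no_abortion(self):
        p = ParameterSet(sigma=0.0, beta=0.0)
        rng = np.random.default_rng(1)
        events = [
            conception_step(woman(sp=1, tech=True), 0.5, 2.0, p, rng)[0]
            for _ in range(2000)
        ]
        assert ConceptionEvent.SEX_SELECTIVE_ABORTION not in events
        conceived = [e for e in events if e is not ConceptionEvent.NO_CONCEPTION]
        male_frac = sum(e is ConceptionEvent.MALE_BIRTH for e in conceived) / len(
            conceived
        )
        se = np.sqrt(p.p_male * (1 - p.p_male) / len(conceived))
        assert male_frac == pytest.approx(p.p_male, abs=3 * se)

    def test_forced_readiness_aborts_every_female_fetus(self):
        # readiness = min(1, 1 * 2.5 / 0.5) = 1: all births male
        p = ParameterSet(sigma=2.5)
        rng = np.random.default_rng(2)
        for _ in range(500):
            event, agent = conception_step(
                woman(sp=1, parity=1, sons=0, tech=True), 1.0, 0.5, p, rng
            )
            assert event in (ConceptionEvent.MALE_BIRTH, ConceptionEvent.SEX_SELECTIVE_ABORTION)
            if event is ConceptionEvent.SEX_SELECTIVE_ABORTION:
                assert agent.abortions == 1 and agent.parity == 1

    def test_male_fetus_never_aborted_and_counters_consistent(self, params):
        rng = np.random.default_rng(3)
        for _ in range(2000):
            event, agent = conception_step(
                woman(sp=1, parity=1, sons=0, tech=True), 0.8, 1.5, params, rng
            )
            if event is ConceptionEvent.MALE_BIRTH:
                assert agent.sons == 1 and agent.parity == 2
            elif event is ConceptionEvent.FEMALE_BIRTH:
                assert agent.sons == 0 and agent.parity == 2
            elif event is ConceptionEvent.SEX_SELECTIVE_ABORTION:
                assert agent.abortions == 1 and agent.parity == 1

    @pytest.mark.parametrize(
        "agent_kwargs,base,tfr",
        [
            (dict(sp=0), 0.15, 2.5),
            (dict(sp=1, sons=0, tech=True), 0.15, 2.5),
            (dict(sp=1, sons=0, tech=True, parity=2), 0.3, 1.6),
            (dict(sp=1, sons=1, parity=1, tech=True), 0.2, 2.0),
            (dict(sp=1, sons=0, tech=False), 0.2, 2.0),
            (dict(sp=1, sons=0, tech=True, parity=0), 0.25, 0.8),
        ],
    )
    def test_empirical_frequencies_match_closed_form(self, agent_kwargs, base, tfr):
        """The sampling path must match the exact product-of-Bernoulli-stages
        distribution for one woman-year."""
        params = ParameterSet()
        agent = woman(**agent_kwargs)
        dist = conception_event_distribution(agent, base, tfr, params)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        rng = np.random.default_rng(
            sum(ord(c) for c in str(sorted(agent_kwargs.items()))) + int(base * 1000)
        )
        n = 100_000
        counts = {e: 0 for e in ConceptionEvent}
        for _ in range(n):
            event, _ = conception_step(agent, base, tfr, params, rng)
            counts[event] += 1
        # joint goodness-of-fit over the whole event distribution
        events = [e for e in ConceptionEvent if dist[e] > 0]
        observed = [counts[e] for e in events]
        expected = [dist[e] * n for e in events]
        assert sum(counts[e] for e in ConceptionEvent if dist[e] == 0) == 0
        res = chisquare(observed, expected)
        assert res.pvalue > 1e-4
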
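"""Tests for the PEST engine, psychometric fits, transforms and concavity rule."""

import numpy as np
import pytest

import costdiscount as cd
from costdiscount.staircase import BlockConfig, StaircaseState

from conftest import make_agent


def fresh_state(step=8.0, magnitude=60.0, jitter=0.0):
    return StaircaseState(
        effort=0.5,
        magnitude=magnitude,
        step=step,
        initial_magnitude=magnitude,
        initial_step=step,
        jitter=jitter,
    )


class TestPestUpdate:
    def test_initial_step_is_applied(self):
        s = fresh_state(step=8.0)
        s2 = cd.pest_update(s, accepted=False)
        assert s2.step == 8.0
        assert s2.magnitude == 68.0

    def test_acceptance_lowers_rejection_raises(self):
        s = fresh_state()
        assert cd.pest_update(s, True).magnitude < s.magnitude
        assert cd.pest_update(s, False).magnitude > s.magnitude

    def test_step_halves_on_reversal(self):
        s = cd.pest_update(fresh_state(), False)
        s = cd.pest_update(s, True)  # reversal
        assert s.step == 4.0

    def test_two_reversals_trigger_reinitialization(self):
        s = cd.pest_update(fresh_state(), False)  # step 8 up
        s = cd.pest_update(s, True)  # reversal -> step 4
        s = cd.pest_update(s, False)  # reversal -> step 2 = 8/4 -> reinit
        assert s.n_reinit == 1
        assert s.step == 8.0
        assert s.magnitude == 60.0  # no rng supplied: no jitter
        assert s.last_direction == 0 and s.run_length == 0

    def test_reinit_jitter_within_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = cd.pest_update(fresh_state(jitter=6.0), False)
            s = cd.pest_update(s, True)
            s = cd.pest_update(s, False, rng)
            assert 54.0 <= s.magnitude <= 66.0

    def test_step_doubles_after_third_same_direction_step(self):
        s = fresh_state()
        for _ in range(3):
            s = cd.pest_update(s, False)
        assert s.step == 8.0  # first three steps keep the initial size
        s = cd.pest_update(s, False)
        # fourth consecutive step would double but is capped at the initial step
        assert s.step == 8.0
        # uncapped doubling is visible from a halved step
        s = cd.pest_update(fresh_state(), False)
        s = cd.pest_update(s, True)  # step 4
        for _ in range(2):
            s = cd.pest_update(s, True)
        assert s.step == 4.0
        s = cd.pest_update(s, True)  # 4th same-direction -> doubles to 8
        assert s.step == 8.0

    def test_alternating_choices_oscillate_within_band(self):
        s = fresh_state()
        mags = []
        accepted = True
        for _ in range(200):
            s = cd.pest_update(s, accepted)
            mags.append(s.magnitude)
            accepted = not accepted
        mags = np.array(mags[10:])
        assert mags.max() - mags.min() <= 2 * 8.0

    def test_magnitude_floored_at_zero(self):
        s = fresh_state(magnitude=3.0)
        s = cd.pest_update(s, True)
        assert s.magnitude == 0.0

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            StaircaseState(effort=0.5, magnitude=-1.0, step=8.0,
                           initial_magnitude=60.0, initial_step=8.0)
        with pytest.raises(ValueError):
            StaircaseState(effort=0.5, magnitude=60.0, step=0.0,
                           initial_magnitude=60.0, initial_step=8.0)


class TestIndifferenceFit:
    def test_separation_convention_midpoint(self):
        choices = {0.5: [(50.0, False), (55.0, False), (58.0, False),
                         (70.0, True), (75.0, True), (80.0, True)]}
        curve = cd.estimate_indifference_points(choices, 40.0)
        assert curve.status[0] == "separated"
        assert curve.x50[0] == pytest.approx((58.0 + 70.0) / 2)
        assert np.isinf(curve.slope[0])

    def test_threshold_agent_x50_inside_gap(self):
        m_star = 63.0
        offers = np.linspace(40, 90, 20)
        choices = {0.5: [(float(m), bool(m > m_star)) for m in offers]}
        curve = cd.estimate_indifference_points(choices, 40.0)
        below = offers[offers <= m_star].max()
        above = offers[offers > m_star].min()
        assert below <= curve.x50[0] <= above

    def test_symmetric_pattern_recovers_center(self):
        # overlapping accept/reject pattern, exactly symmetric around 100
        choices = {0.5: [(90.0, False), (95.0, False), (95.0, True), (100.0, False),
                         (100.0, True), (105.0, False), (105.0, True), (110.0, True)]}
        curve = cd.estimate_indifference_points(choices, 40.0)
        assert curve.status[0] == "ok"
        assert curve.x50[0] == pytest.approx(100.0, abs=1e-3)

    def test_recovery_from_known_psychometric(self):
        rng = np.random.default_rng(123)
        x50_true, slope_true = 60.0, 0.2
        estimates = []
        for _ in range(50):
            x = rng.uniform(30, 90, size=16)
            p = 1.0 / (1.0 + np.exp(-slope_true * (x - x50_true)))
            y = rng.random(16) < p
            if y.all() or not y.any():
                continue
            curve = cd.estimate_indifference_points({0.5: list(zip(x, y))}, 40.0)
            if curve.status[0] == "ok":
                estimates.append(curve.x50[0])
        assert len(estimates) >= 30
        assert abs(np.median(estimates) - x50_true) <= 0.1 * x50_true

    def test_insufficient_levels_flagged(self):
        choices = {0.5: [(50.0, True)] * 8, 0.7: [(50.0, True), (60.0, False)]}
        curve = cd.estimate_indifference_points(choices, 40.0)
        assert curve.status == ("insufficient", "insufficient")
        assert np.isnan(curve.x50).all()

    def test_bad_default_magnitude(self):
        with pytest.raises(ValueError):
            cd.estimate_indifference_points({0.5: []}, 0.0)


class TestTransforms:
    def _curve(self, x50s, default=40.0):
        n = len(x50s)
        return cd.IndifferenceCurve(
            levels=np.array(cd.DEFAULT_EFFORT_LEVELS[:n]),
            x50=np.array(x50s, dtype=float),
            slope=np.ones(n),
            n_choices=np.full(n, 16),
            status=tuple(["ok"] * n),
            default_magnitude=default,
        )

    def test_no_devaluation(self):
        curve = self._curve([40.0])
        assert cd.transform_indifference(curve, "multiplicative")[0] == 1.0
        assert cd.transform_indifference(curve, "additive")[0] == 40.0
        assert cd.transform_indifference(curve, "raw")[0] == 40.0

    def test_formula_arithmetic(self):
        curve = self._curve([80.0], default=40.0)
        assert cd.transform_indifference(curve, "multiplicative")[0] == pytest.approx(0.5)
        assert cd.transform_indifference(curve, "additive")[0] == pytest.approx(0.0)

    def test_additive_can_go_negative(self):
        curve = self._curve([100.0], default=40.0)
        assert cd.transform_indifference(curve, "additive")[0] < 0

    def test_nonpositive_x50_rejected_in_multiplicative(self):
        curve = self._curve([-5.0])
        with pytest.raises(ValueError):
            cd.transform_indifference(curve, "multiplicative")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            cd.transform_indifference(self._curve([40.0]), "exotic")


class TestConcavity:
    def test_points_on_chord_not_concave(self):
        levels = np.array(cd.DEFAULT_EFFORT_LEVELS)
        on_chord = 1.0 + (0.4 - 1.0) * levels / levels[-1]
        res = cd.classify_concavity(on_chord, levels)
        assert res.n_above_chord == 0 and not res.concave

    def test_quadratic_agent_is_concave(self):
        levels = np.array(cd.DEFAULT_EFFORT_LEVELS)
        d, k = 40.0, 40.0
        mult = d / (d + k * levels**2)  # indifference of an additive-quadratic agent
        res = cd.classify_concavity(mult, levels)
        assert res.concave and res.n_above_chord == 5

    def test_steep_hyperbolic_agent_not_concave(self):
        levels = np.array(cd.DEFAULT_EFFORT_LEVELS)
        mult = 1.0 / (1.0 + 8.0 * levels)  # multiplicative hyperbolic devaluation
        res = cd.classify_concavity(mult, levels)
        assert not res.concave

    def test_non_finite_rejected(self):
        vals = [1.0, 0.9, np.nan, 0.7, 0.6, 0.5]
        with pytest.raises(ValueError):
            cd.classify_concavity(vals)

    def test_six_points_required(self):
        with pytest.raises(ValueError):
            cd.classify_concavity([1.0, 0.9, 0.8])


class TestSessionInvariants:
    def test_staircase_convergence_stochastic_agents(self):
        # stochastic threshold agents with indifference inside the offer range
        rng = np.random.default_rng(2024)
        hits = 0
        runs = 100
        for run in range(runs):
            x50 = rng.uniform(45.0, 75.0)
            s = StaircaseState(effort=0.5, magnitude=60.0, step=8.0,
                               initial_magnitude=60.0, initial_step=8.0, jitter=6.0)
            offers = []
            reinits = []
            for _ in range(60):
                p = 1.0 / (1.0 + np.exp(-0.25 * (s.magnitude - x50)))
                accepted = bool(rng.random() < p)
                offers.append(s.magnitude)
                s2 = cd.pest_update(s, accepted, rng)
                if s2.n_reinit > s.n_reinit:
                    reinits.append(len(offers))
                s = s2
            usable = [i for i in reinits if i >= 4]
            window = offers[usable[-1] - 4 : usable[-1]] if usable else offers[-4:]
            if abs(np.mean(window) - x50) <= 2 * 8.0:
                hits += 1
        assert hits >= 90

    def test_interleaving_no_shared_state(self):
        agent = make_agent(model="quadratic", k=30.0, p=None, beta=2.0)
        _, traces = cd.simulate_exp2_session(agent, seed=77)
        blk = cd.StaircaseConfig().blocks[0]

        def replay(accepts, jitter_entropy, jitter_key):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=jitter_entropy, spawn_key=jitter_key)
            )
            s = StaircaseState(effort=0.5, magnitude=blk.initial_magnitude,
                               step=blk.initial_step, initial_magnitude=blk.initial_magnitude,
                               initial_step=blk.initial_step, jitter=blk.jitter)
            offered = []
            for a in accepts:
                offered.append(s.magnitude)
                s = cd.pest_update(s, a, rng)
            return offered

        # each level's offers are a pure function of its own acceptances
        for lvl in cd.DEFAULT_EFFORT_LEVELS:
            tr = traces[(1, lvl)]
            assert replay(tr["accepted"], tr["jitter_seed"], tr["jitter_key"]) == tr["offered"]
        # flipping one level's choices cannot touch another level's offers
        tr_a, tr_b = traces[(1, 0.25)], traces[(1, 0.75)]
        flipped = [not a for a in tr_a["accepted"]]
        _ = replay(flipped, tr_a["jitter_seed"], tr_a["jitter_key"])
        assert replay(tr_b["accepted"], tr_b["jitter_seed"], tr_b["jitter_key"]) == tr_b["offered"]

    def test_magnitude_effect_multiplicative_agent(self):
        # multiplicative (sigmoidal) agent: multiplicative curves agree across blocks
        agent = make_agent(model="sigmoidal", k=4.0, p=0.8, beta=50.0)
        _, traces = cd.simulate_exp2_session(agent, seed=41)
        sc = cd.StaircaseConfig()
        mults = {}
        for bi, blk in enumerate(sc.blocks, start=1):
            choices = {
                lvl: list(zip(traces[(bi, lvl)]["offered"], traces[(bi, lvl)]["accepted"]))
                for lvl in sc.effort_levels
            }
            curve = cd.estimate_indifference_points(choices, blk.default_magnitude)
            mults[bi] = cd.transform_indifference(curve, "multiplicative")
        ok = np.isfinite(mults[1]) & np.isfinite(mults[2])
        assert ok.sum() >= 4
        assert np.allclose(mults[1][ok], mults[2][ok], atol=0.12)

    def test_magnitude_effect_additive_agent(self):
        # additive (quadratic) agent: devaluations x50 - D agree across blocks
        agent = make_agent(model="quadratic", k=30.0, p=None, beta=50.0)
        _, traces = cd.simulate_exp2_session(agent, seed=42)
        sc = cd.StaircaseConfig()
        deval = {}
        for bi, blk in enumerate(sc.blocks, start=1):
            choices = {
                lvl: list(zip(traces[(bi, lvl)]["offered"], traces[(bi, lvl)]["accepted"]))
                for lvl in sc.effort_levels
            }
            curve = cd.estimate_indifference_points(choices, blk.default_magnitude)
            deval[bi] = curve.x50 - blk.default_magnitude
        ok = np.isfinite(deval[1]) & np.isfinite(deval[2])
        assert ok.sum() >= 4
        assert np.allclose(deval[1][ok], deval[2][ok], atol=8.0)

    def test_six_levels_enforced(self):
        with pytest.raises(ValueError, match="six"):
            cd.StaircaseConfig(effort_levels=(0.2, 0.5, 1.0))
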
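"""Motivation dynamics: growth branches, step events, decreases,
initialization and selection probabilities."""

import math

import numpy as np
import pytest

from adlsim import (
    ContractError,
    MotivationState,
    NoiseSpec,
    ResidentProfile,
    StepEvent,
    advance,
    decrease_on_completion,
    increase_rates,
    initialize,
    nominal_duration,
    outside_satisfaction,
    sample_actual_duration,
    sample_profile,
    schedule_step_events,
    selection_probabilities,
)
from adlsim.motivation import INIT_WINDOW_H, at_factor_interval

ALL = frozenset(range(1, 14))
NO_NOISE = NoiseSpec(0.0)


def _state(mv_values=None, norm=100.0, performable=ALL):
    mv = np.zeros(13)
    for i, v in (mv_values or {}).items():
        mv[i - 1] = v
    return MotivationState(mv=mv, performable=performable, norm_mv=norm)


def _profile(**kw):
    D = {1: 8.0, 2: 0.0, 3: 1.0, 4: 0.5, 5: 2.0, 6: 0.05, 7: 0.2, 8: 4.0,
         9: 1.0, 10: 0.5, 11: 0.1, 12: 0.2}
    T = {1: 24.0, 2: 24.0, 3: 8.0, 4: 24.0, 5: 48.0, 6: 4.0, 7: 24.0, 8: 24.0,
         9: 24.0, 10: 48.0, 11: 24.0, 12: 48.0}
    D.update(kw.pop("D", {}))
    T.update(kw.pop("T", {}))
    return ResidentProfile(D, T, naps=False)


@pytest.fixture()
def rates():
    return increase_rates(_profile(), ALL, norm_mv=100.0)


class TestAdvance:
    def test_awake_linear_growth(self, rates):
        s = _state()
        advance(s, 1.0, rates, NO_NOISE)
        assert s.value(8) == pytest.approx(100.0 / 12.0, rel=1e-12)

    def test_sleeping_eat_grows_at_ten_percent(self, rates):
        s = _state()
        s.sleeping = True
        advance(s, 8.0, rates, NO_NOISE)
        assert s.value(3) == pytest.approx(0.1 * rates.omega[3] * 8.0, rel=1e-12)
        assert s.value(6) == pytest.approx(0.1 * rates.omega[6] * 8.0, rel=1e-12)

    def test_sleeping_others_frozen(self, rates):
        s = _state()
        s.sleeping = True
        advance(s, 8.0, rates, NO_NOISE)
        for i in (1, 4, 5, 8, 9, 10, 12):
            assert s.value(i) == 0.0

    def test_performing_as_does_not_self_grow(self, rates):
        s = _state()
        advance(s, 1.0, rates, NO_NOISE, performing=8)
        assert s.value(8) == 0.0
        assert s.value(9) > 0.0

    def test_relax_pinned_and_nonperformable_zero(self, rates):
        s = _state(performable=ALL - {9})
        advance(s, 5.0, rates, NO_NOISE)
        assert s.value(13) == 102.0
        assert s.value(9) == 0.0

    def test_negative_dt_rejected(self, rates):
        with pytest.raises(ContractError):
            advance(_state(), -0.1, rates, NO_NOISE)


class TestStepEvents:
    def test_eating_schedules_toilet_long_step(self, rates):
        s = _state()
        s.clock = 10.0
        schedule_step_events(s, "eating_started", _profile())
        (ev,) = s.pending_steps
        assert ev == StepEvent(12.5, 7, pytest.approx(100.0 / 3.0))
        advance(s, 2.0, rates, NO_NOISE)   # t=12.0: not yet
        assert s.value(7) == 0.0
        advance(s, 1.0, rates, NO_NOISE)   # t=13.0: fired
        assert s.value(7) == pytest.approx(100.0 / 3.0)
        assert not s.pending_steps

    def test_laundry_schedules_full_step_one_hour_later(self, rates):
        s = _state()
        s.clock = 9.0
        schedule_step_events(s, "laundry_loaded", _profile())
        (ev,) = s.pending_steps
        assert (ev.fire_time, ev.target, ev.amount) == (10.0, 11, 100.0)

    def test_no_event_when_target_not_performable(self, rates):
        s = _state(performable=ALL - {11})
        schedule_step_events(s, "laundry_loaded", _profile())
        assert not s.pending_steps
        assert s.value(11) == 0.0


class TestDecrease:
    def test_nominal_performance_removes_norm(self):
        p = _profile()
        s = _state({8: 150.0})
        decrease_on_completion(s, 8, nominal_duration(8, p), p)
        assert s.value(8) == pytest.approx(50.0, rel=1e-12)

    def test_decrease_scales_with_actual_duration(self):
        p = _profile()
        s = _state({10: 150.0})
        decrease_on_completion(s, 10, 0.5 * nominal_duration(10, p), p)
        assert s.value(10) == pytest.approx(100.0, rel=1e-12)

    def test_breakfast_removes_two_thirds(self):
        p = _profile()
        s = _state({3: 150.0})
        decrease_on_completion(s, 3, nominal_duration(3, p), p, is_breakfast=True)
        assert s.value(3) == pytest.approx(150.0 - 200.0 / 3.0, rel=1e-12)

    def test_relax_never_decreases(self):
        s = _state()
        decrease_on_completion(s, 13, 5.0, _profile())
        assert s.value(13) == 102.0

    def test_floor_at_zero(self):
        p = _profile()
        s = _state({8: 30.0})
        decrease_on_completion(s, 8, nominal_duration(8, p), p)
        assert s.value(8) == 0.0

    def test_step_as_clears_one_quantum(self):
        p = _profile()
        s = _state({11: 200.0})
        decrease_on_completion(s, 11, 0.05, p)
        assert s.value(11) == pytest.approx(100.0)

    def test_nonperformable_rejected(self):
        s = _state(performable=ALL - {9})
        with pytest.raises(ContractError):
            decrease_on_completion(s, 9, 1.0, _profile())


class TestActualDuration:
    @pytest.mark.parametrize(
        "i, d, lo, hi",
        [(1, 8.0, 7.76, 8.24), (8, 4.0, 1.2, 2.8), (5, 2.0, 0.8, 1.8), (3, 1.0, 0.95, 1.05)],
    )
    def test_bounds(self, i, d, lo, hi):
        p = _profile(D={i: d})
        rng = np.random.default_rng(0)
        draws = np.array([sample_actual_duration(i, p, rng) for _ in range(2000)])
        assert draws.min() >= lo - 1e-12 and draws.max() <= hi + 1e-12
        # the nominal duration is the interval midpoint
        assert nominal_duration(i, p) == pytest.approx((lo + hi) / 2.0)

    def test_relax_not_sampled_here(self):
        with pytest.raises(ContractError):
            sample_actual_duration(13, _profile(), np.random.default_rng(0))


class TestOutsideSatisfaction:
    def test_satisfies_due_motivations_with_enough_time(self):
        p = _profile()
        s = _state({3: 100.0, 6: 100.0, 7: 100.0})
        s.out_of_house = True
        outside_satisfaction(s, 3.0, p)
        # eat: AT = D_3 = 1.0, nominal = 1.0 -> full Norm_MV removed
        assert s.value(3) == 0.0
        assert s.value(6) == 0.0
        assert s.value(7) == 0.0

    def test_below_threshold_untouched(self):
        s = _state({3: 50.0})
        s.out_of_house = True
        outside_satisfaction(s, 3.0, _profile())
        assert s.value(3) == 50.0

    def test_insufficient_time_untouched(self):
        p = _profile()
        s = _state({3: 100.0})
        s.out_of_house = True
        outside_satisfaction(s, 0.5, p)  # D_3 = 1 h > 0.5 h left
        assert s.value(3) == 100.0

    def test_requires_out_of_house_context(self):
        with pytest.raises(ContractError):
            outside_satisfaction(_state(), 1.0, _profile())


class TestInitialize:
    def test_start_state(self):
        p = _profile()
        rates = increase_rates(p, ALL, norm_mv=100.0)
        state, tod = initialize(p, rates, ALL, np.random.default_rng(4))
        assert INIT_WINDOW_H[0] <= tod <= INIT_WINDOW_H[1]
        assert state.value(1) == 100.0
        assert state.value(7) == 0.0 and state.value(11) == 0.0
        assert state.value(13) == 102.0
        for i in range(1, 13):
            assert state.value(i) <= 100.0 + 1e-12

    def test_breakfast_initialization_formula(self):
        """MV_3 = Norm - 0.1*omega_3*D_1 - omega_3*g with g in [0.5, 1.5] h."""
        p = _profile()
        rates = increase_rates(p, ALL, norm_mv=100.0)
        w3 = rates.omega[3]
        vals = []
        for seed in range(30):
            state, _ = initialize(p, rates, ALL, np.random.default_rng(seed))
            vals.append(state.value(3))
        lo = 100.0 - 0.1 * w3 * 8.0 - w3 * 1.5
        hi = 100.0 - 0.1 * w3 * 8.0 - w3 * 0.5
        assert all(lo - 1e-9 <= v <= hi + 1e-9 for v in vals)

    def test_long_as_first_performances_staggered(self):
        p = _profile()
        rates = increase_rates(p, ALL, norm_mv=100.0)
        for seed in range(10):
            state, _ = initialize(p, rates, ALL, np.random.default_rng(seed))
            # reconstruct awake gaps to threshold for long ASs
            gaps = []
            for i in sorted(set(range(3, 13)) - {6, 7, 11}):
                if p.D[i] > 0.5 and rates.omega[i] > 0:
                    sleep_gain = 0.1 * rates.omega[i] * p.D[1] if i in (3, 6) else 0.0
                    gaps.append((100.0 - sleep_gain - state.value(i)) / rates.omega[i])
            gaps.sort()
            assert all(b - a >= 0.25 - 1e-9 for a, b in zip(gaps, gaps[1:]))


class TestSelection:
    def test_relax_dominates_when_nothing_competes(self):
        """With all other MVs at/below threshold, P(relax) = e^4/(e^4+12)."""
        s = _state({i: 50.0 for i in range(1, 13)})
        p = selection_probabilities(s)
        expected_relax = math.exp(4.0) / (math.exp(4.0) + 12.0)
        assert p[12] == pytest.approx(expected_relax, abs=1e-12)
        assert abs(expected_relax - 0.8198) < 5e-4
        others = [p[i] for i in range(12)]
        assert all(o == pytest.approx(1.0 / (math.exp(4.0) + 12.0), abs=1e-12) for o in others)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonperformable_get_zero_probability(self):
        s = _state(performable=ALL - {9, 11})
        p = selection_probabilities(s)
        assert p[8] == 0.0 and p[10] == 0.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_subthreshold_shifts_do_not_change_probabilities(self):
        a = _state({5: 10.0, 8: 103.0})
        b = _state({5: 90.0, 8: 103.0})
        assert np.allclose(selection_probabilities(a), selection_probabilities(b), atol=1e-15)

    def test_matches_bruteforce_softmax(self):
        """Stable implementation agrees with the naive clamped softmax."""
        rng = np.random.default_rng(42)
        norm = 100.0
        for _ in range(200):
            mv = rng.uniform(0.0, 1.2 * norm, size=13)
            mv[12] = 1.02 * norm
            s = MotivationState(mv=mv, performable=ALL, norm_mv=norm)
            w = np.exp(np.maximum(0.0, s.mv - 0.98 * norm))
            assert np.max(np.abs(selection_probabilities(s) - w / w.sum())) < 1e-12

    def test_large_values_do_not_overflow(self):
        s = _state(norm=200.0, mv_values={6: 450.0})
        p = selection_probabilities(s)
        assert np.isfinite(p).all() and p[5] == pytest.approx(1.0, abs=1e-20)
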
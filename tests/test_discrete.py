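"""Trial-level dynamics: acquisition, extinction, hidden/virtual trials,
error blocking, and the two-quantities stability theorem."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import placebosim as ps
from placebosim.discrete import (
    InstabilityError,
    InvalidStateError,
    ProtocolConfigError,
    State,
)


def acquisition_y(x, alpha, n, init=State()):
    recs = ps.run_protocol([ps.Trial(kind="active", x=x)] * n,
                           ps.ModelParams(alpha=alpha), init)
    return np.array([r.y for r in recs])


class TestTrialStep:
    @pytest.mark.parametrize(
        "trial, state, alpha, expect",
        [
            # first open active administration: y = x, full error, i_R gains alpha*x
            (ps.Trial(kind="active", x=1.0), State(0, 0), 0.5,
             dict(y=1.0, e=1.0, i_R=0.5)),
            # placebo from naive state: nothing to elicit, nothing to learn
            (ps.Trial(kind="placebo"), State(0, 0), 0.5,
             dict(y=0.0, e=0.0, i_R=0.0)),
            # virtual trial: the inferred outcome drives the error
            (ps.Trial(kind="virtual", simulated_outcome=2.0), State(0.5, 1.0), 0.5,
             dict(y=2.0, e=1.0, i_R=1.0, expected_after=2.0)),
        ],
    )
    def test_single_step_examples(self, trial, state, alpha, expect):
        record, new_state = ps.trial_step(trial, state, ps.ModelParams(alpha=alpha))
        assert record.y == pytest.approx(expect["y"])
        assert record.e == pytest.approx(expect["e"])
        assert new_state.i_R == pytest.approx(expect["i_R"])
        if "expected_after" in expect:
            assert new_state.expected == pytest.approx(expect["expected_after"])

    def test_modulators_enter_outcome_and_error(self):
        trial = ps.Trial(kind="active", x=1.0, gamma=0.25, misattributed=0.5,
                         baseline_shift=-0.25)
        record, state = ps.trial_step(trial, State(0.0, 0.0), ps.ModelParams(alpha=0.4))
        assert record.y == pytest.approx(1.0 + 0.25 + 0.5 - 0.25)
        assert record.e == pytest.approx(record.y)
        assert state.i_R == pytest.approx(0.4 * record.y)

    def test_hidden_trial_freezes_learner(self):
        trial = ps.Trial(kind="hidden", x=2.0, baseline_shift=0.5)
        state0 = State(i_R=0.7, expected=1.3)
        record, state = ps.trial_step(trial, state0, ps.ModelParams(alpha=0.5))
        assert record.y == pytest.approx(2.5)  # drug acts, baseline included
        assert math.isnan(record.e)  # no UCS perceived -> no error computed
        assert state == state0

    def test_error_blocked_trial_keeps_reactive_response(self):
        params = ps.ModelParams(alpha=0.5, precision_factor=0.0)
        trial = ps.Trial(kind="placebo", error_blocked=True)
        record, state = ps.trial_step(trial, State(i_R=1.0, expected=2.0), params)
        assert record.y == pytest.approx(1.0)  # placebo elicits the reactive response
        assert state.i_R == pytest.approx(1.0)  # blocked: no extinction step
        assert state.expected == pytest.approx(1.0)  # experienced outcome still updates

    def test_partial_blocking_interpolates(self):
        params = ps.ModelParams(alpha=0.5, precision_factor=0.4)
        trial = ps.Trial(kind="placebo", error_blocked=True)
        _, state = ps.trial_step(trial, State(i_R=1.0, expected=2.0), params)
        # raw e = -1, attenuated to -0.4, update alpha*(-0.4)
        assert state.i_R == pytest.approx(1.0 - 0.5 * 0.4)

    def test_misattribution_self_consistent_state_is_resistant(self):
        # expected already equals the elicited response -> zero error, no update
        params = ps.ModelParams(alpha=0.5)
        trial = ps.Trial(kind="placebo", misattributed=0.8)
        record, state = ps.trial_step(trial, State(i_R=0.0, expected=0.8), params)
        assert record.e == pytest.approx(0.0)
        assert state.i_R == pytest.approx(0.0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ProtocolConfigError):
            ps.Trial(kind="virtual")  # missing simulated_outcome
        with pytest.raises(ProtocolConfigError):
            ps.Trial(kind="placebo", x=1.0)
        with pytest.raises(InvalidStateError):
            State(i_R=float("nan"))
        with pytest.raises(InvalidStateError):
            ps.Trial(kind="active", x=float("inf"))


class TestRunProtocol:
    def test_three_active_trials_geometric_buildup(self):
        assert acquisition_y(1.0, 0.5, 3) == pytest.approx([1.0, 1.5, 1.75])

    def test_alpha_zero_disables_learning(self):
        recs = ps.run_protocol(
            [ps.Trial(kind="active", x=2.0)] * 4 + [ps.Trial(kind="placebo")] * 2,
            ps.ModelParams(alpha=0.0),
        )
        assert [r.y for r in recs] == pytest.approx([2, 2, 2, 2, 0, 0])
        assert all(r.i_R == 0.0 for r in recs)

    def test_hidden_trials_do_not_advance_acquisition(self):
        trials = [ps.Trial(kind="active", x=1.0)] + [ps.Trial(kind="hidden", x=1.0)] * 2
        recs = ps.run_protocol(trials, ps.ModelParams(alpha=0.5))
        assert [r.y for r in recs] == pytest.approx([1.0, 1.0, 1.0])
        assert recs[-1].i_R == pytest.approx(0.5)  # frozen after the open trial

    def test_empty_protocol_rejected(self):
        with pytest.raises(ProtocolConfigError):
            ps.run_protocol([], ps.ModelParams(alpha=0.5))

    def test_error_is_annotated_with_trial_index(self):
        trials = [ps.Trial(kind="active", x=1.0),
                  ps.Trial(kind="active", gamma=float("nan"))]
        with pytest.raises(InvalidStateError, match="trial 2"):
            ps.run_protocol(trials, ps.ModelParams(alpha=0.5))

    def test_unstable_alpha_warns_but_runs(self):
        with pytest.warns(ps.InstabilityWarning):
            recs = ps.run_protocol([ps.Trial(kind="active", x=1.0)] * 5,
                                   ps.ModelParams(alpha=1.5))
        assert len(recs) == 5
        assert recs[-1].y > recs[0].y


class TestClosedForms:
    @pytest.mark.parametrize(
        "x, alpha, n, expect",
        [
            (1.0, 0.5, 3, (1.75, 0.75, 0.25)),
            (1.0, 0.5, 1, (1.0, 0.0, 1.0)),
            (5.0, 0.0, 10, (5.0, 0.0, 0.0)),
        ],
    )
    def test_acquisition_values(self, x, alpha, n, expect):
        assert ps.acquisition_closed_form(x, alpha, n) == pytest.approx(expect)

    def test_alpha_one_limit_is_linear(self):
        y, i_R, e = ps.acquisition_closed_form(2.0, 1.0, 7)
        assert (y, i_R, e) == pytest.approx((14.0, 12.0, 2.0))

    @pytest.mark.parametrize(
        "x, alpha, expect",
        [
            (1.0, 0.5, (2.0, 1.0)),
            (1.0, 0.45, (1 / 0.55, 0.45 / 0.55)),
            (0.0, 0.3, (0.0, 0.0)),
        ],
    )
    def test_asymptote(self, x, alpha, expect):
        assert ps.asymptotic_response(x, alpha) == pytest.approx(expect)

    def test_asymptote_requires_stability(self):
        with pytest.raises(InstabilityError):
            ps.asymptotic_response(1.0, 1.0)
        with pytest.raises(InstabilityError):
            ps.asymptotic_response(1.0, -1.2)

    @pytest.mark.parametrize("n, expect", [(1, 1.0), (3, 0.25)])
    def test_extinction_values(self, n, expect):
        assert ps.extinction_closed_form(1.0, 0.5, n) == pytest.approx(expect)

    def test_extinction_vanishes(self):
        assert ps.extinction_closed_form(1.0, 0.5, 60) == pytest.approx(0.0, abs=1e-15)

    def test_extinction_matches_stepwise_simulation(self):
        x, alpha, n = 2.0, 0.45, 12
        recs = ps.run_protocol([ps.Trial(kind="placebo")] * n,
                               ps.ModelParams(alpha=alpha),
                               ps.asymptotic_state(x, alpha))
        for k, r in enumerate(recs, start=1):
            assert r.y == pytest.approx(ps.extinction_closed_form(x, alpha, k), rel=1e-12)


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x=st.floats(-5, 5),
        alpha=st.floats(-0.99, 0.99),
        n=st.integers(1, 50),
    )
    def test_simulator_matches_closed_form(self, x, alpha, n):
        """Step-wise fold reproduces the geometric-series closed forms."""
        recs = ps.run_protocol([ps.Trial(kind="active", x=x)] * n,
                               ps.ModelParams(alpha=alpha))
        y_cf, _, e_cf = ps.acquisition_closed_form(x, alpha, n)
        # records store i_R after the trial's update = in-trial value at n+1
        _, i_R_next, _ = ps.acquisition_closed_form(x, alpha, n + 1)
        scale = max(abs(y_cf), 1.0)
        assert abs(recs[-1].y - y_cf) <= 1e-10 * scale
        assert abs(recs[-1].i_R - i_R_next) <= 1e-10 * scale
        assert abs(recs[-1].e - e_cf) <= 1e-10 * scale

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=st.floats(0.1, 5), alpha=st.floats(-0.95, 0.95), n=st.integers(3, 30))
    def test_geometric_error_decay(self, x, alpha, n):
        """Consecutive acquisition errors have exact ratio alpha."""
        recs = ps.run_protocol([ps.Trial(kind="active", x=x)] * n,
                               ps.ModelParams(alpha=alpha))
        e = np.array([r.e for r in recs])
        nz = np.abs(e[:-1]) > 1e-12 * x
        assert e[1:][nz] == pytest.approx(alpha * e[:-1][nz], rel=1e-9, abs=1e-12)

    def test_stability_dichotomy(self):
        y_stable = acquisition_y(1.0, 0.8, 200)
        assert np.all(np.abs(y_stable) <= 1.0 / (1 - 0.8) + 1e-9)
        assert np.all(np.diff(np.abs(y_stable)) >= -1e-12)  # monotone approach
        with pytest.warns(ps.InstabilityWarning):
            y_unstable = acquisition_y(1.0, 1.3, 200)
        assert np.abs(y_unstable[-1]) > 1e20

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), alpha=st.floats(-0.9, 0.9))
    def test_superposition(self, a, b, alpha):
        """Responses to summed stimuli equal the sum of responses."""
        total = acquisition_y(a + b, alpha, 15)
        assert total == pytest.approx(acquisition_y(a, alpha, 15)
                                      + acquisition_y(b, alpha, 15),
                                      rel=1e-9, abs=1e-9)

    def test_extinction_conservation(self):
        x, alpha = 1.0, 0.45
        recs = ps.run_protocol([ps.Trial(kind="placebo")] * 10,
                               ps.ModelParams(alpha=alpha),
                               ps.asymptotic_state(x, alpha))
        y = np.array([r.y for r in recs])
        assert y[1:] == pytest.approx(alpha * y[:-1], rel=1e-12)

    def test_nocebo_symmetry(self):
        pos = ps.run_protocol([ps.Trial(kind="active", x=1.0)] * 10,
                              ps.ModelParams(alpha=0.45))
        neg = ps.run_protocol([ps.Trial(kind="active", x=-1.0)] * 10,
                              ps.ModelParams(alpha=0.45))
        for p, n in zip(pos, neg):
            assert (n.y, n.e, n.i_R) == pytest.approx((-p.y, -p.e, -p.i_R))


class TestCycleProtocol:
    def test_perfect_cycles_accumulate_reactive_floor(self):
        _, i_R0 = ps.run_cycle_protocol(1.0, 0.5, n_active=60, n_blocked_placebo=5,
                                        n_cycles=3)
        assert i_R0 == pytest.approx(3.0, abs=1e-10)

    def test_cycle_accumulation_is_linear_in_cycles(self):
        _, one = ps.run_cycle_protocol(2.0, 0.45, 60, 4, 1)
        _, five = ps.run_cycle_protocol(2.0, 0.45, 60, 4, 5)
        assert five == pytest.approx(5 * one, abs=1e-10)

    def test_unblocked_placebo_reduces_to_extinction(self):
        params = ps.ModelParams(alpha=0.5, precision_factor=1.0)
        _, i_R0 = ps.run_cycle_protocol(1.0, 0.5, n_active=60, n_blocked_placebo=80,
                                        n_cycles=1, params=params)
        assert i_R0 == pytest.approx(0.0, abs=1e-12)

    def test_zero_cycles_identity(self):
        records, i_R0 = ps.run_cycle_protocol(1.0, 0.5, 10, 5, 0)
        assert records == [] and i_R0 == 0.0

    def test_blocked_response_follows_accumulated_floor(self):
        # after one perfect cycle the next acquisition run rides on i_R0
        records, _ = ps.run_cycle_protocol(1.0, 0.5, 60, 5, 2)
        second_cycle = records[65:125]
        i_R0 = 1.0  # locked in by cycle 1 (= x*alpha/(1-alpha))
        for n, r in enumerate(second_cycle, start=1):
            y_cf, _, _ = ps.acquisition_closed_form(1.0, 0.5, n)
            assert r.y == pytest.approx(y_cf + i_R0, rel=1e-9)


class TestTheoremDemonstration:
    def test_single_quantity_model_grows_linearly(self):
        y = ps.single_quantity_variant(1.0, 5)
        assert y == pytest.approx([1, 2, 3, 4, 5])
        assert ps.single_quantity_variant(0.0, 7) == pytest.approx(np.zeros(7))

    def test_two_quantity_model_stays_bounded(self):
        single = ps.single_quantity_variant(1.0, 100)
        two = acquisition_y(1.0, 0.5, 100)
        assert single[-1] == pytest.approx(100.0)
        # bounded by the asymptote x/(1-alpha) (reached only in the float limit)
        assert np.all(two <= 2.0)
        assert np.all(two[:20] < 2.0)


def test_trace_frame_schema():
    recs = ps.run_protocol([ps.Trial(kind="active", x=1.0)] * 2,
                           ps.ModelParams(alpha=0.5))
    frame = ps.records_to_frame(recs)
    assert list(frame.columns) == [
        "trial_index", "kind", "x", "gamma", "misattributed",
        "baseline_shift", "expected", "y", "e", "i_R",
    ]
    assert list(frame["trial_index"]) == [1, 2]
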
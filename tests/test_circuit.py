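"""One ART module: registration, AND-matching, choice, reset, learning."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from artgc.circuit import (
    ARTModule,
    ARTParams,
    ARTWeights,
    NoCategoryAvailable,
    RESONANT_OUTPUT,
    WEAK_OUTPUT_BAND,
    learn,
    mismatch_drive,
    resonance_status,
)
from artgc.dynamics import LayerState, TraceRecorder

DT = 0.01


def tiny_module(templates, vigilance=0.8, n_input=10, r_preset="fast", **overrides):
    t = np.zeros((len(templates), n_input))
    for j, sup in enumerate(templates):
        t[j, list(sup)] = 1.0
    w = ARTWeights.from_templates(t)
    params = replace(ARTParams(), vigilance=vigilance, **overrides)
    return ARTModule("tiny", n_input, w, params, r_preset=r_preset)


def pattern(n, support, amplitude=1.0):
    p = np.zeros(n)
    p[list(support)] = amplitude
    return p


class TestWeights:
    def test_from_templates_normalized(self):
        w = ARTWeights.from_templates(np.array([[1.0, 1, 0, 0], [0, 0, 1, 1]]))
        assert np.allclose(w.bottom_up.sum(axis=1), 1.0)
        assert np.array_equal(w.top_down, [[1, 1, 0, 0], [0, 0, 1, 1]])
        assert w.committed.all()

    def test_range_enforced(self):
        with pytest.raises(ValueError):
            ARTWeights(
                np.array([[1.5, 0.0]]), np.array([[1.0, 0.0]]), np.ones(1, bool)
            )

    def test_json_round_trip(self, tmp_path):
        w = ARTWeights.from_templates(np.array([[1.0, 0, 1], [0, 1, 0]]))
        path = tmp_path / "w.json"
        w.to_json(path)
        w2 = ARTWeights.from_json(path)
        assert np.array_equal(w.bottom_up, w2.bottom_up)
        assert np.array_equal(w.top_down, w2.top_down)


class TestRegisterInput:
    def test_zero_pattern_silent_f0_and_tonic_g2(self):
        mod = tiny_module([{0, 1, 2, 3}])
        mod.run(10.0, DT)
        assert np.all(mod.f0.outputs == 0.0)
        assert mod.g2.outputs[0] > 0.1  # G2 uninhibited without input

    def test_input_suppresses_g2(self):
        mod = tiny_module([{0, 1, 2, 3}])
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        mod.run(10.0, DT)
        assert mod.g2.outputs[0] < 0.01

    def test_uniform_noise_suppressed(self):
        """A hue bump plus 10% uniform noise: only bump nodes are supra."""
        mod = tiny_module([{0, 1, 2, 3}])
        p = pattern(10, {0, 1, 2, 3}) + 0.1
        mod.register_input(p)
        mod.run(10.0, DT)
        assert np.all(mod.f0.outputs[:4] > 0.0)
        assert np.all(mod.f0.outputs[4:] == 0.0)

    def test_two_patterns_preserved(self):
        """F0 contrast-enhances but does not choose between two bumps."""
        mod = tiny_module([{0, 1}, {6, 7}], vigilance=0.3)
        mod.register_input(pattern(10, {0, 1}) + pattern(10, {6, 7}))
        mod.run(10.0, DT)
        assert np.all(mod.f0.outputs[[0, 1, 6, 7]] > 0.0)

    def test_negative_rejected(self):
        mod = tiny_module([{0}])
        with pytest.raises(ValueError, match="non-negative"):
            mod.register_input(-pattern(10, {0}))

    def test_wrong_length_rejected(self):
        mod = tiny_module([{0}])
        with pytest.raises(ValueError):
            mod.register_input(np.ones(7))


class TestF1Matching:
    def test_mirrors_f0_without_f2(self):
        """In the absence of top-down signals F1 is supra on the F0 set."""
        mod = tiny_module([{6, 7, 8}], vigilance=0.2)
        mod.register_input(pattern(10, {3, 4, 5}))
        # G2 held on (no category should win) not needed: template disjoint
        for _ in range(300):
            mod.step(DT)
            if mod.f2.outputs.max() > 0:
                break
        early = mod.f1.outputs
        assert np.all(early[[3, 4, 5]] > 0.0)

    def test_priming_never_reaches_threshold(self):
        """Top-down expectation alone leaves every F1 node sub-threshold."""
        mod = tiny_module([{3, 4, 5, 6}])
        mod.set_priming(np.array([0.8]))
        mod.run(20.0, DT)
        theta = mod.params.f1.params.output_threshold
        assert np.all(mod.f1.potentials < theta)
        assert np.all(mod.f1.outputs == 0.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(amp=st.floats(0.05, 1.5))
    def test_no_hallucination_any_priming_amplitude(self, amp):
        """The module never resonates (and F1 never fires) on priming alone."""
        mod = tiny_module([{2, 3, 4, 5}, {6, 7, 8, 9}])
        mod.set_priming(np.array([amp, amp / 2]))
        mod.run(12.0, DT)
        assert np.all(mod.f1.outputs == 0.0)
        assert mod.f2.outputs.max() < RESONANT_OUTPUT

    def test_and_of_input_and_template(self):
        """F0 on {3,4,5} against an expected template {5,6,7}: F1 ends up
        supra-threshold on the intersection {5} only."""
        mod = tiny_module([{5, 6, 7}], vigilance=0.2)
        mod.set_priming(np.array([0.8]))  # the template is the expectation
        mod.register_input(pattern(10, {3, 4, 5}))
        mod.run(30.0, DT)
        assert mod.f2.outputs[0] > RESONANT_OUTPUT  # category active
        supra = set(np.flatnonzero(mod.f1.outputs > 0.0).tolist())
        assert supra == {5}


class TestF2Choice:
    def test_single_candidate_full_amplitude(self):
        mod = tiny_module([{0, 1, 2, 3}, {6, 7, 8, 9}])
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        mod.run(30.0, DT)
        assert mod.f2.outputs[0] > RESONANT_OUTPUT
        assert mod.f2.outputs[1] < WEAK_OUTPUT_BAND
        assert mod.latched.sum() == 0

    def test_settled_choice_is_winner_take_all(self):
        mod = tiny_module([{0, 1, 2, 3}, {2, 3, 4, 5}], vigilance=0.3)
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        mod.run(30.0, DT)
        assert int(np.sum(mod.f2.outputs >= RESONANT_OUTPUT)) == 1

    def test_exact_tie_resolved_to_lowest_index(self):
        mod = tiny_module([{0, 1}, {4, 5}], vigilance=0.3)
        mod.register_input(pattern(10, {0, 1, 4, 5}))
        mod.run(30.0, DT)
        assert mod.f2.outputs[0] > RESONANT_OUTPUT
        assert mod.f2.outputs[1] < WEAK_OUTPUT_BAND

    def test_latched_candidate_frees_the_runner_up(self):
        """With the best-matching category latched, the field settles on the
        next one instead."""
        mod = tiny_module([{0, 1, 2, 3}, {2, 3, 4, 5}], vigilance=0.3)
        mod.latched[0] = True
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        mod.run(30.0, DT)
        assert mod.f2.outputs[0] == 0.0
        assert mod.f2.outputs[1] > RESONANT_OUTPUT


class TestMismatchDrive:
    def _state(self, outputs):
        o = np.asarray(outputs, dtype=float)
        return LayerState(o.copy(), o)

    def test_full_match_zero(self):
        assert mismatch_drive(self._state([1.0]), self._state([1.0]), 0.9) == 0.0

    def test_empty_f1(self):
        assert mismatch_drive(self._state([1.0]), self._state([0.0]), 0.9) == (
            pytest.approx(0.9)
        )

    def test_boundary_counts_as_match(self):
        assert mismatch_drive(self._state([1.0]), self._state([0.9]), 0.9) == 0.0

    def test_no_input_no_drive(self):
        assert mismatch_drive(self._state([0.0]), self._state([0.0]), 0.9) == 0.0


class TestOrientingSubsystem:
    def test_unknown_preset_rejected(self):
        mod = tiny_module([{0}])
        with pytest.raises(ValueError, match="preset"):
            mod.set_r_preset("ludicrous")

    def test_preset_ordering_enforced(self):
        t = np.ones((1, 4))
        w = ARTWeights.from_templates(t)
        with pytest.raises(ValueError, match="tau_fast"):
            ARTModule(
                "m", 4, w, r_time_constants={"fast": 5, "medium": 4, "slow": 20}
            )

    def test_mismatch_without_f2_leaves_r_quiet(self):
        """The first feedforward wave (F0 before F1) must not trigger R."""
        mod = tiny_module([{6, 7, 8, 9}])  # template disjoint from input
        mod.register_input(pattern(10, {0, 1, 2}))
        mod.run(6.0, DT)
        # no category can win (no bottom-up overlap), so R must stay sub
        theta = mod.params.r.params.output_threshold
        assert mod.f2.outputs.max() < RESONANT_OUTPUT
        assert mod.r.potentials[0] <= theta

    def test_f2_without_mismatch_leaves_r_quiet(self):
        mod = tiny_module([{0, 1, 2, 3}])
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        mod.run(30.0, DT)
        assert mod.f2.outputs[0] > RESONANT_OUTPUT
        assert mod.r.outputs[0] == 0.0

    def test_latch_gate_requires_both_signals(self):
        mod = tiny_module([{0, 1}])
        # R supra, F2 silent: latch unchanged
        mod._r_was_supra = False
        mod.r = LayerState(np.array([0.5]), np.array([1.0]))
        mod.f3_reset()
        assert mod.latched.sum() == 0
        # R sub, F2 active: latch unchanged
        mod.reset_state()
        mod.f2 = LayerState(np.array([0.8]), np.array([0.7]))
        mod.f3_reset()
        assert mod.latched.sum() == 0
        # both: latched
        mod.r = LayerState(np.array([0.5]), np.array([1.0]))
        mod._r_was_supra = False
        with pytest.raises(NoCategoryAvailable):
            mod.f3_reset()  # single category -> nothing left to search
        assert mod.latched[0]

    def test_latch_permanence(self):
        """Once latched, a category's output is zero until trial end under
        full bottom-up drive."""
        mod = tiny_module([{0, 1, 2, 3}, {6, 7, 8, 9}])
        mod.latched[0] = True
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        for _ in range(int(20.0 / DT)):
            mod.step(DT)
            assert mod.f2.outputs[0] == 0.0

    def test_vigilance_monotonicity(self):
        """For a fixed partial-overlap input against a primed expectation,
        raising vigilance can only convert match into reset, never the
        reverse."""
        resets = []
        for rho in (0.2, 0.4, 0.6, 0.9, 0.95):
            mod = tiny_module(
                [{0, 1, 2, 3}, {6, 7, 8, 9}], vigilance=rho, r_preset="fast"
            )
            mod.set_priming(np.array([0.8, 0.0]))
            mod.register_input(pattern(10, {0}) + pattern(10, {4, 5}))
            mod.run(40.0, DT)
            resets.append(bool(mod.latched[0]))
        assert resets == sorted(resets)  # monotone False..True
        assert not resets[0] and resets[-1]


class TestResonanceStatus:
    def _run(self, mod, duration):
        rec = TraceRecorder()
        mod.run(duration, DT, recorder=rec)
        return rec.build()

    def test_idle(self):
        mod = tiny_module([{0, 1, 2, 3}])
        tr = self._run(mod, 5.0)
        assert resonance_status(mod, tr, 2.0) == "idle"

    def test_priming(self):
        mod = tiny_module([{0, 1, 2, 3}])
        mod.set_priming(np.array([0.8]))
        tr = self._run(mod, 20.0)
        assert resonance_status(mod, tr, 2.0) == "priming"

    def test_resonant(self):
        mod = tiny_module([{0, 1, 2, 3}, {6, 7, 8, 9}])
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        tr = self._run(mod, 30.0)
        assert resonance_status(mod, tr, 2.0) == "resonant(0)"

    def test_searching_then_resonant(self):
        """A primed wrong expectation yields a search (reset) before the
        correct category resonates."""
        mod = tiny_module([{0, 1, 2, 3}, {6, 7, 8, 9}], r_preset="fast")
        mod.set_priming(np.array([0.0, 0.8]))
        rec = TraceRecorder()
        mod.run(20.0, DT, recorder=rec)  # priming phase
        mod.register_input(pattern(10, {0, 1, 2, 3}))
        mod.run(40.0, DT, recorder=rec, t0=20.0)
        tr = rec.build()
        theta = mod.params.r.params.output_threshold
        r_series = tr.potentials[("tiny", "r")][:, 0]
        above = np.flatnonzero(r_series > theta)
        assert above.size, "reset should have occurred"
        t_reset = tr.times[above[0]]
        assert resonance_status(mod, tr.window(0.0, t_reset + 0.2), 1.0) == (
            "searching"
        )
        assert resonance_status(mod, tr, 2.0) == "resonant(0)"
        assert mod.latched[1] and not mod.latched[0]


class TestLearning:
    def _resonant_module(self, templates, inp, vigilance=0.2, prime=None):
        mod = tiny_module(templates, vigilance=vigilance)
        if prime is not None:
            mod.set_priming(np.asarray(prime, dtype=float))
        mod.register_input(inp)
        mod.run(30.0, DT)
        return mod

    def test_refused_outside_resonance(self):
        mod = tiny_module([{0, 1, 2, 3}])
        with pytest.raises(RuntimeError, match="resonant"):
            learn(mod)

    def test_matched_pattern_is_fixed_point(self):
        mod = self._resonant_module(
            [{0, 1, 2, 3}, {6, 7, 8, 9}], pattern(10, {0, 1, 2, 3})
        )
        w2 = learn(mod)
        assert np.array_equal(w2.top_down, mod.weights.top_down)
        assert np.allclose(w2.bottom_up, mod.weights.bottom_up)

    def test_template_contracts_to_intersection(self):
        mod = self._resonant_module(
            [{2, 3, 4, 5}, {7, 8, 9}], pattern(10, {2, 3}), prime=[0.8, 0.0]
        )
        w2 = learn(mod)
        assert np.array_equal(np.flatnonzero(w2.top_down[0]), [2, 3])
        assert np.array_equal(w2.top_down[1], mod.weights.top_down[1])

    def test_stable_direct_access_after_learning(self):
        """Re-presenting the learned pattern resonates with zero resets."""
        mod = self._resonant_module(
            [{2, 3, 4, 5}, {7, 8, 9}], pattern(10, {2, 3}), prime=[0.8, 0.0]
        )
        w2 = learn(mod)
        mod2 = ARTModule("tiny", 10, w2, mod.params, r_preset="fast")
        mod2.register_input(pattern(10, {2, 3}))
        mod2.run(30.0, DT)
        assert mod2.f2.outputs[0] > RESONANT_OUTPUT
        assert mod2.latched.sum() == 0
        assert mod2.mismatch() == 0.0
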
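"""Delay buffer, AU amplification, condition gating, and baseline replay."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirrorkit import (
    ConfigurationError,
    DelayBuffer,
    ExpressionState,
    FaceState,
    HeadPose,
    Pipeline,
    ReplaySource,
    SimulatedClock,
    au_scale,
    condition_gate,
    make_rest_script,
    sample_states,
)


def _state(yaw=0.0, au12=0.0):
    return FaceState(
        pose=HeadPose(ry=yaw),
        expression=ExpressionState.neutral().with_au("AU12", au12),
    )


def _random_state(rng):
    return FaceState(
        pose=HeadPose.from_array(rng.uniform(-30, 30, 6)),
        expression=ExpressionState(rng.uniform(0, 5, 17)),
    )


class TestDelayBuffer:
    def test_zero_delay_is_identity(self):
        buf = DelayBuffer(0.0)
        for i in range(10):
            t = i * 10.0
            state = _state(yaw=float(i))
            buf.push(state, t)
            out, emitted_t = buf.emit(t)
            assert out.pose.ry == float(i)
            assert emitted_t == t

    def test_step_input_appears_after_exactly_the_delay(self):
        # yaw steps 0 -> 25 at t=1000 ms; with d=2000 the step emerges at t=3000
        buf = DelayBuffer(2000.0)
        dt = 1000.0 / 120
        times = np.arange(0, 5000, dt)
        outputs = []
        for t in times:
            buf.push(_state(yaw=25.0 if t >= 1000 else 0.0), t)
            out, _ = buf.emit(t)
            outputs.append(out.pose.ry)
        outputs = np.array(outputs)
        first_turned = times[np.argmax(outputs == 25.0)]
        assert 3000 - dt <= first_turned <= 3000 + dt

    def test_warmup_emits_flagged_neutral(self):
        buf = DelayBuffer(500.0)
        buf.push(_state(yaw=10.0), 0.0)
        out, emitted_t = buf.emit(100.0)
        assert emitted_t is None
        assert out.pose.ry == 0.0 and out.expression.is_neutral()

    @pytest.mark.parametrize("d", [0.0, 500.0, 2000.0])
    def test_age_contract_on_120fps_stream(self, d):
        buf = DelayBuffer(d)
        dt = 1000.0 / 120
        ages = []
        for i in range(int(5000 / dt)):
            t = i * dt
            buf.push(_state(yaw=float(i % 7)), t)
            _, emitted_t = buf.emit(t)
            if emitted_t is not None:
                ages.append(t - emitted_t)
        ages = np.array(ages)
        assert np.all(ages >= d)
        assert np.all(ages <= d + dt + 1e-9)
        if d == 500.0:
            assert 500.0 <= ages.mean() <= 508.4

    def test_non_monotonic_push_rejected(self):
        buf = DelayBuffer(0.0)
        buf.push(_state(), 100.0)
        with pytest.raises(ValueError):
            buf.push(_state(), 50.0)


class TestAuScale:
    def test_factor_one_is_identity(self):
        state = _state(yaw=5.0, au12=2.0)
        out = au_scale(state, 1.0)
        assert np.array_equal(out.as_vector(), state.as_vector())

    def test_amplification_by_1_5(self):
        out = au_scale(_state(au12=2.0), 1.5)
        assert out.expression["AU12"] == pytest.approx(3.0)

    def test_clamps_at_au_ceiling(self):
        state = FaceState(expression=ExpressionState.neutral().with_au("AU06", 4.5))
        out = au_scale(state, 2.0)
        assert out.expression["AU06"] == 5.0

    def test_pose_untouched(self):
        out = au_scale(_state(yaw=17.0, au12=1.0), 3.0)
        assert out.pose.ry == 17.0

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            au_scale(_state(), -0.5)

    @given(
        s1=st.floats(0.1, 1.2),
        s2=st.floats(0.1, 1.2),
        au=st.floats(0.0, 3.0),
    )
    def test_composition_is_multiplicative_below_clamp(self, s1, s2, au):
        state = _state(au12=au)
        if s1 * s2 * au <= 5.0 and s2 * au <= 5.0:
            composed = au_scale(au_scale(state, s2), s1)
            direct = au_scale(state, s1 * s2)
            np.testing.assert_allclose(
                composed.expression.au, direct.expression.au, atol=1e-12
            )


class TestConditionGate:
    def test_pose_only_neutralizes_expression(self):
        out = condition_gate(_state(yaw=10.0, au12=3.0), "P")
        assert out.pose.ry == 10.0
        assert out.expression.is_neutral()

    def test_expression_only_holds_pose_at_rest(self):
        out = condition_gate(_state(yaw=10.0, au12=3.0), "E")
        assert out.pose.ry == 0.0
        assert out.expression["AU12"] == 3.0

    def test_pose_and_expression_is_identity(self):
        state = _state(yaw=10.0, au12=3.0)
        out = condition_gate(state, "PE")
        assert out is state

    def test_baseline_returns_replay_ignoring_input(self):
        replay = _state(yaw=-4.0)
        out = condition_gate(_state(yaw=30.0, au12=5.0), "B", replay_state=replay)
        assert out is replay

    def test_baseline_without_replay_is_config_error(self):
        with pytest.raises(ConfigurationError):
            condition_gate(_state(), "B")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            condition_gate(_state(), "X")

    def test_gate_algebra(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = _random_state(rng)
            # P idempotent
            p1 = condition_gate(x, "P")
            p2 = condition_gate(p1, "P")
            assert np.array_equal(p1.as_vector(), p2.as_vector())
            # E after P == fully at rest and neutral
            ep = condition_gate(condition_gate(x, "P"), "E")
            assert np.all(ep.pose.as_array() == 0.0)
            assert ep.expression.is_neutral()


class TestReplaySource:
    def _recording(self):
        script = make_rest_script(duration_s=2, breathing_amplitude=2.0,
                                  breathing_period_s=2.0)
        return sample_states(script, fps=10, n_frames=20)

    def test_wraparound_at_duration_returns_first_state(self):
        samples = self._recording()
        replay = ReplaySource(samples, loop=True)
        wrapped = replay.state_at(replay.duration_ms)
        assert np.array_equal(wrapped.as_vector(), samples[0].state.as_vector())

    def test_unlooped_holds_final_state(self):
        samples = self._recording()
        replay = ReplaySource(samples, loop=False)
        held = replay.state_at(1e9)
        assert np.array_equal(held.as_vector(), samples[-1].state.as_vector())

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            ReplaySource([])

    def test_baseline_decouples_avatar_from_live_input(self, tmp_path):
        # identical replay output whether the live face is neutral or extreme
        from mirrorkit import write_track

        rest = tmp_path / "rest.csv"
        write_track(self._recording(), rest)
        outputs = {}
        for kind, yaw in (("neutral", 0.0), ("extreme", 25.0)):
            p = Pipeline(
                f"synth_source fps=30 yaw={yaw} script=calibration\n"
                f"gate mode=B replay={rest.name}\nsink",
                clock=SimulatedClock(),
                workdir=tmp_path,
            )
            report = p.run_stepped(30)
            outputs[kind] = [d["pose.tz"] for d in report.delivered_data]
        assert outputs["neutral"] == outputs["extreme"]


class TestDelayPipelineModule:
    def test_invalid_state_passthrough_flagged(self):
        from mirrorkit.modules import AuScale
        from mirrorkit.pipeline import PipelineContext
        from mirrorkit.face import state_to_data

        ctx = PipelineContext(clock=SimulatedClock())
        module = AuScale("au_scale", {"factor": "2.0"}, ctx)
        data = state_to_data(FaceState(valid=False))
        data["au.AU12"] = 2.0
        out, _ = module.process(dict(data), None)
        assert out["manipulator.skipped"] is True
        assert out["au.AU12"] == 2.0  # untouched
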
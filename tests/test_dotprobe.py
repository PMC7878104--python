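"""Dot-probe engine: plan structure, probe contingency, execution, gating."""

import collections

import pytest
from hypothesis import given
from hypothesis import strategies as hst

from steptrain import (
    InvalidInputError,
    ProtocolConstants,
    SessionLog,
    ThoughtStimulus,
    anti_responder,
    block_summary,
    build_session_plan,
    classify_for_training,
    perfect_responder,
    protocol_adherence,
    run_session,
    tutorial_gate,
)
from steptrain.dotprobe import PAIRING_TYPES, TrialRecord, TrialSpec


@pytest.fixture(scope="module")
def partition(small_inventory):
    return classify_for_training(small_inventory)


@pytest.fixture(scope="module")
def plan(partition):
    return build_session_plan(partition.probe_targets, partition.distractors, seed=1)


def stimulus_index(inventory):
    return {s.stimulus_id: s for s in inventory}


class TestProtocolConstants:
    def test_session_target_is_three_daily_over_four_weeks(self):
        c = ProtocolConstants()
        assert c.total_target_sessions == 84
        assert c.trials_per_session == 200

    def test_non_positive_constants_rejected(self):
        with pytest.raises(InvalidInputError):
            ProtocolConstants(fixation_ms=0)


class TestSessionPlan:
    def test_four_blocks_of_fifty(self, plan):
        assert len(plan) == 200
        per_block = collections.Counter(t.block_index for t in plan)
        assert per_block == {0: 50, 1: 50, 2: 50, 3: 50}

    def test_session_balanced_fifty_per_pairing_type(self, plan):
        counts = collections.Counter(t.pairing_type for t in plan)
        assert counts == {pt: 50 for pt in PAIRING_TYPES}

    def test_block_allocation_13_13_12_12(self, plan):
        for b in range(4):
            block_counts = sorted(
                collections.Counter(
                    t.pairing_type for t in plan if t.block_index == b
                ).values(),
                reverse=True,
            )
            assert block_counts == [13, 13, 12, 12]

    def test_deterministic_given_seed(self, partition):
        a = build_session_plan(partition.probe_targets, partition.distractors, seed=9)
        b = build_session_plan(partition.probe_targets, partition.distractors, seed=9)
        assert a == b
        c = build_session_plan(partition.probe_targets, partition.distractors, seed=10)
        assert a != c

    @given(seed=hst.integers(0, 2**20))
    def test_probe_never_on_negative_or_avoidance(self, small_inventory, seed):
        part = classify_for_training(small_inventory)
        idx = stimulus_index(small_inventory)
        plan = build_session_plan(part.probe_targets, part.distractors, seed=seed)
        for t in plan:
            probed = idx[t.probed_stimulus_id]
            assert probed.valence != "negative"
            assert probed.orientation != "avoidance"

    @given(seed=hst.integers(0, 2**20))
    def test_probe_placement_follows_pairing_rule(self, small_inventory, seed):
        idx = stimulus_index(small_inventory)
        part = classify_for_training(small_inventory)
        plan = build_session_plan(part.probe_targets, part.distractors, seed=seed)
        for t in plan:
            probed = idx[t.probed_stimulus_id]
            if t.pairing_type in ("positive-neutral", "positive-negative"):
                assert probed.valence == "positive"
            elif t.pairing_type == "negative-neutral":
                assert probed.valence == "neutral"
            else:
                assert probed.valence == "neutral"

    @pytest.mark.parametrize("seed", range(10))
    def test_left_right_counterbalance_within_one(self, partition, seed):
        plan = build_session_plan(partition.probe_targets, partition.distractors, seed=seed)
        for b in range(4):
            sides = [
                t.probe_side
                for t in plan
                if t.block_index == b and t.pairing_type != "neutral-neutral"
            ]
            assert abs(sides.count("left") - sides.count("right")) <= 1

    def test_left_and_right_stimuli_always_differ(self, plan):
        assert all(t.left_stimulus_id != t.right_stimulus_id for t in plan)

    def test_missing_valence_category_rejected(self):
        no_neg = [
            ThoughtStimulus("p0", "p", "positive", "approach"),
            ThoughtStimulus("n0", "n1", "neutral", "neutral"),
            ThoughtStimulus("n1", "n2", "neutral", "neutral"),
        ]
        part = classify_for_training(no_neg)
        with pytest.raises(InvalidInputError):
            build_session_plan(part.probe_targets, part.distractors, seed=0)

    def test_single_neutral_rejected(self):
        inv = [
            ThoughtStimulus("p0", "p", "positive", "approach"),
            ThoughtStimulus("g0", "g", "negative", "avoidance"),
            ThoughtStimulus("n0", "n", "neutral", "neutral"),
        ]
        part = classify_for_training(inv)
        with pytest.raises(InvalidInputError):
            build_session_plan(part.probe_targets, part.distractors, seed=0)


class TestRunSession:
    def test_perfect_responder_full_accuracy_no_feedback(self, plan):
        log = run_session(plan, perfect_responder(600.0))
        assert log.is_complete
        assert log.accuracy == 1.0
        assert sum(t.feedback_emitted for t in log.trials) == 0

    def test_anti_responder_zero_accuracy_full_feedback(self, plan):
        log = run_session(plan, anti_responder())
        assert log.accuracy == 0.0
        assert sum(t.feedback_emitted for t in log.trials) == 200

    def test_fixed_rt_passthrough(self, plan):
        log = run_session(plan, perfect_responder(500.0))
        assert all(t.rt_ms == 500.0 for t in log.trials)

    def test_slow_response_recorded_as_timeout(self, plan):
        log = run_session(plan, perfect_responder(6000.0))  # beyond 5000 ms timeout
        assert all(t.response_side == "none" and t.rt_ms is None for t in log.trials)
        assert log.accuracy == 0.0

    def test_responder_failure_yields_incomplete_log(self, plan):
        calls = {"n": 0}

        def flaky(spec):
            calls["n"] += 1
            if calls["n"] > 120:
                raise RuntimeError("participant closed the browser")
            return spec.probe_side, 700.0

        log = run_session(plan, flaky)
        assert not log.is_complete
        assert len(log.trials) == 120


class TestBlockSummary:
    def _trial(self, spec, correct, rt):
        side = spec.probe_side if correct else ("left" if spec.probe_side == "right" else "right")
        return TrialRecord(spec, side, rt, correct, not correct)

    def _specs(self, n):
        return [
            TrialSpec(i + 1, 0, "positive-neutral", "a", "b", "left" if i % 2 else "right")
            for i in range(n)
        ]

    def test_all_correct_uniform_rt(self):
        block = [self._trial(s, True, 600.0) for s in self._specs(50)]
        s = block_summary(block)
        assert (s.mean_rt_ms, s.accuracy) == (600.0, 1.0)

    def test_accuracy_matches_reported_scale(self):
        specs = self._specs(50)
        block = [self._trial(s, i < 47, 500.0) for i, s in enumerate(specs)]
        assert block_summary(block).accuracy == pytest.approx(0.94)

    def test_incorrect_rts_excluded_from_mean(self):
        specs = self._specs(10)
        block = [self._trial(s, i < 5, 400.0 if i < 5 else 900.0) for i, s in enumerate(specs)]
        s = block_summary(block)
        assert (s.mean_rt_ms, s.accuracy) == (400.0, 0.5)

    def test_zero_correct_reports_absent_mean(self):
        block = [self._trial(s, False, 900.0) for s in self._specs(10)]
        s = block_summary(block)
        assert s.mean_rt_ms is None and s.accuracy == 0.0


class TestTutorialGate:
    def _log_with_accuracy(self, plan, n_correct):
        def responder(spec):
            correct = spec.trial_index <= n_correct
            side = spec.probe_side if correct else (
                "left" if spec.probe_side == "right" else "right"
            )
            return side, 800.0

        return run_session(plan, responder)

    def test_exactly_eighty_percent_passes(self, plan):
        log = self._log_with_accuracy(plan, 160)
        assert log.accuracy == 0.80
        assert tutorial_gate(log).passed

    def test_perfect_passes_and_just_below_fails(self, plan):
        assert tutorial_gate(self._log_with_accuracy(plan, 200)).passed
        res = tutorial_gate(self._log_with_accuracy(plan, 158))  # 79%
        assert not res.passed

    def test_incomplete_log_fails_with_reason(self, plan):
        log = run_session(plan[:100], perfect_responder())
        res = tutorial_gate(log)
        assert not res.passed and res.reason == "incomplete"


class TestProtocolAdherence:
    def _complete_log(self, plan, i):
        log = run_session(plan, perfect_responder(), session_index=i)
        return log

    def test_median_completer_dose_fraction(self, plan):
        logs = [self._complete_log(plan, i) for i in range(48)]
        summary = protocol_adherence(logs)
        assert summary.sessions_completed == 48
        assert summary.target == 84
        assert summary.fraction_of_target == pytest.approx(48 / 84)

    def test_no_sessions(self):
        assert protocol_adherence([]).sessions_completed == 0

    def test_partial_session_not_counted(self, plan):
        logs = [self._complete_log(plan, i) for i in range(3)]
        partial = run_session(plan[:150], perfect_responder(), session_index=99)  # 3 blocks
        assert not partial.is_complete
        assert protocol_adherence(logs + [partial]).sessions_completed == 3
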
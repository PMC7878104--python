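"""Modified dot-probe training engine.

Each trial shows a central fixation cross for 1000 ms, then two contrasting
thought stimuli on opposite sides of the screen for ~2500 ms, then a probe
in the location of one of them; the participant indicates the probe's side
as fast as possible.  The training contingency: the probe always appears at
the stimulus that is treatment approach-oriented with a neutral or positive
emotional tone — never at a negative or avoidance-oriented stimulus.  A
session is 4 blocks of 50 trials; an 80%-accuracy tutorial gates entry; the
program targets 3 sessions/day over 4 weeks (84 sessions).

This module builds session plans, executes them headlessly against a
response-provider callable, and summarizes blocks and protocol adherence.
Audio feedback is modeled as a boolean event in the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .errors import InvalidInputError
from .stimuli import ThoughtStimulus, TrainingPartition

PAIRING_TYPES = (
    "positive-neutral",
    "negative-neutral",
    "positive-negative",
    "neutral-neutral",
)
SIDES = ("left", "right")
ASSESSMENT_PERIODS = ("baseline", "training", "posttraining")


@dataclass(frozen=True)
class ProtocolConstants:
    """Timing and dosage constants of the training protocol."""

    fixation_ms: int = 1000
    stimulus_exposure_ms: int = 2500
    trials_per_block: int = 50
    blocks_per_session: int = 4
    tutorial_accuracy_gate: float = 0.80
    sessions_per_day_target: int = 3
    program_days: int = 28
    response_timeout_ms: float = 5000.0
    inter_trial_interval_ms: int = 0

    def __post_init__(self):
        for name in (
            "fixation_ms",
            "stimulus_exposure_ms",
            "trials_per_block",
            "blocks_per_session",
            "tutorial_accuracy_gate",
            "sessions_per_day_target",
            "program_days",
            "response_timeout_ms",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")

    @property
    def trials_per_session(self) -> int:
        return self.trials_per_block * self.blocks_per_session

    @property
    def total_target_sessions(self) -> int:
        # 3 sessions/day for 4 weeks of 7 days = 84
        return self.sessions_per_day_target * self.program_days


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int  # 1-based across the session
    block_index: int  # 0-based
    pairing_type: str
    left_stimulus_id: str
    right_stimulus_id: str
    probe_side: str

    def __post_init__(self):
        if self.trial_index < 1:
            raise InvalidInputError("trial_index is 1-based")
        if self.pairing_type not in PAIRING_TYPES:
            raise InvalidInputError(f"unknown pairing type {self.pairing_type!r}")
        if self.probe_side not in SIDES:
            raise InvalidInputError(f"probe_side must be left/right, got {self.probe_side!r}")
        if self.left_stimulus_id == self.right_stimulus_id:
            raise InvalidInputError("left and right stimuli must differ")

    @property
    def probed_stimulus_id(self) -> str:
        return self.left_stimulus_id if self.probe_side == "left" else self.right_stimulus_id


@dataclass(frozen=True)
class TrialRecord:
    spec: TrialSpec
    response_side: str  # left | right | none
    rt_ms: Optional[float]
    correct: bool
    feedback_emitted: bool

    def __post_init__(self):
        if self.response_side not in ("left", "right", "none"):
            raise InvalidInputError(f"bad response_side {self.response_side!r}")
        if (self.rt_ms is None) != (self.response_side == "none"):
            raise InvalidInputError("rt_ms must be present iff a response was made")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise InvalidInputError("rt_ms must be positive")
        if self.correct != (self.response_side == self.spec.probe_side):
            raise InvalidInputError("correct flag inconsistent with response/probe sides")


@dataclass(frozen=True)
class SessionLog:
    participant_id: str
    session_index: int
    assessment_period: str
    blocks: tuple[tuple[TrialRecord, ...], ...]
    seed: int
    constants: ProtocolConstants = field(default_factory=ProtocolConstants)
    complete: bool = True

    def __post_init__(self):
        if self.assessment_period not in ASSESSMENT_PERIODS:
            raise InvalidInputError(
                f"assessment_period must be one of {ASSESSMENT_PERIODS}"
            )
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))

    @property
    def trials(self) -> tuple[TrialRecord, ...]:
        return tuple(t for b in self.blocks for t in b)

    @property
    def is_complete(self) -> bool:
        """A session counts only if all blocks are present and full."""
        c = self.constants
        return (
            self.complete
            and len(self.blocks) == c.blocks_per_session
            and all(len(b) == c.trials_per_block for b in self.blocks)
        )

    @property
    def accuracy(self) -> float:
        trials = self.trials
        if not trials:
            return 0.0
        return sum(t.correct for t in trials) / len(trials)


@dataclass(frozen=True)
class BlockSummary:
    mean_rt_ms: Optional[float]
    accuracy: float


@dataclass(frozen=True)
class GateResult:
    passed: bool
    accuracy: float
    reason: str = ""


@dataclass(frozen=True)
class AdherenceSummary:
    sessions_completed: int
    target: int
    fraction_of_target: float


def _pools(
    probe_targets: Sequence[ThoughtStimulus], distractors: Sequence[ThoughtStimulus]
) -> tuple[list[str], list[str], list[str], list[str]]:
    positives = [s.stimulus_id for s in probe_targets if s.valence == "positive"]
    probed_neutrals = [s.stimulus_id for s in probe_targets if s.valence == "neutral"]
    negatives = [s.stimulus_id for s in distractors if s.valence == "negative"]
    all_neutrals = probed_neutrals + [
        s.stimulus_id for s in distractors if s.valence == "neutral"
    ]
    return positives, probed_neutrals, negatives, all_neutrals


def build_session_plan(
    probe_targets: Sequence[ThoughtStimulus],
    distractors: Sequence[ThoughtStimulus],
    constants: ProtocolConstants = ProtocolConstants(),
    seed: int = 0,
) -> list[TrialSpec]:
    """Generate one session's TrialSpecs (default 4 blocks x 50 trials).

    Pairing types are allocated 13/13/12/12 within each 50-trial block, with
    which types receive 13 rotated across blocks (rotation offset drawn from
    the seed) so a full session is exactly balanced at 50 trials per type.
    The probe goes to the positive member of positive-neutral and
    positive-negative pairs, to the neutral member of negative-neutral
    pairs, and to a uniformly random side on neutral-neutral pairs; probed
    left/right placement is counterbalanced within block to at most one
    trial off 50/50.
    """
    positives, probed_neutrals, negatives, all_neutrals = _pools(probe_targets, distractors)
    if not positives:
        raise InvalidInputError("need at least one positive-valence probe target")
    if not negatives:
        raise InvalidInputError("need at least one negative-valence distractor")
    if not probed_neutrals:
        raise InvalidInputError("need at least one neutral-valence probe target")
    if len(all_neutrals) < 2:
        raise InvalidInputError(
            "need at least two neutral stimuli to form neutral-neutral pairs"
        )

    rng = np.random.default_rng(seed)
    n_types = len(PAIRING_TYPES)
    base = constants.trials_per_block // n_types
    n_extra = constants.trials_per_block - base * n_types  # types getting base+1
    rotation = int(rng.integers(n_types))

    plan: list[TrialSpec] = []
    trial_index = 1
    for block in range(constants.blocks_per_session):
        counts = {}
        for t_idx, ptype in enumerate(PAIRING_TYPES):
            slot = (t_idx + rotation + block) % n_types
            counts[ptype] = base + (1 if slot < n_extra else 0)
        types = [pt for pt, c in counts.items() for _ in range(c)]
        rng.shuffle(types)

        n_non_nn = sum(1 for t in types if t != "neutral-neutral")
        sides = ["left"] * (n_non_nn // 2) + ["right"] * (n_non_nn - n_non_nn // 2)
        rng.shuffle(sides)
        side_iter = iter(sides)

        for ptype in types:
            if ptype == "positive-neutral":
                probed = positives[rng.integers(len(positives))]
                other_pool = [s for s in all_neutrals if s != probed]
                other = other_pool[rng.integers(len(other_pool))]
                probe_side = next(side_iter)
            elif ptype == "positive-negative":
                probed = positives[rng.integers(len(positives))]
                other = negatives[rng.integers(len(negatives))]
                probe_side = next(side_iter)
            elif ptype == "negative-neutral":
                probed = probed_neutrals[rng.integers(len(probed_neutrals))]
                other = negatives[rng.integers(len(negatives))]
                probe_side = next(side_iter)
            else:  # neutral-neutral: probe side uniform at random
                probed = probed_neutrals[rng.integers(len(probed_neutrals))]
                pool = [s for s in all_neutrals if s != probed]
                other = pool[rng.integers(len(pool))]
                probe_side = SIDES[rng.integers(2)]
            left, right = (probed, other) if probe_side == "left" else (other, probed)
            plan.append(
                TrialSpec(
                    trial_index=trial_index,
                    block_index=block,
                    pairing_type=ptype,
                    left_stimulus_id=left,
                    right_stimulus_id=right,
                    probe_side=probe_side,
                )
            )
            trial_index += 1
    return plan


def build_session_plan_from_partition(
    partition: TrainingPartition,
    constants: ProtocolConstants = ProtocolConstants(),
    seed: int = 0,
) -> list[TrialSpec]:
    return build_session_plan(partition.probe_targets, partition.distractors, constants, seed)


Responder = Callable[[TrialSpec], Optional[tuple[str, float]]]


def run_session(
    plan: Sequence[TrialSpec],
    responder: Responder,
    constants: ProtocolConstants = ProtocolConstants(),
    participant_id: str = "p0",
    session_index: int = 1,
    assessment_period: str = "training",
    seed: int = 0,
) -> SessionLog:
    """Execute a plan headlessly against a response provider.

    The responder receives each TrialSpec after the simulated fixation and
    stimulus exposure and returns ``(response_side, rt_ms)`` or ``None`` for
    no response.  Responses slower than the timeout are recorded as absent.
    Feedback (the audible alert) is emitted exactly on incorrect trials.  A
    responder exception mid-session yields a partial log flagged incomplete.
    """
    records: list[TrialRecord] = []
    complete = True
    for spec in plan:
        try:
            answer = responder(spec)
        except Exception:
            complete = False
            break
        if answer is not None and answer[1] > constants.response_timeout_ms:
            answer = None  # timeout
        if answer is None:
            side, rt = "none", None
        else:
            side, rt = answer
        correct = side == spec.probe_side
        records.append(
            TrialRecord(
                spec=spec,
                response_side=side,
                rt_ms=rt,
                correct=correct,
                feedback_emitted=not correct,
            )
        )
    blocks: list[tuple[TrialRecord, ...]] = []
    for b in range(constants.blocks_per_session):
        block = tuple(r for r in records if r.spec.block_index == b)
        if block:
            blocks.append(block)
    return SessionLog(
        participant_id=participant_id,
        session_index=session_index,
        assessment_period=assessment_period,
        blocks=tuple(blocks),
        seed=seed,
        constants=constants,
        complete=complete,
    )


def block_summary(block: Sequence[TrialRecord]) -> BlockSummary:
    """End-of-block feedback screen: mean RT over correct trials, accuracy."""
    if not block:
        raise InvalidInputError("empty block")
    correct_rts = [t.rt_ms for t in block if t.correct and t.rt_ms is not None]
    accuracy = sum(t.correct for t in block) / len(block)
    mean_rt = float(np.mean(correct_rts)) if correct_rts else None
    return BlockSummary(mean_rt_ms=mean_rt, accuracy=accuracy)


def tutorial_gate(
    tutorial_log: SessionLog, constants: ProtocolConstants = ProtocolConstants()
) -> GateResult:
    """Entry gate: pass iff tutorial accuracy >= 80% (inclusive) on a complete log."""
    if not tutorial_log.is_complete:
        return GateResult(passed=False, accuracy=tutorial_log.accuracy, reason="incomplete")
    acc = tutorial_log.accuracy
    passed = acc >= constants.tutorial_accuracy_gate - 1e-12
    return GateResult(passed=passed, accuracy=acc, reason="" if passed else "below threshold")


def protocol_adherence(
    logs: Iterable[SessionLog], constants: ProtocolConstants = ProtocolConstants()
) -> AdherenceSummary:
    """Count complete sessions against the 84-session program target."""
    completed = sum(1 for log in logs if log.is_complete)
    target = constants.total_target_sessions
    return AdherenceSummary(
        sessions_completed=completed,
        target=target,
        fraction_of_target=completed / target,
    )


def perfect_responder(rt_ms: float = 600.0) -> Responder:
    """A responder that always answers the probe side with a fixed latency."""

    def _respond(spec: TrialSpec) -> tuple[str, float]:
        return spec.probe_side, rt_ms

    return _respond


def anti_responder(rt_ms: float = 600.0) -> Responder:
    """A responder that always answers the wrong side (for engine tests)."""

    def _respond(spec: TrialSpec) -> tuple[str, float]:
        side = "left" if spec.probe_side == "right" else "right"
        return side, rt_ms

    return _respond
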
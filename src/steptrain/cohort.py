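"""Synthetic cohort generator.

Emulates the statistical structure of a small pre/post attention-training
cohort so every pipeline stage can be exercised without patient data:
per-participant stimulus inventories and similarity ratings (from latent 2D
thought maps), dot-probe assessment sessions at baseline and posttraining,
and survey batteries.

The generative anchors are the reported cohort summaries: baseline mean RT
about 2550 ms with ~700 ms between-person SD and pairing-type offsets
matching the printed means (2553 / 2579 / 2561 / 2483 ms), a mean training
reduction of ~330 ms, accuracy in the mid-90s via a Bernoulli lapse
process, baseline PHQ-9 of 13.4 (SD 6.8) with a mean drop of 4.8 points at
a generating paired d of 1.2, and 5/12 low adherers at baseline.  Within a
person, trial RTs follow an ex-Gaussian law (normal + exponential), the
right-skewed shape that makes symmetric SD trimming consequential.
Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .dotprobe import (
    PAIRING_TYPES,
    ProtocolConstants,
    SessionLog,
    TrialSpec,
    build_session_plan,
    run_session,
)
from .errors import InvalidInputError
from .outcomes import SurveyBattery
from .stimuli import (
    SimilarityRatings,
    ThoughtStimulus,
    classify_for_training,
)

# pairing-type offsets relative to the grand baseline mean, ms
_DEFAULT_OFFSETS = (3.0, 29.0, 11.0, -67.0)  # order follows PAIRING_TYPES


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters; defaults reproduce the reported study conditions."""

    n_participants: int = 12
    rt_baseline_mean_ms: float = 2550.0
    between_person_sd_ms: float = 700.0
    pairing_offsets_ms: tuple[float, float, float, float] = _DEFAULT_OFFSETS
    training_reduction_mean_ms: float = 330.0
    training_reduction_sd_ms: float = 350.0
    exgauss_sigma_ms: float = 150.0  # within-person Gaussian SD
    exgauss_tau_ms: float = 300.0  # within-person exponential tail
    lapse_rate_baseline: float = 0.04
    lapse_rate_post: float = 0.02
    timeout_rate: float = 0.0
    phq9_pre_mean: float = 13.4
    phq9_pre_sd: float = 6.8
    phq9_change_mean: float = 4.8
    phq9_effect_d: float = 1.2
    adherence_pre_low_prob: float = 5.0 / 12.0
    adherence_improve_prob: float = 0.4
    adherence_worsen_prob: float = 0.0
    n_stimuli_per_class: int = 3  # positives, negatives, neutrals each
    similarity_scale: tuple[float, float] = (1.0, 9.0)
    similarity_noise_sd: float = 0.0
    n_training_sessions: int = 0  # extra at-home sessions per participant
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise InvalidInputError("n_participants must be >= 1")
        for name in (
            "between_person_sd_ms",
            "training_reduction_sd_ms",
            "exgauss_sigma_ms",
            "exgauss_tau_ms",
            "phq9_pre_sd",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        for name in (
            "lapse_rate_baseline",
            "lapse_rate_post",
            "timeout_rate",
            "adherence_pre_low_prob",
            "adherence_improve_prob",
            "adherence_worsen_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be a probability in [0, 1]")
        if len(self.pairing_offsets_ms) != len(PAIRING_TYPES):
            raise InvalidInputError("pairing_offsets_ms needs one offset per pairing type")
        if self.phq9_effect_d <= 0:
            raise InvalidInputError("phq9_effect_d must be > 0")
        if self.n_stimuli_per_class < 1:
            raise InvalidInputError("n_stimuli_per_class must be >= 1")

    @property
    def phq9_change_sd(self) -> float:
        """Implied SD of the latent symptom change: mean change / generating d."""
        return self.phq9_change_mean / self.phq9_effect_d


@dataclass(frozen=True)
class SyntheticParticipant:
    participant_id: str
    rt_intercept_ms: float
    training_reduction_ms: float
    phq9_pre_latent: float
    phq9_change: float
    vas_pre: int
    vas_post: int
    inventory: tuple[ThoughtStimulus, ...]
    latent_coords: np.ndarray = field(repr=False)
    seed: int = 0


@dataclass(frozen=True)
class Cohort:
    params: CohortParams
    participants: tuple[SyntheticParticipant, ...]
    surveys_pre: tuple[SurveyBattery, ...]
    surveys_post: tuple[SurveyBattery, ...]
    assessment_logs: tuple[SessionLog, ...]  # baseline + posttraining per participant
    training_logs: tuple[SessionLog, ...] = ()


def make_inventory(participant_id: str, n_per_class: int = 3) -> tuple[ThoughtStimulus, ...]:
    """A balanced synthetic thought inventory: approach/positive thoughts,
    avoidance/negative thoughts, and orientation-neutral neutral thoughts."""
    stimuli = []
    for k in range(n_per_class):
        stimuli.append(
            ThoughtStimulus(
                f"{participant_id}-pos{k}",
                f"{participant_id} staying on my meds keeps me strong ({k})",
                "positive",
                "approach",
            )
        )
        stimuli.append(
            ThoughtStimulus(
                f"{participant_id}-neg{k}",
                f"{participant_id} the pills just remind me I'm sick ({k})",
                "negative",
                "avoidance",
            )
        )
        stimuli.append(
            ThoughtStimulus(
                f"{participant_id}-neu{k}",
                f"{participant_id} I keep the bottle on the shelf ({k})",
                "neutral",
                "neutral",
            )
        )
    return tuple(stimuli)


def generate_similarity(
    inventory: tuple[ThoughtStimulus, ...],
    latent_coords: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale_bounds: tuple[float, float] = (1.0, 9.0),
) -> SimilarityRatings:
    """Similarity ratings derived from latent 2D thought positions.

    Similarity decreases linearly with latent Euclidean distance (rescaled
    so the farthest pair sits at the scale minimum), plus optional Gaussian
    rating noise; identical latent positions give uniformly maximal
    ratings.  With zero noise, the MDS embedding should recover the latent
    configuration up to rotation/reflection/scale.
    """
    n = len(inventory)
    if n < 3:
        raise InvalidInputError("need at least 3 stimuli")
    rng = np.random.default_rng(seed)
    if latent_coords is None:
        latent_coords = rng.normal(size=(n, 2))
    latent_coords = np.asarray(latent_coords, dtype=float)
    if latent_coords.shape != (n, 2):
        raise InvalidInputError("latent_coords must be n x 2")
    diff = latent_coords[:, None, :] - latent_coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    s_min, s_max = scale_bounds
    dmax = dist.max()
    if dmax == 0:
        sims = np.full((n, n), s_max)
    else:
        sims = s_max - (s_max - s_min) * dist / dmax
    if noise_sd > 0:
        noise = rng.normal(scale=noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        sims = np.clip(sims + noise, s_min, s_max)
    sims = (sims + sims.T) / 2.0
    np.fill_diagonal(sims, s_max)
    ids = tuple(s.stimulus_id for s in inventory)
    return SimilarityRatings(ids, sims, scale_bounds)


def _distribute_total(total: int, n_items: int, item_max: int, rng) -> tuple[int, ...]:
    """Split an instrument total into item scores uniformly at random."""
    items = np.zeros(n_items, dtype=int)
    for _ in range(total):
        open_items = np.flatnonzero(items < item_max)
        items[open_items[rng.integers(len(open_items))]] += 1
    return tuple(int(v) for v in items)


def _make_participant(params: CohortParams, index: int, rng) -> SyntheticParticipant:
    pid = f"p{index:02d}"
    intercept = rng.normal(params.rt_baseline_mean_ms, params.between_person_sd_ms)
    reduction = rng.normal(params.training_reduction_mean_ms, params.training_reduction_sd_ms)
    phq_pre = rng.normal(params.phq9_pre_mean, params.phq9_pre_sd)
    phq_change = rng.normal(params.phq9_change_mean, params.phq9_change_sd)
    low_pre = rng.random() < params.adherence_pre_low_prob
    vas_pre = 3 if low_pre else 4  # reported low adherers sat in the 50–75% bin
    if low_pre:
        vas_post = 4 if rng.random() < params.adherence_improve_prob else 3
    else:
        vas_post = 3 if rng.random() < params.adherence_worsen_prob else 4
    inventory = make_inventory(pid, params.n_stimuli_per_class)
    coords = rng.normal(size=(len(inventory), 2))
    return SyntheticParticipant(
        participant_id=pid,
        rt_intercept_ms=intercept,
        training_reduction_ms=reduction,
        phq9_pre_latent=phq_pre,
        phq9_change=phq_change,
        vas_pre=vas_pre,
        vas_post=vas_post,
        inventory=inventory,
        latent_coords=coords,
        seed=index,
    )


def _surveys_for(participant: SyntheticParticipant, rng) -> tuple[SurveyBattery, SurveyBattery]:
    pre_total = int(np.clip(round(participant.phq9_pre_latent), 0, 27))
    post_total = int(np.clip(round(participant.phq9_pre_latent - participant.phq9_change), 0, 27))
    pclc_total = int(np.clip(round(rng.normal(28.0, 10.0)), 17, 85))
    batteries = []
    for period, phq_total, vas in (
        ("baseline", pre_total, participant.vas_pre),
        ("posttraining", post_total, participant.vas_post),
    ):
        batteries.append(
            SurveyBattery(
                participant_id=participant.participant_id,
                period=period,
                phq9_items=_distribute_total(phq_total, 9, 3, rng),
                vas_category=vas,
                pclc_items=tuple(
                    1 + v for v in _distribute_total(pclc_total - 17, 17, 4, rng)
                ),
                mms_anxiety_items=tuple(int(rng.random() < 0.6) for _ in range(9)),
                stigma_items=tuple(int(rng.random() < 0.6) for _ in range(6)),
                csa_items=tuple(int(rng.random() < 0.26) for _ in range(2)),
            )
        )
    return batteries[0], batteries[1]


def simulated_responder(
    participant: SyntheticParticipant,
    period: str,
    params: CohortParams,
    rng,
):
    """Response provider for one assessment session.

    Trial RT = person/pairing mean + ex-Gaussian noise (centered: normal
    with SD sigma plus exponential tail tau minus tau).  Errors are
    independent lapses (respond to the wrong side); timeouts occur at a
    configurable low rate.
    """
    offsets = dict(zip(PAIRING_TYPES, params.pairing_offsets_ms))
    lapse = params.lapse_rate_baseline if period == "baseline" else params.lapse_rate_post
    reduction = participant.training_reduction_ms if period == "posttraining" else 0.0

    def _respond(spec: TrialSpec) -> Optional[tuple[str, float]]:
        if rng.random() < params.timeout_rate:
            return None
        mean = participant.rt_intercept_ms + offsets[spec.pairing_type] - reduction
        rt = mean + rng.normal(0.0, params.exgauss_sigma_ms)
        rt += rng.exponential(params.exgauss_tau_ms) - params.exgauss_tau_ms
        rt = max(rt, 50.0)
        if rng.random() < lapse:
            side = "left" if spec.probe_side == "right" else "right"
        else:
            side = spec.probe_side
        return side, rt

    return _respond


def _assessment_log(
    participant: SyntheticParticipant,
    period: str,
    params: CohortParams,
    constants: ProtocolConstants,
    session_seed: int,
    rng,
) -> SessionLog:
    partition = classify_for_training(participant.inventory)
    plan = build_session_plan(
        partition.probe_targets, partition.distractors, constants, seed=session_seed
    )
    responder = simulated_responder(participant, period, params, rng)
    return run_session(
        plan,
        responder,
        constants,
        participant_id=participant.participant_id,
        session_index=0 if period == "baseline" else 999,
        assessment_period=period,
        seed=session_seed,
    )


def generate_cohort(
    params: CohortParams,
    constants: ProtocolConstants | None = None,
    include_trials: bool = True,
) -> Cohort:
    """Generate a full synthetic cohort, reproducible from ``params.seed``.

    With ``include_trials=False`` only participants and surveys are
    generated (fast path for survey-only Monte-Carlo work).  Unless other
    constants are supplied, simulated sessions use a very long response
    timeout: the probe stays on screen until the participant answers, so
    slow ex-Gaussian tails are responses, not timeouts.
    """
    if constants is None:
        constants = ProtocolConstants(response_timeout_ms=60_000.0)
    root = np.random.SeedSequence(params.seed)
    n = params.n_participants
    child_seqs = root.spawn(n)
    participants = []
    surveys_pre = []
    surveys_post = []
    logs: list[SessionLog] = []
    training_logs: list[SessionLog] = []
    for i, seq in enumerate(child_seqs):
        rng = np.random.default_rng(seq)
        p = _make_participant(params, i, rng)
        participants.append(p)
        pre_b, post_b = _surveys_for(p, rng)
        surveys_pre.append(pre_b)
        surveys_post.append(post_b)
        if include_trials:
            plan_seed = int(rng.integers(2**31 - 1))
            logs.append(_assessment_log(p, "baseline", params, constants, plan_seed, rng))
            plan_seed = int(rng.integers(2**31 - 1))
            logs.append(_assessment_log(p, "posttraining", params, constants, plan_seed, rng))
            for s in range(params.n_training_sessions):
                plan_seed = int(rng.integers(2**31 - 1))
                partition = classify_for_training(p.inventory)
                plan = build_session_plan(
                    partition.probe_targets, partition.distractors, constants, seed=plan_seed
                )
                responder = simulated_responder(p, "training", params, rng)
                training_logs.append(
                    run_session(
                        plan,
                        responder,
                        constants,
                        participant_id=p.participant_id,
                        session_index=s + 1,
                        assessment_period="training",
                        seed=plan_seed,
                    )
                )
    return Cohort(
        params=params,
        participants=tuple(participants),
        surveys_pre=tuple(surveys_pre),
        surveys_post=tuple(surveys_post),
        assessment_logs=tuple(logs),
        training_logs=tuple(training_logs),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Monte-Carlo parameter-recovery summary over replicate cohorts."""

    n_reps: int
    generating_d: float
    mean_recovered_d: float
    sd_recovered_d: float
    d_bias: float
    mean_percent_reduction: float
    rt_reps: int
    generating_reduction_ms: float
    mean_recovered_reduction_ms: float
    sd_recovered_reduction_ms: float
    reduction_ci95_ms: tuple[float, float]
    mean_recovered_phi: float

    @property
    def d_ci95(self) -> tuple[float, float]:
        half = 1.96 * self.sd_recovered_d / np.sqrt(self.n_reps)
        return (self.mean_recovered_d - half, self.mean_recovered_d + half)


def parameter_recovery_suite(
    params: CohortParams,
    n_reps: int = 200,
    seed: int = 0,
    rt_reps: int | None = None,
    constants: ProtocolConstants | None = None,
) -> RecoveryReport:
    """Run the full estimation pipeline on replicate synthetic cohorts and
    compare recovered estimates to the generating values.

    Survey outcomes (PHQ-9 paired d, percent reduction, adherence phi) are
    recovered on ``n_reps`` cohorts; the trial-level RT pipeline (filter →
    trim → pairing means), which is far costlier, is recovered on
    ``rt_reps`` cohorts (default ``min(n_reps, 40)``).  The reported 95% CI
    on the recovered positive-negative reduction is the Monte-Carlo CI of
    the replicate mean.
    """
    from . import rt as rt_mod
    from .outcomes import outcome_report

    if n_reps < 1 or n_reps > 1000:
        raise InvalidInputError("n_reps must be in 1..1000 (desk-scale)")
    if rt_reps is None:
        rt_reps = min(n_reps, 40)
    seed_rng = np.random.default_rng(seed)
    rep_seeds = seed_rng.integers(2**31 - 1, size=max(n_reps, rt_reps))

    ds, prs, phis = [], [], []
    for r in range(n_reps):
        cohort = generate_cohort(
            replace(params, seed=int(rep_seeds[r])), constants, include_trials=False
        )
        report = outcome_report(cohort.surveys_pre, cohort.surveys_post)
        ds.append(report.cohen_d)
        prs.append(report.percent_reduction)
        phis.append(report.phi)

    reductions = []
    pn_index = PAIRING_TYPES.index("positive-negative")
    for r in range(rt_reps):
        cohort = generate_cohort(
            replace(params, seed=int(rep_seeds[r])), constants, include_trials=True
        )
        obs = rt_mod.observations_from_logs(cohort.assessment_logs)
        obs = rt_mod.trim_outliers(rt_mod.filter_correct(obs))
        table = rt_mod.pairing_means(obs).table
        reductions.append(float(table["reduction_ms"].iloc[pn_index]))

    ds = np.asarray(ds)
    reductions = np.asarray(reductions)
    red_mean = float(reductions.mean())
    red_sd = float(reductions.std(ddof=1)) if rt_reps >= 2 else float("nan")
    half = 1.96 * red_sd / np.sqrt(rt_reps) if rt_reps >= 2 else float("nan")
    return RecoveryReport(
        n_reps=n_reps,
        generating_d=params.phq9_effect_d,
        mean_recovered_d=float(ds.mean()),
        sd_recovered_d=float(ds.std(ddof=1)) if n_reps >= 2 else float("nan"),
        d_bias=float(ds.mean()) - params.phq9_effect_d,
        mean_percent_reduction=float(np.mean(prs)),
        rt_reps=rt_reps,
        generating_reduction_ms=params.training_reduction_mean_ms,
        mean_recovered_reduction_ms=red_mean,
        sd_recovered_reduction_ms=red_sd,
        reduction_ci95_ms=(red_mean - half, red_mean + half),
        mean_recovered_phi=float(np.mean(phis)),
    )
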
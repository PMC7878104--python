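"""Reaction-time reduction pipeline.

Raw dot-probe trial logs are reduced to attentional-processing-speed
summaries in three steps: keep correct responses only, trim each
participant's RTs at 1.5 SD around their own mean (one pass, computed per
participant within assessment period, pooled across pairing types), then
tabulate participant-level mean RTs by pairing type and assessment period.
Cohort means/SDs are computed over participant means so each participant
contributes equally; pre/post comparisons are paired t-tests on those
means with the paired-design effect size d = t/sqrt(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .dotprobe import PAIRING_TYPES, SessionLog
from .errors import InvalidInputError
from .outcomes import cohen_d_paired, paired_t

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["participant_id", "assessment_period", "pairing_type", "rt_ms", "correct"]


def observations_from_logs(logs: Iterable[SessionLog]) -> pd.DataFrame:
    """Flatten session logs into one row per trial.

    Timeout trials (no response) are kept with ``rt_ms = NaN`` so accuracy
    tables count them as errors; they never survive :func:`filter_correct`.
    """
    rows = []
    for log in logs:
        for rec in log.trials:
            rows.append(
                (
                    log.participant_id,
                    log.assessment_period,
                    rec.spec.pairing_type,
                    float(rec.rt_ms) if rec.rt_ms is not None else np.nan,
                    bool(rec.correct),
                )
            )
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def _check_observations(obs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise InvalidInputError(f"observations missing columns {missing}")
    if len(obs) and (obs["rt_ms"] <= 0).any():
        raise InvalidInputError("rt_ms must be positive")
    return obs


def filter_correct(obs: pd.DataFrame) -> pd.DataFrame:
    """Keep reaction times from correct responses only."""
    obs = _check_observations(obs)
    return obs[obs["correct"]].reset_index(drop=True)


def trim_outliers(obs: pd.DataFrame, k: float = 1.5) -> pd.DataFrame:
    """Drop RTs more than ``k`` SD from the participant's own mean.

    The reference mean and SD are computed once per participant within each
    assessment period, pooled across pairing types; there is no iterative
    re-trimming.  Groups with fewer than 2 observations (SD undefined) are
    retained untrimmed with a warning, and zero-variance groups are never
    trimmed.
    """
    obs = _check_observations(obs)
    if obs.empty:
        return obs.copy()
    keep = np.ones(len(obs), dtype=bool)
    grouped = obs.groupby(["participant_id", "assessment_period"], sort=False)
    for key, idx in grouped.indices.items():
        rts = obs["rt_ms"].to_numpy()[idx]
        if len(rts) < 2:
            logger.warning("participant group %s has <2 observations; retained untrimmed", key)
            continue
        m = rts.mean()
        s = rts.std(ddof=1)
        keep[idx] = (rts >= m - k * s) & (rts <= m + k * s)
    return obs[keep].reset_index(drop=True)


def rt_reduction_ms(baseline_mean: float, posttraining_mean: float) -> float:
    """Mean RT reduction from baseline to posttraining, in ms."""
    return baseline_mean - posttraining_mean


@dataclass(frozen=True)
class PairingMeansTable:
    """Pairing-type x assessment-period RT summary with paired tests.

    ``table`` has one row per pairing type with cohort mean/SD at baseline
    and posttraining (over participant-level means), the RT reduction, the
    paired t, df, p, and d = t/sqrt(n).  ``n`` is the number of
    participants contributing to the paired comparisons.
    """

    table: pd.DataFrame
    n: int

    def __post_init__(self):
        if list(self.table["pairing_type"]) != list(PAIRING_TYPES):
            raise InvalidInputError("table must have exactly the 4 pairing types, in order")


def participant_means(obs: pd.DataFrame) -> pd.DataFrame:
    """Participant-level mean RT per pairing type and assessment period."""
    obs = _check_observations(obs)
    return (
        obs.groupby(["participant_id", "pairing_type", "assessment_period"], sort=False)[
            "rt_ms"
        ]
        .mean()
        .reset_index(name="mean_rt_ms")
    )


def pairing_means(obs: pd.DataFrame) -> PairingMeansTable:
    """Build the pairing-type RT table with baseline/posttraining comparison.

    Expects trimmed, correct-only observations from the two assessment
    periods.  Participants missing a period for a pairing type are excluded
    pairwise from that row's test (and logged).
    """
    pm = participant_means(obs)
    rows = []
    ns = []
    for ptype in PAIRING_TYPES:
        sub = pm[pm["pairing_type"] == ptype]
        wide = sub.pivot(index="participant_id", columns="assessment_period", values="mean_rt_ms")
        for period in ("baseline", "posttraining"):
            if period not in wide.columns:
                wide[period] = np.nan
        paired = wide.dropna(subset=["baseline", "posttraining"])
        dropped = len(wide) - len(paired)
        if dropped:
            logger.warning("%s: %d participant(s) missing a period, excluded pairwise", ptype, dropped)
        n = len(paired)
        base = paired["baseline"].to_numpy()
        post = paired["posttraining"].to_numpy()
        if n >= 2:
            res = paired_t(base, post)
            t, df, p = res.t, res.df, res.p
            d = cohen_d_paired(t, n)
        else:
            t = df = p = d = np.nan
        rows.append(
            {
                "pairing_type": ptype,
                "baseline_mean": base.mean() if n else np.nan,
                "baseline_sd": base.std(ddof=1) if n >= 2 else np.nan,
                "posttraining_mean": post.mean() if n else np.nan,
                "posttraining_sd": post.std(ddof=1) if n >= 2 else np.nan,
                "reduction_ms": rt_reduction_ms(base.mean(), post.mean()) if n else np.nan,
                "t": t,
                "df": df,
                "p": p,
                "cohen_d": d,
                "n": n,
            }
        )
        ns.append(n)
    return PairingMeansTable(table=pd.DataFrame(rows), n=max(ns) if ns else 0)


def accuracy_table(obs: pd.DataFrame) -> pd.DataFrame:
    """Accuracy (correct/total) per pairing type and assessment period.

    Uses untrimmed observations including incorrect trials; empty cells are
    reported as NaN.
    """
    obs = _check_observations(obs)
    cells = []
    for ptype in PAIRING_TYPES:
        row: dict = {"pairing_type": ptype}
        for period in ("baseline", "posttraining"):
            cell = obs[(obs["pairing_type"] == ptype) & (obs["assessment_period"] == period)]
            row[period] = cell["correct"].mean() if len(cell) else np.nan
        cells.append(row)
    return pd.DataFrame(cells)
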
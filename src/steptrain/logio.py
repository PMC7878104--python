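"""Session-log serialization and run configuration.

Trial logs are JSON-lines: each session starts with a header record
(participant, session index, period, seed, protocol-constants snapshot)
followed by one trial record per line.  The encoding is canonical (sorted
keys, fixed separators) so a write → read → write round trip is
byte-identical.  Readers validate every line and report the 1-based line
numbers of malformed records rather than coercing them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .dotprobe import ProtocolConstants, SessionLog, TrialRecord, TrialSpec
from .errors import InvalidInputError, SessionLogError


def _dumps(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _header_record(log: SessionLog) -> dict:
    return {
        "record": "header",
        "participant_id": log.participant_id,
        "session_index": log.session_index,
        "assessment_period": log.assessment_period,
        "seed": log.seed,
        "complete": log.complete,
        "constants": dataclasses.asdict(log.constants),
    }


def _trial_record(rec: TrialRecord) -> dict:
    return {
        "record": "trial",
        "trial_index": rec.spec.trial_index,
        "block_index": rec.spec.block_index,
        "pairing_type": rec.spec.pairing_type,
        "left_stimulus_id": rec.spec.left_stimulus_id,
        "right_stimulus_id": rec.spec.right_stimulus_id,
        "probe_side": rec.spec.probe_side,
        "response_side": rec.response_side,
        "rt_ms": rec.rt_ms,
        "correct": rec.correct,
        "feedback_emitted": rec.feedback_emitted,
    }


def write_session_log(log: SessionLog, path: str | Path) -> None:
    lines = [_dumps(_header_record(log))]
    lines += [_dumps(_trial_record(rec)) for rec in log.trials]
    Path(path).write_text("\n".join(lines) + "\n")


def write_session_logs(logs: Iterable[SessionLog], directory: str | Path) -> list[Path]:
    """Write one JSON-lines file per session into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for log in logs:
        name = f"{log.participant_id}_{log.assessment_period}_s{log.session_index:03d}.jsonl"
        p = directory / name
        write_session_log(log, p)
        paths.append(p)
    return paths


def _parse_lines(lines: list[str], source: str) -> SessionLog:
    bad: list[int] = []
    header = None
    records: list[TrialRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
            kind = obj["record"]
            if kind == "header":
                if header is not None:
                    raise ValueError("duplicate header")
                header = obj
            elif kind == "trial":
                spec = TrialSpec(
                    trial_index=obj["trial_index"],
                    block_index=obj["block_index"],
                    pairing_type=obj["pairing_type"],
                    left_stimulus_id=obj["left_stimulus_id"],
                    right_stimulus_id=obj["right_stimulus_id"],
                    probe_side=obj["probe_side"],
                )
                records.append(
                    TrialRecord(
                        spec=spec,
                        response_side=obj["response_side"],
                        rt_ms=obj["rt_ms"],
                        correct=obj["correct"],
                        feedback_emitted=obj["feedback_emitted"],
                    )
                )
            else:
                raise ValueError(f"unknown record kind {kind!r}")
        except (ValueError, KeyError, TypeError) as exc:
            bad.append(lineno)
    if bad:
        raise SessionLogError(
            f"{source}: malformed record(s) at line(s) {bad}", bad_lines=bad
        )
    if header is None:
        raise SessionLogError(f"{source}: missing header record", bad_lines=[1])
    constants = ProtocolConstants(**header["constants"])
    blocks = []
    for b in range(constants.blocks_per_session):
        block = tuple(r for r in records if r.spec.block_index == b)
        if block:
            blocks.append(block)
    return SessionLog(
        participant_id=header["participant_id"],
        session_index=header["session_index"],
        assessment_period=header["assessment_period"],
        blocks=tuple(blocks),
        seed=header["seed"],
        constants=constants,
        complete=header["complete"],
    )


def read_session_log(path: str | Path) -> SessionLog:
    path = Path(path)
    return _parse_lines(path.read_text().splitlines(), str(path))


def read_session_logs(path: str | Path) -> list[SessionLog]:
    """Read session logs from a JSON-lines file or a directory of them."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.jsonl"))
        if not files:
            raise InvalidInputError(f"no .jsonl session logs found in {path}")
        return [read_session_log(f) for f in files]
    return [read_session_log(path)]


_SURVEY_INSTRUMENTS = {
    "phq9": ("phq9_items", 9),
    "pclc": ("pclc_items", 17),
    "mms_anxiety": ("mms_anxiety_items", 9),
    "stigma": ("stigma_items", 6),
    "csa": ("csa_items", 2),
    "vas": ("vas_category", 1),
}


def write_surveys(batteries, path: str | Path) -> None:
    """Write survey batteries as tidy CSV
    (participant_id, period, instrument, item_index, value)."""
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["participant_id", "period", "instrument", "item_index", "value"])
        for b in batteries:
            for inst, (attr, _) in _SURVEY_INSTRUMENTS.items():
                value = getattr(b, attr)
                if value is None:
                    continue
                if inst == "vas":
                    w.writerow([b.participant_id, b.period, inst, 1, value])
                else:
                    for i, v in enumerate(value, start=1):
                        w.writerow([b.participant_id, b.period, inst, i, v])


def read_surveys(path: str | Path):
    """Read tidy survey CSV back into SurveyBattery objects."""
    import csv as _csv

    from .outcomes import SurveyBattery

    cells: dict[tuple[str, str], dict[str, dict[int, int]]] = {}
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        required = {"participant_id", "period", "instrument", "item_index", "value"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise InvalidInputError(f"survey CSV must have columns {sorted(required)}")
        for row in reader:
            inst = row["instrument"]
            if inst not in _SURVEY_INSTRUMENTS:
                raise InvalidInputError(f"unknown instrument {inst!r}")
            key = (row["participant_id"], row["period"])
            cells.setdefault(key, {}).setdefault(inst, {})[int(row["item_index"])] = int(
                row["value"]
            )
    batteries = []
    for (pid, period), insts in cells.items():
        kwargs: dict = {"participant_id": pid, "period": period}
        for inst, (attr, n_items) in _SURVEY_INSTRUMENTS.items():
            if inst not in insts:
                if inst in ("phq9", "vas"):
                    raise InvalidInputError(f"{pid}/{period}: missing {inst} items")
                continue
            items = insts[inst]
            if inst == "vas":
                kwargs["vas_category"] = items[1]
            else:
                if sorted(items) != list(range(1, n_items + 1)):
                    raise InvalidInputError(
                        f"{pid}/{period}/{inst}: expected items 1..{n_items}, got {sorted(items)}"
                    )
                kwargs[attr] = tuple(items[i] for i in range(1, n_items + 1))
        batteries.append(SurveyBattery(**kwargs))
    return batteries


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration; unknown keys are rejected on load."""

    inventory_path: str | None = None
    ratings_path: str | None = None
    logs_path: str | None = None
    surveys_path: str | None = None
    output_dir: str = "steptrain_out"
    trim_k: float = 1.5
    seed: int = 0
    report_format: str = "markdown"  # markdown | csv
    constants: ProtocolConstants = ProtocolConstants()

    def __post_init__(self):
        if self.report_format not in ("markdown", "csv"):
            raise InvalidInputError("report_format must be markdown or csv")
        if self.trim_k <= 0:
            raise InvalidInputError("trim_k must be > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "constants" in data and isinstance(data["constants"], dict):
            data["constants"] = ProtocolConstants(**data["constants"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
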
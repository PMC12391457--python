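"""Raw interaction-session records and their JSON-lines serialisation.

A session holds everything one participant produced during the seven-task
assessment battery: three mouse-tracing tasks (straight line, sine wave,
spiral) at three difficulty levels each, three keyboard tasks (constant
key, two-letter, random sequence) at three levels each, one randomized
click task and one digit-span working-memory run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np

SCHEMA = "motorfair.session.v1"

PATH_KINDS = ("straight", "sine", "spiral")
KEY_TASK_KINDS = ("constant", "two_letter", "random")
LEVELS = (1, 2, 3)


@dataclass
class MouseTrace:
    path_kind: str
    level: int
    samples: np.ndarray  # (n, 3) columns t_ms, x_px, y_px
    centerline_params: Dict[str, float]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.path_kind not in PATH_KINDS:
            raise ValueError(f"unknown path_kind {self.path_kind!r}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        if len(self.samples) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.diff(self.samples[:, 0]) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class KeyTaskRecord:
    task_kind: str
    level: int
    prompts: List[Tuple[float, str]]  # (t_prompt_ms, expected_key)
    presses: List[Tuple[float, str]]  # (t_press_ms, key)

    def __post_init__(self) -> None:
        if self.task_kind not in KEY_TASK_KINDS:
            raise ValueError(f"unknown task_kind {self.task_kind!r}")


@dataclass
class ClickTaskRecord:
    targets: List[Tuple[float, float, float]]  # (t_shown_ms, x, y)
    clicks: List[Tuple[float, float, float, bool]]  # (t_click_ms, x, y, hit)

    def __post_init__(self) -> None:
        if len(self.clicks) != len(self.targets):
            raise ValueError("one click attempt per target is required")


@dataclass
class MemoryTaskRecord:
    trials: List[Tuple[int, bool]]  # (sequence_length, correct)
    max_length_reached: int


@dataclass
class Session:
    participant_id: str
    screen: Tuple[int, int]  # (window_width, window_height) px
    trace_tasks: List[MouseTrace] = field(default_factory=list)
    key_tasks: List[KeyTaskRecord] = field(default_factory=list)
    click_task: ClickTaskRecord | None = None
    memory_task: MemoryTaskRecord | None = None

    def traces_of_kind(self, kind: str) -> List[MouseTrace]:
        return [t for t in self.trace_tasks if t.path_kind == kind]

    def key_tasks_of_kind(self, kind: str) -> List[KeyTaskRecord]:
        return [t for t in self.key_tasks if t.task_kind == kind]


def session_to_dict(session: Session) -> dict:
    return {
        "schema": SCHEMA,
        "participant_id": session.participant_id,
        "screen": list(session.screen),
        "trace_tasks": [
            {
                "path_kind": t.path_kind,
                "level": t.level,
                "samples": t.samples.tolist(),
                "centerline_params": t.centerline_params,
            }
            for t in session.trace_tasks
        ],
        "key_tasks": [
            {
                "task_kind": t.task_kind,
                "level": t.level,
                "prompts": [[p[0], p[1]] for p in t.prompts],
                "presses": [[p[0], p[1]] for p in t.presses],
            }
            for t in session.key_tasks
        ],
        "click_task": None
        if session.click_task is None
        else {
            "targets": [list(t) for t in session.click_task.targets],
            "clicks": [list(c) for c in session.click_task.clicks],
        },
        "memory_task": None
        if session.memory_task is None
        else {
            "trials": [list(t) for t in session.memory_task.trials],
            "max_length_reached": session.memory_task.max_length_reached,
        },
    }


def session_from_dict(d: dict) -> Session:
    if d.get("schema") != SCHEMA:
        raise ValueError(f"unsupported session schema {d.get('schema')!r}")
    click = d.get("click_task")
    memory = d.get("memory_task")
    return Session(
        participant_id=d["participant_id"],
        screen=tuple(d["screen"]),
        trace_tasks=[
            MouseTrace(
                path_kind=t["path_kind"],
                level=t["level"],
                samples=np.asarray(t["samples"], dtype=float),
                centerline_params=t["centerline_params"],
            )
            for t in d["trace_tasks"]
        ],
        key_tasks=[
            KeyTaskRecord(
                task_kind=t["task_kind"],
                level=t["level"],
                prompts=[(p[0], p[1]) for p in t["prompts"]],
                presses=[(p[0], p[1]) for p in t["presses"]],
            )
            for t in d["key_tasks"]
        ],
        click_task=None
        if click is None
        else ClickTaskRecord(
            targets=[tuple(t) for t in click["targets"]],
            clicks=[(c[0], c[1], c[2], bool(c[3])) for c in click["clicks"]],
        ),
        memory_task=None
        if memory is None
        else MemoryTaskRecord(
            trials=[(int(t[0]), bool(t[1])) for t in memory["trials"]],
            max_length_reached=int(memory["max_length_reached"]),
        ),
    )


def write_sessions_jsonl(sessions: Iterable[Session], path) -> None:
    with open(path, "w") as fh:
        for s in sessions:
            fh.write(json.dumps(session_to_dict(s)) + "\n")


def read_sessions_jsonl(path) -> Iterator[Session]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield session_from_dict(json.loads(line))
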
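"""Canonical session data model, file readers/writers, and validation.

A :class:`Session` is one mouse-session of ordered trials (choices, rewards,
block structure, trial durations) plus metadata identifying the animal, its
transgenic line, the drug condition and the task.  Two on-disk layouts are
supported:

* **CSV** — one row per trial, session metadata repeated on every row.
  Column order is fixed: ``mouse_id, line, treatment, task, stage, day,
  block_index, trial_index, choice, reward, duration, high_side, p_left,
  p_right``.
* **JSON** — a list of nested session objects (higher fidelity; block reward
  probabilities stored once per session).

Trial and block indices are 1-based and ranges are inclusive throughout the
package, matching the "reversal at trial 31" convention used to describe the
behavioral tasks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "Session",
    "SessionSet",
    "FormatError",
    "ValidationError",
    "read_sessions",
    "write_sessions",
    "CSV_COLUMNS",
]

LINES = ("D1R", "D2R")
TREATMENTS = ("CNO", "DMSO", "eGFP-CNO")
TASKS = ("TAB", "reversal")
SIDES = ("L", "R")

CSV_COLUMNS = [
    "mouse_id",
    "line",
    "treatment",
    "task",
    "stage",
    "day",
    "block_index",
    "trial_index",
    "choice",
    "reward",
    "duration",
    "high_side",
    "p_left",
    "p_right",
]


class FormatError(ValueError):
    """File does not conform to the documented column/field layout."""


class ValidationError(ValueError):
    """Data violates a session invariant (indices, enums, ranges)."""


@dataclass(slots=True)
class TrialRecord:
    """One trial: what the animal did, what it got, and the task state.

    ``high_side`` is the side whose reward probability is currently higher
    (two-armed-bandit task) or the currently rewarded side (reversal task).
    """

    trial_index: int
    block_index: int
    choice: Literal["L", "R"]
    reward: int
    duration: float
    high_side: Literal["L", "R"]


@dataclass
class Session:
    """One animal-session with ordered trials and experiment metadata."""

    mouse_id: str
    line: str
    treatment: str
    task: str
    stage: int | None
    day: int
    block_probs: list[tuple[float, float]]
    trials: list[TrialRecord] = field(default_factory=list)

    _arrays: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def mean_duration(self) -> float:
        """Arithmetic mean of trial durations (always recomputed)."""
        return float(np.mean([t.duration for t in self.trials]))

    @property
    def key(self) -> tuple:
        return (self.mouse_id, self.task, self.stage, self.day, self.treatment)

    def arrays(self) -> dict:
        """Trial fields as numpy arrays (cached; invalidate by setting _arrays=None).

        ``is_left``/``high_is_left``: uint8 indicators; ``reward``: uint8;
        ``block``: int32 block index; ``duration``: float64.
        """
        if self._arrays is None:
            self._arrays = {
                "is_left": np.array(
                    [1 if t.choice == "L" else 0 for t in self.trials], dtype=np.uint8
                ),
                "reward": np.array([t.reward for t in self.trials], dtype=np.uint8),
                "block": np.array([t.block_index for t in self.trials], dtype=np.int32),
                "high_is_left": np.array(
                    [1 if t.high_side == "L" else 0 for t in self.trials],
                    dtype=np.uint8,
                ),
                "duration": np.array([t.duration for t in self.trials], dtype=float),
            }
        return self._arrays

    def block_slices(self) -> list[tuple[int, slice]]:
        """(block_index, slice into trial arrays) per block, in order."""
        blocks = self.arrays()["block"]
        out = []
        for b in np.unique(blocks):
            idx = np.flatnonzero(blocks == b)
            out.append((int(b), slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    def validate(self) -> None:
        sid = f"session {self.key}"
        if self.line not in LINES:
            raise ValidationError(f"{sid}: unknown line {self.line!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"{sid}: unknown treatment {self.treatment!r}")
        if self.task not in TASKS:
            raise ValidationError(f"{sid}: unknown task {self.task!r}")
        if self.task == "reversal" and not (
            self.stage is None or 1 <= int(self.stage) <= 5
        ):
            raise ValidationError(f"{sid}: reversal stage must be 1-5")
        if not self.trials:
            raise ValidationError(f"{sid}: empty session")
        prev_block = 0
        for i, t in enumerate(self.trials, start=1):
            if t.trial_index != i:
                raise ValidationError(
                    f"{sid}: trial_index not contiguous at position {i} "
                    f"(found {t.trial_index})"
                )
            if t.block_index < prev_block:
                raise ValidationError(f"{sid}: block_index decreases at trial {i}")
            if t.block_index < 1:
                raise ValidationError(f"{sid}: block_index must be >= 1")
            prev_block = t.block_index
            if t.choice not in SIDES:
                raise ValidationError(f"{sid}: bad choice {t.choice!r} at trial {i}")
            if t.high_side not in SIDES:
                raise ValidationError(
                    f"{sid}: bad high_side {t.high_side!r} at trial {i}"
                )
            if t.reward not in (0, 1):
                raise ValidationError(f"{sid}: reward must be 0/1 at trial {i}")
            if not t.duration > 0:
                raise ValidationError(f"{sid}: duration must be > 0 at trial {i}")
        n_blocks = len({t.block_index for t in self.trials})
        if len(self.block_probs) != n_blocks:
            raise ValidationError(
                f"{sid}: block_probs has {len(self.block_probs)} entries for "
                f"{n_blocks} blocks"
            )
        for p_l, p_r in self.block_probs:
            if not (0 <= p_l <= 1 and 0 <= p_r <= 1):
                raise ValidationError(f"{sid}: block probabilities outside [0,1]")


@dataclass
class SessionSet:
    """An ordered collection of sessions with a provenance note."""

    sessions: list[Session]
    provenance: str = ""

    def __iter__(self) -> Iterator[Session]:
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    def validate(self) -> None:
        seen: set[tuple] = set()
        for s in self.sessions:
            s.validate()
            if s.key in seen:
                raise ValidationError(f"duplicate session key {s.key}")
            seen.add(s.key)

    def filter(self, **kwargs) -> "SessionSet":
        """Subset by equality on Session attributes, e.g. line='D1R'."""
        kept = [
            s
            for s in self.sessions
            if all(getattr(s, k) == v for k, v in kwargs.items())
        ]
        return SessionSet(kept, provenance=self.provenance)

    def groupby(self, *attrs: str) -> dict[tuple, list[Session]]:
        out: dict[tuple, list[Session]] = {}
        for s in self.sessions:
            key = tuple(getattr(s, a) for a in attrs)
            out.setdefault(key, []).append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long per-trial table in the documented CSV column order."""
        rows = []
        for s in self.sessions:
            for t in s.trials:
                p_l, p_r = s.block_probs[t.block_index - 1]
                rows.append(
                    (
                        s.mouse_id,
                        s.line,
                        s.treatment,
                        s.task,
                        s.stage,
                        s.day,
                        t.block_index,
                        t.trial_index,
                        t.choice,
                        t.reward,
                        t.duration,
                        t.high_side,
                        p_l,
                        p_r,
                    )
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _session_to_dict(s: Session) -> dict:
    return {
        "mouse_id": s.mouse_id,
        "line": s.line,
        "treatment": s.treatment,
        "task": s.task,
        "stage": s.stage,
        "day": s.day,
        "block_probs": [list(bp) for bp in s.block_probs],
        "trials": [
            {
                "trial_index": t.trial_index,
                "block_index": t.block_index,
                "choice": t.choice,
                "reward": t.reward,
                "duration": t.duration,
                "high_side": t.high_side,
            }
            for t in s.trials
        ],
    }


def _session_from_dict(d: dict) -> Session:
    stage = d.get("stage")
    return Session(
        mouse_id=str(d["mouse_id"]),
        line=d["line"],
        treatment=d["treatment"],
        task=d["task"],
        stage=None if stage is None else int(stage),
        day=int(d["day"]),
        block_probs=[(float(p[0]), float(p[1])) for p in d["block_probs"]],
        trials=[
            TrialRecord(
                trial_index=int(t["trial_index"]),
                block_index=int(t["block_index"]),
                choice=t["choice"],
                reward=int(t["reward"]),
                duration=float(t["duration"]),
                high_side=t["high_side"],
            )
            for t in d["trials"]
        ],
    )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise FormatError(f"cannot infer format from suffix of {path}")


def write_sessions(
    data: SessionSet, path: str | Path, format: str | None = None
) -> Path:
    """Serialize a SessionSet; see module docstring for the layouts."""
    path = Path(path)
    fmt = _infer_format(path, format)
    data.validate()
    if fmt == "csv":
        data.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "provenance": data.provenance,
            "sessions": [_session_to_dict(s) for s in data.sessions],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


def _sessions_from_frame(df: pd.DataFrame) -> list[Session]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    sessions = []
    # preserve file order of first appearance of each session key
    key_cols = ["mouse_id", "task", "stage", "day", "treatment"]
    df = df.copy()
    df["stage"] = df["stage"].astype("object").where(df["stage"].notna(), None)
    for _, g in df.groupby(key_cols, sort=False, dropna=False):
        first = g.iloc[0]
        if g["line"].nunique() > 1:
            raise ValidationError(
                f"session {tuple(first[k] for k in key_cols)}: "
                "inconsistent line values across trials"
            )
        block_probs: list[tuple[float, float]] = []
        for _, bg in g.groupby("block_index", sort=True):
            block_probs.append(
                (float(bg.iloc[0]["p_left"]), float(bg.iloc[0]["p_right"]))
            )
        stage = first["stage"]
        sessions.append(
            Session(
                mouse_id=str(first["mouse_id"]),
                line=str(first["line"]),
                treatment=str(first["treatment"]),
                task=str(first["task"]),
                stage=None if stage is None else int(stage),
                day=int(first["day"]),
                block_probs=block_probs,
                trials=[
                    TrialRecord(
                        trial_index=int(r.trial_index),
                        block_index=int(r.block_index),
                        choice=str(r.choice),
                        reward=int(r.reward),
                        duration=float(r.duration),
                        high_side=str(r.high_side),
                    )
                    for r in g.itertuples()
                ],
            )
        )
    return sessions


def read_sessions(path: str | Path, format: str | None = None) -> SessionSet:
    """Read and validate a SessionSet written by :func:`write_sessions`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as e:
            raise FormatError(f"{path}: empty file") from e
        sessions = _sessions_from_frame(df)
        out = SessionSet(sessions, provenance=str(path))
    elif fmt == "json":
        payload = json.loads(Path(path).read_text())
        if "sessions" not in payload:
            raise FormatError(f"{path}: missing 'sessions' field")
        out = SessionSet(
            [_session_from_dict(d) for d in payload["sessions"]],
            provenance=payload.get("provenance", str(path)),
        )
    else:
        raise FormatError(f"unknown format {fmt!r}")
    out.validate()
    return out
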
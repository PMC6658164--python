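"""Session preprocessing, state segmentation, and choice metrics.

Dynamic vs steady states: within each block, the indicator of choosing the
currently higher-reward-probability side is smoothed with a 7-trial moving
average (centered, truncated at block boundaries).  With M the block maximum
of the smoothed series, the *dynamic* state runs from block start until the
smoothed series first strictly exceeds 0.70*M, and the *steady* state runs
from the first trial strictly exceeding 0.90*M to block end.  Trials between
the two crossings belong to neither state.

Choice metrics: P(R) rewarded-trial proportion; P(H) high-side choice
proportion; P(WS) probability of repeating the previous choice after a
rewarded trial; P(LS) probability of switching after an unrewarded trial.
Win-stay/lose-switch always condition on the *actual* preceding trial in the
session, even when that trial falls outside the requested state window, and
never across session boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Session, SessionSet, TrialRecord
from .rl_models import ParamSet, value_trajectory

__all__ = [
    "BlockSegmentation",
    "StateSegmentation",
    "ChoiceMetrics",
    "QProfile",
    "exclude_duration_outliers",
    "match_durations",
    "segment_block_states",
    "compute_choice_metrics",
    "session_metrics",
    "animal_measure_table",
    "pre_transition_choice_profile",
    "qvalue_block_profile",
    "smooth_series",
]

MEASURES = ("p_reward", "p_high", "p_winstay", "p_loseswitch")


# ---------------------------------------------------------------------------
# preprocessing


def exclude_duration_outliers(
    sessions: Sequence[Session],
    population_key: tuple[str, ...] = ("line", "treatment"),
    k: float = 3.0,
) -> tuple[list[Session], list[Session]]:
    """Drop sessions whose mean trial duration is an extreme outlier.

    Populations are defined by equality on ``population_key`` attributes and
    are never pooled; within each population a session is dropped when its
    mean duration exceeds ``mean + k * SD`` (sample SD over all candidate
    sessions, computed once — a single pass, not iterated).  Populations of
    fewer than two sessions are left untouched with a warning.
    """
    kept: list[Session] = []
    dropped: list[Session] = []
    groups: dict[tuple, list[Session]] = {}
    for s in sessions:
        groups.setdefault(tuple(getattr(s, a) for a in population_key), []).append(s)
    for key, members in groups.items():
        if len(members) < 2:
            warnings.warn(
                f"population {key} has < 2 sessions; outlier exclusion skipped",
                stacklevel=2,
            )
            kept.extend(members)
            continue
        means = np.array([s.mean_duration for s in members])
        sd = float(np.std(means, ddof=1))
        threshold = float(np.mean(means)) + k * sd
        for s, m in zip(members, means):
            (dropped if m > threshold else kept).append(s)
    order = {id(s): i for i, s in enumerate(sessions)}
    kept.sort(key=lambda s: order[id(s)])
    dropped.sort(key=lambda s: order[id(s)])
    return kept, dropped


def match_durations(
    cno: Sequence[Session],
    dmso: Sequence[Session],
    tolerance: float = 0.5,
    max_fraction_removed: float = 0.2,
) -> tuple[list[Session], list[Session], list[dict]]:
    """Equalize mean trial durations by trimming opposing tails.

    CNO sessions are typically slower; the matcher repeatedly removes either
    the longest remaining CNO session or the shortest remaining DMSO session
    — whichever single removal most reduces the absolute gap between the two
    group means of session mean durations — until the gap is within
    ``tolerance`` seconds or the removal budget
    (``max_fraction_removed`` of the initial session count) is exhausted.
    Every removal is logged; replaying the log reproduces the matched sets.
    """
    if not cno or not dmso:
        raise ValueError("both session lists must be non-empty")
    cno = list(cno)
    dmso = list(dmso)
    budget = int(np.floor(max_fraction_removed * (len(cno) + len(dmso))))
    log: list[dict] = []

    def gap(a: list[Session], b: list[Session]) -> float:
        return abs(
            float(np.mean([s.mean_duration for s in a]))
            - float(np.mean([s.mean_duration for s in b]))
        )

    while gap(cno, dmso) > tolerance and len(log) < budget:
        candidates = []
        if len(cno) > 1:
            i = int(np.argmax([s.mean_duration for s in cno]))
            candidates.append(("CNO", i, gap(cno[:i] + cno[i + 1 :], dmso)))
        if len(dmso) > 1:
            i = int(np.argmin([s.mean_duration for s in dmso]))
            candidates.append(("DMSO", i, gap(cno, dmso[:i] + dmso[i + 1 :])))
        if not candidates:
            break
        g0 = gap(cno, dmso)
        group, i, g1 = min(candidates, key=lambda c: c[2])
        if g1 >= g0:
            break  # no single removal helps
        removed = (cno if group == "CNO" else dmso).pop(i)
        log.append(
            {
                "group": group,
                "session_key": removed.key,
                "mean_duration": removed.mean_duration,
                "gap_before": g0,
                "gap_after": g1,
            }
        )
    if gap(cno, dmso) > tolerance:
        warnings.warn(
            f"duration matching stopped at gap {gap(cno, dmso):.3f} s "
            f"(tolerance {tolerance} s)",
            stacklevel=2,
        )
    return cno, dmso, log


# ---------------------------------------------------------------------------
# state segmentation


def smooth_series(
    x: np.ndarray, window: int = 7, alignment: str = "centered"
) -> np.ndarray:
    """Moving average truncated at the series edges.

    ``centered``: mean over [i - w//2, i + w//2]; ``trailing``: mean over
    [i - w + 1, i].  Windows never extend past the ends of ``x`` (they
    shrink instead), so smoothing never crosses block boundaries when
    applied per block.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    out = np.empty(n)
    half = window // 2
    for i in range(n):
        if alignment == "centered":
            lo, hi = max(0, i - half), min(n, i + half + 1)
        elif alignment == "trailing":
            lo, hi = max(0, i - window + 1), i + 1
        else:
            raise ValueError("alignment must be 'centered' or 'trailing'")
        out[i] = x[lo:hi].mean()
    return out


@dataclass
class BlockSegmentation:
    """State ranges of one block; ranges are 1-based inclusive, block-relative."""

    block_index: int
    offset: int  # 0-based session index of the block's first trial
    smoothed: np.ndarray
    max_smoothed: float
    dynamic: tuple[int, int] | None
    steady: tuple[int, int] | None

    @property
    def n_trials(self) -> int:
        return int(self.smoothed.shape[0])

    def _mask(self, rng: tuple[int, int] | None) -> np.ndarray:
        m = np.zeros(self.n_trials, dtype=bool)
        if rng is not None:
            m[rng[0] - 1 : rng[1]] = True
        return m


@dataclass
class StateSegmentation:
    """Per-block dynamic/steady ranges for one session."""

    session_key: tuple
    n_trials: int
    blocks: list[BlockSegmentation]

    def state_mask(self, state: str) -> np.ndarray:
        """Boolean mask over the session's trials for 'dynamic' or 'steady'."""
        mask = np.zeros(self.n_trials, dtype=bool)
        for b in self.blocks:
            rng = b.dynamic if state == "dynamic" else b.steady
            mask[b.offset : b.offset + b.n_trials] = b._mask(rng)
        return mask

    def state_trial_counts(self, state: str) -> list[int]:
        out = []
        for b in self.blocks:
            rng = b.dynamic if state == "dynamic" else b.steady
            out.append(0 if rng is None else rng[1] - rng[0] + 1)
        return out


def segment_block_states(
    session: Session,
    window: int = 7,
    thresholds: tuple[float, float] = (0.70, 0.90),
    alignment: str = "centered",
) -> StateSegmentation:
    """Split each block into dynamic and steady states from smoothed P(H).

    Both threshold crossings are strict (>), so a block in which the animal
    never chooses the high side (block max M = 0) is entirely dynamic with
    an empty steady state.
    """
    t_dyn, t_steady = thresholds
    arr = session.arrays()
    h = (arr["is_left"] == arr["high_is_left"]).astype(float)
    blocks = []
    for block_index, sl in session.block_slices():
        hb = h[sl]
        if hb.shape[0] < 2:
            warnings.warn(
                f"block {block_index} of session {session.key} shorter than 2 "
                "trials; empty segmentation",
                stacklevel=2,
            )
            blocks.append(
                BlockSegmentation(
                    block_index, sl.start, smooth_series(hb, window, alignment),
                    float("nan"), None, None,
                )
            )
            continue
        sm = smooth_series(hb, window, alignment)
        m = float(sm.max())
        above_dyn = np.flatnonzero(sm > t_dyn * m)
        above_steady = np.flatnonzero(sm > t_steady * m)
        n = hb.shape[0]
        if above_dyn.size == 0:  # never exceeds (e.g. M = 0): all dynamic
            dynamic: tuple[int, int] | None = (1, n)
        elif above_dyn[0] == 0:  # exceeded from the first trial
            dynamic = None
        else:
            dynamic = (1, int(above_dyn[0]))  # ends just before the crossing
        if above_steady.size == 0:
            steady: tuple[int, int] | None = None
        else:
            steady = (int(above_steady[0]) + 1, n)
        blocks.append(
            BlockSegmentation(block_index, sl.start, sm, m, dynamic, steady)
        )
    return StateSegmentation(session.key, session.n_trials, blocks)


# ---------------------------------------------------------------------------
# choice metrics


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


@dataclass
class ChoiceMetrics:
    """Choice-metric proportions with their counts.

    Undefined metrics (zero denominator) are NaN, never zero, and are
    excluded from any downstream aggregation.
    """

    n_reward: int
    n_trials: int
    n_high: int
    n_stay_after_win: int
    n_after_win: int
    n_switch_after_lose: int
    n_after_lose: int

    @property
    def p_reward(self) -> float:
        return _ratio(self.n_reward, self.n_trials)

    @property
    def p_high(self) -> float:
        return _ratio(self.n_high, self.n_trials)

    @property
    def p_winstay(self) -> float:
        return _ratio(self.n_stay_after_win, self.n_after_win)

    @property
    def p_loseswitch(self) -> float:
        return _ratio(self.n_switch_after_lose, self.n_after_lose)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}

    @classmethod
    def pool(cls, parts: Iterable["ChoiceMetrics"]) -> "ChoiceMetrics":
        """Sum counts across parts (e.g. across a mouse's sessions)."""
        parts = list(parts)
        return cls(
            *(
                sum(getattr(p, f) for p in parts)
                for f in (
                    "n_reward",
                    "n_trials",
                    "n_high",
                    "n_stay_after_win",
                    "n_after_win",
                    "n_switch_after_lose",
                    "n_after_lose",
                )
            )
        )


def compute_choice_metrics(
    trials: Sequence[TrialRecord],
    scope: str = "all",
    segmentation: StateSegmentation | None = None,
) -> ChoiceMetrics:
    """P(R), P(H), P(WS), P(LS) over one session's trials (optionally scoped).

    For ``scope`` 'dynamic'/'steady', only in-state trials enter numerators
    and denominators, but the win/lose predecessor condition is evaluated on
    the actual preceding trial, in or out of scope.  Trial 1 of a session has
    no predecessor and never enters the WS/LS denominators.
    """
    if scope not in ("all", "dynamic", "steady"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope != "all":
        if segmentation is None:
            raise ValueError("scoped metrics need a StateSegmentation")
        mask = segmentation.state_mask(scope)
        if len(mask) != len(trials):
            raise ValueError("segmentation does not match the trial list")
    else:
        mask = np.ones(len(trials), dtype=bool)

    n_trials = n_reward = n_high = 0
    n_after_win = n_stay_after_win = 0
    n_after_lose = n_switch_after_lose = 0
    for i, t in enumerate(trials):
        if not mask[i]:
            continue
        n_trials += 1
        n_reward += t.reward
        n_high += t.choice == t.high_side
        if i == 0:
            continue
        prev = trials[i - 1]
        stay = t.choice == prev.choice
        if prev.reward == 1:
            n_after_win += 1
            n_stay_after_win += stay
        else:
            n_after_lose += 1
            n_switch_after_lose += not stay
    return ChoiceMetrics(
        n_reward,
        n_trials,
        n_high,
        n_stay_after_win,
        n_after_win,
        n_switch_after_lose,
        n_after_lose,
    )


def session_metrics(
    session: Session,
    scope: str = "all",
    segmentation: StateSegmentation | None = None,
) -> ChoiceMetrics:
    if scope != "all" and segmentation is None:
        segmentation = segment_block_states(session)
    return compute_choice_metrics(session.trials, scope, segmentation)


def animal_measure_table(
    data: SessionSet | Sequence[Session],
    scopes: Sequence[str] = ("all", "dynamic", "steady"),
) -> pd.DataFrame:
    """Animal-level measure table for group statistics.

    Session-level proportions are averaged within animal x treatment x scope
    (undefined session values excluded), yielding one row per animal per
    treatment per measure per scope: columns mouse_id, line, treatment,
    measure, scope, value.
    """
    sessions = list(data)
    rows = []
    for s in sessions:
        seg = segment_block_states(s) if any(sc != "all" for sc in scopes) else None
        for scope in scopes:
            metrics = compute_choice_metrics(s.trials, scope, seg)
            for measure, value in metrics.as_dict().items():
                rows.append(
                    (s.mouse_id, s.line, s.treatment, measure, scope, value)
                )
    df = pd.DataFrame(
        rows, columns=["mouse_id", "line", "treatment", "measure", "scope", "value"]
    )
    out = (
        df.dropna(subset=["value"])
        .groupby(["mouse_id", "line", "treatment", "measure", "scope"], as_index=False)
        ["value"]
        .mean()
    )
    return out


# ---------------------------------------------------------------------------
# profiles


def pre_transition_choice_profile(
    sessions: Sequence[Session], window: int = 10
) -> pd.DataFrame:
    """P(choosing the lower-probability side) by distance to the next
    transition.

    Positions run -window..-1 (-1 = last trial before the transition),
    pooled over all blocks that are followed by another block.  Blocks
    shorter than the window contribute only the positions they cover
    (a warning notes the truncation).
    """
    n_low = np.zeros(window, dtype=int)
    n_tot = np.zeros(window, dtype=int)
    truncated = False
    for s in sessions:
        arr = s.arrays()
        low = arr["is_left"] != arr["high_is_left"]
        slices = s.block_slices()
        if len(slices) < 2:
            continue
        for _, sl in slices[:-1]:
            blk = low[sl]
            w = min(window, blk.shape[0])
            truncated = truncated or w < window
            tail = blk[-w:]
            n_low[window - w :] += tail.astype(int)
            n_tot[window - w :] += 1
    if truncated:
        warnings.warn(
            "window longer than some blocks; profile truncated for those blocks",
            stacklevel=2,
        )
    positions = np.arange(-window, 0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_tot > 0, n_low / np.maximum(n_tot, 1), np.nan)
    return pd.DataFrame(
        {"position": positions, "n_low": n_low, "n_blocks": n_tot, "p_low": p}
    )


@dataclass
class QProfile:
    """Fitted-value profiles around block transitions.

    ``aligned``: per (mouse_id, treatment, align in {post, pre}, offset) mean
    q_high/q_low — offsets 1..n_post after a transition, -n_pre..-1 before
    one.  ``state_means``: per (mouse_id, treatment, state) mean q_high/q_low
    over dynamic- or steady-state trials.  Both use blocks 2-4 only: the
    first block follows no transition and its starting values reflect
    initialization rather than relearning.
    """

    aligned: pd.DataFrame
    state_means: pd.DataFrame


def qvalue_block_profile(
    sessions: Sequence[Session],
    fits: Mapping[tuple[str, str], object],
    blocks: tuple[int, ...] = (2, 3, 4),
    n_post: int = 15,
    n_pre: int = 10,
    q_init: tuple[float, float] = (0.0, 0.0),
) -> QProfile:
    """Replay fitted parameters on each animal's own sessions and align
    values to block transitions.

    ``fits`` maps (mouse_id, treatment) to a ParamSet or an object with a
    ``params`` attribute (e.g. a FitResult).  Alignment windows truncate at
    block edges (a 35-trial block contributes 15 post- but only 10 of its
    pre-transition trials as available).
    """
    acc: dict[tuple, list] = {}
    state_acc: dict[tuple, list] = {}
    for s in sessions:
        key = (s.mouse_id, s.treatment)
        if key not in fits:
            raise ValueError(f"no fitted parameters for animal/condition {key}")
        params = fits[key]
        if not isinstance(params, ParamSet):
            params = params.params
        traj = value_trajectory(s, params, q_init=q_init)
        seg = segment_block_states(s)
        masks = {st: seg.state_mask(st) for st in ("dynamic", "steady")}
        for block_index, sl in s.block_slices():
            if block_index not in blocks:
                continue
            qh = traj.q_high[sl]
            ql = traj.q_low[sl]
            n = qh.shape[0]
            for off in range(min(n_post, n)):
                acc.setdefault((key, "post", off + 1), []).append(
                    (qh[off], ql[off])
                )
            for off in range(min(n_pre, n)):
                acc.setdefault((key, "pre", -off - 1), []).append(
                    (qh[n - 1 - off], ql[n - 1 - off])
                )
            for st in ("dynamic", "steady"):
                in_state = masks[st][sl]
                if in_state.any():
                    state_acc.setdefault((key, st), []).append(
                        np.column_stack([qh[in_state], ql[in_state]])
                    )
    aligned = pd.DataFrame(
        [
            {
                "mouse_id": key[0],
                "treatment": key[1],
                "align": align,
                "offset": off,
                "q_high": float(np.mean([v[0] for v in vals])),
                "q_low": float(np.mean([v[1] for v in vals])),
                "n": len(vals),
            }
            for (key, align, off), vals in sorted(acc.items())
        ]
    )
    state_means = pd.DataFrame(
        [
            {
                "mouse_id": key[0],
                "treatment": key[1],
                "state": st,
                "q_high": float(np.concatenate(chunks)[:, 0].mean()),
                "q_low": float(np.concatenate(chunks)[:, 1].mean()),
                "n_trials": int(sum(c.shape[0] for c in chunks)),
            }
            for (key, st), chunks in sorted(state_acc.items())
        ]
    )
    return QProfile(aligned=aligned, state_means=state_means)
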
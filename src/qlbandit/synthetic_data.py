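"""Task environments, Q-learning agents, and full synthetic cohorts.

Two tasks are generated:

* **Dynamic two-armed-bandit (TAB)**: 4 blocks per session, block length
  drawn uniformly from {35, 40, 45, 50} trials, reward probabilities
  72% / 12% assigned to the two sides and swapped at every (uncued) block
  transition.
* **Progressive reversal**: 5 stages; 60-trial sessions in stages 1-4 and
  90-trial sessions in stage 5; the rewarded side is deterministic (reward
  probability 1 for the correct choice), reverses across sessions from stage
  3 on and within sessions at trial 31 (stage 4) or trials 31 and 61
  (stage 5).

Cohorts emulate the two-line within-subject pharmacology design: two mouse
lines (D1R-Cre, D2R-Cre) each run 10 CNO and 10 DMSO TAB sessions on
alternating days, and the CNO "effect map" multiplies named agent parameters
(defaults: the action-selection gain beta x0.6 in D1R animals; both learning
rates x0.5 in D2R animals).  Trial durations are log-normal with a
session-level random effect and a multiplicative CNO shift, so the
session-exclusion and duration-matching stages downstream have realistic
right-skewed material to work on.

Q-values start at 0/0 at each session start and are never reset at block
transitions (the animal receives no transition cue).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Session, SessionSet, TrialRecord
from .rl_models import (
    MODELS,
    ActionValues,
    ModelSpec,
    ParamSet,
    choice_prob_left,
    update_values,
)

__all__ = [
    "TabTaskConfig",
    "ReversalTaskConfig",
    "DurationModel",
    "CohortConfig",
    "simulate_tab_session",
    "simulate_reversal_session",
    "generate_cohort",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "mouse_id",
    "line",
    "treatment",
    "alpha_pos",
    "alpha_neg",
    "beta",
    "bias",
    "gamma_win",
    "gamma_lose",
    "epsilon",
    "rho",
]


@dataclass(frozen=True)
class TabTaskConfig:
    """Dynamic two-armed-bandit task parameters."""

    n_blocks: int = 4
    block_lengths: tuple[int, ...] = (35, 40, 45, 50)
    p_high: float = 0.72
    p_low: float = 0.12
    first_block_side: str = "random"  # {L, R, random}

    def validate(self) -> None:
        if not (0 <= self.p_low < self.p_high <= 1):
            raise ValueError("require 0 <= p_low < p_high <= 1")
        if any(b <= 0 for b in self.block_lengths):
            raise ValueError("block lengths must be positive")
        if self.first_block_side not in ("L", "R", "random"):
            raise ValueError("first_block_side must be L, R or random")


@dataclass(frozen=True)
class ReversalTaskConfig:
    """Five-stage progressive reversal task parameters."""

    stage_days: tuple[int, ...] = (3, 4, 4, 4, 4)

    def trials_for_stage(self, stage: int) -> int:
        return 90 if stage == 5 else 60

    def reversal_trials(self, stage: int) -> tuple[int, ...]:
        """1-based trial indices at which the rewarded side flips (takes
        effect at that trial)."""
        if stage == 4:
            return (31,)
        if stage == 5:
            return (31, 61)
        return ()

    def across_session_reversal(self, stage: int) -> bool:
        return stage >= 3

    def validate(self) -> None:
        for stage in range(1, 6):
            n = self.trials_for_stage(stage)
            for r in self.reversal_trials(stage):
                if not 1 < r <= n:
                    raise ValueError("reversal trials must lie inside the session")


@dataclass(frozen=True)
class DurationModel:
    """Log-normal per-trial durations with a session random effect.

    duration = exp(log_mean + session_effect + log_sd * z) * shift, with
    session_effect ~ N(0, session_sd^2) drawn once per session and
    shift = treatment_shift for CNO sessions (1 otherwise).  Median trial
    duration at default settings is ~5 s, typical of self-paced nose-poke
    trials.
    """

    log_mean: float = float(np.log(5.0))
    log_sd: float = 0.25
    session_sd: float = 0.20
    treatment_shift: float = 1.1

    def session_durations(
        self, n_trials: int, treatment: str, rng: np.random.Generator
    ) -> np.ndarray:
        eff = rng.normal(0.0, self.session_sd)
        z = rng.normal(0.0, 1.0, size=n_trials)
        shift = self.treatment_shift if treatment == "CNO" else 1.0
        return np.exp(self.log_mean + eff + self.log_sd * z) * shift


def _other(side: str) -> str:
    return "R" if side == "L" else "L"


def _simulate_choices(
    params: ParamSet,
    model: ModelSpec,
    high_is_left: np.ndarray,
    p_high: float,
    p_low: float,
    rng: np.random.Generator,
    deterministic_reward: bool = False,
):
    """Run an agent through a side schedule; returns (choices, rewards)."""
    n = high_is_left.shape[0]
    q = ActionValues()
    choices = np.empty(n, dtype="<U1")
    rewards = np.empty(n, dtype=np.uint8)
    for t in range(n):
        p_left = choice_prob_left(q, params, model)
        choice = "L" if rng.random() < p_left else "R"
        on_high = (choice == "L") == bool(high_is_left[t])
        if deterministic_reward:
            r = 1 if on_high else 0
        else:
            p_r = p_high if on_high else p_low
            r = 1 if rng.random() < p_r else 0
        choices[t] = choice
        rewards[t] = r
        q = update_values(q, choice, r, params, model)
    return choices, rewards


def simulate_tab_session(
    params: ParamSet,
    model: ModelSpec,
    task: TabTaskConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    mouse_id: str = "m0",
    line: str = "D1R",
    treatment: str = "DMSO",
    day: int = 1,
    duration_model: DurationModel | None = None,
) -> Session:
    """Simulate one dynamic-TAB session; fully reproducible from the seed.

    Reward probabilities of the first block are assigned randomly (or per
    ``first_block_side``) and swap sides at every block transition.
    """
    task = task or TabTaskConfig()
    task.validate()
    model.validate_params(params)
    rng = np.random.default_rng(seed)

    lengths = rng.choice(np.asarray(task.block_lengths), size=task.n_blocks)
    if task.first_block_side == "random":
        first_left = bool(rng.random() < 0.5)
    else:
        first_left = task.first_block_side == "L"

    block_idx = np.concatenate(
        [np.full(int(l), b + 1, dtype=np.int32) for b, l in enumerate(lengths)]
    )
    high_is_left = np.concatenate(
        [
            np.full(int(l), 1 if (first_left == (b % 2 == 0)) else 0, dtype=np.uint8)
            for b, l in enumerate(lengths)
        ]
    )
    choices, rewards = _simulate_choices(
        params, model, high_is_left, task.p_high, task.p_low, rng
    )
    durations = (duration_model or DurationModel()).session_durations(
        block_idx.shape[0], treatment, rng
    )
    block_probs = []
    for b in range(task.n_blocks):
        left_high = first_left == (b % 2 == 0)
        block_probs.append(
            (task.p_high, task.p_low) if left_high else (task.p_low, task.p_high)
        )
    trials = [
        TrialRecord(
            trial_index=t + 1,
            block_index=int(block_idx[t]),
            choice=str(choices[t]),
            reward=int(rewards[t]),
            duration=float(durations[t]),
            high_side="L" if high_is_left[t] else "R",
        )
        for t in range(block_idx.shape[0])
    ]
    return Session(
        mouse_id=mouse_id,
        line=line,
        treatment=treatment,
        task="TAB",
        stage=None,
        day=day,
        block_probs=block_probs,
        trials=trials,
    )


def simulate_reversal_session(
    params: ParamSet,
    model: ModelSpec,
    stage: int,
    config: ReversalTaskConfig | None = None,
    rewarded_side_at_start: str = "L",
    seed: int | np.random.SeedSequence = 0,
    *,
    mouse_id: str = "m0",
    line: str = "D1R",
    treatment: str = "eGFP-CNO",
    day: int = 1,
    duration_model: DurationModel | None = None,
) -> Session:
    """Simulate one reversal-task session (correct choice rewarded p = 1).

    ``high_side`` tracks the currently rewarded target; within-session
    reversals take effect at the configured 1-based trial indices.  Each
    segment between reversals is recorded as a block.
    """
    if not 1 <= stage <= 5:
        raise ValueError(f"stage must be in 1..5, got {stage}")
    if rewarded_side_at_start not in ("L", "R"):
        raise ValueError("rewarded_side_at_start must be L or R")
    config = config or ReversalTaskConfig()
    config.validate()
    model.validate_params(params)
    rng = np.random.default_rng(seed)

    n = config.trials_for_stage(stage)
    flips = config.reversal_trials(stage)
    side = rewarded_side_at_start
    high_is_left = np.empty(n, dtype=np.uint8)
    block_idx = np.empty(n, dtype=np.int32)
    block = 1
    for t in range(1, n + 1):
        if t in flips:
            side = _other(side)
            block += 1
        high_is_left[t - 1] = 1 if side == "L" else 0
        block_idx[t - 1] = block

    choices, rewards = _simulate_choices(
        params, model, high_is_left, 1.0, 0.0, rng, deterministic_reward=True
    )
    durations = (duration_model or DurationModel()).session_durations(
        n, treatment, rng
    )
    block_probs = []
    for b in range(1, block + 1):
        left = high_is_left[block_idx == b][0]
        block_probs.append((1.0, 0.0) if left else (0.0, 1.0))
    trials = [
        TrialRecord(
            trial_index=t + 1,
            block_index=int(block_idx[t]),
            choice=str(choices[t]),
            reward=int(rewards[t]),
            duration=float(durations[t]),
            high_side="L" if high_is_left[t] else "R",
        )
        for t in range(n)
    ]
    return Session(
        mouse_id=mouse_id,
        line=line,
        treatment=treatment,
        task="reversal",
        stage=stage,
        day=day,
        block_probs=block_probs,
        trials=trials,
    )


@dataclass(frozen=True)
class CohortConfig:
    """The two-line within-subject TAB pharmacology cohort.

    ``baseline`` maps parameter names to (low, high) uniform ranges from
    which each animal's drug-free ParamSet is drawn; ``effects`` maps
    (line, treatment) to multiplicative factors on named parameters
    (``"alpha"`` scales both learning rates).  CNO/DMSO alternate across the
    20 daily sessions, first-day drug counterbalanced across animals.
    """

    n_per_line: tuple[int, int] = (20, 19)  # (D1R, D2R)
    sessions_per_treatment: int = 10
    model_id: int = 1
    baseline: dict = field(
        default_factory=lambda: {"alpha": (0.45, 0.75), "beta": (2.0, 4.0)}
    )
    effects: dict = field(
        default_factory=lambda: {
            ("D1R", "CNO"): {"beta": 0.6},
            ("D2R", "CNO"): {"alpha": 0.5},
        }
    )
    task: TabTaskConfig = field(default_factory=TabTaskConfig)
    duration_model: DurationModel = field(default_factory=DurationModel)

    def validate(self) -> None:
        self.task.validate()
        model = MODELS[self.model_id]
        free = set(model.free)
        for name in self.baseline:
            if name not in free:
                raise ValueError(
                    f"baseline names parameter {name!r} not free in model "
                    f"{self.model_id}"
                )
        for key, fac in self.effects.items():
            for name, f in fac.items():
                if name not in free:
                    raise ValueError(
                        f"effect map names unknown/pinned parameter {name!r}"
                    )
                if f <= 0:
                    raise ValueError("effect factors must be > 0")


def _draw_baseline(cfg: CohortConfig, rng: np.random.Generator) -> dict[str, float]:
    model = MODELS[cfg.model_id]
    vals = {}
    for name in model.free:
        lo, hi = cfg.baseline.get(name, (0.0, 0.0))
        vals[name] = float(rng.uniform(lo, hi))
    return vals


def _apply_effects(vals: dict[str, float], factors: dict[str, float]) -> dict:
    out = dict(vals)
    for name, f in factors.items():
        out[name] = out[name] * f
    return out


def generate_cohort(
    config: CohortConfig | None = None, seed: int | np.random.SeedSequence = 0
) -> tuple[SessionSet, pd.DataFrame]:
    """Generate the full two-line cohort plus its ground-truth table.

    Returns (sessions, truth): truth holds one row per animal per treatment
    with the true generating parameters (columns :data:`TRUTH_COLUMNS`).
    """
    config = config or CohortConfig()
    config.validate()
    model = MODELS[config.model_id]
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    sessions: list[Session] = []
    truth_rows = []
    animal_seeds = root.spawn(sum(config.n_per_line))
    idx = 0
    for line, n_animals in zip(("D1R", "D2R"), config.n_per_line):
        for a in range(n_animals):
            mouse_id = f"{line}-{a + 1:02d}"
            aseq = animal_seeds[idx]
            idx += 1
            rng = np.random.default_rng(aseq)
            base = _draw_baseline(config, rng)
            per_treatment = {}
            for treatment in ("DMSO", "CNO"):
                factors = config.effects.get((line, treatment), {})
                vals = _apply_effects(base, factors)
                ps = model.paramset_from_vector(
                    [vals[name] for name in model.free]
                )
                per_treatment[treatment] = ps
                truth_rows.append(
                    {"mouse_id": mouse_id, "line": line, "treatment": treatment}
                    | ps.as_dict()
                )
            first_drug = "CNO" if idx % 2 == 0 else "DMSO"
            n_days = 2 * config.sessions_per_treatment
            day_seeds = aseq.spawn(n_days)
            for day in range(1, n_days + 1):
                odd = day % 2 == 1
                treatment = first_drug if odd else (
                    "DMSO" if first_drug == "CNO" else "CNO"
                )
                sessions.append(
                    simulate_tab_session(
                        per_treatment[treatment],
                        model,
                        config.task,
                        day_seeds[day - 1],
                        mouse_id=mouse_id,
                        line=line,
                        treatment=treatment,
                        day=day,
                        duration_model=config.duration_model,
                    )
                )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    tag = hashlib.sha1(
        f"{config}|{root.entropy}".encode(), usedforsecurity=False
    ).hexdigest()[:12]
    out = SessionSet(sessions, provenance=f"generate_cohort:{tag}")
    out.validate()
    return out, truth
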
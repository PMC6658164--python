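"""Shared fixtures: tiny hand-built sessions and small simulated cohorts."""

from __future__ import annotations

import pytest

from qlbandit.core_io import Session, TrialRecord
from qlbandit.rl_models import MODELS
from qlbandit.synthetic_data import CohortConfig, DurationModel, generate_cohort


def build_session(
    choices: str,
    rewards: str,
    high_sides: str | None = None,
    blocks: str | None = None,
    mouse_id: str = "m1",
    line: str = "D1R",
    treatment: str = "DMSO",
    task: str = "TAB",
    stage: int | None = None,
    day: int = 1,
    durations=None,
    block_probs=None,
) -> Session:
    """Build a session from compact strings, e.g. choices='LLRRL',
    rewards='10010'."""
    n = len(choices)
    high_sides = high_sides or "L" * n
    blocks = blocks or "1" * n
    if durations is None:
        durations = [5.0] * n
    n_blocks = len(set(blocks))
    if block_probs is None:
        block_probs = [(0.72, 0.12)] * n_blocks
    trials = [
        TrialRecord(
            trial_index=i + 1,
            block_index=int(blocks[i]),
            choice=choices[i],
            reward=int(rewards[i]),
            duration=float(durations[i]),
            high_side=high_sides[i],
        )
        for i in range(n)
    ]
    return Session(
        mouse_id=mouse_id,
        line=line,
        treatment=treatment,
        task=task,
        stage=stage,
        day=day,
        block_probs=block_probs,
        trials=trials,
    )


@pytest.fixture
def five_trial_session() -> Session:
    """The canonical 5-trial win-stay / lose-switch fixture:
    (L,1), (L,0), (R,0), (R,1), (L,0)."""
    return build_session("LLRRL", "10010")


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """A scaled-down cohort (6 + 6 animals, 4 sessions/treatment) for tests
    that need the full two-line structure but not its statistical power."""
    return CohortConfig(
        n_per_line=(6, 6),
        sessions_per_treatment=4,
        duration_model=DurationModel(),
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config, seed=11)


@pytest.fixture(scope="session")
def model1():
    return MODELS[1]
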
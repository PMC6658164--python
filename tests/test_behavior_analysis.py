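"""Preprocessing fixtures, segmentation hand-traces, and choice metrics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from qlbandit.behavior_analysis import (
    ChoiceMetrics,
    compute_choice_metrics,
    exclude_duration_outliers,
    match_durations,
    pre_transition_choice_profile,
    qvalue_block_profile,
    segment_block_states,
    smooth_series,
)
from qlbandit.rl_models import MODELS, ParamSet
from qlbandit.synthetic_data import simulate_tab_session

from conftest import build_session


# ---------------------------------------------------------------------------
# outlier exclusion


def _uniform_session(day, mean_dur, treatment="DMSO"):
    return build_session(
        "LRLR", "1010", durations=[mean_dur] * 4, day=day, treatment=treatment
    )


def test_outlier_fixture_drops_only_the_slow_session():
    """19 sessions at 10 s plus one at 100 s: mean 14.5, SD ~20.1,
    threshold ~74.8 -> exactly the 100 s session is dropped."""
    sessions = [_uniform_session(d, 10.0) for d in range(1, 20)]
    sessions.append(_uniform_session(20, 100.0))
    kept, dropped = exclude_duration_outliers(sessions)
    assert len(dropped) == 1
    assert dropped[0].mean_duration == pytest.approx(100.0)
    assert len(kept) == 19


def test_equal_durations_drop_nothing():
    sessions = [_uniform_session(d, 10.0) for d in range(1, 11)]
    kept, dropped = exclude_duration_outliers(sessions)
    assert not dropped and len(kept) == 10


def test_populations_judged_separately():
    """An outlier relative to one population is not judged against another."""
    fast = [_uniform_session(d, 10.0, "DMSO") for d in range(1, 20)]
    # CNO population is uniformly slow: no within-population outlier
    slow = [_uniform_session(d, 100.0, "CNO") for d in range(20, 39)]
    kept, dropped = exclude_duration_outliers(fast + slow)
    assert not dropped
    assert len(kept) == 38


def test_small_population_warns_and_keeps():
    sessions = [_uniform_session(1, 10.0)]
    with pytest.warns(UserWarning, match="< 2 sessions"):
        kept, dropped = exclude_duration_outliers(sessions)
    assert kept == sessions and not dropped


# ---------------------------------------------------------------------------
# duration matching


def test_matching_fixture_removes_exactly_one_cno_session():
    cno = [_uniform_session(d, m, "CNO") for d, m in enumerate([10, 11, 30], 1)]
    dmso = [_uniform_session(d, m, "DMSO") for d, m in enumerate([10, 11, 12], 4)]
    mc, md, log = match_durations(cno, dmso, tolerance=1.0)
    assert len(log) == 1
    assert log[0]["group"] == "CNO"
    assert log[0]["mean_duration"] == pytest.approx(30.0)
    assert len(mc) == 2 and len(md) == 3


def test_matching_noop_when_already_within_tolerance():
    cno = [_uniform_session(d, m, "CNO") for d, m in enumerate([10, 11], 1)]
    dmso = [_uniform_session(d, m, "DMSO") for d, m in enumerate([10, 11], 3)]
    mc, md, log = match_durations(cno, dmso, tolerance=1.0)
    assert not log
    assert len(mc) == 2 and len(md) == 2


def test_removal_log_replays_to_matched_sets():
    rng = np.random.default_rng(2)
    cno = [
        _uniform_session(d, 10 + 3 * rng.random() + (5 if d == 3 else 0), "CNO")
        for d in range(1, 9)
    ]
    dmso = [_uniform_session(d, 10 + 3 * rng.random(), "DMSO") for d in range(9, 17)]
    mc, md, log = match_durations(list(cno), list(dmso), tolerance=0.2,
                                  max_fraction_removed=0.5)
    replay_c, replay_d = list(cno), list(dmso)
    for entry in log:
        pool = replay_c if entry["group"] == "CNO" else replay_d
        pool.remove(next(s for s in pool if s.key == entry["session_key"]))
    assert [s.key for s in replay_c] == [s.key for s in mc]
    assert [s.key for s in replay_d] == [s.key for s in md]


def test_matching_warns_when_budget_exhausted():
    cno = [_uniform_session(d, 20.0, "CNO") for d in range(1, 6)]
    dmso = [_uniform_session(d, 10.0, "DMSO") for d in range(6, 11)]
    with pytest.warns(UserWarning, match="stopped at gap"):
        mc, md, log = match_durations(cno, dmso, tolerance=0.1,
                                      max_fraction_removed=0.2)


# ---------------------------------------------------------------------------
# segmentation


def test_saturated_block_is_all_steady():
    s = build_session("L" * 20, "1" * 20, high_sides="L" * 20)
    seg = segment_block_states(s)
    b = seg.blocks[0]
    assert b.dynamic is None
    assert b.steady == (1, 20)
    np.testing.assert_allclose(b.smoothed, 1.0)


def test_zero_max_block_is_all_dynamic():
    s = build_session("R" * 20, "0" * 20, high_sides="L" * 20)
    seg = segment_block_states(s)
    b = seg.blocks[0]
    assert b.max_smoothed == 0.0
    assert b.dynamic == (1, 20)
    assert b.steady is None


def test_ramp_block_matches_hand_trace():
    """10 low-side then 30 high-side choices; the truncated centered
    7-trial moving average first exceeds 0.7 at trial 12 (5/7 at trial 12)
    and 0.9 at trial 14, so dynamic = 1-11 and steady = 14-40."""
    s = build_session("R" * 10 + "L" * 30, "0" * 10 + "1" * 30,
                      high_sides="L" * 40)
    seg = segment_block_states(s)
    b = seg.blocks[0]
    assert b.max_smoothed == pytest.approx(1.0)
    assert b.dynamic == (1, 11)
    assert b.steady == (14, 40)
    # hand-checked smoothing values around the crossings
    assert b.smoothed[10] == pytest.approx(4 / 7)
    assert b.smoothed[11] == pytest.approx(5 / 7)
    assert b.smoothed[12] == pytest.approx(6 / 7)
    assert b.smoothed[13] == pytest.approx(1.0)


def test_smoothing_truncates_at_edges():
    x = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    sm = smooth_series(x, window=7)
    assert sm[0] == pytest.approx(1 / 4)  # window [0, 3]
    assert sm[7] == pytest.approx(0.0)
    trailing = smooth_series(x, window=7, alignment="trailing")
    assert trailing[0] == pytest.approx(1.0)
    assert trailing[6] == pytest.approx(1 / 7)


def test_segmentation_invariant_to_side_relabeling():
    rng = np.random.default_rng(8)
    model = MODELS[1]
    p = model.paramset_from_vector([0.5, 3.0])
    s = simulate_tab_session(p, model, seed=5)
    flip = {"L": "R", "R": "L"}
    mirrored = build_session(
        "".join(flip[t.choice] for t in s.trials),
        "".join(str(t.reward) for t in s.trials),
        high_sides="".join(flip[t.high_side] for t in s.trials),
        blocks="".join(str(t.block_index) for t in s.trials),
        block_probs=[(pr, pl) for pl, pr in s.block_probs],
    )
    a = segment_block_states(s)
    b = segment_block_states(mirrored)
    for ba, bb in zip(a.blocks, b.blocks):
        assert ba.dynamic == bb.dynamic
        assert ba.steady == bb.steady


def test_states_partition_each_block():
    model = MODELS[1]
    p = model.paramset_from_vector([0.4, 2.5])
    for seed in range(5):
        s = simulate_tab_session(p, model, seed=seed)
        seg = segment_block_states(s)
        for b in seg.blocks:
            n_dyn = 0 if b.dynamic is None else b.dynamic[1] - b.dynamic[0] + 1
            n_st = 0 if b.steady is None else b.steady[1] - b.steady[0] + 1
            if b.dynamic is not None and b.steady is not None:
                gap = b.steady[0] - b.dynamic[1] - 1
            elif b.dynamic is None and b.steady is not None:
                gap = b.steady[0] - 1
            elif b.steady is None and b.dynamic is not None:
                gap = b.n_trials - b.dynamic[1]
            else:
                gap = b.n_trials
            assert gap >= 0
            assert n_dyn + gap + n_st == b.n_trials


def test_short_block_warns_empty_segmentation():
    s = build_session("LL", "11", blocks="12",
                      block_probs=[(0.72, 0.12), (0.12, 0.72)])
    with pytest.warns(UserWarning, match="shorter than 2"):
        seg = segment_block_states(s)
    assert all(b.dynamic is None and b.steady is None for b in seg.blocks)


# ---------------------------------------------------------------------------
# choice metrics


def test_five_trial_winstay_loseswitch(five_trial_session):
    m = compute_choice_metrics(five_trial_session.trials)
    assert m.p_winstay == pytest.approx(0.5)
    assert m.p_loseswitch == pytest.approx(0.5)
    assert m.n_after_win == 2 and m.n_after_lose == 2


def test_p_reward_simple_count():
    s = build_session("LRLRL", "11010")
    m = compute_choice_metrics(s.trials)
    assert m.p_reward == pytest.approx(3 / 5)


def test_undefined_metric_is_nan_not_zero():
    s = build_session("LLL", "000")
    m = compute_choice_metrics(s.trials)
    assert np.isnan(m.p_winstay)
    assert not np.isnan(m.p_loseswitch)
    assert m.p_loseswitch == pytest.approx(0.0)  # always stayed


def test_scope_all_equals_weighted_combination():
    model = MODELS[1]
    p = model.paramset_from_vector([0.5, 3.0])
    s = simulate_tab_session(p, model, seed=12)
    seg = segment_block_states(s)
    m_all = compute_choice_metrics(s.trials, "all")
    m_dyn = compute_choice_metrics(s.trials, "dynamic", seg)
    m_st = compute_choice_metrics(s.trials, "steady", seg)
    # per-trial indicators: scoped counts can never exceed the total
    assert m_dyn.n_trials + m_st.n_trials <= m_all.n_trials
    assert m_dyn.n_reward + m_st.n_reward <= m_all.n_reward


def test_scoped_predecessor_uses_true_previous_trial():
    # block of 4: first two trials out of steady scope by construction
    s = build_session("RRLL", "0111", high_sides="LLLL")
    seg = segment_block_states(s)
    b = seg.blocks[0]
    assert b.steady is not None
    start = b.steady[0]
    m = compute_choice_metrics(s.trials, "steady", seg)
    # the first steady trial's predecessor lies before the steady window but
    # still defines the win/lose condition
    prev = s.trials[start - 2]
    if prev.reward:
        assert m.n_after_win >= 1
    else:
        assert m.n_after_lose >= 1


def test_scope_requires_segmentation(five_trial_session):
    with pytest.raises(ValueError, match="StateSegmentation"):
        compute_choice_metrics(five_trial_session.trials, "dynamic", None)


def test_metric_pooling_sums_counts(five_trial_session):
    m = compute_choice_metrics(five_trial_session.trials)
    pooled = ChoiceMetrics.pool([m, m])
    assert pooled.n_trials == 2 * m.n_trials
    assert pooled.p_winstay == m.p_winstay


# ---------------------------------------------------------------------------
# pre-transition profile


def test_pre_transition_counts_bookkeeping():
    model = MODELS[1]
    p = model.paramset_from_vector([0.5, 3.0])
    sessions = [simulate_tab_session(p, model, seed=s, day=s + 1) for s in range(5)]
    prof = pre_transition_choice_profile(sessions, window=10)
    n_completed = sum(len(s.block_probs) - 1 for s in sessions)
    assert (prof["n_blocks"] == n_completed).all()  # blocks are >= 35 trials
    assert (prof["position"] == np.arange(-10, 0)).all()


def test_anticipating_oracle_agent_shows_rising_tail():
    """An agent that switches to the low side 5 trials before each
    transition produces a strictly rising profile tail."""
    blocks = "1" * 40 + "2" * 40
    high = "L" * 40 + "R" * 40
    choices = "L" * 35 + "R" * 5 + "R" * 35 + "L" * 5
    s = build_session(choices, "1" * 80, high_sides=high, blocks=blocks,
                      block_probs=[(0.72, 0.12), (0.12, 0.72)])
    prof = pre_transition_choice_profile([s], window=10)
    p = prof["p_low"].to_numpy()
    assert (p[:5] == 0).all() and (p[5:] == 1).all()


def test_memoryless_agent_profile_tail_not_rising():
    """Q-learning agents cannot anticipate uncued transitions: the
    regression slope of P(low) over the last 10 pre-transition trials is
    not significantly positive."""
    model = MODELS[1]
    p = model.paramset_from_vector([0.5, 3.0])
    sessions = [simulate_tab_session(p, model, seed=s, day=s + 1) for s in range(200)]
    prof = pre_transition_choice_profile(sessions, window=10)
    res = sps.linregress(prof["position"], prof["p_low"])
    assert (res.slope <= 0) or (res.pvalue > 0.05)


def test_window_longer_than_block_truncates_with_warning():
    s = build_session("LLLL", "1111", blocks="1122", high_sides="LLRR",
                      block_probs=[(0.72, 0.12), (0.12, 0.72)])
    with pytest.warns(UserWarning, match="truncated"):
        prof = pre_transition_choice_profile([s], window=5)
    assert prof["n_blocks"].sum() == 2  # only two positions covered


# ---------------------------------------------------------------------------
# q-value block profile


@pytest.fixture(scope="module")
def profiled_sessions():
    model = MODELS[1]
    p = model.paramset_from_vector([0.5, 3.0])
    sessions = [
        simulate_tab_session(p, model, seed=s, mouse_id="m1", day=s + 1)
        for s in range(4)
    ]
    fits = {("m1", "DMSO"): p}
    return sessions, fits


def test_profile_alignment_windows(profiled_sessions):
    sessions, fits = profiled_sessions
    prof = qvalue_block_profile(sessions, fits)
    post = prof.aligned[prof.aligned["align"] == "post"]
    pre = prof.aligned[prof.aligned["align"] == "pre"]
    assert set(post["offset"]) == set(range(1, 16))
    assert set(pre["offset"]) == set(range(-10, 0))
    n_blocks_used = sum(
        1 for s in sessions for b, _ in s.block_slices() if b in (2, 3, 4)
    )
    assert (post["n"] == n_blocks_used).all()


def test_profile_excludes_first_block(profiled_sessions):
    sessions, fits = profiled_sessions
    prof = qvalue_block_profile(sessions, fits, blocks=(2, 3, 4))
    # block 1 starts from the 0/0 initialization, so its offset-1 value is
    # exactly 0; blocks 2-4 start from the previous block's learned low value
    only_b1 = qvalue_block_profile(sessions, fits, blocks=(1,))
    q1_init = only_b1.aligned.query("align == 'post' and offset == 1")["q_high"].iloc[0]
    assert q1_init == pytest.approx(0.0, abs=1e-12)
    # relearning after the swap: q_high climbs over the post-transition window
    post = prof.aligned.query("align == 'post'").sort_values("offset")
    assert post["q_high"].iloc[-1] > post["q_high"].iloc[0] + 0.2


def test_profile_missing_fit_raises(profiled_sessions):
    sessions, _ = profiled_sessions
    with pytest.raises(ValueError, match="no fitted parameters"):
        qvalue_block_profile(sessions, {})


def test_state_means_within_value_range(profiled_sessions):
    sessions, fits = profiled_sessions
    prof = qvalue_block_profile(sessions, fits)
    sm = prof.state_means
    assert set(sm["state"]) == {"dynamic", "steady"}
    assert ((sm["q_high"] >= 0) & (sm["q_high"] <= 1)).all()
    st = sm[sm["state"] == "steady"]
    dyn = sm[sm["state"] == "dynamic"]
    # relearning: steady-state q_high exceeds dynamic-state q_high
    assert st["q_high"].iloc[0] > dyn["q_high"].iloc[0]
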
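"""Compiled inner loop for replaying Q-value dynamics over trial sequences.

The likelihood of a Q-learning model is inherently sequential (each trial's
choice probability depends on the values left by the previous trial), so the
replay is written as a scalar loop and JIT-compiled with numba.  Everything
else in the package stays in plain numpy/pandas.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def replay(
    is_left,
    reward,
    session_start,
    alpha_pos,
    alpha_neg,
    beta,
    bias,
    gamma_win,
    gamma_lose,
    epsilon,
    rho,
    q_init_left,
    q_init_right,
):
    """Replay observed choices/rewards through the value-update equations.

    Parameters are scalars; ``is_left``/``reward`` are uint8 arrays over the
    concatenated trials of one or more sessions and ``session_start`` marks
    trials at which the value state is re-initialized.

    Returns per-trial pre-choice (q_left, q_right, p_left).  The probability
    of choosing left is the softmax of the value difference,
    ``P_L = 1 / (1 + exp(-(beta*(Q_L - Q_R) - b + rho*(U_L - U_R))))``,
    where U are the uncertainty accumulators used by the exploration variant
    (epsilon = rho = 0 otherwise).
    """
    n = is_left.shape[0]
    q_left = np.empty(n)
    q_right = np.empty(n)
    p_left = np.empty(n)
    ql = q_init_left
    qr = q_init_right
    ul = 0.0
    ur = 0.0
    for t in range(n):
        if session_start[t]:
            ql = q_init_left
            qr = q_init_right
            ul = 0.0
            ur = 0.0
        q_left[t] = ql
        q_right[t] = qr
        arg = beta * (ql - qr) - bias + rho * (ul - ur)
        # numerically safe logistic
        if arg >= 0.0:
            p = 1.0 / (1.0 + np.exp(-arg))
        else:
            e = np.exp(arg)
            p = e / (1.0 + e)
        p_left[t] = p
        r = float(reward[t])
        if reward[t] == 1:
            a, g = alpha_pos, gamma_win
        else:
            a, g = alpha_neg, gamma_lose
        if is_left[t] == 1:
            ql = (1.0 - a) * ql + a * r - g
            ul = 0.0
            ur += epsilon
        else:
            qr = (1.0 - a) * qr + a * r - g
            ur = 0.0
            ul += epsilon
    return q_left, q_right, p_left
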
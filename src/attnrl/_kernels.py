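"""Numba hot loops for likelihood replay and forward simulation.

Both kernels walk the trial sequence once, maintaining the per-attribute
action-value table Q[k, i]:

* chosen option:  Q <- Q + alpha_c * (r - Q) with r = N * x^gamma,
* unchosen:       Q <- Q + alpha_u * (0 - Q), alpha_u = alpha_c * Q^(mu-1)
                  clamped to [0, 1] with Q floored inside the power,
* choice:         softmax over sum_k w[k] * Q[k, i] at inverse
                  temperature beta, with max-subtraction.

A pure-Python reference path with the identical operation order lives in
``rl_core``; tests assert the two agree.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _trial_probs(Q, w_s, beta, v):
    n_attr, n_opt = Q.shape
    for i in range(n_opt):
        acc = 0.0
        for k in range(n_attr):
            acc += w_s[k] * Q[k, i]
        v[i] = acc
    vmax = v[0]
    for i in range(1, n_opt):
        if v[i] > vmax:
            vmax = v[i]
    z = 0.0
    for i in range(n_opt):
        v[i] = np.exp(beta * (v[i] - vmax))
        z += v[i]
    for i in range(n_opt):
        v[i] = v[i] / z


@njit(cache=False)
def _update(Q, x_s, c, alpha_c, mu, gamma, n_const, q_floor, update_unchosen):
    n_attr, n_opt = Q.shape
    for k in range(n_attr):
        r = n_const * x_s[k, c] ** gamma
        Q[k, c] = Q[k, c] + alpha_c * (r - Q[k, c])
        if Q[k, c] < 0.0:
            Q[k, c] = 0.0
        if update_unchosen:
            for i in range(n_opt):
                if i == c:
                    continue
                q = Q[k, i]
                qf = q if q > q_floor else q_floor
                au = alpha_c * qf ** (mu - 1.0)
                if au > 1.0:
                    au = 1.0
                elif au < 0.0:
                    au = 0.0
                q = q + au * (0.0 - q)
                Q[k, i] = q if q > 0.0 else 0.0


@njit(cache=False)
def replay_kernel(
    choices,
    session_idx,
    x,
    w,
    q0,
    alpha_c,
    mu,
    beta,
    gamma,
    n_const,
    q_floor,
    p_floor,
    update_unchosen,
    session_reset,
    probs_out,
):
    """Accumulate -ln P(choice_t) over the sequence; fill per-trial probs."""
    n_attr, n_opt = q0.shape
    Q = q0.copy()
    v = np.empty(n_opt)
    nll = 0.0
    for t in range(choices.size):
        s = session_idx[t]
        if session_reset and t > 0 and s != session_idx[t - 1]:
            for k in range(n_attr):
                for i in range(n_opt):
                    Q[k, i] = q0[k, i]
        _trial_probs(Q, w[s], beta, v)
        for i in range(n_opt):
            probs_out[t, i] = v[i]
        c = choices[t]
        p_c = v[c]
        if p_c < p_floor:
            p_c = p_floor
        nll -= np.log(p_c)
        _update(Q, x[s], c, alpha_c, mu, gamma, n_const, q_floor, update_unchosen)
    return nll


@njit(cache=False)
def simulate_kernel(
    uniforms,
    session_idx,
    x,
    w,
    q0,
    alpha_c,
    mu,
    beta,
    gamma,
    n_const,
    q_floor,
    update_unchosen,
    session_reset,
    choices_out,
    probs_out,
    values_out,
    pe_out,
):
    """Draw each choice by inverse-CDF sampling from the softmax."""
    n_attr, n_opt = q0.shape
    Q = q0.copy()
    v = np.empty(n_opt)
    for t in range(uniforms.size):
        s = session_idx[t]
        if session_reset and t > 0 and s != session_idx[t - 1]:
            for k in range(n_attr):
                for i in range(n_opt):
                    Q[k, i] = q0[k, i]
        for i in range(n_opt):
            acc = 0.0
            for k in range(n_attr):
                acc += w[s, k] * Q[k, i]
            values_out[t, i] = acc
        _trial_probs(Q, w[s], beta, v)
        cum = 0.0
        c = n_opt - 1
        for i in range(n_opt):
            probs_out[t, i] = v[i]
            cum += v[i]
            if uniforms[t] < cum:
                c = i
                break
        for i in range(c + 1, n_opt):
            probs_out[t, i] = v[i]
        choices_out[t] = c
        for k in range(n_attr):
            r = n_const * x[s, k, c] ** gamma
            for i in range(n_opt):
                pe_out[t, k, i] = (r if i == c else 0.0) - Q[k, i]
        _update(Q, x[s], c, alpha_c, mu, gamma, n_const, q_floor, update_unchosen)
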
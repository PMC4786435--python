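"""Numba kernels for the hybrid two-step agent.

The hot paths of the package -- simulating sessions and evaluating the
session log-likelihood with its analytic gradient -- loop over trials and
are JIT-compiled.  Everything here works on plain arrays; the dataclass
wrappers live in :mod:`mbdim.task` and :mod:`mbdim.rl`.

Parameter vector layout (raw scale) used throughout:

    theta = [alpha, beta_stage2, beta_MB, beta_MF0, beta_MF1, beta_stick]

The model uses the rescaled parameterization in which the learning-rate
factor is omitted from the innovation term of every delta rule
(Q <- (1-alpha) Q + target), and all unchosen / unvisited values decay
multiplicatively by (1-alpha) at the end of each trial.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_PARAMS = 6


@njit(cache=False)
def simulate_trials(theta, walks, p_common, u, miss_prob, q_init, mf0_updated):
    """Play one session of the two-step task.

    Parameters
    ----------
    theta : (6,) float64
    walks : (4, T) reward probabilities, row index = 2*state + choice.
    u : (T, 5) iid uniforms (miss, stage-1 choice, transition, stage-2
        choice, reward) -- passing pre-drawn uniforms keeps the kernel
        deterministic under a caller-owned numpy Generator.

    Returns
    -------
    c1, s, c2, r : (T,) int64 (-1 where missed), missed : (T,) bool
    """
    alpha, b2, bmb, bmf0, bmf1, bstick = (
        theta[0], theta[1], theta[2], theta[3], theta[4], theta[5],
    )
    T = walks.shape[1]
    c1 = np.full(T, -1, dtype=np.int64)
    s = np.full(T, -1, dtype=np.int64)
    c2 = np.full(T, -1, dtype=np.int64)
    r = np.full(T, -1, dtype=np.int64)
    missed = np.zeros(T, dtype=np.bool_)

    q2 = np.full((2, 2), q_init)
    qmf0 = np.full(2, q_init)
    qmf1 = np.full(2, q_init)
    prev = -1

    for t in range(T):
        if u[t, 0] < miss_prob:
            missed[t] = True
            continue
        # stage-1 softmax over the hybrid value mixture
        v0 = 0.0
        v1 = 0.0
        qmb0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        qmb1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        v0 = bmb * qmb0 + bmf0 * qmf0[0] + bmf1 * qmf1[0]
        v1 = bmb * qmb1 + bmf0 * qmf0[1] + bmf1 * qmf1[1]
        if prev == 0:
            v0 += bstick
        elif prev == 1:
            v1 += bstick
        m = v0 if v0 > v1 else v1
        p1 = np.exp(v0 - m) / (np.exp(v0 - m) + np.exp(v1 - m))
        a1 = 0 if u[t, 1] < p1 else 1
        common = u[t, 2] < p_common
        st = a1 if common else 1 - a1
        # stage-2 softmax
        w0 = b2 * q2[st, 0]
        w1 = b2 * q2[st, 1]
        m2 = w0 if w0 > w1 else w1
        p2 = np.exp(w0 - m2) / (np.exp(w0 - m2) + np.exp(w1 - m2))
        a2 = 0 if u[t, 3] < p2 else 1
        rew = 1 if u[t, 4] < walks[2 * st + a2, t] else 0

        c1[t] = a1
        s[t] = st
        c2[t] = a2
        r[t] = rew

        # updates: chosen stage-2 cell, then MF0/MF1 for the stage-1 choice,
        # with multiplicative (1-alpha) decay of everything unchosen.
        q2_pre = q2[st, a2]
        q2[st, a2] = (1.0 - alpha) * q2_pre + rew
        for ss in range(2):
            for cc in range(2):
                if not (ss == st and cc == a2):
                    q2[ss, cc] *= 1.0 - alpha
        target = q2[st, a2] if mf0_updated else q2_pre
        qmf0[a1] = (1.0 - alpha) * qmf0[a1] + target
        qmf0[1 - a1] *= 1.0 - alpha
        qmf1[a1] = (1.0 - alpha) * qmf1[a1] + rew
        qmf1[1 - a1] *= 1.0 - alpha
        prev = a1
    return c1, s, c2, r, missed


@njit(cache=False)
def loglik_grad(theta, c1, s, c2, r, missed, q_init, mf0_updated):
    """Session log-likelihood and analytic gradient w.r.t. raw theta.

    Missed trials contribute no choice terms and trigger no update.
    """
    alpha, b2, bmb, bmf0, bmf1, bstick = (
        theta[0], theta[1], theta[2], theta[3], theta[4], theta[5],
    )
    T = c1.shape[0]
    q2 = np.full((2, 2), q_init)
    qmf0 = np.full(2, q_init)
    qmf1 = np.full(2, q_init)
    # derivatives with respect to alpha
    dq2 = np.zeros((2, 2))
    dqmf0 = np.zeros(2)
    dqmf1 = np.zeros(2)
    prev = -1

    ll = 0.0
    g = np.zeros(N_PARAMS)

    for t in range(T):
        if missed[t]:
            continue
        a1 = c1[t]
        st = s[t]
        a2 = c2[t]
        rew = r[t]

        # model-based values and their alpha-derivatives (max rule)
        if q2[0, 0] >= q2[0, 1]:
            qmb0, dqmb0 = q2[0, 0], dq2[0, 0]
        else:
            qmb0, dqmb0 = q2[0, 1], dq2[0, 1]
        if q2[1, 0] >= q2[1, 1]:
            qmb1, dqmb1 = q2[1, 0], dq2[1, 0]
        else:
            qmb1, dqmb1 = q2[1, 1], dq2[1, 1]

        stick0 = 1.0 if prev == 0 else 0.0
        stick1 = 1.0 if prev == 1 else 0.0
        v0 = bmb * qmb0 + bmf0 * qmf0[0] + bmf1 * qmf1[0] + bstick * stick0
        v1 = bmb * qmb1 + bmf0 * qmf0[1] + bmf1 * qmf1[1] + bstick * stick1
        m = v0 if v0 > v1 else v1
        e0 = np.exp(v0 - m)
        e1 = np.exp(v1 - m)
        z = e0 + e1
        p0 = e0 / z
        p1 = 1.0 - p0
        ll += (v0 - m if a1 == 0 else v1 - m) - np.log(z)

        # gradient of the stage-1 term: chosen feature minus expectation
        f_mb = (qmb0 if a1 == 0 else qmb1) - (p0 * qmb0 + p1 * qmb1)
        f_mf0 = (qmf0[a1]) - (p0 * qmf0[0] + p1 * qmf0[1])
        f_mf1 = (qmf1[a1]) - (p0 * qmf1[0] + p1 * qmf1[1])
        f_st = (stick0 if a1 == 0 else stick1) - (p0 * stick0 + p1 * stick1)
        g[2] += f_mb
        g[3] += f_mf0
        g[4] += f_mf1
        g[5] += f_st
        dv0 = bmb * dqmb0 + bmf0 * dqmf0[0] + bmf1 * dqmf1[0]
        dv1 = bmb * dqmb1 + bmf0 * dqmf0[1] + bmf1 * dqmf1[1]
        g[0] += (dv0 if a1 == 0 else dv1) - (p0 * dv0 + p1 * dv1)

        # stage-2 term
        w0 = b2 * q2[st, 0]
        w1 = b2 * q2[st, 1]
        m2 = w0 if w0 > w1 else w1
        e20 = np.exp(w0 - m2)
        e21 = np.exp(w1 - m2)
        z2 = e20 + e21
        p20 = e20 / z2
        p21 = 1.0 - p20
        ll += (w0 - m2 if a2 == 0 else w1 - m2) - np.log(z2)
        g[1] += q2[st, a2] - (p20 * q2[st, 0] + p21 * q2[st, 1])
        g[0] += b2 * (dq2[st, a2] - (p20 * dq2[st, 0] + p21 * dq2[st, 1]))

        # updates (values and alpha-derivatives)
        q2_pre = q2[st, a2]
        dq2_pre = dq2[st, a2]
        q2[st, a2] = (1.0 - alpha) * q2_pre + rew
        dq2[st, a2] = (1.0 - alpha) * dq2_pre - q2_pre
        for ss in range(2):
            for cc in range(2):
                if not (ss == st and cc == a2):
                    dq2[ss, cc] = (1.0 - alpha) * dq2[ss, cc] - q2[ss, cc]
                    q2[ss, cc] *= 1.0 - alpha
        if mf0_updated:
            target = q2[st, a2]
            dtarget = dq2[st, a2]
        else:
            target = q2_pre
            dtarget = dq2_pre
        dqmf0[a1] = (1.0 - alpha) * dqmf0[a1] - qmf0[a1] + dtarget
        qmf0[a1] = (1.0 - alpha) * qmf0[a1] + target
        dqmf0[1 - a1] = (1.0 - alpha) * dqmf0[1 - a1] - qmf0[1 - a1]
        qmf0[1 - a1] *= 1.0 - alpha
        dqmf1[a1] = (1.0 - alpha) * dqmf1[a1] - qmf1[a1]
        qmf1[a1] = (1.0 - alpha) * qmf1[a1] + rew
        dqmf1[1 - a1] = (1.0 - alpha) * dqmf1[1 - a1] - qmf1[1 - a1]
        qmf1[1 - a1] *= 1.0 - alpha
        prev = a1

    return ll, g
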
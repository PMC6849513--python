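"""Fused numba kernel for online training, used by the experiment harness.

One call trains a whole epoch of trials (forward, strict-argmax scoring
before the update, unrolled backpropagation through time, SGD) with weights
updated in place. The math is identical to the reference path in
``multicue.network`` (an equivalence test keeps the two in lock-step); the
kernel merely skips quantities that provably do not affect the result:

* ``semantic(t)`` outside the error window (except the scored final step);
* ``hidden(T)`` and the step-T hidden delta (nothing downstream reads them);
* rank-1 gradient terms multiplied by ``hidden(0) = 0``.

Everything is hand-rolled into flat loops because the per-trial matrices are
small (~100x100) and BLAS call overhead would dominate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_epoch_kernel", "train_epoch_kernel_t6w4"]


@njit(cache=True, fastmath=True)
def train_epoch_kernel(
    w_in: np.ndarray,  # (nh, ni), updated in place
    w_rec: np.ndarray,  # (nh, nh)
    w_out: np.ndarray,  # (ns, nh)
    b_h: np.ndarray,  # (nh,)
    b_s: np.ndarray,  # (ns,)
    X: np.ndarray,  # (n, ni) trial inputs
    targets: np.ndarray,  # (n,) int64 semantic indices
    lr: float,
    T: int,
    err_lo: int,  # 1-based inclusive error window
    err_hi: int,
) -> int:
    n, ni = X.shape
    nh = b_h.shape[0]
    ns = b_s.shape[0]
    h = np.zeros((T + 1, nh))  # h[t] = hidden after step t; h[0] stays 0
    s = np.zeros((T + 1, ns))  # s[t] = semantic output at step t
    dpre = np.zeros((T + 1, nh))  # pre-activation hidden deltas
    ds = np.zeros((T + 1, ns))  # pre-activation semantic deltas
    drive = np.empty(nh)  # w_in @ x + b_h, constant across steps (clamped x)
    gh = np.empty(nh)  # dL/dh(t) while walking backwards
    gh_prev = np.empty(nh)
    sum_dpre = np.empty(nh)
    correct = 0
    for i in range(n):
        x = X[i]
        tgt = targets[i]
        for j in range(nh):
            drive[j] = b_h[j]
        for k in range(ni):
            xk = x[k]
            if xk != 0.0:
                for j in range(nh):
                    drive[j] += w_in[j, k] * xk
        # forward: semantic reads the previous hidden state
        for t in range(1, T + 1):
            h_prev = h[t - 1]
            if (err_lo <= t <= err_hi) or t == T:
                st = s[t]
                for j in range(ns):
                    acc = b_s[j]
                    row = w_out[j]
                    for k in range(nh):
                        acc += row[k] * h_prev[k]
                    st[j] = 1.0 / (1.0 + np.exp(-acc))
            if t < T:
                ht = h[t]
                for j in range(nh):
                    acc = drive[j]
                    row = w_rec[j]
                    for k in range(nh):
                        acc += row[k] * h_prev[k]
                    ht[j] = 1.0 / (1.0 + np.exp(-acc))
        # strict-max scoring on the final step, before this trial's update
        out = s[T]
        is_max = True
        for j in range(ns):
            if j != tgt and out[j] >= out[tgt]:
                is_max = False
                break
        if is_max:
            correct += 1
        # semantic deltas over the error window
        for t in range(err_lo, err_hi + 1):
            st = s[t]
            dst = ds[t]
            for j in range(ns):
                y = 1.0 if j == tgt else 0.0
                dst[j] = 2.0 * (st[j] - y) * st[j] * (1.0 - st[j])
        # backward through time; dL/dh(T) = 0, so seed from the step-T output error
        for k in range(nh):
            gh[k] = 0.0
        if err_lo <= T <= err_hi:
            dsT = ds[T]
            for j in range(ns):
                d = dsT[j]
                row = w_out[j]
                for k in range(nh):
                    gh[k] += row[k] * d
        for t in range(T - 1, 0, -1):
            ht = h[t]
            dpt = dpre[t]
            for j in range(nh):
                dpt[j] = gh[j] * ht[j] * (1.0 - ht[j])
            for k in range(nh):
                gh_prev[k] = 0.0
            for j in range(nh):
                d = dpt[j]
                row = w_rec[j]
                for k in range(nh):
                    gh_prev[k] += row[k] * d
            if err_lo <= t <= err_hi:
                dst = ds[t]
                for j in range(ns):
                    d = dst[j]
                    row = w_out[j]
                    for k in range(nh):
                        gh_prev[k] += row[k] * d
            tmp = gh
            gh = gh_prev
            gh_prev = tmp
        # SGD updates; the input gradient factorizes because x is clamped
        for j in range(nh):
            acc = 0.0
            for t in range(1, T):
                acc += dpre[t, j]
            sum_dpre[j] = acc
            b_h[j] -= lr * acc
        for k in range(ni):
            xk = x[k]
            if xk != 0.0:
                c = lr * xk
                for j in range(nh):
                    w_in[j, k] -= c * sum_dpre[j]
        for t in range(2, T):  # the t=1 rank-1 term vanishes (h(0) = 0)
            h_prev = h[t - 1]
            dpt = dpre[t]
            for j in range(nh):
                d = lr * dpt[j]
                row = w_rec[j]
                for k in range(nh):
                    row[k] -= d * h_prev[k]
        for t in range(err_lo, err_hi + 1):
            dst = ds[t]
            if t >= 2:
                h_prev = h[t - 1]
                for j in range(ns):
                    d = lr * dst[j]
                    b_s[j] -= d
                    row = w_out[j]
                    for k in range(nh):
                        row[k] -= d * h_prev[k]
            else:
                for j in range(ns):
                    b_s[j] -= lr * dst[j]
    return correct


@njit(cache=True, fastmath=True)
def train_epoch_kernel_t6w4(w_in, w_rec, w_out, b_h, b_s, X, targets, lr):
    """Specialization of :func:`train_epoch_kernel` for the standard dynamics
    (6 time steps, error window 3-6). Mathematically identical; the four
    output steps and the four rank-1 updates per matrix are fused into
    single passes, and the hidden(0)=0 multiplies are elided.
    """
    n, ni = X.shape
    nh = b_h.shape[0]
    ns = b_s.shape[0]
    h = np.zeros((6, nh))  # h[t] after step t, t = 1..5; h[0] stays 0
    s = np.zeros((7, ns))  # s[t] at step t, t = 3..6
    ds = np.zeros((7, ns))
    dpre = np.zeros((6, nh))
    drive = np.empty(nh)
    gh = np.empty(nh)
    gow = np.zeros((7, nh))  # w_out.T @ ds[t]
    sum_dpre = np.empty(nh)
    correct = 0
    for i in range(n):
        x = X[i]
        tgt = targets[i]
        for j in range(nh):
            drive[j] = b_h[j]
        for k in range(ni):
            xk = x[k]
            if xk != 0.0:
                for j in range(nh):
                    drive[j] += w_in[j, k] * xk
        # hidden trajectory: h(1) = sigmoid(drive) since h(0) = 0
        h1 = h[1]
        for j in range(nh):
            h1[j] = 1.0 / (1.0 + np.exp(-drive[j]))
        for t in range(2, 6):
            h_prev = h[t - 1]
            ht = h[t]
            j = 0
            while j + 2 <= nh:  # two rows per pass: shared loads, two FMA chains
                a0 = drive[j]
                a1 = drive[j + 1]
                r0 = w_rec[j]
                r1 = w_rec[j + 1]
                for k in range(nh):
                    hk = h_prev[k]
                    a0 += r0[k] * hk
                    a1 += r1[k] * hk
                ht[j] = 1.0 / (1.0 + np.exp(-a0))
                ht[j + 1] = 1.0 / (1.0 + np.exp(-a1))
                j += 2
            while j < nh:
                acc = drive[j]
                row = w_rec[j]
                for k in range(nh):
                    acc += row[k] * h_prev[k]
                ht[j] = 1.0 / (1.0 + np.exp(-acc))
                j += 1
        # all four output steps in one pass over w_out (s(t) reads h(t-1))
        h2 = h[2]
        h3 = h[3]
        h4 = h[4]
        h5 = h[5]
        s3 = s[3]
        s4 = s[4]
        s5 = s[5]
        s6 = s[6]
        for j in range(ns):
            row = w_out[j]
            a3 = b_s[j]
            a4 = a3
            a5 = a3
            a6 = a3
            for k in range(nh):
                r = row[k]
                a3 += r * h2[k]
                a4 += r * h3[k]
                a5 += r * h4[k]
                a6 += r * h5[k]
            s3[j] = 1.0 / (1.0 + np.exp(-a3))
            s4[j] = 1.0 / (1.0 + np.exp(-a4))
            s5[j] = 1.0 / (1.0 + np.exp(-a5))
            s6[j] = 1.0 / (1.0 + np.exp(-a6))
        is_max = True
        for j in range(ns):
            if j != tgt and s6[j] >= s6[tgt]:
                is_max = False
                break
        if is_max:
            correct += 1
        # semantic deltas and their back-projections, one pass over w_out
        ds3 = ds[3]
        ds4 = ds[4]
        ds5 = ds[5]
        ds6 = ds[6]
        for j in range(ns):
            y = 1.0 if j == tgt else 0.0
            ds3[j] = 2.0 * (s3[j] - y) * s3[j] * (1.0 - s3[j])
            ds4[j] = 2.0 * (s4[j] - y) * s4[j] * (1.0 - s4[j])
            ds5[j] = 2.0 * (s5[j] - y) * s5[j] * (1.0 - s5[j])
            ds6[j] = 2.0 * (s6[j] - y) * s6[j] * (1.0 - s6[j])
        g3 = gow[3]
        g4 = gow[4]
        g5 = gow[5]
        g6 = gow[6]
        for k in range(nh):
            g3[k] = 0.0
            g4[k] = 0.0
            g5[k] = 0.0
            g6[k] = 0.0
        for j in range(ns):
            row = w_out[j]
            d3 = ds3[j]
            d4 = ds4[j]
            d5 = ds5[j]
            d6 = ds6[j]
            for k in range(nh):
                r = row[k]
                g3[k] += r * d3
                g4[k] += r * d4
                g5[k] += r * d5
                g6[k] += r * d6
        # backward chain: dL/dh(5) = gow(6); dpre(6) = 0 identically
        for t in range(5, 0, -1):
            ht = h[t]
            dpt = dpre[t]
            if t == 5:
                for j in range(nh):
                    dpt[j] = g6[j] * ht[j] * (1.0 - ht[j])
            else:
                for j in range(nh):
                    dpt[j] = gh[j] * ht[j] * (1.0 - ht[j])
            if t == 1:
                break
            # dL/dh(t-1) = w_rec.T @ dpre(t) + gow(t)
            src = gow[t]
            for k in range(nh):
                gh[k] = src[k]
            j = 0
            while j + 2 <= nh:
                d0 = dpt[j]
                d1 = dpt[j + 1]
                r0 = w_rec[j]
                r1 = w_rec[j + 1]
                for k in range(nh):
                    gh[k] += r0[k] * d0 + r1[k] * d1
                j += 2
            while j < nh:
                d = dpt[j]
                row = w_rec[j]
                for k in range(nh):
                    gh[k] += row[k] * d
                j += 1
        # updates; four rank-1 terms fused into one pass per matrix
        dp1 = dpre[1]
        dp2 = dpre[2]
        dp3 = dpre[3]
        dp4 = dpre[4]
        dp5 = dpre[5]
        for j in range(nh):
            acc = dp1[j] + dp2[j] + dp3[j] + dp4[j] + dp5[j]
            sum_dpre[j] = acc
            b_h[j] -= lr * acc
        for k in range(ni):
            xk = x[k]
            if xk != 0.0:
                c = lr * xk
                for j in range(nh):
                    w_in[j, k] -= c * sum_dpre[j]
        for j in range(nh):
            c2 = lr * dp2[j]
            c3 = lr * dp3[j]
            c4 = lr * dp4[j]
            c5 = lr * dp5[j]
            row = w_rec[j]
            for k in range(nh):
                row[k] -= c2 * h1[k] + c3 * h2[k] + c4 * h3[k] + c5 * h4[k]
        for j in range(ns):
            c3 = lr * ds3[j]
            c4 = lr * ds4[j]
            c5 = lr * ds5[j]
            c6 = lr * ds6[j]
            b_s[j] -= c3 + c4 + c5 + c6
            row = w_out[j]
            for k in range(nh):
                row[k] -= c3 * h2[k] + c4 * h3[k] + c5 * h4[k] + c6 * h5[k]
    return correct
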
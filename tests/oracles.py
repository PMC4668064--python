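"""Independent reference implementations used only as test oracles.

Everything here recomputes quantities by a different route than the
package (literal summation, exhaustive optimisation, direct counting) so
the two paths can be compared on small instances.
"""

from __future__ import annotations

import numpy as np


def modularity_direct(net, labels: np.ndarray) -> float:
    """Term-by-term literal summation of the multislice quality function.

    Quadruple loop over (i, j, s, r): intraslice terms (A - gamma V) for
    s == r, plus omega for every ordered slice pair s != r where node j
    keeps its label.  Entirely independent of the supra-matrix route.
    """
    A = net.slices
    N, T = net.n_nodes, net.n_slices
    k = A.sum(axis=2)
    m = k.sum(axis=1) / 2.0
    two_mu = 2.0 * m.sum() + N * T * (T - 1) * net.omega
    Q = 0.0
    for s in range(T):
        for i in range(N):
            for j in range(N):
                if labels[i, s] == labels[j, s]:
                    V = k[s, i] * k[s, j] / (2.0 * m[s]) if m[s] > 0 else 0.0
                    Q += A[s, i, j] - net.gamma[s] * V
    for j in range(N):
        for s in range(T):
            for r in range(T):
                if s != r and labels[j, s] == labels[j, r]:
                    Q += net.omega
    return Q / two_mu


def exact_max_quality(B: np.ndarray, mu: float) -> float:
    """Global maximum of Q over *all* set partitions of the supra-nodes.

    Max-weight set partition by dynamic programming over subsets:
    best(S) = max over subsets C of S containing S's lowest element of
    w(C) + best(S \\ C), where w(C) is the total (directed) weight of B
    inside C.  Exact, and feasible up to ~14 supra-nodes.
    """
    n = B.shape[0]
    full = 1 << n
    w = np.zeros(full)
    for S in range(1, full):
        m_bit = (S & -S).bit_length() - 1
        rest = S ^ (1 << m_bit)
        acc = B[m_bit, m_bit]
        r = rest
        while r:
            l = (r & -r).bit_length() - 1
            acc += 2.0 * B[m_bit, l]
            r ^= 1 << l
        w[S] = w[rest] + acc
    best = np.zeros(full)
    for S in range(1, full):
        m_bit = (S & -S).bit_length() - 1
        rest = S ^ (1 << m_bit)
        sub = rest
        b = -np.inf
        while True:
            C = sub | (1 << m_bit)
            v = w[C] + best[S ^ C]
            if v > b:
                b = v
            if sub == 0:
                break
            sub = (sub - 1) & rest
        best[S] = b
    return best[full - 1] / (2.0 * mu)


def allegiance_counting(partitions) -> np.ndarray:
    """Direct double-loop count of co-assignment frequencies."""
    N = partitions[0].labels.shape[0]
    T = partitions[0].labels.shape[1]
    O = len(partitions)
    P = np.zeros((N, N))
    for part in partitions:
        for t in range(T):
            for i in range(N):
                for j in range(N):
                    if part.labels[i, t] == part.labels[j, t]:
                        P[i, j] += 1.0
    return P / (O * T)


def random_multilayer(rng, n_nodes: int, n_slices: int, gamma=1.0, omega=0.0):
    """Random symmetric nonnegative-weight multilayer instance."""
    from funcarto import MultilayerNetwork

    A = rng.random((n_slices, n_nodes, n_nodes))
    A = (A + A.transpose(0, 2, 1)) / 2.0
    return MultilayerNetwork(
        A, [f"n{i}" for i in range(n_nodes)], gamma=gamma, omega=omega
    )
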
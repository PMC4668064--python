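"""Multilayer (multislice) networks and the multislice modularity quality.

A multilayer network here is an ordered stack of ``T`` symmetric weighted
adjacency matrices ("slices") over one fixed set of ``N`` nodes — e.g. one
functional-connectivity matrix per task condition.  Node identity is
imposed across slices by *categorical* interslice coupling: node ``j`` in
slice ``s`` is connected to node ``j`` in every other slice ``r != s``
with uniform weight ``omega``.  Community structure of the whole stack is
scored by the multislice modularity

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma_s V_ijs) delta_sr
                               + delta_ij omega ] * delta(g_is, g_jr)

where ``V_ijs = k_is k_js / (2 m_s)`` is the Newman–Girvan null within
slice ``s``, ``gamma_s`` is the per-slice resolution, ``g_is`` the
community label of node ``i`` in slice ``s``, and ``2 mu`` the total edge
weight including the coupling terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError

SIGN_POLICIES = ("truncate_negative", "keep")

#: Maximum tolerated |A - A.T| entry for a slice to count as symmetric.
SYMMETRY_ATOL = 1e-10


@dataclass
class MultilayerNetwork:
    """Ordered stack of symmetric slices plus resolution/coupling parameters.

    Parameters
    ----------
    slices : array, shape (T, N, N)
        Intraslice adjacency matrices.  Must be symmetric within
        ``SYMMETRY_ATOL``; diagonals are forced to zero (self-weights carry
        no information for community structure — the ``omega`` coupling is
        the only self-interaction).
    node_ids : sequence of str
        Node labels, authoritative order for every downstream table.
    gamma : float or array, shape (T,)
        Structural resolution parameter(s), one per slice.
    omega : float
        Categorical interslice coupling weight (>= 0).
    sign_policy : {"truncate_negative", "keep"}
        How negative weights are handled.  The Newman–Girvan null is
        ill-defined for signed strengths, so the default truncates
        negative weights to zero at construction.
    """

    slices: np.ndarray
    node_ids: Sequence[str]
    gamma: float | np.ndarray = 1.0
    omega: float = 0.0
    sign_policy: str = "truncate_negative"

    def __post_init__(self) -> None:
        A = np.asarray(self.slices, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValidationError(
                f"slices must have shape (T, N, N); got {A.shape}"
            )
        if np.isnan(A).any():
            raise ValidationError("slice matrices contain NaN entries")
        asym = np.abs(A - A.transpose(0, 2, 1)).max() if A.size else 0.0
        if asym > SYMMETRY_ATOL:
            raise ValidationError(
                f"slice matrices are not symmetric (max asymmetry {asym:.3g})"
            )
        A = (A + A.transpose(0, 2, 1)) / 2.0
        for t in range(A.shape[0]):
            np.fill_diagonal(A[t], 0.0)
        if self.sign_policy not in SIGN_POLICIES:
            raise ValidationError(
                f"sign_policy must be one of {SIGN_POLICIES}; got {self.sign_policy!r}"
            )
        if self.sign_policy == "truncate_negative":
            A = np.where(A < 0.0, 0.0, A)
        self.slices = A
        self.node_ids = list(self.node_ids)
        if len(self.node_ids) != A.shape[1]:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for N={A.shape[1]} nodes"
            )
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 0:
            g = np.full(A.shape[0], float(g))
        elif g.shape != (A.shape[0],):
            raise ValidationError(
                f"gamma must be scalar or length T={A.shape[0]}; got shape {g.shape}"
            )
        self.gamma = g
        self.omega = float(self.omega)
        if self.omega < 0:
            raise ValidationError("omega must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.slices.shape[1]

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def with_params(self, gamma=None, omega=None) -> "MultilayerNetwork":
        """Copy of the network with new resolution/coupling parameters."""
        return replace(
            self,
            slices=self.slices.copy(),
            gamma=self.gamma if gamma is None else gamma,
            omega=self.omega if omega is None else omega,
        )


@dataclass
class Partition:
    """Community labels for every (node, slice) pair.

    ``labels`` has shape (N, T): ``labels[i, s]`` is the community of node
    ``i`` in slice ``s``.  Labels are non-negative integers; their values
    are meaningful only up to relabeling.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.labels)
        if L.ndim != 2:
            raise ValidationError(f"labels must be 2-D (N, T); got {L.shape}")
        if not np.issubdtype(L.dtype, np.integer):
            if not np.all(L == np.round(L)):
                raise ValidationError("community labels must be integers")
            L = L.astype(np.int64)
        if L.size and L.min() < 0:
            raise ValidationError("community labels must be non-negative")
        self.labels = L.astype(np.int64, copy=False)

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.labels.shape[1]

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def canonical(self) -> "Partition":
        """Relabel communities by order of first appearance (node-major)."""
        flat = self.labels.ravel()
        _, first = np.unique(flat, return_index=True)
        order = flat[np.sort(first)]
        mapping = {int(old): new for new, old in enumerate(order)}
        out = np.vectorize(mapping.__getitem__, otypes=[np.int64])(self.labels)
        return Partition(out)

    def slice_labels(self, s: int) -> np.ndarray:
        return self.labels[:, s]


@dataclass(frozen=True)
class QualityContext:
    """Strength bookkeeping entering the modularity normalisation.

    ``slice_strengths[s, j]`` is the intraslice strength k_js, the slice
    totals are m_s = 1/2 sum_ij A_ijs, every node carries coupling
    strength c_js = (T - 1) * omega, and the grand total is
    mu = 1/2 sum_js (k_js + c_js).
    """

    slice_strengths: np.ndarray  # (T, N)
    slice_totals: np.ndarray  # (T,)
    coupling_strength: float
    total: float  # mu

    @property
    def two_mu(self) -> float:
        return 2.0 * self.total


def quality_context(net: MultilayerNetwork) -> QualityContext:
    k = net.slices.sum(axis=2)  # (T, N)
    m = k.sum(axis=1) / 2.0
    c = (net.n_slices - 1) * net.omega
    two_mu = 2.0 * m.sum() + net.n_nodes * net.n_slices * c
    if two_mu <= 0:
        raise ValidationError("network has zero total weight (mu = 0)")
    return QualityContext(k, m, c, two_mu / 2.0)


def newman_girvan_null(net: MultilayerNetwork, slice_index: int) -> np.ndarray:
    """Expected edge weight ``V_ijs = k_is k_js / (2 m_s)`` for one slice.

    An empty slice (m_s = 0) yields an all-zero null matrix with a warning.
    """
    A = net.slices[slice_index]
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        warnings.warn(
            f"slice {slice_index} has zero total weight; null model is zero",
            stacklevel=2,
        )
        return np.zeros_like(A)
    return np.outer(k, k) / two_m


def supra_modularity_matrix(net: MultilayerNetwork) -> tuple[np.ndarray, float]:
    """Flatten the quality function into one (N*T, N*T) matrix ``B``.

    Supra-node ``s*N + i`` is node ``i`` in slice ``s``.  Diagonal blocks
    hold ``A_s - gamma_s V_s`` (including the diagonal null term
    ``-gamma_s V_iis``); off-diagonal blocks hold ``omega`` on their
    diagonals (categorical coupling).  Returns ``(B, mu)`` such that
    ``Q = sum_{kl in same community} B_kl / (2 mu)``.
    """
    N, T = net.n_nodes, net.n_slices
    ctx = quality_context(net)
    B = np.zeros((N * T, N * T))
    for s in range(T):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            V = newman_girvan_null(net, s)
        B[s * N:(s + 1) * N, s * N:(s + 1) * N] = net.slices[s] - net.gamma[s] * V
    if net.omega != 0.0 and T > 1:
        coupling = np.kron(1.0 - np.eye(T), np.eye(N)) * net.omega
        B += coupling
    return B, ctx.total


def multislice_modularity(net: MultilayerNetwork, partition: Partition) -> float:
    """Evaluate the multislice modularity Q of a partition (pure function).

    The sum runs over *all* ordered (i, j, s, r) tuples, so the constant
    diagonal null terms -gamma_s V_iis are included, exactly as the
    quality function is written.
    """
    if partition.labels.shape != (net.n_nodes, net.n_slices):
        raise ValidationError(
            f"partition shape {partition.labels.shape} does not match network "
            f"({net.n_nodes} nodes x {net.n_slices} slices)"
        )
    B, mu = supra_modularity_matrix(net)
    flat = partition.labels.T.ravel()  # supra order s*N + i
    total = 0.0
    for lab in np.unique(flat):
        idx = np.flatnonzero(flat == lab)
        total += B[np.ix_(idx, idx)].sum()
    return total / (2.0 * mu)


def apply_sign_policy(net: MultilayerNetwork) -> MultilayerNetwork:
    """Return a network with its sign policy applied to the slices.

    ``truncate_negative`` zeroes negative weights; ``keep`` passes all
    weights through.  Construction already enforces the policy, so this
    is idempotent.
    """
    if net.sign_policy == "truncate_negative":
        return replace(net, slices=np.where(net.slices < 0, 0.0, net.slices))
    return replace(net, slices=net.slices.copy())
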
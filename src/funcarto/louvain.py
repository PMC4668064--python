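"""Generalized Louvain maximization of multislice modularity.

The quality function is flattened into one supra-modularity matrix ``B``
over the ``N*T`` (node, slice) pairs (see
:func:`funcarto.multilayer.supra_modularity_matrix`); maximizing Q is then
a max-weight set-partition problem on ``B``.  The classic two-phase
heuristic applies directly: phase 1 greedily moves supra-nodes between
communities while any move improves Q; phase 2 aggregates communities
into super-nodes (summing all intra/inter weights, which carries the
coupling contributions along) and recurses.  Because the null model and
the coupling are baked into ``B``, the aggregated problem has exactly the
same form as the original.

Every run starts from all-singleton communities and visits supra-nodes in
a seed-shuffled order, so independent restarts explore different local
optima; an ensemble of restarts is the raw material for the module
allegiance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .multilayer import (
    MultilayerNetwork,
    Partition,
    multislice_modularity,
    supra_modularity_matrix,
)

#: A move must improve Q by more than this to be taken.
IMPROVEMENT_TOL = 1e-10


@dataclass
class PartitionEnsemble:
    """Partitions from independent Louvain restarts on one network."""

    partitions: list[Partition]
    qualities: np.ndarray
    seeds: list[int]
    gamma: float | np.ndarray
    omega: float

    def __post_init__(self) -> None:
        if len(self.partitions) < 1:
            raise ValidationError("an ensemble needs at least one partition")
        shapes = {p.labels.shape for p in self.partitions}
        if len(shapes) != 1:
            raise ValidationError("ensemble partitions disagree on shape")
        self.qualities = np.asarray(self.qualities, dtype=float)
        if self.qualities.shape != (len(self.partitions),):
            raise ValidationError("one quality required per partition")
        if len(self.seeds) != len(self.partitions):
            raise ValidationError("one seed required per partition")

    @property
    def n_runs(self) -> int:
        return len(self.partitions)

    @property
    def n_nodes(self) -> int:
        return self.partitions[0].n_nodes

    @property
    def n_slices(self) -> int:
        return self.partitions[0].n_slices

    def best(self) -> tuple[Partition, float]:
        i = int(np.argmax(self.qualities))
        return self.partitions[i], float(self.qualities[i])


def _one_level(B: np.ndarray, mu: float, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Phase 1: greedy node moves until no move improves Q by > tol.

    Returns compacted labels and whether any move was taken.  Ties are
    broken toward the lowest community index (argmax returns the first
    maximum, and label slots are indexed in ascending order); an empty
    slot has community weight 0, so breaking away into a singleton is a
    candidate move whenever staying is net-negative.
    """
    n = B.shape[0]
    labels = np.arange(n)
    improved = False
    while True:
        moved = 0
        for k in rng.permutation(n):
            cur = labels[k]
            w = np.bincount(labels, weights=B[k], minlength=n)
            w[cur] -= B[k, k]  # self-weight moves with the node; ignore it
            best = int(np.argmax(w))
            if best != cur and (w[best] - w[cur]) / mu > IMPROVEMENT_TOL:
                labels[k] = best
                moved += 1
        if moved == 0:
            break
        improved = True
    _, compact = np.unique(labels, return_inverse=True)
    return compact, improved


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Phase 2: collapse communities into super-nodes, summing weights."""
    n_comm = labels.max() + 1
    H = np.zeros((B.shape[0], n_comm))
    H[np.arange(B.shape[0]), labels] = 1.0
    return H.T @ B @ H


def _partition_weight(B: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        total += B[np.ix_(idx, idx)].sum()
    return total


def _generalized_louvain(B: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Full two-phase loop on a supra-modularity matrix; returns labels."""
    assign = np.arange(B.shape[0])
    Bcur = B
    prev_weight = _partition_weight(B, assign)
    while True:
        labels, improved = _one_level(Bcur, mu, rng)
        if not improved:
            break
        assign = labels[assign]
        Bcur = _aggregate(Bcur, labels)
        if __debug__:
            new_weight = np.trace(Bcur)  # intra-community total after collapse
            assert new_weight >= prev_weight - 1e-9 * max(1.0, abs(prev_weight)), (
                "quality decreased across a Louvain level"
            )
            prev_weight = new_weight
        if Bcur.shape[0] == 1:
            break
    return assign


def louvain_once(
    net: MultilayerNetwork,
    seed: int,
    _supra: tuple[np.ndarray, float] | None = None,
) -> tuple[Partition, float]:
    """One seeded Louvain restart; deterministic given the seed.

    Returns the canonicalized partition and its multislice modularity.
    ``_supra`` lets :func:`run_ensemble` share the precomputed supra
    matrix across restarts.
    """
    if net.n_nodes * net.n_slices < 1:
        raise ValidationError("network has no supra-nodes")
    B, mu = _supra if _supra is not None else supra_modularity_matrix(net)
    rng = np.random.default_rng(seed)
    assign = _generalized_louvain(B, mu, rng)
    N, T = net.n_nodes, net.n_slices
    labels = assign.reshape(T, N).T  # supra order is slice-major
    part = Partition(labels).canonical()
    return part, multislice_modularity(net, part)


def derive_run_seed(master_seed: int, run_index: int) -> int:
    """Per-run seed from a master seed via a splittable counter scheme."""
    ss = np.random.SeedSequence((int(master_seed), int(run_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def run_ensemble(
    net: MultilayerNetwork,
    n_runs: int = 100,
    seed: int = 0,
) -> PartitionEnsemble:
    """Independent Louvain restarts with per-run seeds derived from ``seed``.

    All partitions are retained — the allegiance matrix consumes the full
    ensemble, so no consensus collapse happens here.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    supra = supra_modularity_matrix(net)
    partitions: list[Partition] = []
    qualities: list[float] = []
    seeds: list[int] = []
    for r in range(n_runs):
        s = derive_run_seed(seed, r)
        part, q = louvain_once(net, s, _supra=supra)
        partitions.append(part)
        qualities.append(q)
        seeds.append(s)
    return PartitionEnsemble(
        partitions=partitions,
        qualities=np.asarray(qualities),
        seeds=seeds,
        gamma=net.gamma.copy(),
        omega=net.omega,
    )
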
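"""Synthetic multilayer networks, role scenarios, and block time series.

No public data ship with the method, so every downstream stage is
exercised on planted fixtures:

* :func:`generate_planted_multilayer` plants slice-wise communities that
  follow a node-to-system map up to i.i.d. label flips, with Gaussian
  edge weights split by community co-membership — a noisy, dynamic
  stochastic-block stand-in for a stack of per-condition connectivity
  matrices.
* :func:`generate_role_scenario` warps one designated system's
  generative rules so the downstream cartography should assign it a
  known role (stable loner, stable integrator, ephemeral loner, stable
  connector).
* :func:`generate_timeseries` draws per-condition multivariate-normal
  samples with a compound-symmetric block covariance, feeding the
  connectivity stage.

Flips are i.i.d. across nodes and slices (no temporal autocorrelation),
matching the categorical (orderless) coupling used downstream.  Sampled
negative weights are passed through; the multilayer sign policy decides
their fate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cartography import SystemMap
from .connectivity import ConditionTimeSeries
from .errors import ValidationError
from .multilayer import MultilayerNetwork, Partition

ROLE_SCENARIOS = (
    "stable_loner",
    "stable_integrator",
    "ephemeral_loner",
    "stable_connector",
)

#: Probability that an ephemeral-loner node scatters into its own
#: singleton community in a given slice.
EPHEMERAL_SINGLETON_PROB = 0.9

#: Number of partner systems a stable integrator merges with per slice.
INTEGRATOR_PARTNERS = 3



@dataclass
class PlantedScenario:
    """Parameters of a planted dynamic-community generative model."""

    system_map: SystemMap
    n_slices: int
    flip_prob: float = 0.0
    mu_in: float = 1.0
    mu_out: float = 0.0
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.system_map, SystemMap):
            raise ValidationError("system_map must be a SystemMap")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be a positive integer")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValidationError("flip_prob must lie in [0, 1]")
        if self.sigma < 0.0:
            raise ValidationError("sigma must be non-negative")
        if self.mu_in <= self.mu_out:
            warnings.warn(
                "mu_in <= mu_out: planted structure is not recoverable",
                stacklevel=2,
            )

    @property
    def n_nodes(self) -> int:
        return self.system_map.n_nodes

    @classmethod
    def uniform(
        cls,
        n_systems: int,
        nodes_per_system: int,
        n_slices: int,
        **kwargs,
    ) -> "PlantedScenario":
        """Equal-size systems named S01, S02, ... with nodes n000, n001, ..."""
        if n_systems < 1 or nodes_per_system < 1:
            raise ValidationError("system counts must be positive")
        node_ids = [
            f"n{i:03d}" for i in range(n_systems * nodes_per_system)
        ]
        assignment = [
            f"S{k + 1:02d}"
            for k in range(n_systems)
            for _ in range(nodes_per_system)
        ]
        return cls(SystemMap(node_ids, assignment), n_slices, **kwargs)


def _planted_labels(scenario: PlantedScenario, rng: np.random.Generator) -> np.ndarray:
    """(N, T) slice-wise community labels: system index, flipped i.i.d."""
    sys_idx = scenario.system_map.system_indices()
    K = len(scenario.system_map.systems)
    N, T = scenario.n_nodes, scenario.n_slices
    labels = np.tile(sys_idx[:, None], (1, T))
    if scenario.flip_prob > 0.0:
        if K < 2:
            raise ValidationError(
                "flips require at least two systems to reassign into"
            )
        flips = rng.random((N, T)) < scenario.flip_prob
        offsets = rng.integers(1, K, size=(N, T))
        labels = np.where(flips, (labels + offsets) % K, labels)
    return labels


def _weights_from_labels(
    labels: np.ndarray,
    mu_in: float,
    mu_out: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(T, N, N) Gaussian weights split by slice-community co-membership.

    Drawn dense, means selected by co-membership, then symmetrized by
    averaging (A + A.T)/2 with a forced zero diagonal — mirroring the
    structure of a noisy correlation matrix.
    """
    N, T = labels.shape
    out = np.empty((T, N, N))
    for t in range(T):
        same = labels[:, t][:, None] == labels[:, t][None, :]
        mean = np.where(same, mu_in, mu_out)
        W = mean + rng.normal(0.0, sigma, size=(N, N)) if sigma > 0 else mean.astype(float).copy()
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        out[t] = W
    return out


def generate_planted_multilayer(
    scenario: PlantedScenario,
    gamma: float = 1.0,
    omega: float = 0.45,
    sign_policy: str = "truncate_negative",
) -> tuple[MultilayerNetwork, Partition]:
    """Planted multilayer network plus its ground-truth partition.

    Per slice, each node keeps its system label with probability
    1 - flip_prob, otherwise it is reassigned uniformly to another
    system.  Edges within a slice community draw from
    Normal(mu_in, sigma), all others from Normal(mu_out, sigma).
    """
    rng = np.random.default_rng(scenario.seed)
    labels = _planted_labels(scenario, rng)
    slices = _weights_from_labels(
        labels, scenario.mu_in, scenario.mu_out, scenario.sigma, rng
    )
    net = MultilayerNetwork(
        slices=slices,
        node_ids=list(scenario.system_map.node_ids),
        gamma=gamma,
        omega=omega,
        sign_policy=sign_policy,
    )
    return net, Partition(labels)


def generate_role_scenario(
    role: str,
    base: PlantedScenario,
    designated: str | None = None,
    gamma: float = 1.0,
    omega: float = 0.45,
    sign_policy: str = "truncate_negative",
) -> tuple[MultilayerNetwork, SystemMap, str]:
    """Warp one system's generative rules to plant a known network role.

    * ``stable_loner`` — the designated block never flips and never
      merges: high recruitment, minimal integration.
    * ``stable_integrator`` — the block never flips, and in every slice
      it merges (shares a community, hence mu_in weights) with
      ``INTEGRATOR_PARTNERS`` randomly chosen other systems: high
      recruitment *and* high integration.
    * ``ephemeral_loner`` — each designated node scatters into its own
      globally-unique singleton label with probability
      ``EPHEMERAL_SINGLETON_PROB``, and the designated nodes are fully
      decoupled in weight space (every edge touching them is zero in
      every slice): low recruitment, low integration.  Leaving them a
      background weight of mu_out would instead let the low-strength
      nodes form a pocket community, or let an isolated coupling chain
      adopt an outsider community for free, under the degree-based
      null.
    * ``stable_connector`` — the block never flips and merges with one
      random partner system per slice: high recruitment, integration at
      the level typical of the network as a whole.

    In every scenario, outsider flips never target the designated system,
    so its membership stays fully rule-controlled.  Returns the network,
    the ground-truth system map, and the expected role label (e.g.
    ``"stable loner"``).
    """
    if role not in ROLE_SCENARIOS:
        raise ValidationError(
            f"unknown role scenario {role!r}; expected one of {ROLE_SCENARIOS}"
        )
    systems = base.system_map.systems
    if designated is None:
        designated = systems[0]
    if designated not in systems:
        raise ValidationError(
            f"designated system {designated!r} absent from the system map"
        )
    K = len(systems)
    if role == "stable_integrator" and K < INTEGRATOR_PARTNERS + 2:
        raise ValidationError(
            f"stable_integrator needs at least {INTEGRATOR_PARTNERS + 2} systems"
        )
    if K < 2:
        raise ValidationError("role scenarios need at least two systems")

    rng = np.random.default_rng(base.seed)
    sys_idx = base.system_map.system_indices()
    d = systems.index(designated)
    members = sys_idx == d
    N, T = base.n_nodes, base.n_slices

    # Outsider labels: base flip rule, but flips never land on system d.
    labels = np.tile(sys_idx[:, None], (1, T))
    others = np.array([k for k in range(K) if k != d])
    if base.flip_prob > 0.0:
        if K < 3:
            raise ValidationError(
                "outsider flips need a third system to reassign into"
            )
        flips = (rng.random((N, T)) < base.flip_prob) & ~members[:, None]
        for t in range(T):
            for i in np.flatnonzero(flips[:, t]):
                choices = [k for k in others if k != labels[i, t]]
                labels[i, t] = rng.choice(choices)

    if role == "stable_loner":
        labels[members] = d
    elif role == "stable_integrator":
        labels[members] = d
        for t in range(T):
            partners = rng.choice(others, size=INTEGRATOR_PARTNERS, replace=False)
            merged = np.isin(labels[:, t], np.append(partners, d))
            labels[merged, t] = d
    elif role == "stable_connector":
        labels[members] = d
        for t in range(T):
            partner = rng.choice(others)
            labels[labels[:, t] == partner, t] = d
    scatter = None
    if role == "ephemeral_loner":
        labels[members] = d
        scatter = (rng.random((N, T)) < EPHEMERAL_SINGLETON_PROB) & members[:, None]
        singleton_ids = K + np.arange(N * T).reshape(N, T)
        labels = np.where(scatter, singleton_ids, labels)

    slices = _weights_from_labels(labels, base.mu_in, base.mu_out, base.sigma, rng)
    if scatter is not None:
        member_idx = np.flatnonzero(members)
        for t in range(T):
            slices[t][member_idx, :] = 0.0
            slices[t][:, member_idx] = 0.0
    net = MultilayerNetwork(
        slices=slices,
        node_ids=list(base.system_map.node_ids),
        gamma=gamma,
        omega=omega,
        sign_policy=sign_policy,
    )
    expected = role.replace("_", " ")
    return net, base.system_map, expected


def generate_timeseries(
    system_map: SystemMap,
    n_conditions: int,
    samples_per_condition: int,
    rho_in: float,
    rho_out: float,
    seed: int = 0,
) -> ConditionTimeSeries:
    """Per-condition multivariate-normal samples with block covariance.

    The covariance has 1 on the diagonal, ``rho_in`` within systems, and
    ``rho_out`` between systems.  With 0 <= rho_out <= rho_in < 1 this
    compound-symmetric structure is positive semi-definite; if a
    numerical eigenvalue check fails anyway, rho_in is shrunk toward
    rho_out until it passes (error after repeated shrinkage).
    """
    if n_conditions < 1 or samples_per_condition < 1:
        raise ValidationError("condition counts must be positive")
    if not (0.0 <= rho_out <= rho_in < 1.0):
        raise ValidationError("need 0 <= rho_out <= rho_in < 1")
    idx = system_map.system_indices()
    same = idx[:, None] == idx[None, :]
    rng = np.random.default_rng(seed)
    N = system_map.n_nodes
    for _ in range(50):
        C = np.where(same, rho_in, rho_out)
        np.fill_diagonal(C, 1.0)
        min_eig = np.linalg.eigvalsh(C).min()
        if min_eig > -1e-10:
            break
        warnings.warn(
            f"block covariance not PSD (min eigenvalue {min_eig:.3g}); "
            "shrinking rho_in",
            stacklevel=2,
        )
        rho_in = rho_out + 0.9 * (rho_in - rho_out)
    else:
        raise ValidationError("block covariance not PSD after shrinkage")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(N))
    blocks = []
    labels = []
    for c in range(n_conditions):
        Z = rng.standard_normal((samples_per_condition, N))
        blocks.append(Z @ L.T)
        labels.extend([f"cond{c:03d}"] * samples_per_condition)
    return ConditionTimeSeries(
        np.vstack(blocks), labels, list(system_map.node_ids)
    )
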
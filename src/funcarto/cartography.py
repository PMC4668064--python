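"""Module allegiance, flexibility, recruitment/integration, and roles.

An ensemble of multislice partitions is summarized by the module
allegiance matrix ``P``, whose entry ``P_ij`` is the fraction of
(optimization, slice) pairs in which nodes ``i`` and ``j`` share a
community.  Against a fixed node-to-system map, allegiance yields

* recruitment of region i to its system S:  R_i = (1/n_S) sum_{j in S} P_ij
* integration of region i:                  I_i = (1/(N-n_S)) sum_{j not in S} P_ij
* system recruitment:     R_S   = (1/n_S^2) sum_{i,j in S} P_ij
* pairwise integration:   I_kl  = (1/(n_k n_l)) sum_{i in S_k, j in S_l} P_ij
* system integration:     I_S   = (1/(n_S (N-n_S))) sum_{i in S, j not in S} P_ij

The literal summation ranges include the self term ``P_ii = 1``; pass
``exclude_self=True`` for the diagonal-free variant.

Significance is calibrated by a permutation null that reassigns nodes to
systems uniformly at random while preserving the number and sizes of
systems.  Comparing each coefficient with the null's [2.5, 97.5]
percentile band classifies every system on a 3x3 grid of roles:
{ephemeral, unstable, stable} (recruitment) x {loner, connector,
integrator} (integration) — e.g. "stable loner".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .louvain import PartitionEnsemble
from .multilayer import Partition

RECRUITMENT_CLASSES = ("ephemeral", "unstable", "stable")
INTEGRATION_CLASSES = ("loner", "connector", "integrator")

#: Percentile band corresponding to the 95% confidence interval.
CI_PERCENTILES = (2.5, 97.5)


@dataclass
class SystemMap:
    """Assignment of each node to exactly one named system."""

    node_ids: Sequence[str]
    assignment: Sequence[str]

    def __post_init__(self) -> None:
        self.node_ids = [str(n) for n in self.node_ids]
        self.assignment = [str(s) for s in self.assignment]
        if len(self.node_ids) != len(self.assignment):
            raise ValidationError("one system label required per node")
        if len(set(self.node_ids)) != len(self.node_ids):
            dupes = sorted(
                {n for n in self.node_ids if self.node_ids.count(n) > 1}
            )
            raise ValidationError(f"duplicate node ids: {', '.join(dupes)}")
        if not self.node_ids:
            raise ValidationError("system map is empty")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def systems(self) -> list[str]:
        """System labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.assignment:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def sizes(self) -> dict[str, int]:
        out = {s: 0 for s in self.systems}
        for s in self.assignment:
            out[s] += 1
        return out

    def indicator(self) -> np.ndarray:
        """(N, K) one-hot membership matrix in `systems` order."""
        systems = self.systems
        index = {s: k for k, s in enumerate(systems)}
        M = np.zeros((self.n_nodes, len(systems)))
        for i, s in enumerate(self.assignment):
            M[i, index[s]] = 1.0
        return M

    def system_indices(self) -> np.ndarray:
        index = {s: k for k, s in enumerate(self.systems)}
        return np.array([index[s] for s in self.assignment])

    def reordered(self, node_ids: Sequence[str]) -> "SystemMap":
        """Align to an authoritative node order; error on missing nodes."""
        lookup = dict(zip(self.node_ids, self.assignment))
        missing = [n for n in node_ids if str(n) not in lookup]
        if missing:
            raise ValidationError(
                f"nodes absent from system map: {', '.join(map(str, missing))}"
            )
        extra = set(self.node_ids) - {str(n) for n in node_ids}
        if extra:
            raise ValidationError(
                f"system map nodes absent from matrices: {', '.join(sorted(extra))}"
            )
        return SystemMap(list(node_ids), [lookup[str(n)] for n in node_ids])


@dataclass
class AllegianceMatrix:
    """Node-by-node co-assignment probabilities over an ensemble."""

    P: np.ndarray
    n_optimizations: int
    n_slices: int
    node_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValidationError("allegiance matrix must be square")
        if np.abs(P - P.T).max(initial=0.0) > 1e-12:
            raise ValidationError("allegiance matrix must be symmetric")
        if P.size and (P.min() < -1e-12 or P.max() > 1.0 + 1e-12):
            raise ValidationError("allegiance entries must lie in [0, 1]")
        if P.size and np.abs(np.diag(P) - 1.0).max() > 1e-12:
            raise ValidationError("allegiance diagonal must be exactly 1")
        self.P = P
        if not self.node_ids:
            self.node_ids = [f"n{i:03d}" for i in range(P.shape[0])]
        self.node_ids = list(self.node_ids)
        if len(self.node_ids) != P.shape[0]:
            raise ValidationError("node_ids length does not match matrix")

    @property
    def n_nodes(self) -> int:
        return self.P.shape[0]


@dataclass
class FlexibilityVector:
    """Per-node fraction of consecutive slice transitions that change label."""

    f: np.ndarray
    node_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.ndim != 1:
            raise ValidationError("flexibility must be a vector")
        if f.size and (f.min() < -1e-12 or f.max() > 1.0 + 1e-12):
            raise ValidationError("flexibility entries must lie in [0, 1]")
        self.f = f
        if not self.node_ids:
            self.node_ids = [f"n{i:03d}" for i in range(f.size)]
        self.node_ids = list(self.node_ids)

    @property
    def network_mean(self) -> float:
        return float(self.f.mean())


@dataclass
class NullDistributions:
    """Per-system permutation-null samples of R_S and I_S (and pairs)."""

    systems: list[str]
    recruitment: np.ndarray  # (n_perm, K)
    integration: np.ndarray  # (n_perm, K)
    pairwise: np.ndarray | None = None  # (n_perm, K, K)

    @property
    def n_perm(self) -> int:
        return self.recruitment.shape[0]

    def ci(self, which: str = "recruitment") -> pd.DataFrame:
        samples = getattr(self, which)
        lo, hi = np.percentile(samples, CI_PERCENTILES, axis=0)
        return pd.DataFrame(
            {"lo": lo, "hi": hi, "mean": samples.mean(axis=0)},
            index=pd.Index(self.systems, name="system"),
        )


@dataclass
class CartographyResult:
    """Everything the role analysis produces for one ensemble."""

    allegiance: AllegianceMatrix
    system_map: SystemMap
    region_recruitment: pd.Series
    region_integration: pd.Series
    system_recruitment: pd.Series
    system_integration: pd.Series
    pairwise_integration: pd.DataFrame
    null: NullDistributions
    roles: pd.DataFrame
    edge_flags: pd.DataFrame

    def to_dict(self) -> dict:
        """JSON-serializable summary (roles, coefficients, CIs, flags)."""
        rci = self.null.ci("recruitment")
        ici = self.null.ci("integration")
        return {
            "systems": {
                s: {
                    "recruitment": float(self.system_recruitment[s]),
                    "integration": float(self.system_integration[s]),
                    "recruitment_null_ci": [float(rci.loc[s, "lo"]), float(rci.loc[s, "hi"])],
                    "integration_null_ci": [float(ici.loc[s, "lo"]), float(ici.loc[s, "hi"])],
                    "role": str(self.roles.loc[s, "role"]),
                }
                for s in self.system_map.systems
            },
            "edge_flags": {
                f"{a}|{b}": str(self.edge_flags.loc[a, b])
                for i, a in enumerate(self.system_map.systems)
                for b in self.system_map.systems[i + 1:]
            },
            "n_permutations": int(self.null.n_perm),
            "n_optimizations": int(self.allegiance.n_optimizations),
            "n_slices": int(self.allegiance.n_slices),
        }


def module_allegiance(ensemble: PartitionEnsemble, node_ids=None) -> AllegianceMatrix:
    """P_ij = fraction of (run, slice) pairs where i and j share a community."""
    if ensemble.n_runs < 1:
        raise ValidationError("empty ensemble")
    N = ensemble.n_nodes
    T = ensemble.n_slices
    count = np.zeros((N, N))
    for part in ensemble.partitions:
        for t in range(T):
            lab = part.labels[:, t]
            count += lab[:, None] == lab[None, :]
    P = count / (ensemble.n_runs * T)
    np.fill_diagonal(P, 1.0)
    return AllegianceMatrix(
        P, n_optimizations=ensemble.n_runs, n_slices=T,
        node_ids=node_ids or [],
    )


def flexibility(partition: Partition, node_ids=None) -> FlexibilityVector:
    """f_i = (# consecutive slice transitions where the label changes) / (T-1)."""
    if partition.n_slices < 2:
        raise ValidationError("flexibility needs at least two slices")
    changes = partition.labels[:, 1:] != partition.labels[:, :-1]
    return FlexibilityVector(changes.mean(axis=1), node_ids or [])


def ensemble_flexibility(ensemble: PartitionEnsemble, node_ids=None) -> FlexibilityVector:
    """Per-node flexibility averaged over every partition in the ensemble."""
    stack = np.stack([flexibility(p).f for p in ensemble.partitions])
    return FlexibilityVector(stack.mean(axis=0), node_ids or [])


def _validate_systems(P: AllegianceMatrix, systems: SystemMap) -> None:
    if systems.n_nodes != P.n_nodes:
        raise ValidationError(
            f"system map covers {systems.n_nodes} nodes; allegiance has {P.n_nodes}"
        )
    sizes = systems.sizes
    if any(n == 0 for n in sizes.values()):
        raise ValidationError("empty system in system map")
    if len(sizes) < 2:
        raise ValidationError(
            "integration is undefined when one system spans the whole network"
        )


def region_coefficients(
    P: AllegianceMatrix,
    systems: SystemMap,
    exclude_self: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """Per-node recruitment and integration with respect to its own system."""
    _validate_systems(P, systems)
    idx = systems.system_indices()
    sizes = np.array([systems.sizes[s] for s in systems.systems])
    N = P.n_nodes
    R = np.empty(N)
    I = np.empty(N)
    for i in range(N):
        members = idx == idx[i]
        n_S = sizes[idx[i]]
        if exclude_self:
            if n_S < 2:
                raise ValidationError(
                    "exclude_self recruitment undefined for singleton systems"
                )
            R[i] = (P.P[i, members].sum() - 1.0) / (n_S - 1)
        else:
            R[i] = P.P[i, members].sum() / n_S
        I[i] = P.P[i, ~members].sum() / (N - n_S)
    index = pd.Index(P.node_ids, name="node")
    return pd.Series(R, index=index, name="recruitment"), pd.Series(
        I, index=index, name="integration"
    )


def _system_blocks(P: np.ndarray, M: np.ndarray) -> np.ndarray:
    """(K, K) sums of P over system-by-system blocks given one-hot M."""
    return M.T @ P @ M


def _coeffs_from_blocks(
    block: np.ndarray, sizes: np.ndarray, N: int, exclude_self: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """R_S, pairwise I, I_S from block sums (diagonal of P assumed 1)."""
    diag = np.diag(block)
    if exclude_self:
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (diag - sizes) / (sizes * (sizes - 1.0))
    else:
        R = diag / sizes**2
    pair = block / np.outer(sizes, sizes)
    off = block.sum(axis=1) - diag
    I = off / (sizes * (N - sizes))
    return R, pair, I


def system_coefficients(
    P: AllegianceMatrix,
    systems: SystemMap,
    exclude_self: bool = False,
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """System recruitment R_S, pairwise integration I_kl, and overall I_S.

    The diagonal of the pairwise matrix is set to NaN: a system's
    self-entry is its recruitment, reported separately.
    """
    _validate_systems(P, systems)
    names = systems.systems
    sizes = np.array([systems.sizes[s] for s in names], dtype=float)
    block = _system_blocks(P.P, systems.indicator())
    R, pair, I = _coeffs_from_blocks(block, sizes, P.n_nodes, exclude_self)
    np.fill_diagonal(pair, np.nan)
    sidx = pd.Index(names, name="system")
    return (
        pd.Series(R, index=sidx, name="recruitment"),
        pd.DataFrame(pair, index=sidx, columns=sidx),
        pd.Series(I, index=sidx, name="integration"),
    )


def permutation_null(
    P: AllegianceMatrix,
    systems: SystemMap,
    n_perm: int = 1000,
    seed: int | None = None,
    exclude_self: bool = False,
    pairwise: bool = True,
) -> NullDistributions:
    """Null distributions of R_S and I_S under random node-to-system maps.

    Each replicate permutes the node->system assignment uniformly at
    random, preserving the number of systems and every system's size, and
    recomputes the coefficients.
    """
    _validate_systems(P, systems)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is small for stable percentile CIs (< 100)",
            stacklevel=2,
        )
    names = systems.systems
    sizes = np.array([systems.sizes[s] for s in names], dtype=float)
    M = systems.indicator()
    rng = np.random.default_rng(seed)
    K = len(names)
    Rs = np.empty((n_perm, K))
    Is = np.empty((n_perm, K))
    pairs = np.empty((n_perm, K, K)) if pairwise else None
    for b in range(n_perm):
        Mp = M[rng.permutation(P.n_nodes)]
        block = _system_blocks(P.P, Mp)
        R, pairmat, I = _coeffs_from_blocks(block, sizes, P.n_nodes, exclude_self)
        Rs[b] = R
        Is[b] = I
        if pairs is not None:
            pairs[b] = pairmat
    return NullDistributions(names, Rs, Is, pairs)


def _band_class(value: float, lo: float, hi: float, classes: tuple[str, str, str]) -> str:
    if value < lo:
        return classes[0]
    if value > hi:
        return classes[2]
    return classes[1]


def classify_roles(
    system_recruitment: pd.Series,
    system_integration: pd.Series,
    null: NullDistributions,
) -> pd.DataFrame:
    """Assign each system a role from the 3x3 recruitment x integration grid."""
    rci = null.ci("recruitment")
    ici = null.ci("integration")
    rows = []
    for s in null.systems:
        rcls = _band_class(
            float(system_recruitment[s]), rci.loc[s, "lo"], rci.loc[s, "hi"],
            RECRUITMENT_CLASSES,
        )
        icls = _band_class(
            float(system_integration[s]), ici.loc[s, "lo"], ici.loc[s, "hi"],
            INTEGRATION_CLASSES,
        )
        rows.append(
            {
                "system": s,
                "recruitment": float(system_recruitment[s]),
                "integration": float(system_integration[s]),
                "recruitment_class": rcls,
                "integration_class": icls,
                "role": f"{rcls} {icls}",
            }
        )
    return pd.DataFrame(rows).set_index("system")


def flag_integration_edges(
    pairwise_integration: pd.DataFrame,
    null: NullDistributions,
) -> pd.DataFrame:
    """Flag each system pair stronger/weaker/ns against the mean edge weight.

    The statistic is each pair's integration minus the mean over all
    off-diagonal pairs; a pair is "stronger" ("weaker") when the observed
    statistic falls above (below) the null's [2.5, 97.5] percentile band
    of the same statistic, at alpha = 0.05.
    """
    if null.pairwise is None:
        raise ValidationError("null was computed without pairwise samples")
    names = list(pairwise_integration.index)
    K = len(names)
    obs = pairwise_integration.to_numpy()
    off = ~np.eye(K, dtype=bool)
    d_obs = obs - obs[off].mean()
    null_pairs = null.pairwise
    null_means = null_pairs[:, off].mean(axis=1)
    d_null = null_pairs - null_means[:, None, None]
    lo, hi = np.percentile(d_null, CI_PERCENTILES, axis=0)
    flags = np.full((K, K), "ns", dtype=object)
    for i in range(K):
        for j in range(K):
            if i == j:
                flags[i, j] = ""
                continue
            if d_obs[i, j] > hi[i, j]:
                flags[i, j] = "stronger"
            elif d_obs[i, j] < lo[i, j]:
                flags[i, j] = "weaker"
    sidx = pd.Index(names, name="system")
    return pd.DataFrame(flags, index=sidx, columns=sidx)


def functional_cartography(
    ensemble: PartitionEnsemble,
    systems: SystemMap,
    n_perm: int = 1000,
    seed: int | None = None,
    exclude_self: bool = False,
) -> CartographyResult:
    """Full role analysis: allegiance -> coefficients -> null -> roles."""
    P = module_allegiance(ensemble, node_ids=list(systems.node_ids))
    Rreg, Ireg = region_coefficients(P, systems, exclude_self=exclude_self)
    Rsys, pair, Isys = system_coefficients(P, systems, exclude_self=exclude_self)
    null = permutation_null(
        P, systems, n_perm=n_perm, seed=seed, exclude_self=exclude_self,
        pairwise=True,
    )
    roles = classify_roles(Rsys, Isys, null)
    flags = flag_integration_edges(pair, null)
    return CartographyResult(
        allegiance=P,
        system_map=systems,
        region_recruitment=Rreg,
        region_integration=Ireg,
        system_recruitment=Rsys,
        system_integration=Isys,
        pairwise_integration=pair,
        null=null,
        roles=roles,
        edge_flags=flags,
    )
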
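"""Grid search over (gamma, omega) and flexibility-variability selection.

The resolution gamma controls community size within a slice; the coupling
omega controls label persistence across slices.  The operating point is
chosen to maximize the standard deviation of node flexibility — the point
where nodes are maximally spread between highly stable and highly
flexible — with partition-similarity diagnostics (z-Rand across restarts
and across slices) as documented tie-breakers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cartography import ensemble_flexibility
from .errors import ValidationError
from .louvain import run_ensemble
from .multilayer import MultilayerNetwork

#: Grid points whose flex_std is within this relative tolerance of the
#: maximum are candidates for the secondary selection criteria.
TIE_TOLERANCE = 0.01


@dataclass(frozen=True)
class GridResult:
    """Summary statistics of one (gamma, omega) grid point."""

    gamma: float
    omega: float
    flex_mean: float
    flex_std: float
    sim_across_runs: float
    sim_across_slices: float
    n_communities: float
    quality: float


def _pair_counts(labels1: np.ndarray, labels2: np.ndarray) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    a, ai = np.unique(labels1, return_inverse=True)
    b, bi = np.unique(labels2, return_inverse=True)
    cont = np.zeros((a.size, b.size))
    np.add.at(cont, (ai, bi), 1.0)
    rows = cont.sum(axis=1)
    cols = cont.sum(axis=0)
    w = (cont * (cont - 1.0) / 2.0).sum()
    M1 = (rows * (rows - 1.0) / 2.0).sum()
    M2 = (cols * (cols - 1.0) / 2.0).sum()
    return w, M1, M2, rows, cols


def zrand_similarity(labels1, labels2) -> float:
    """z-score of the Rand coefficient under the pair-counting null.

    Pairs of items are classified as co-grouped or not in each partition;
    the number of pairs co-grouped in both is compared with its
    expectation and variance under random pairings that preserve both
    partitions' group sizes (hypergeometric null).  Larger is more
    similar; independent partitions score around 0.  A degenerate
    comparison with zero null variance (e.g. all-singletons vs
    all-singletons) is reported as 0 with a warning.
    """
    l1 = np.asarray(labels1).ravel()
    l2 = np.asarray(labels2).ravel()
    if l1.shape != l2.shape:
        raise ValidationError("partitions must cover the same node set")
    n = float(l1.size)
    if n < 2:
        raise ValidationError("need at least two nodes to compare partitions")
    M = n * (n - 1.0) / 2.0
    w, M1, M2, rows, cols = _pair_counts(l1, l2)
    C1 = n * (n**2 - 3.0 * n - 2.0) - 8.0 * (n + 1.0) * M1 + 4.0 * (rows**3).sum()
    C2 = n * (n**2 - 3.0 * n - 2.0) - 8.0 * (n + 1.0) * M2 + 4.0 * (cols**3).sum()
    a = 4.0 * M1 - 2.0 * M
    b = 4.0 * M2 - 2.0 * M
    var = (
        M / 16.0
        - (a**2) * (b**2) / (256.0 * M**2)
        + C1 * C2 / (16.0 * n * (n - 1.0) * (n - 2.0))
        + (a**2 - 4.0 * C1 - 4.0 * M)
        * (b**2 - 4.0 * C2 - 4.0 * M)
        / (64.0 * n * (n - 1.0) * (n - 2.0) * (n - 3.0))
    )
    if var <= 0.0:
        warnings.warn(
            "degenerate partition comparison (zero null variance); "
            "similarity reported as 0",
            stacklevel=2,
        )
        return 0.0
    return float((w - M1 * M2 / M) / np.sqrt(var))


def _similarity_stats(ensemble) -> tuple[float, float]:
    """(mean z-Rand across restarts, mean z-Rand across slices)."""
    parts = ensemble.partitions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        across_runs = [
            zrand_similarity(p.labels.ravel(), q.labels.ravel())
            for p, q in itertools.combinations(parts, 2)
        ]
        across_slices = []
        for p in parts:
            T = p.n_slices
            across_slices.extend(
                zrand_similarity(p.labels[:, s], p.labels[:, r])
                for s, r in itertools.combinations(range(T), 2)
            )
    runs = float(np.mean(across_runs)) if across_runs else np.nan
    slices = float(np.mean(across_slices)) if across_slices else np.nan
    return runs, slices


def grid_search(
    net: MultilayerNetwork,
    gamma_grid: Sequence[float],
    omega_grid: Sequence[float],
    n_runs: int = 20,
    seed: int = 0,
) -> list[GridResult]:
    """Run an ensemble at every (gamma, omega) point and record statistics.

    Deterministic given the seed: every grid point uses the same master
    seed, so restarts are paired across points.
    """
    if len(gamma_grid) == 0 or len(omega_grid) == 0:
        raise ValidationError("gamma and omega grids must be non-empty")
    results: list[GridResult] = []
    for gamma in gamma_grid:
        for omega in omega_grid:
            ens = run_ensemble(net.with_params(gamma=gamma, omega=omega),
                               n_runs=n_runs, seed=seed)
            flex = ensemble_flexibility(ens)
            sim_runs, sim_slices = _similarity_stats(ens)
            results.append(
                GridResult(
                    gamma=float(gamma),
                    omega=float(omega),
                    flex_mean=float(flex.f.mean()),
                    flex_std=float(flex.f.std()),
                    sim_across_runs=sim_runs,
                    sim_across_slices=sim_slices,
                    n_communities=float(
                        np.mean([p.n_communities for p in ens.partitions])
                    ),
                    quality=float(ens.qualities.mean()),
                )
            )
    return results


def results_frame(results: Sequence[GridResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def select_parameters(
    results: Sequence[GridResult],
    tie_tolerance: float = TIE_TOLERANCE,
) -> tuple[float, float]:
    """Pick the grid point with maximal flexibility variability.

    Points within ``tie_tolerance`` (relative) of the maximal flex_std are
    tie-candidates; among them the point with the highest similarity
    across restarts wins, then the lowest similarity across slices, then
    the lexicographically smallest (gamma, omega) — so the selection does
    not depend on input ordering.
    """
    if not results:
        raise ValidationError("no grid results to select from")
    best_std = max(r.flex_std for r in results)
    cutoff = best_std * (1.0 - tie_tolerance)
    candidates = [r for r in results if r.flex_std >= cutoff]

    def key(r: GridResult):
        sim_runs = r.sim_across_runs if np.isfinite(r.sim_across_runs) else -np.inf
        sim_slices = r.sim_across_slices if np.isfinite(r.sim_across_slices) else np.inf
        return (-sim_runs, sim_slices, r.gamma, r.omega)

    winner = min(candidates, key=key)
    return winner.gamma, winner.omega
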
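"""From multi-condition time series to stacks of connectivity matrices.

The pipeline stage implemented here mirrors standard task-state
functional-connectivity estimation: optionally regress a design matrix
out of every node's signal (so stimulus-locked activation does not
masquerade as connectivity), compute one Pearson correlation matrix per
condition, and Fisher-z transform the coefficients.  Resting-style
recordings with a single condition label can be chopped into fixed-width
windows first so that each window becomes its own pseudo-condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .multilayer import MultilayerNetwork

#: |r| is clipped to this before atanh so z stays finite.
FISHER_CLIP = 1.0 - 1e-7

#: Minimum samples per condition for a meaningful correlation.
MIN_SAMPLES_PER_CONDITION = 3


@dataclass
class ConditionTimeSeries:
    """Node signals with a condition label per timepoint.

    ``samples`` is (timepoints x nodes); ``condition_labels`` assigns each
    timepoint to a condition; input order is preserved and defines the
    slice order of every downstream stack.
    """

    samples: np.ndarray
    condition_labels: Sequence[str]
    node_ids: Sequence[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.samples, dtype=float)
        if X.ndim != 2:
            raise ValidationError(f"samples must be 2-D; got shape {X.shape}")
        if np.isnan(X).any():
            raise ValidationError("time series contain missing values (NaN)")
        labels = np.asarray(self.condition_labels, dtype=object)
        if labels.shape != (X.shape[0],):
            raise ValidationError(
                f"{labels.shape[0] if labels.ndim else 0} condition labels for "
                f"{X.shape[0]} timepoints"
            )
        uniq, counts = np.unique(labels.astype(str), return_counts=True)
        if counts.size and counts.min() < MIN_SAMPLES_PER_CONDITION:
            bad = uniq[counts < MIN_SAMPLES_PER_CONDITION]
            raise ValidationError(
                f"conditions with fewer than {MIN_SAMPLES_PER_CONDITION} "
                f"timepoints: {', '.join(map(str, bad))}"
            )
        self.samples = X
        self.condition_labels = labels
        self.node_ids = list(self.node_ids)
        if len(self.node_ids) != X.shape[1]:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for {X.shape[1]} signal columns"
            )

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.samples.shape[1]

    def conditions(self) -> list[str]:
        """Distinct condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.condition_labels:
            seen.setdefault(str(lab), None)
        return list(seen)


@dataclass
class DesignMatrix:
    """Task regressors to residualize out before correlation."""

    columns: np.ndarray
    column_names: Sequence[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.columns, dtype=float)
        if X.ndim != 2:
            raise ValidationError("design matrix must be 2-D")
        if np.isnan(X).any():
            raise ValidationError("design matrix contains NaN entries")
        if X.shape[1] and np.any(np.all(X == 0.0, axis=0)):
            raise ValidationError("design matrix has an all-zero column")
        self.columns = X
        self.column_names = list(self.column_names)
        if len(self.column_names) != X.shape[1]:
            raise ValidationError("column_names length does not match columns")


@dataclass
class ConnectivityStack:
    """Ordered per-condition connectivity matrices over one node set."""

    matrices: np.ndarray  # (K, N, N)
    condition_ids: Sequence[str]
    node_ids: Sequence[str]
    transform: str = "raw_r"  # {"raw_r", "fisher_z"}

    def __post_init__(self) -> None:
        M = np.asarray(self.matrices, dtype=float)
        if M.ndim != 3 or M.shape[1] != M.shape[2]:
            raise ValidationError(f"matrices must be (K, N, N); got {M.shape}")
        if np.isnan(M).any():
            raise ValidationError("connectivity matrices contain NaN entries")
        if np.abs(M - M.transpose(0, 2, 1)).max(initial=0.0) > 1e-10:
            raise ValidationError("connectivity matrices are not symmetric")
        if self.transform not in ("raw_r", "fisher_z"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.transform == "raw_r" and M.size and (
            M.min() < -1.0 - 1e-12 or M.max() > 1.0 + 1e-12
        ):
            raise ValidationError("raw correlation entries outside [-1, 1]")
        self.matrices = M
        self.condition_ids = list(self.condition_ids)
        self.node_ids = list(self.node_ids)
        if len(self.condition_ids) != M.shape[0]:
            raise ValidationError("one condition id required per matrix")
        if len(self.node_ids) != M.shape[1]:
            raise ValidationError("node_ids length does not match matrices")

    @property
    def n_conditions(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    def to_multilayer(
        self,
        gamma: float = 1.0,
        omega: float = 0.45,
        sign_policy: str = "truncate_negative",
    ) -> MultilayerNetwork:
        """View the stack as a multilayer network (slices in stack order)."""
        return MultilayerNetwork(
            slices=self.matrices.copy(),
            node_ids=list(self.node_ids),
            gamma=gamma,
            omega=omega,
            sign_policy=sign_policy,
        )


def residualize(ts: ConditionTimeSeries, design: DesignMatrix) -> ConditionTimeSeries:
    """Ordinary-least-squares residuals of every node against the design.

    An intercept column is always included, so residualizing against an
    empty design is plain mean-centering.  A rank-deficient design falls
    back to the minimum-norm (pseudo-inverse) solution with a warning;
    the residuals are unaffected by which solution is picked.
    """
    if design.columns.shape[0] != ts.n_timepoints:
        raise ValidationError(
            f"design has {design.columns.shape[0]} rows for "
            f"{ts.n_timepoints} timepoints"
        )
    X = np.column_stack([np.ones(ts.n_timepoints), design.columns])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "design matrix is rank-deficient; using pseudo-inverse solution",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, ts.samples, rcond=None)
    resid = ts.samples - X @ beta
    return ConditionTimeSeries(resid, ts.condition_labels, ts.node_ids)


def condition_correlation(ts: ConditionTimeSeries) -> ConnectivityStack:
    """One Pearson correlation matrix per condition, in first-appearance order.

    A node whose signal has zero variance within a condition yields zero
    correlations to every other node (with a warning) instead of NaNs,
    keeping the stack well-formed; its raw diagonal stays at 1.
    """
    labels = np.asarray([str(x) for x in ts.condition_labels])
    conditions = ts.conditions()
    mats = np.empty((len(conditions), ts.n_nodes, ts.n_nodes))
    for k, cond in enumerate(conditions):
        sub = ts.samples[labels == cond]
        sd = sub.std(axis=0)
        dead = np.flatnonzero(sd == 0.0)
        if dead.size:
            warnings.warn(
                f"condition {cond!r}: zero-variance node(s) "
                f"{[ts.node_ids[i] for i in dead]}; correlations set to 0",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(sub.T)
        C = np.atleast_2d(C)
        C[dead, :] = 0.0
        C[:, dead] = 0.0
        np.fill_diagonal(C, 1.0)
        C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
        mats[k] = C
    return ConnectivityStack(mats, conditions, ts.node_ids, transform="raw_r")


def fisher_z(stack: ConnectivityStack) -> ConnectivityStack:
    """Entrywise atanh of a raw-r stack, with |r| clipped to 1 - 1e-7.

    The diagonal is set to 0 after the transform: self-correlations carry
    no information and a +inf diagonal would poison the modularity null.
    """
    if stack.transform != "raw_r":
        raise ValidationError("fisher_z expects a raw_r stack")
    Z = np.arctanh(np.clip(stack.matrices, -FISHER_CLIP, FISHER_CLIP))
    for k in range(Z.shape[0]):
        np.fill_diagonal(Z[k], 0.0)
    return ConnectivityStack(
        Z, list(stack.condition_ids), list(stack.node_ids), transform="fisher_z"
    )


def window_rest(ts: ConditionTimeSeries, window_len: int = 11) -> ConditionTimeSeries:
    """Relabel timepoints into consecutive non-overlapping windows.

    Trailing timepoints that do not fill a window are dropped, so 300
    timepoints at the default window of 11 yield 27 windows (3 dropped).
    Original condition labels are discarded; the windows become the new
    conditions (``win000``, ``win001``, ...).
    """
    if window_len < 1:
        raise ValidationError("window_len must be a positive integer")
    n = ts.n_timepoints
    if n < window_len:
        raise ValidationError(
            f"{n} timepoints are fewer than one window of {window_len}"
        )
    n_win = n // window_len
    kept = n_win * window_len
    labels = [f"win{w:03d}" for w in range(n_win) for _ in range(window_len)]
    return ConditionTimeSeries(ts.samples[:kept], labels, ts.node_ids)
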
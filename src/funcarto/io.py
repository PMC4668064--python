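"""Delimited-text readers/writers and run manifests.

All matrices and tables are plain delimited text (TSV by default, CSV
accepted); structured results and manifests are JSON.  Floats are
written with 17 significant digits so every writer/reader pair
round-trips bit-exactly.  The node order in a matrix header is
authoritative: every other file (system maps, partitions) is aligned to
it on read.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cartography import SystemMap
from .connectivity import ConditionTimeSeries, ConnectivityStack, DesignMatrix
from .errors import ValidationError
from .louvain import PartitionEnsemble
from .multilayer import MultilayerNetwork, Partition

FLOAT_FMT = "%.17g"

#: Default tolerated asymmetry when reading a matrix file.
DEFAULT_SYMMETRY_TOL = 1e-8


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# square matrices

def write_matrix(path, M: np.ndarray, node_ids: Sequence[str]) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("node" + sep + sep.join(map(str, node_ids)) + "\n")
        for i, nid in enumerate(node_ids):
            row = sep.join(FLOAT_FMT % v for v in M[i])
            fh.write(f"{nid}{sep}{row}\n")


def read_matrix(
    path, symmetry_tol: float = DEFAULT_SYMMETRY_TOL
) -> tuple[np.ndarray, list[str]]:
    """Read one square matrix; returns (matrix, node_ids).

    Asymmetry above ``symmetry_tol`` is an error naming the file and the
    maximum asymmetry; asymmetry within tolerance is symmetrized with a
    warning.  NaN entries are always an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    node_ids = [str(c) for c in df.columns]
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValidationError(
            f"{path}: expected a square matrix, got shape {M.shape}"
        )
    if [str(i) for i in df.index] != node_ids:
        raise ValidationError(f"{path}: row labels do not match column header")
    if np.isnan(M).any():
        raise ValidationError(f"{path}: matrix contains NaN entries")
    asym = float(np.abs(M - M.T).max(initial=0.0))
    if asym > symmetry_tol:
        raise ValidationError(
            f"{path}: matrix asymmetry {asym:.3g} exceeds tolerance "
            f"{symmetry_tol:.3g}"
        )
    if asym > 0.0:
        warnings.warn(
            f"{path}: symmetrizing matrix (max asymmetry {asym:.3g})",
            stacklevel=2,
        )
        M = (M + M.T) / 2.0
    return M, node_ids


def write_matrix_stack(
    out_dir, matrices: np.ndarray, node_ids: Sequence[str],
    condition_ids: Sequence[str],
) -> list[Path]:
    """One matrix file per condition plus an index recording the order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, cond in enumerate(condition_ids):
        p = out_dir / f"{cond}.tsv"
        write_matrix(p, matrices[k], node_ids)
        paths.append(p)
    (out_dir / "conditions.json").write_text(
        json.dumps([str(c) for c in condition_ids], indent=2) + "\n"
    )
    return paths


def _stack_paths(source) -> list[Path]:
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        d = Path(source)
        order = d / "conditions.json"
        if order.exists():
            conds = json.loads(order.read_text())
            return [d / f"{c}.tsv" for c in conds]
        return sorted(p for p in d.glob("*.tsv"))
    return [Path(p) for p in source]


def read_matrix_stack(
    source, symmetry_tol: float = DEFAULT_SYMMETRY_TOL
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an ordered stack; returns (matrices, node_ids, condition_ids).

    ``source`` is a directory (ordered by its ``conditions.json`` index,
    else by sorted filename) or an explicit ordered list of files.
    Condition ids come from file stems.  All files must agree on node ids.
    """
    paths = _stack_paths(source)
    if not paths:
        raise ValidationError(f"no matrix files found in {source}")
    mats = []
    node_ids: list[str] | None = None
    conds = []
    for p in paths:
        if not p.exists():
            raise ValidationError(f"matrix file does not exist: {p}")
        M, ids = read_matrix(p, symmetry_tol=symmetry_tol)
        if node_ids is None:
            node_ids = ids
        elif ids != node_ids:
            raise ValidationError(
                f"{p}: node ids disagree with first file in the stack"
            )
        mats.append(M)
        conds.append(p.stem)
    return np.stack(mats), node_ids, conds


def read_connectivity_stack(
    source, transform: str = "raw_r",
    symmetry_tol: float = DEFAULT_SYMMETRY_TOL,
) -> ConnectivityStack:
    mats, node_ids, conds = read_matrix_stack(source, symmetry_tol)
    return ConnectivityStack(mats, conds, node_ids, transform=transform)


def read_multilayer(
    source, gamma: float = 1.0, omega: float = 0.45,
    sign_policy: str = "truncate_negative",
    symmetry_tol: float = DEFAULT_SYMMETRY_TOL,
) -> MultilayerNetwork:
    mats, node_ids, _ = read_matrix_stack(source, symmetry_tol)
    return MultilayerNetwork(mats, node_ids, gamma=gamma, omega=omega,
                             sign_policy=sign_policy)


# ---------------------------------------------------------------------------
# edge lists (alternative slice format)

def write_edgelist_stack(path, matrices: np.ndarray, node_ids, condition_ids) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["slice", "node_i", "node_j", "weight"]) + "\n")
        for k, cond in enumerate(condition_ids):
            M = matrices[k]
            for i in range(len(node_ids)):
                for j in range(i + 1, len(node_ids)):
                    if M[i, j] != 0.0:
                        fh.write(sep.join([
                            str(cond), str(node_ids[i]), str(node_ids[j]),
                            FLOAT_FMT % M[i, j],
                        ]) + "\n")


def read_edgelist_stack(path, node_ids=None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a (slice, node_i, node_j, weight) table into a dense stack."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str, 1: str, 2: str},
                     float_precision="round_trip")
    needed = ["slice", "node_i", "node_j", "weight"]
    if list(df.columns) != needed:
        raise ValidationError(f"{path}: expected columns {needed}")
    conds = list(dict.fromkeys(df["slice"].astype(str)))
    if node_ids is None:
        node_ids = sorted(set(df["node_i"].astype(str)) | set(df["node_j"].astype(str)))
    index = {n: i for i, n in enumerate(node_ids)}
    mats = np.zeros((len(conds), len(node_ids), len(node_ids)))
    cidx = {c: k for k, c in enumerate(conds)}
    for _, row in df.iterrows():
        k = cidx[str(row["slice"])]
        try:
            i, j = index[str(row["node_i"])], index[str(row["node_j"])]
        except KeyError as exc:
            raise ValidationError(f"{path}: unknown node {exc}") from exc
        w = float(row["weight"])
        mats[k, i, j] = w
        mats[k, j, i] = w
    return mats, list(node_ids), conds


# ---------------------------------------------------------------------------
# time series / design / system map

def write_timeseries(path, ts: ConditionTimeSeries) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("condition" + sep + sep.join(map(str, ts.node_ids)) + "\n")
        for lab, row in zip(ts.condition_labels, ts.samples):
            fh.write(str(lab) + sep + sep.join(FLOAT_FMT % v for v in row) + "\n")


def read_timeseries(path) -> ConditionTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if df.columns[0] != "condition":
        raise ValidationError(f"{path}: first column must be 'condition'")
    labels = df["condition"].astype(str).tolist()
    node_ids = [str(c) for c in df.columns[1:]]
    return ConditionTimeSeries(
        df.iloc[:, 1:].to_numpy(dtype=float), labels, node_ids
    )


def read_design_matrix(path) -> DesignMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    return DesignMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def write_system_map(path, systems: SystemMap) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("node" + sep + "system\n")
        for n, s in zip(systems.node_ids, systems.assignment):
            fh.write(f"{n}{sep}{s}\n")


def read_system_map(path, node_ids: Sequence[str] | None = None) -> SystemMap:
    """Two-column (node, system) table; optionally aligned to a node order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                     comment="#")
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected two columns, got {df.shape[1]}")
    rows = df.to_numpy()
    if tuple(rows[0]) == ("node", "system"):
        rows = rows[1:]
    if rows.size == 0:
        raise ValidationError(f"{path}: system map is empty")
    smap = SystemMap([r[0] for r in rows], [r[1] for r in rows])
    if node_ids is not None:
        smap = smap.reordered(list(node_ids))
    return smap


# ---------------------------------------------------------------------------
# partitions / ensembles

def write_partition(path, partition: Partition, node_ids, condition_ids) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("node" + sep + sep.join(map(str, condition_ids)) + "\n")
        for i, nid in enumerate(node_ids):
            fh.write(str(nid) + sep
                     + sep.join(str(int(v)) for v in partition.labels[i]) + "\n")


def read_partition(path) -> tuple[Partition, list[str], list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    labels = df.to_numpy(dtype=np.int64)
    return (
        Partition(labels),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_ensemble(out_dir, ensemble: PartitionEnsemble, node_ids,
                   condition_ids, master_seed: int | None = None) -> None:
    """Partition files plus an ensemble manifest with seeds and qualities."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r, part in enumerate(ensemble.partitions):
        write_partition(out_dir / f"partition_{r:03d}.tsv", part,
                        node_ids, condition_ids)
    gamma = np.asarray(ensemble.gamma, dtype=float)
    manifest = {
        "n_runs": ensemble.n_runs,
        "gamma": gamma.tolist() if gamma.ndim else float(gamma),
        "omega": float(ensemble.omega),
        "master_seed": master_seed,
        "seeds": [int(s) for s in ensemble.seeds],
        "qualities": [float(q) for q in ensemble.qualities],
        "node_ids": [str(n) for n in node_ids],
        "condition_ids": [str(c) for c in condition_ids],
    }
    (out_dir / "ensemble.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_ensemble(in_dir) -> tuple[PartitionEnsemble, list[str], list[str]]:
    in_dir = Path(in_dir)
    meta_path = in_dir / "ensemble.json"
    if not meta_path.exists():
        raise ValidationError(f"{in_dir}: missing ensemble.json")
    meta = json.loads(meta_path.read_text())
    partitions = []
    for r in range(meta["n_runs"]):
        part, node_ids, condition_ids = read_partition(
            in_dir / f"partition_{r:03d}.tsv"
        )
        if node_ids != meta["node_ids"] or condition_ids != meta["condition_ids"]:
            raise ValidationError(
                f"{in_dir}: partition_{r:03d}.tsv labels disagree with manifest"
            )
        partitions.append(part)
    ens = PartitionEnsemble(
        partitions=partitions,
        qualities=np.asarray(meta["qualities"], dtype=float),
        seeds=[int(s) for s in meta["seeds"]],
        gamma=np.asarray(meta["gamma"], dtype=float),
        omega=float(meta["omega"]),
    )
    return ens, meta["node_ids"], meta["condition_ids"]


# ---------------------------------------------------------------------------
# run manifests

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a command bit-identically."""

    command: str
    parameters: dict
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "parameters": self.parameters,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "version": self.version,
            "timestamp": self.timestamp,
        }


def write_manifest(out_dir, command: str, parameters: dict,
                   seeds: dict | None = None,
                   input_paths: Iterable = ()) -> RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        parameters=parameters,
        seeds=seeds or {},
        inputs={str(p): _sha256(Path(p)) for p in input_paths},
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return manifest
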
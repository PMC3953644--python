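"""HDF5 containers for TT objects, operators and solver runs.

Every container is self-describing: mode sizes, ranks, the virtual
ordering tag with its explicit permutation, tolerances and seeds are
stored as attributes, one dataset per TT core.  Save/load round-trips
are bit-exact.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np

from . import __version__
from .network import FSPWindow, ReactionNetwork
from .quantization import QuantizationMap
from .tt import TTMatrix, TTVector

__all__ = [
    "save_tt",
    "load_tt",
    "save_operator",
    "load_operator",
    "save_result",
    "run_manifest",
]


def _write_cores(grp, obj):
    grp.attrs["n_cores"] = obj.d
    grp.attrs["ranks"] = np.asarray(obj.ranks, dtype=np.int64)
    if isinstance(obj, TTMatrix):
        grp.attrs["kind"] = "matrix"
        grp.attrs["row_sizes"] = np.asarray(obj.row_sizes, dtype=np.int64)
        grp.attrs["col_sizes"] = np.asarray(obj.col_sizes, dtype=np.int64)
    else:
        grp.attrs["kind"] = "vector"
        grp.attrs["mode_sizes"] = np.asarray(obj.mode_sizes, dtype=np.int64)
    for k, c in enumerate(obj.cores):
        grp.create_dataset(f"core_{k}", data=c)


def _read_cores(grp):
    n = int(grp.attrs["n_cores"])
    cores = [np.asarray(grp[f"core_{k}"]) for k in range(n)]
    if grp.attrs["kind"] == "matrix":
        return TTMatrix(cores)
    return TTVector(cores)


def save_tt(path_or_group, obj, name: str = "tt"):
    """Write a TTVector/TTMatrix (bit-exact) to an HDF5 file or group."""
    if isinstance(path_or_group, (str,)) or hasattr(path_or_group, "__fspath__"):
        with h5py.File(path_or_group, "w") as fh:
            _write_cores(fh.create_group(name), obj)
    else:
        _write_cores(path_or_group.create_group(name), obj)


def load_tt(path_or_group, name: str = "tt"):
    if isinstance(path_or_group, (str,)) or hasattr(path_or_group, "__fspath__"):
        with h5py.File(path_or_group, "r") as fh:
            return _read_cores(fh[name])
    return _read_cores(path_or_group[name])


def _write_qmap(grp, qmap: QuantizationMap):
    grp.attrs["ordering"] = qmap.ordering
    grp.attrs["permutation"] = np.asarray(qmap.permutation, dtype=np.int64)
    grp.attrs["window"] = np.asarray(qmap.mode_sizes, dtype=np.int64)


def save_operator(path, op, manifest: dict = None):
    from .assembly import CMEOperator

    with h5py.File(path, "w") as fh:
        g = fh.create_group("operator")
        _write_cores(g.create_group("matrix"), op.matrix)
        _write_qmap(g, op.qmap)
        g.attrs["tolerance"] = op.tol
        g.attrs["boundary"] = op.boundary
        g.attrs["rank_bounds"] = np.asarray(op.rank_bounds, dtype=np.int64)
        fh.create_dataset("model_yaml", data=op.network.to_yaml())
        if manifest:
            fh.attrs["manifest"] = json.dumps(manifest)


def load_operator(path):
    from .assembly import CMEOperator

    with h5py.File(path, "r") as fh:
        g = fh["operator"]
        matrix = _read_cores(g["matrix"])
        window = FSPWindow(tuple(int(n) for n in g.attrs["window"]))
        qmap = QuantizationMap(window.sizes, ordering=str(g.attrs["ordering"]))
        net = ReactionNetwork.from_yaml(fh["model_yaml"][()].decode())
        return CMEOperator(
            matrix=matrix,
            qmap=qmap,
            window=window,
            network=net,
            tol=float(g.attrs["tolerance"]),
            boundary=str(g.attrs["boundary"]),
            rank_bounds=tuple(int(b) for b in g.attrs["rank_bounds"]),
        )


def save_result(path, result, manifest: dict = None):
    """Write a SolveResult: per-step endpoint TT cores plus diagnostics
    (the diagnostics table is also written as CSV next to the file)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_endpoints"] = len(result.endpoints)
        fh.attrs["breakpoints"] = np.asarray(result.mesh.breakpoints)
        if result.qmap is not None:
            _write_qmap(fh, result.qmap)
        for i, y in enumerate(result.endpoints):
            _write_cores(fh.create_group(f"endpoint_{i}"), y)
        rec = result.diagnostics.to_records(index=False)
        fh.create_dataset("diagnostics", data=rec)
        if manifest:
            fh.attrs["manifest"] = json.dumps(manifest)
    csv_path = str(path) + ".diagnostics.csv"
    result.diagnostics.to_csv(csv_path, index=False)
    return csv_path


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(seed: int, **file_paths) -> dict:
    """Reproducibility manifest: package version, seed, input hashes."""
    man = {"package": "qttcme", "version": __version__, "seed": int(seed)}
    for key, path in file_paths.items():
        if path is not None:
            man[f"{key}_sha256"] = _sha256(path)
    return man
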
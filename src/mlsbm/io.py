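"""Readers and writers for networks, parcellations, metadata and fit
results.

Vertex indices are 0-based everywhere internally; Matrix Market files use
1-based indices only at the file boundary. Readers reject malformed input
rather than guessing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParameterError, ParseError
from .inference import FitResult
from .metrics import VertexMetadata
from .model import BinaryNetwork, Hyperparameters, MultiLayerNetwork, Parcellation

logger = logging.getLogger(__name__)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("edgelist", "matrix-market"):
            raise ParameterError(f"unknown network format {fmt!r}")
        return fmt
    return "matrix-market" if path.suffix.lower() == ".mtx" else "edgelist"


def read_network(
    path: str | Path, fmt: str | None = None, n_vertices: int | None = None
) -> BinaryNetwork:
    """Read a binary network from a whitespace edge list (0-based) or a
    Matrix Market coordinate file (1-based, symmetrized).

    Self-links and duplicate entries are dropped with a logged count. For
    edge lists, ``n_vertices`` overrides the 1 + max-index default.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-market":
        mat = scipy.io.mmread(path).tocoo()
        if mat.shape[0] != mat.shape[1]:
            raise ParseError(f"{path}: matrix is not square")
        rows, cols = mat.row, mat.col
        n = mat.shape[0] if n_vertices is None else n_vertices
        pairs = set()
        dropped = 0
        for i, j in zip(rows.tolist(), cols.tolist()):
            if i == j:
                dropped += 1
                continue
            pairs.add((i, j) if i < j else (j, i))
        if dropped:
            logger.warning("%s: dropped %d diagonal entries", path, dropped)
        return BinaryNetwork(n, pairs)

    pairs = set()
    max_idx = -1
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("# n_vertices") and n_vertices is None:
                n_vertices = int(line.split()[-1])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError("expected at least two columns", line=lineno)
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer vertex id in {parts[:2]}", line=lineno)
            if i < 0 or j < 0:
                raise ParseError("negative vertex id", line=lineno)
            if i == j:
                dropped += 1
                continue
            pair = (i, j) if i < j else (j, i)
            if pair in pairs:
                dropped += 1
            pairs.add(pair)
            max_idx = max(max_idx, i, j)
    if dropped:
        logger.warning("%s: dropped %d self/duplicate entries", path, dropped)
    n = (max_idx + 1) if n_vertices is None else n_vertices
    if n < 1:
        raise ParseError(f"{path}: no edges and no vertex count given")
    return BinaryNetwork(n, pairs)


def write_network(network: BinaryNetwork, path: str | Path, fmt: str | None = None):
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-market":
        e = network.edge_array()
        # store the lower triangle: symmetric Matrix Market keeps row >= col
        mat = scipy.sparse.coo_matrix(
            (np.ones(e.shape[0]), (e[:, 1], e[:, 0])),
            shape=(network.n_vertices, network.n_vertices),
        )
        scipy.io.mmwrite(path, mat, symmetry="symmetric", field="pattern")
    else:
        with open(path, "w") as fh:
            fh.write(f"# n_vertices {network.n_vertices}\n")
            for i, j in network.edge_array().tolist():
                fh.write(f"{i} {j}\n")


def read_multilayer(
    paths: list[str | Path], names: list[str] | None = None
) -> MultiLayerNetwork:
    nets = [read_network(p) for p in paths]
    n = max(net.n_vertices for net in nets)
    nets = [
        BinaryNetwork(n, net.links) if net.n_vertices != n else net for net in nets
    ]
    if names is None:
        names = [Path(p).stem for p in paths]
    return MultiLayerNetwork(nets, names)


def read_parcellation(path: str | Path, K: int | None = None):
    """Read one integer label per line (optionally ``vertex<TAB>label``).

    Labels are re-indexed densely to [0, K) in order of first appearance;
    the original labels are returned in a sidecar mapping.
    """
    path = Path(path)
    raw: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            token = parts[-1]  # single column, or "vertex<TAB>label"
            try:
                raw.append(int(token))
            except ValueError:
                raise ParseError(f"non-integer label {token!r}", line=lineno)
    mapping: dict[int, int] = {}
    dense = []
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        dense.append(mapping[lab])
    k = K if K is not None else max(len(mapping), 1)
    return Parcellation(dense, k), mapping


def write_parcellation(parcellation: Parcellation, path: str | Path):
    with open(path, "w") as fh:
        for v, lab in enumerate(parcellation.labels.tolist()):
            fh.write(f"{v}\t{lab}\n")


def read_metadata(path: str | Path) -> VertexMetadata:
    """TSV with columns vertex, hemisphere, traversal_index."""
    df = pd.read_csv(path, sep="\t")
    for col in ("vertex", "hemisphere", "traversal_index"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df = df.sort_values("vertex")
    return VertexMetadata(
        hemisphere=df["hemisphere"].to_numpy(),
        traversal_index=df["traversal_index"].to_numpy(),
    )


def write_metadata(meta: VertexMetadata, path: str | Path):
    pd.DataFrame(
        {
            "vertex": np.arange(meta.n_vertices),
            "hemisphere": meta.hemisphere,
            "traversal_index": meta.traversal_index,
        }
    ).to_csv(path, sep="\t", index=False)


def write_fit_result(result: FitResult, out_dir: str | Path, extra: dict | None = None):
    """Serialize a fit as a JSON summary plus a label file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_parcellation(result.parcellation, out_dir / "labels.tsv")
    payload = {
        "K": result.parcellation.K,
        "hyperparameters": {
            "beta_plus": result.hypers.beta_plus,
            "beta_minus": result.hypers.beta_minus,
            "alpha": result.hypers.alpha,
        },
        "log_joint_trace": [float(x) for x in result.log_joint_trace],
        "seed": result.seed,
        "schedule": {
            "n_iterations": result.schedule[0],
            "mh_proposals": result.schedule[1],
        },
        "mh_acceptances": result.mh_acceptances,
    }
    if extra:
        payload.update(extra)
    with open(out_dir / "fit.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_hyperparameters(path: str | Path) -> Hyperparameters:
    with open(path) as fh:
        payload = json.load(fh)
    h = payload["hyperparameters"] if "hyperparameters" in payload else payload
    return Hyperparameters(
        beta_plus=h["beta_plus"], beta_minus=h["beta_minus"], alpha=h["alpha"]
    )


def write_permutation(mapping: np.ndarray, path: str | Path):
    """Two-column TSV: original index, new index."""
    with open(path, "w") as fh:
        fh.write("original\tnew\n")
        for orig, new in enumerate(np.asarray(mapping).tolist()):
            fh.write(f"{orig}\t{new}\n")


def read_permutation(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    mapping = np.empty(len(df), dtype=np.int64)
    mapping[df["original"].to_numpy()] = df["new"].to_numpy()
    return mapping
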
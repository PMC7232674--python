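"""File formats: delimited datasets, edge lists, adjacency matrices, manifests.

All formats are plain text.  Datasets are delimited (comma by default, tab
accepted) with a header row; networks are tab-separated edge lists
``parent<TAB>child<TAB>weight`` with a variables sidecar
``name<TAB>kind<TAB>levels`` (levels ``-`` for continuous nodes).  Weights
round-trip at full precision via ``repr``.  Missing data are rejected
loudly: the simulations this package serves have none.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset
from .exceptions import DataFormatError
from .network import CONTINUOUS, DISCRETE, TypedDag, VariableSpec

logger = logging.getLogger(__name__)

# inference rule: at most this many distinct integer-like values => discrete
DISCRETE_INFERENCE_MAX_LEVELS = 6


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _infer_spec(name: str, col: pd.Series) -> VariableSpec:
    values = col.to_numpy()
    uniq = np.unique(values)
    integer_like = np.all(np.asarray(uniq, dtype=float) % 1 == 0)
    if integer_like and len(uniq) <= DISCRETE_INFERENCE_MAX_LEVELS and uniq.min() >= 0:
        levels = int(uniq.max()) + 1
        if levels >= 2:
            logger.info("inferred column %r as discrete with %d levels", name, levels)
            return VariableSpec(name, DISCRETE, levels)
    logger.info("inferred column %r as continuous", name)
    return VariableSpec(name, CONTINUOUS)


def read_dataset(
    path: str | Path,
    variables: Sequence[VariableSpec] | str | Path | None = None,
    delimiter: str | None = None,
) -> Dataset:
    """Read a delimited, headered, rectangular sample-by-variable table.

    ``variables`` may be explicit specs, a path to a variables sidecar, or
    None, in which case kinds are inferred (<= 6 distinct non-negative
    integer values => discrete) and logged.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, header=0, engine="python")
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if frame.empty and len(frame.columns) == 0:
        raise DataFormatError(f"{path}: no columns found")
    na_mask = frame.isna()
    if na_mask.any().any():
        col = na_mask.any().idxmax()
        row = int(na_mask[col].idxmax())
        raise DataFormatError(
            f"{path}: missing value at row {row}, column {col!r} (missing data unsupported)"
        )
    for col in frame.columns:
        if not np.issubdtype(frame[col].to_numpy().dtype, np.number):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            row = int(bad.index[0]) if len(bad) else 0
            raise DataFormatError(
                f"{path}: non-numeric value at row {row}, column {col!r}"
            )
    if isinstance(variables, (str, Path)):
        variables = read_variables(variables)
    if variables is None:
        specs = tuple(_infer_spec(str(c), frame[c]) for c in frame.columns)
    else:
        by_name = {v.name: v for v in variables}
        missing = set(map(str, frame.columns)) ^ set(by_name)
        if missing:
            raise DataFormatError(
                f"{path}: variable declaration does not cover columns exactly: {sorted(missing)}"
            )
        specs = tuple(by_name[str(c)] for c in frame.columns)
    for spec in specs:
        if spec.is_discrete:
            vals = frame[spec.name].to_numpy()
            if np.any(np.asarray(vals, dtype=float) % 1 != 0):
                raise DataFormatError(
                    f"{path}: non-integer value in discrete column {spec.name!r}"
                )
            if vals.min() < 0 or vals.max() >= spec.levels:
                raise DataFormatError(
                    f"{path}: level outside [0, {spec.levels}) in column {spec.name!r}"
                )
            frame[spec.name] = frame[spec.name].astype(np.int64)
    return Dataset(frame, specs)


def write_dataset(dataset: Dataset, path: str | Path, delimiter: str = ",") -> None:
    dataset.frame.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# variables sidecar
# ---------------------------------------------------------------------------

def write_variables(variables: Iterable[VariableSpec], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tkind\tlevels\n")
        for v in variables:
            levels = str(v.levels) if v.is_discrete else "-"
            fh.write(f"{v.name}\t{v.kind}\t{levels}\n")


def read_variables(path: str | Path) -> tuple[VariableSpec, ...]:
    specs = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "kind", "levels"]:
            raise DataFormatError(f"{path}: bad variables header {header!r}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise DataFormatError(f"{path}:{line_no}: expected 3 fields")
            name, kind, levels = parts
            specs.append(
                VariableSpec(name, kind, None if levels == "-" else int(levels))
            )
    return tuple(specs)


# ---------------------------------------------------------------------------
# network edge lists and adjacency matrices
# ---------------------------------------------------------------------------

def write_network(
    dag: TypedDag,
    path: str | Path,
    weights: Mapping[tuple[str, str], float] | None = None,
    variables_path: str | Path | None = None,
) -> None:
    """Tab-separated ``parent child weight`` edge list, edges sorted.

    Edges without an entry in ``weights`` get weight 1.0 (discrete edges).
    """
    weights = weights or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("parent\tchild\tweight\n")
        for u, v in sorted(dag.edges):
            w = float(weights.get((u, v), 1.0))
            fh.write(f"{u}\t{v}\t{w!r}\n")
    if variables_path is not None:
        write_variables(dag.variables, variables_path)


def read_network(
    path: str | Path, variables: Sequence[VariableSpec] | str | Path
) -> tuple[TypedDag, dict[tuple[str, str], float]]:
    if isinstance(variables, (str, Path)):
        variables = read_variables(variables)
    known = {v.name for v in variables}
    edges = set()
    weights: dict[tuple[str, str], float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["parent", "child", "weight"]:
            raise DataFormatError(f"{path}: bad edge-list header {header!r}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise DataFormatError(f"{path}:{line_no}: expected 3 fields")
            u, v, w = parts
            if u not in known or v not in known:
                raise DataFormatError(f"{path}:{line_no}: unknown node in edge {u}->{v}")
            edges.add((u, v))
            weights[(u, v)] = float(w)
    return TypedDag(tuple(variables), frozenset(edges)), weights


def write_adjacency(
    dag: TypedDag,
    path: str | Path,
    weights: Mapping[tuple[str, str], float] | None = None,
) -> None:
    """Dense adjacency matrix with a header row and column of node names."""
    weights = weights or {}
    names = list(dag.names)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + names) + "\n")
        for u in names:
            row = []
            for v in names:
                if (u, v) in dag.edges:
                    row.append(repr(float(weights.get((u, v), 1.0))))
                else:
                    row.append("0.0")
            fh.write("\t".join([u] + row) + "\n")


def read_adjacency(
    path: str | Path, variables: Sequence[VariableSpec] | str | Path
) -> tuple[TypedDag, dict[tuple[str, str], float]]:
    if isinstance(variables, (str, Path)):
        variables = read_variables(variables)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        edges = set()
        weights = {}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            u = parts[0]
            for v, cell in zip(header, parts[1:]):
                w = float(cell)
                if w != 0.0:
                    edges.add((u, v))
                    weights[(u, v)] = w
    return TypedDag(tuple(variables), frozenset(edges)), weights


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    command: str,
    config: Mapping,
    seeds: Mapping[str, int],
    inputs: Mapping[str, str | Path] | None = None,
) -> dict:
    """JSON-compatible record sufficient to replay a run bit-identically."""
    from . import __version__

    return {
        "tool": "bicnet",
        "version": __version__,
        "command": command,
        "config": dict(config),
        "seeds": dict(seeds),
        "input_hashes": {
            name: sha256_file(p) for name, p in (inputs or {}).items()
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
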
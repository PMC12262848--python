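"""File formats: catalogs, single matrices, label lists, feature tables, barcodes.

Everything is plain text — TSV for tables, JSON for metadata — and every
writer has a matching reader (round-trip tested).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import GraphCatalog
from .cluster import LabelSet
from .dualgraph import DualGraph, GraphID, InputError, parse_graph_id
from .persistence import Bar, Barcode

__all__ = [
    "write_catalog",
    "read_catalog",
    "read_matrix",
    "write_matrix",
    "read_label_list",
    "write_label_list",
    "write_features",
    "read_features",
    "write_barcodes",
    "read_barcodes",
]


def write_catalog(catalog: GraphCatalog, path) -> Path:
    """TSV with columns id, n, adjacency (row-major comma-separated) plus a
    ``.meta.json`` sidecar holding the generation metadata."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tn\tadjacency\n")
        for gid, g in catalog.items():
            flat = ",".join(map(str, g.A.flatten().tolist()))
            fh.write(f"{gid}\t{g.n}\t{flat}\n")
    meta = dict(catalog.metadata)
    meta.setdefault("tool_version", __version__)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_catalog(path) -> GraphCatalog:
    path = Path(path)
    graphs: dict[GraphID, DualGraph] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "n", "adjacency"]:
            raise InputError(f"unexpected catalog header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                gid, n, flat = line.rstrip("\n").split("\t")
                n = int(n)
                entries = np.array([int(x) for x in flat.split(",")])
                A = entries.reshape(n, n)
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}:{lineno}: malformed catalog row") from exc
            parse_graph_id(gid)
            graphs[GraphID(gid)] = DualGraph(A)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return GraphCatalog(graphs, meta)


def read_matrix(path) -> np.ndarray:
    """Whitespace-delimited integer matrix, one row per line."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            rows.append([int(tok) for tok in line.split()])
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: non-integer entry") from exc
    if not rows:
        raise InputError(f"{path}: empty matrix file")
    if len({len(r) for r in rows}) != 1:
        raise InputError(f"{path}: ragged rows")
    return np.array(rows, dtype=np.int64)


def write_matrix(A, path) -> Path:
    path = Path(path)
    A = np.asarray(A)
    path.write_text("\n".join(" ".join(map(str, row)) for row in A.tolist()) + "\n")
    return path


def read_label_list(path, catalog: GraphCatalog | None = None) -> LabelSet:
    """One GraphID per line; ``#`` starts a comment.  Malformed IDs raise
    with their line number; with a catalog, unknown IDs are reported too."""
    path = Path(path)
    ids = []
    unknown = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            parse_graph_id(line)
        except InputError as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from exc
        if catalog is not None and line not in catalog:
            unknown.append((lineno, line))
        ids.append(line)
    if unknown:
        listing = ", ".join(f"line {ln}: {gid}" for ln, gid in unknown)
        raise InputError(f"{path}: IDs not in catalog ({listing})")
    if not ids:
        raise InputError(f"{path}: no graph IDs found")
    return LabelSet(frozenset(ids), provenance=str(path))


def write_label_list(labels: LabelSet, path) -> Path:
    path = Path(path)
    ordered = sorted(labels.ids, key=parse_graph_id)
    header = f"# {len(ordered)} known-RNA graph IDs ({labels.provenance})\n"
    path.write_text(header + "\n".join(ordered) + "\n")
    return path


def write_features(features: pd.DataFrame, path) -> Path:
    path = Path(path)
    # %.17g round-trips doubles exactly
    features.to_csv(path, sep="\t", index_label="id", float_format="%.17g")
    return path


def read_features(path) -> pd.DataFrame:
    # the feature schema is all-float; integer-looking columns must not
    # come back as int64
    return pd.read_csv(
        Path(path), sep="\t", index_col="id", float_precision="round_trip"
    ).astype(float)


def write_barcodes(barcodes: dict, path) -> Path:
    """JSON-lines export: one record per bar (id, q, birth, death)."""
    path = Path(path)
    with path.open("w") as fh:
        for gid, bc in barcodes.items():
            for bar in bc.bars:
                fh.write(
                    json.dumps(
                        {"id": str(gid), "q": bar.q, "birth": bar.birth, "death": bar.death}
                    )
                    + "\n"
                )
    return path


def read_barcodes(path) -> dict:
    out: dict[str, list[Bar]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            bar = Bar(int(rec["q"]), int(rec["birth"]),
                      None if rec["death"] is None else int(rec["death"]))
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise InputError(f"{path}:{lineno}: malformed barcode record") from exc
        out.setdefault(rec["id"], []).append(bar)
    return {gid: Barcode(tuple(bars)) for gid, bars in out.items()}
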
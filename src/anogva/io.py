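"""Readers and writers for graphs, manifests, densities and results.

Graphs are exchanged either as dense adjacency CSV/TSV (optional header
row) or as 1-based two-column edge lists with a ``#n=<vertices>`` header
line.  Populations are grouped by a TSV manifest with columns
``file_path`` and ``population_name``.  Structured results serialize to
JSON with a schema-version stamp; tabular results to TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Graph, GraphPopulation
from .permutation import AnogvaResult
from .simulation import FeatureBenchmarkResult, RocCurve
from .spectral import SpectralDensity

logger = logging.getLogger("anogva")

SCHEMA_VERSION = 1
_ASYM_TOL = 1e-8


def _read_edge_list(path: Path) -> Graph:
    n = None
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.replace(" ", "").startswith("#n="):
                    n = int(line.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            i, j = int(parts[0]), int(parts[1])
            if i == j:
                logger.warning("%s:%d: self-loop %d-%d dropped", path, lineno, i, j)
                continue
            edges.append((i - 1, j - 1))      # 1-based on disk
    if n is None:
        raise ValueError(f"{path}: missing '#n=<vertices>' header")
    a = np.zeros((n, n))
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"{path}: vertex index out of range (n={n})")
        a[i, j] = a[j, i] = 1.0
    return Graph(a, label=path.stem)


def _read_dense(path: Path, delimiter: str) -> Graph:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.replace(delimiter, " ").split() if f]
            if lineno == 1:
                try:
                    [float(f) for f in fields]
                except ValueError:
                    continue          # header row
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    width = len(rows[0])
    for i, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ValueError(f"{path}: ragged row {i} ({len(r)} != {width})")
    a = np.asarray(rows)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"{path}: matrix is {a.shape[0]}x{a.shape[1]}, not square")
    if not np.allclose(a, a.T, atol=_ASYM_TOL):
        raise ValueError(f"{path}: adjacency asymmetric beyond tolerance")
    if np.any(np.diag(a) != 0):
        logger.warning("%s: nonzero diagonal dropped", path)
    return Graph(a, label=path.stem)


def read_graph(path, fmt: str | None = None) -> Graph:
    """Read a graph from dense CSV/TSV or a '#n=' headed edge list.

    ``fmt`` is one of ``dense``/``edgelist`` or None to infer: files whose
    first non-blank line starts with ``#n=`` are edge lists.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if line:
                    fmt = ("edgelist" if line.replace(" ", "").startswith("#n=")
                           else "dense")
                    break
            else:
                raise ValueError(f"{path}: empty file")
    if fmt == "edgelist":
        return _read_edge_list(path)
    if fmt == "dense":
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        return _read_dense(path, delimiter)
    raise ValueError(f"unknown graph format {fmt!r}")


def write_graph(graph: Graph, path, fmt: str = "dense") -> None:
    path = Path(path)
    if fmt == "dense":
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        np.savetxt(path, graph.adjacency, delimiter=delimiter, fmt="%.12g")
    elif fmt == "edgelist":
        i, j = np.nonzero(np.triu(graph.adjacency, k=1))
        with open(path, "w") as fh:
            fh.write(f"#n={graph.n_vertices}\n")
            for a, b in zip(i, j):
                fh.write(f"{a + 1}\t{b + 1}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_population_manifest(path) -> list[GraphPopulation]:
    """TSV manifest (file_path, population_name) → list of populations.

    Relative graph paths are resolved against the manifest's directory.
    Population order follows first appearance in the manifest.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = {"file_path", "population_name"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    groups: dict[str, list[Graph]] = {}
    for _, row in table.iterrows():
        gpath = Path(row["file_path"])
        if not gpath.is_absolute():
            gpath = path.parent / gpath
        groups.setdefault(str(row["population_name"]), []).append(read_graph(gpath))
    return [GraphPopulation(name, graphs) for name, graphs in groups.items()]


def write_density(density: SpectralDensity, path) -> None:
    """Two-column TSV (grid, value) for plotting."""
    np.savetxt(path, np.column_stack([density.grid, density.values]),
               delimiter="\t", header="grid\tdensity", comments="")


def write_result(result, path) -> None:
    """Serialize a result object: JSON for structured, TSV for tabular."""
    path = Path(path)
    if isinstance(result, AnogvaResult):
        payload = {"schema_version": SCHEMA_VERSION,
                   "type": "anogva_result", **result.to_dict()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif isinstance(result, RocCurve):
        np.savetxt(path, np.column_stack([result.thresholds,
                                          result.rejection_proportions]),
                   delimiter="\t", header="threshold\trejection_proportion",
                   comments="")
    elif isinstance(result, FeatureBenchmarkResult):
        rows = []
        for model, methods in result.outcomes.items():
            for method, o in methods.items():
                rows.append({"model": model, "method": method,
                             "rejection_proportion": o.proportion,
                             "ci_low": o.ci_low, "ci_high": o.ci_high,
                             "n_replicates": o.n_replicates,
                             "n_skipped": o.n_skipped})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif isinstance(result, dict):
        path.write_text(json.dumps({"schema_version": SCHEMA_VERSION,
                                    **result}, indent=2, default=float) + "\n")
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")


def read_result(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        logger.warning("%s: schema version %r != %d", path,
                       payload.get("schema_version"), SCHEMA_VERSION)
    return payload


def read_cohort_manifest(path):
    """Cohort manifest TSV → (subjects, covariate table).

    Columns: subject_id, group, file, site, gender, age, scrub_proportion;
    ``file`` points to a T×R CSV/TSV of the subject's ROI time series.
    """
    from .connectivity import SubjectTimeSeries

    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "file"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    subjects = []
    for _, row in table.iterrows():
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        sep = "\t" if fpath.suffix.lower() in (".tsv", ".tab") else ","
        series = np.loadtxt(fpath, delimiter=sep)
        cov = {c: row[c] for c in table.columns
               if c not in ("subject_id", "group", "file")}
        subjects.append(SubjectTimeSeries(str(row["subject_id"]),
                                          str(row["group"]), series, cov))
    return subjects


def read_labels(path) -> dict[int, str]:
    """ROI sub-network labels TSV (roi_index, subnetwork), 1-based on disk."""
    table = pd.read_csv(path, sep="\t")
    if not {"roi_index", "subnetwork"}.issubset(table.columns):
        raise ValueError(f"{path}: needs columns roi_index, subnetwork")
    return {int(r.roi_index) - 1: str(r.subnetwork)
            for r in table.itertuples()}
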
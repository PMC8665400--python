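"""Plain-text dataset layout: readers and writers.

A dataset directory holds everything one analysis needs::

    dataset/
      cohort.tsv          tab-separated cohort table, one row per participant
      meta.json           freq_axis (Hz), node coordinates (mm), spacing, seed
      pre/<id>.txt        per-participant node x frequency power matrix
      post/<id>.txt       idem, post-intervention session
      roi_map.tsv         optional: node_index <TAB> roi_name
      truth.json          optional: planted-effect ground truth (synthetic data)

Matrices are whitespace-delimited text written at 17 significant digits so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CohortTable,
    CohortError,
    PowerTensor,
    SourceGraph,
    SESSIONS,
)
from .adjacency import grid_adjacency

_FLOAT_FMT = "%.17e"


def load_cohort_table(path: str | os.PathLike, age_range=(8.0, 11.0)) -> CohortTable:
    """Read and validate a tab-separated cohort table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CohortError(f"no participants: {path} is empty") from None
    if len(df) == 0:
        raise CohortError(f"no participants in {path}")
    for col in ("medicated", "psych_treatment"):
        if col in df.columns:
            df[col] = _parse_bool(df[col], col)
    return CohortTable(df, age_range=age_range)


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = []
    for v in col:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
            continue
        key = str(v).strip().lower()
        if key not in mapping:
            raise CohortError(f"cannot parse {name} value {v!r} as boolean")
        out.append(mapping[key])
    return pd.Series(out, index=col.index)


def write_cohort_table(cohort: CohortTable, path: str | os.PathLike) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_meta(dataset_dir: str | os.PathLike) -> dict:
    with open(Path(dataset_dir) / "meta.json") as fh:
        return json.load(fh)


def load_source_graph(dataset_dir: str | os.PathLike) -> SourceGraph:
    """Rebuild the source graph from meta.json (coords + grid spacing)."""
    meta = load_meta(dataset_dir)
    coords = np.asarray(meta["coords"], float)
    spacing = float(meta.get("spacing", 10.0))
    graph = grid_adjacency(coords, spacing)
    roi_path = Path(dataset_dir) / "roi_map.tsv"
    if roi_path.exists():
        from .adjacency import assign_nodes_to_rois

        graph = assign_nodes_to_rois(graph, load_roi_map(roi_path))
    return graph


def load_roi_map(path: str | os.PathLike) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t", header=0)
    if list(df.columns[:2]) != ["node_index", "roi_name"]:
        raise ValueError(
            "roi map must have columns 'node_index' and 'roi_name', "
            f"got {list(df.columns)}"
        )
    return {int(r.node_index): str(r.roi_name) for r in df.itertuples()}


def write_roi_map(roi_map: dict[int, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("node_index\troi_name\n")
        for node in sorted(roi_map):
            fh.write(f"{node}\t{roi_map[node]}\n")


def load_power_tensor(
    dataset_dir: str | os.PathLike, session: str
) -> PowerTensor:
    """Load one session's per-participant matrices into a tensor.

    Participant order follows cohort.tsv; a missing matrix file for any
    participant is an error, as is any shape or frequency-axis inconsistency.
    """
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}")
    dataset_dir = Path(dataset_dir)
    meta = load_meta(dataset_dir)
    freq_axis = np.asarray(meta["freq_axis"], float)
    n_nodes = int(meta["n_nodes"])
    cohort = load_cohort_table(dataset_dir / "cohort.tsv",
                               age_range=tuple(meta.get("age_range", (8.0, 11.0))))
    mats = []
    for pid in cohort.participant_ids:
        fpath = dataset_dir / session / f"{pid}.txt"
        if not fpath.exists():
            raise FileNotFoundError(
                f"missing {session} power matrix for participant {pid}: {fpath}"
            )
        m = np.loadtxt(fpath, ndmin=2)
        if m.shape != (n_nodes, freq_axis.size):
            raise ValueError(
                f"{fpath}: expected shape {(n_nodes, freq_axis.size)}, got {m.shape}"
            )
        mats.append(m)
    return PowerTensor(
        values=np.stack(mats),
        freq_axis=freq_axis,
        session=session,
        participant_order=cohort.participant_ids,
    )


def write_power_tensor(
    tensor: PowerTensor, dataset_dir: str | os.PathLike
) -> None:
    outdir = Path(dataset_dir) / tensor.session
    outdir.mkdir(parents=True, exist_ok=True)
    for i, pid in enumerate(tensor.participant_order):
        np.savetxt(outdir / f"{pid}.txt", tensor.values[i], fmt=_FLOAT_FMT)


def load_dataset(dataset_dir: str | os.PathLike):
    """Convenience loader: (cohort, pre tensor, post tensor, source graph)."""
    dataset_dir = Path(dataset_dir)
    meta = load_meta(dataset_dir)
    cohort = load_cohort_table(dataset_dir / "cohort.tsv",
                               age_range=tuple(meta.get("age_range", (8.0, 11.0))))
    pre = load_power_tensor(dataset_dir, "pre")
    post = load_power_tensor(dataset_dir, "post")
    graph = load_source_graph(dataset_dir)
    return cohort, pre, post, graph
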
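"""Plain-text serialization: TSV matrices, JSON parameters and summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mem import MEMParameters
from .preprocess import BinaryStateSeries, ClusterAssignment

FLOAT_FORMAT = "%.12g"  # stable text formatting so reruns are byte-identical


def write_series_tsv(path: str | Path, series: np.ndarray, node_labels: list[str] | None = None) -> None:
    """Write a time × node matrix as TSV with a header row of node names."""
    X = np.asarray(series)
    if node_labels is None:
        node_labels = [f"n{i + 1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=node_labels)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_series_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_binary_series_tsv(path: str | Path, series: BinaryStateSeries) -> None:
    write_series_tsv(path, series.values, series.node_labels)


def read_binary_series_tsv(path: str | Path, source: str = "file") -> BinaryStateSeries:
    df = read_series_tsv(path)
    return BinaryStateSeries(
        values=df.to_numpy(dtype=np.int8), node_labels=list(df.columns), source=source
    )


def write_params_json(path: str | Path, params: MEMParameters) -> None:
    payload = {"h": params.h.tolist(), "J": params.J.tolist(), "order": params.order}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_params_json(path: str | Path) -> MEMParameters:
    payload = json.loads(Path(path).read_text())
    return MEMParameters(
        h=np.array(payload["h"]),
        J=np.array(payload["J"]),
        order=payload.get("order", "pairwise"),
    )


def write_cluster_json(path: str | Path, assignment: ClusterAssignment) -> None:
    payload = {"k": assignment.k, "labels": assignment.labels.tolist()}
    Path(path).write_text(json.dumps(payload) + "\n")


def read_cluster_json(path: str | Path) -> ClusterAssignment:
    payload = json.loads(Path(path).read_text())
    return ClusterAssignment(labels=np.array(payload["labels"]), k=payload["k"])


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
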
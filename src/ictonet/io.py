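"""Plain-text input/output.

One CSV dialect is shared by every module that exchanges square matrices
(functional networks, binary networks, coupling matrices): node labels as
both header and index of a square table.  Multichannel signals travel as
CSV with one row per channel, the channel label in the first column, and
the sampling rate on a leading ``# fs=`` comment line.  Trajectories are
written wide (time plus real/imaginary columns per node) with a JSON
sidecar echoing the run configuration for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ComplexTrajectory
from .funcnet import FunctionalNetwork, SignalSet
from .graphs import BinaryNetwork

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_network",
    "read_binary_network",
    "read_signals",
    "write_signals",
    "write_trajectory",
    "load_config",
]


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix CSV -> (values, labels)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {df.shape}")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_matrix(path, adjacency: np.ndarray, labels=None) -> None:
    adjacency = np.asarray(adjacency)
    if labels is None:
        labels = [f"n{i}" for i in range(adjacency.shape[0])]
    pd.DataFrame(adjacency, index=labels, columns=labels).to_csv(path)


def read_network(path) -> FunctionalNetwork:
    values, labels = read_matrix(path)
    return FunctionalNetwork(values, labels)


def read_binary_network(path) -> BinaryNetwork:
    values, labels = read_matrix(path)
    return BinaryNetwork(values.astype(int), labels)


def write_network(path, network) -> None:
    write_matrix(path, network.adjacency, network.labels)


def read_signals(path) -> SignalSet:
    """Read a channels-by-samples signal CSV with a ``# fs=`` header line."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=<rate>' header line")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, index_col=0)
    return SignalSet(df.to_numpy(dtype=float), fs, [str(i) for i in df.index])


def write_signals(path, signals: SignalSet) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={signals.fs}\n")
        df = pd.DataFrame(
            signals.data,
            index=signals.labels,
            columns=[f"s{k}" for k in range(signals.n_samples)],
        )
        df.index.name = "channel"
        df.to_csv(fh)


def write_trajectory(path, trajectory: ComplexTrajectory, labels=None, config: dict | None = None) -> None:
    """Write a trajectory CSV plus a ``<path>.json`` provenance sidecar."""
    path = Path(path)
    n = trajectory.n_nodes
    if labels is None:
        labels = [f"n{i}" for i in range(n)]
    cols = {"time": trajectory.times}
    for i, lab in enumerate(labels):
        cols[f"node_{lab}_re"] = trajectory.states[i].real
        cols[f"node_{lab}_im"] = trajectory.states[i].imag
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {
        "dt": trajectory.dt,
        "n_nodes": n,
        "node_frequencies": list(map(float, trajectory.node_frequencies)),
        "config": config or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
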
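"""Readers and writers for the tabular formats the tool consumes/produces.

Conventions: parcellation and report tables are TSV with a header; matrices
are headerless CSV or TSV (delimiter sniffed from the first line). Node
indexing is 0-based everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .datamodel import (
    FormatError,
    Parcellation,
    SubjectObservations,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .core import CoreResult

_PARC_COLUMNS = ["node_id", "region_name", "network_label", "volume"]


def _sniff_delimiter(path: Path) -> str:
    first = Path(path).open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_parcellation(path) -> Parcellation:
    """Read a parcellation table (columns: node_id, region_name,
    network_label, volume); row order defines node order for the run."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")
    missing = [c for c in _PARC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    ids = df["node_id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate node_id values")
    return Parcellation(
        node_ids=tuple(int(i) for i in ids),
        region_names=tuple(str(s) for s in df["region_name"]),
        network_labels=tuple(str(s) for s in df["network_label"]),
        volumes=df["volume"].to_numpy(dtype=float),
    )


def write_parcellation(parc: Parcellation, path) -> None:
    pd.DataFrame(
        {
            "node_id": parc.node_ids,
            "region_name": parc.region_names,
            "network_label": parc.network_labels,
            "volume": parc.volumes,
        }
    ).to_csv(path, sep="\t", index=False)


def read_square_matrix(path, n_nodes: int, asym_tol: float = 1e-9) -> np.ndarray:
    """Read a headerless N x N delimited matrix.

    Symmetrizes by averaging with the transpose only when the maximum
    asymmetry is within ``asym_tol``; larger asymmetry is an error.
    """
    path = Path(path)
    try:
        mat = np.loadtxt(path, delimiter=_sniff_delimiter(path), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as a numeric matrix ({exc})") from exc
    if mat.shape != (n_nodes, n_nodes):
        raise FormatError(f"{path}: expected {n_nodes}x{n_nodes}, got {mat.shape}")
    asym = np.abs(mat - mat.T).max()
    if asym > asym_tol:
        raise ValidationError(f"{path}: asymmetry {asym:.3g} exceeds tolerance {asym_tol:g}")
    return (mat + mat.T) / 2.0


def write_square_matrix(matrix: np.ndarray, path, fmt: str = "%.12g") -> None:
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt=fmt)


def write_core_report(result: "CoreResult", path) -> None:
    """Write the per-node coreness table plus a JSON configuration sidecar.

    Coreness values are written with enough digits that a round-trip read
    reproduces them to 12 significant digits.
    """
    parc = result.parcellation
    top = result.top_core
    df = pd.DataFrame(
        {
            "node_id": parc.node_ids,
            "region_name": parc.region_names,
            "network_label": parc.network_labels,
            "coreness_coefficient": result.coreness,
            "in_top_fraction": [int(i in top) for i in parc.node_ids],
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = result.config
    sidecar.write_text(
        json.dumps(
            {
                "source": result.source,
                "density_grid": list(cfg.density_grid),
                "delta_grid": list(cfg.delta_grid),
                "top_fraction": cfg.top_fraction,
                "power_iteration_tol": cfg.power_iteration_tol,
                "max_iterations": cfg.max_iterations,
                "seed": cfg.seed,
                "std_convention": "population (ddof=0)",
                "n_configurations": cfg.n_configurations,
                "top_core": sorted(top),
            },
            indent=2,
        )
    )


def read_core_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Dataset directory layout (as written by `multiplexcore synth`)
# ---------------------------------------------------------------------------

def write_dataset(directory, parc: Parcellation, obs: SubjectObservations,
                  ground_truth: dict | None = None) -> None:
    """Write a complete dataset directory in the tool's input formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_parcellation(parc, directory / "parcellation.tsv")
    if obs.timeseries is not None:
        d = directory / "timeseries"
        d.mkdir(exist_ok=True)
        for k, ts in enumerate(obs.timeseries):
            np.savetxt(d / f"sub-{k:03d}.tsv", ts, delimiter="\t", fmt="%.8g")
    if obs.uptake is not None:
        cols = [f"node_{i}" for i in parc.node_ids]
        pd.DataFrame(obs.uptake, columns=cols).to_csv(directory / "uptake.csv", index=False)
    if obs.streamline_counts is not None:
        d = directory / "streamlines"
        d.mkdir(exist_ok=True)
        for k, c in enumerate(obs.streamline_counts):
            np.savetxt(d / f"sub-{k:03d}.csv", c, delimiter=",", fmt="%d")
    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))


def read_dataset(directory) -> tuple[Parcellation, SubjectObservations]:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    parc = read_parcellation(directory / "parcellation.tsv")
    n = parc.n_nodes

    timeseries = None
    ts_dir = directory / "timeseries"
    if ts_dir.is_dir():
        files = sorted(ts_dir.iterdir())
        series = []
        for f in files:
            t = np.loadtxt(f, delimiter=_sniff_delimiter(f), ndmin=2)
            if t.shape[1] != n:
                raise FormatError(f"{f}: expected {n} columns, got {t.shape[1]}")
            series.append(t)
        timeseries = tuple(series)

    uptake = None
    up_path = directory / "uptake.csv"
    if up_path.exists():
        df = pd.read_csv(up_path, float_precision="round_trip")
        if df.shape[1] != n:
            raise FormatError(f"{up_path}: expected {n} columns, got {df.shape[1]}")
        uptake = df.to_numpy(dtype=float)

    counts = None
    sl_dir = directory / "streamlines"
    if sl_dir.is_dir():
        counts = tuple(read_square_matrix(f, n) for f in sorted(sl_dir.iterdir()))

    return parc, SubjectObservations(
        parcellation=parc,
        timeseries=timeseries,
        uptake=uptake,
        streamline_counts=counts,
    )
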
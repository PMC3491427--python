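"""Delimited-text readers/writers and run manifests.

The canonical input is a CSV/TSV matrix with rows = channels and columns =
time samples, optionally with a header row of channel labels (an
orientation flag accepts transposed files).  Outputs are a long-format
edge list (realigned time, source, target), a tidy metric table, and a
JSON manifest recording parameters and seeds.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .graphmetrics import MetricSeries
from .netbuild import NetworkSequence
from .symbolize import SymbolSequence, TimeSeriesSet

__all__ = [
    "read_timeseries",
    "write_symbols",
    "read_edge_list",
    "write_outputs",
]


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_timeseries(
    path,
    orientation: str = "channels",
    delimiter: str | None = None,
    sampling_rate: float | None = None,
) -> TimeSeriesSet:
    """Read a delimited matrix into a :class:`TimeSeriesSet`.

    ``orientation="channels"`` means rows are channels (the canonical
    layout); ``"time"`` transposes.  A first row with any non-numeric cell
    is taken as the header of channel labels.
    """
    path = Path(path)
    if orientation not in {"channels", "time"}:
        raise ValueError("orientation must be 'channels' or 'time'")
    delim = _sniff_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delim) if row and any(c.strip() for c in row)]
    if not rows:
        raise ValueError(f"{path}: file is empty")
    labels: list[str] | None = None
    if all(not _is_number(c) for c in rows[0]):
        labels = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header only, no data rows")
    # channel-major files may label rows in their first column instead
    row_labels: list[str] | None = None
    if rows and rows[0] and not _is_number(rows[0][0]):
        row_labels = [row[0].strip() for row in rows]
        rows = [row[1:] for row in rows]
    width = len(rows[0])
    data = np.empty((len(rows), width))
    for r, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: line {r + 1 + (labels is not None)} has {len(row)} "
                f"fields, expected {width}"
            )
        for c, cell in enumerate(row):
            if not _is_number(cell):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at line "
                    f"{r + 1 + (labels is not None)}, column {c + 1}"
                )
            data[r, c] = float(cell)
    if orientation == "time":
        data = data.T
        channel_labels = labels
    else:
        channel_labels = row_labels if row_labels is not None else labels
    if channel_labels is None or len(channel_labels) != data.shape[0]:
        channel_labels = [f"ch{idx}" for idx in range(data.shape[0])]
    return TimeSeriesSet(labels=channel_labels, values=data, sampling_rate=sampling_rate)


def write_symbols(sequences: list[SymbolSequence], prefix) -> tuple[Path, Path]:
    """Write symbol sequences as an integer TSV matrix plus a JSON sidecar
    with (d, tau, start_index, labels)."""
    prefix = Path(prefix)
    first = sequences[0]
    mat = np.stack([s.symbols for s in sequences])
    tsv = prefix.with_suffix(".tsv")
    np.savetxt(tsv, mat, fmt="%d", delimiter="\t")
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "d": first.d,
                "tau": first.tau,
                "start_index": first.start_index,
                "labels": [s.label for s in sequences],
            },
            indent=2,
        )
    )
    return tsv, sidecar


def _edge_frame(nets: NetworkSequence) -> pd.DataFrame:
    records = []
    for k in range(len(nets)):
        t = nets.times[k]
        for i, j in nets.edges(k):
            records.append((t, nets.labels[i], nets.labels[j]))
    return pd.DataFrame(records, columns=["time", "source", "target"])


def write_edge_list(nets: NetworkSequence, path) -> Path:
    path = Path(path)
    _edge_frame(nets).to_csv(path, sep="\t", index=False)
    return path


def read_edge_list(path, sidecar) -> NetworkSequence:
    """Reconstruct a NetworkSequence from an edge list plus its manifest.

    Edge lists omit empty networks, so the sidecar's full time axis and
    label set are required for an exact round trip.  Symbols are
    reconstructed as component labels (0-based within each time slice),
    which reproduces every adjacency matrix exactly.
    """
    meta = json.loads(Path(sidecar).read_text())
    labels = meta["labels"]
    times = np.asarray(meta["times"], dtype=float)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    edges = pd.read_csv(path, sep="\t")
    symbols = np.tile(np.arange(n, dtype=np.int64)[:, None], (1, times.size))
    # merge channels sharing an edge at each time point
    time_key = {t: k for k, t in enumerate(times)}
    for t, grp in edges.groupby("time"):
        k = time_key[float(t)]
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for _, row in grp.iterrows():
            a, b = find(index[row["source"]]), find(index[row["target"]])
            if a != b:
                parent[b] = a
        symbols[:, k] = [find(i) for i in range(n)]
    return NetworkSequence(
        symbols, times, labels, d=meta.get("d", 2), tau=meta.get("tau", 1)
    )


def write_outputs(
    nets: NetworkSequence,
    metrics: list[MetricSeries],
    manifest_extra: dict | None = None,
    outdir=".",
) -> dict[str, Path]:
    """Write the standard file set: edge list, tidy metrics, JSON manifest."""
    if len(nets) == 0:
        raise ValueError("empty network sequence: nothing to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["edges"] = write_edge_list(nets, outdir / "edges.tsv")
    if metrics:
        tidy = pd.concat(
            [
                pd.DataFrame({"time": m.times, "metric": m.name, "value": m.values})
                for m in metrics
            ],
            ignore_index=True,
        )
        tidy.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        paths["metrics"] = outdir / "metrics.tsv"
    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "n_channels": nets.n_channels,
        "n_networks": len(nets),
        "d": nets.d,
        "tau": nets.tau,
        "labels": nets.labels,
        "times": [float(t) for t in nets.times],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mpath
    return paths
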
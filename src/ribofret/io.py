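"""Reading and writing of per-molecule trace files and dataset manifests.

The canonical on-disk layout is one CSV per molecule with the header
``frame,time_s,donor,acceptor`` plus a JSON manifest listing the files in
order together with provenance (fixture name, seed, acquisition parameters,
condition labels).  CSV was chosen over a binary container so fixtures stay
human-inspectable and diff-able; intensities are stored as real numbers and
may be negative after background subtraction (no clamping at I/O time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "TraceSet",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "load_dataset",
    "write_dataset",
]

#: required CSV columns, in order
TRACE_COLUMNS = ("frame", "time_s", "donor", "acceptor")

#: tolerance on uniform frame spacing, seconds
_TIME_TOL = 1e-6


class TraceFormatError(ValueError):
    """Raised when a trace file or manifest violates the on-disk schema."""


@dataclass
class Trace:
    """Two-channel fluorescence intensity time series for one molecule.

    Attributes
    ----------
    molecule_id:
        Unique identifier within a dataset.
    time:
        Frame mid/start times in seconds, strictly increasing on a uniform
        grid of spacing ``1/frame_rate``.
    donor, acceptor:
        Cy3 (donor) and Cy5 (acceptor) intensities in camera counts.
    frame_rate:
        Acquisition rate in Hz.
    """

    molecule_id: str
    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = len(self.time)
        if not (len(self.donor) == len(self.acceptor) == n):
            raise TraceFormatError(
                f"{self.molecule_id}: channel lengths differ "
                f"(time={n}, donor={len(self.donor)}, acceptor={len(self.acceptor)})"
            )
        if n < 1:
            raise TraceFormatError(f"{self.molecule_id}: empty trace")
        if self.frame_rate <= 0:
            raise TraceFormatError(f"{self.molecule_id}: frame_rate must be > 0")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise TraceFormatError(
                    f"{self.molecule_id}: non-monotone time at row {row}"
                )
            expected = 1.0 / self.frame_rate
            bad = np.abs(dt - expected) > _TIME_TOL
            if np.any(bad):
                row = int(np.argmax(bad)) + 1
                raise TraceFormatError(
                    f"{self.molecule_id}: non-uniform time grid at row {row} "
                    f"(spacing {dt[bad][0]:.6g} s, expected {expected:.6g} s)"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def total(self) -> np.ndarray:
        """Summed donor + acceptor intensity per frame."""
        return self.donor + self.acceptor

    def truncated(self, end_frame: int) -> "Trace":
        """Copy of the trace restricted to frames ``[0, end_frame)``."""
        if end_frame < 1:
            raise ValueError("end_frame must be >= 1")
        return Trace(
            self.molecule_id,
            self.time[:end_frame],
            self.donor[:end_frame],
            self.acceptor[:end_frame],
            self.frame_rate,
        )


@dataclass
class TraceSet:
    """Ordered collection of traces plus a provenance manifest."""

    traces: list[Trace]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.molecule_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise TraceFormatError(f"duplicate molecule_id {dup!r}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)


def read_trace(path: str | Path, molecule_id: str | None = None) -> Trace:
    """Read and validate one per-molecule CSV trace file.

    Malformed rows are rejected with an error naming the offending row;
    nothing is silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    for col in TRACE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 1
            raise TraceFormatError(f"{path}: non-numeric value in '{col}' at row {row}")
        df[col] = vals
    if len(df) < 1:
        raise TraceFormatError(f"{path}: empty trace file")
    time = df["time_s"].to_numpy(float)
    if len(time) > 1:
        dt = float(np.median(np.diff(time)))
        if dt <= 0:
            raise TraceFormatError(f"{path}: non-monotone time")
        frame_rate = 1.0 / dt
    else:
        frame_rate = 1.0
    try:
        return Trace(
            molecule_id or path.stem,
            time,
            df["donor"].to_numpy(float),
            df["acceptor"].to_numpy(float),
            frame_rate,
        )
    except TraceFormatError as err:
        raise TraceFormatError(f"{path}: {err}") from None


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as schema-conformant CSV with deterministic formatting.

    Times are written with 4 decimal places and intensities with 6, so
    identical traces always yield byte-identical files.
    """
    if len(trace) < 1:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for i in range(len(trace)):
            fh.write(
                f"{i},{trace.time[i]:.4f},{trace.donor[i]:.6f},{trace.acceptor[i]:.6f}\n"
            )


def write_dataset(ts: TraceSet, out_dir: str | Path, ground_truth: dict | None = None) -> Path:
    """Write a TraceSet as one CSV per molecule plus ``manifest.json``.

    Returns the manifest path.  ``ground_truth``, if given, is written as
    ``ground_truth.json`` and referenced from the manifest.
    """
    out_dir = Path(out_dir)
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for t in ts:
        rel = f"traces/{t.molecule_id}.csv"
        write_trace(t, out_dir / rel)
        files.append(rel)
    manifest = dict(ts.manifest)
    manifest["n_molecules"] = len(ts)
    manifest["files"] = files
    if ground_truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1, sort_keys=True)
        manifest["ground_truth"] = "ground_truth.json"
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path


def load_dataset(manifest_path: str | Path) -> TraceSet:
    """Load a dataset from its manifest, preserving manifest file order.

    A listed file that does not exist is an error, never a silent skip;
    duplicate molecule ids are rejected.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    traces = []
    for rel in manifest.get("files", []):
        p = base / rel
        if not p.exists():
            raise TraceFormatError(f"manifest references missing file {p}")
        traces.append(read_trace(p))
    frame_rate = manifest.get("frame_rate_hz")
    if frame_rate:
        for t in traces:
            t.frame_rate = float(frame_rate)
    return TraceSet(traces, manifest)
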
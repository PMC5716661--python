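"""Uniformly sampled fluorescence intensity traces and their TSV dialect.

A :class:`FluorescenceTrace` is the common currency between the synthetic
generators and the fluctuation-analysis routines: a vector of intensities in
arbitrary camera units, a fixed sampling interval ``dt`` (seconds), and a
start time.  Traces are written to plain TSV with ``#``-prefixed metadata
lines so that a recording and the parameters that produced it travel
together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FluorescenceTrace", "write_traces_tsv", "read_traces_tsv"]


@dataclass
class FluorescenceTrace:
    """Intensity time series with a fixed sampling interval.

    Parameters
    ----------
    values : array of float
        Intensity per sample, arbitrary units.
    dt : float
        Sampling interval in seconds (2 ms for a 500 Hz camera).
    t0 : float
        Time of the first sample, seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total recorded time in seconds."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times (bin centers are at t0 + i*dt)."""
        return self.t0 + np.arange(self.n) * self.dt


def write_traces_tsv(path, traces: dict[str, FluorescenceTrace], metadata: dict | None = None) -> None:
    """Write one or more equal-length traces as TSV.

    Column 1 is time in seconds; one column per trace.  Metadata keys are
    stored as ``# key=value`` header lines (``dt`` is always included).
    """
    if not traces:
        raise ValueError("no traces to write")
    items = list(traces.items())
    dt = items[0][1].dt
    n = items[0][1].n
    for name, tr in items:
        if tr.n != n or tr.dt != dt:
            raise ValueError("all traces must share length and dt")
    meta = {"dt": dt}
    meta.update(metadata or {})
    frame = pd.DataFrame({"time_s": items[0][1].times})
    for name, tr in items:
        frame[name] = tr.values
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_traces_tsv(path) -> tuple[dict[str, FluorescenceTrace], dict[str, str]]:
    """Read the TSV dialect written by :func:`write_traces_tsv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    dt = float(meta["dt"])
    t0 = float(frame["time_s"].iloc[0])
    traces = {
        name: FluorescenceTrace(frame[name].to_numpy(), dt=dt, t0=t0)
        for name in frame.columns
        if name != "time_s"
    }
    return traces, meta
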
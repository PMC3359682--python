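"""Trace and spectrum exchange formats.

Two trace formats are supported:

* a 2-column delimited text file ``(time_s, amplitude)`` with ``#``-prefixed
  header lines carrying the sampling rate and generation metadata, and
* a raw little-endian float64 array with a plain-text sidecar header
  (``<path>.hdr``); this round-trips losslessly.

PSD estimates are written as 2-column text ``(frequency_hz, power)`` with
method and grid information in the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .simulate import EchoTrace
from .spectral import PSDEstimate


def _meta_to_lines(meta: dict) -> list[str]:
    return [f"meta {k} = {json.dumps(v)}" for k, v in sorted(meta.items())]


def write_trace_text(trace: EchoTrace, path: str | Path) -> None:
    """Write a trace as ``time_s  amplitude`` text with a ``#`` header."""
    header = [
        f"sampling_rate_hz = {trace.sampling_rate!r}",
        f"start_time_s = {trace.start_time!r}",
        *_meta_to_lines(dict(trace.metadata)),
    ]
    data = np.column_stack([trace.times, trace.samples])
    np.savetxt(path, data, fmt="%.17g", header="\n".join(header))


def read_trace_text(path: str | Path) -> EchoTrace:
    path = Path(path)
    meta: dict = {}
    sampling_rate = None
    start_time = 0.0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("sampling_rate_hz ="):
                sampling_rate = float(body.split("=", 1)[1])
            elif body.startswith("start_time_s ="):
                start_time = float(body.split("=", 1)[1])
            elif body.startswith("meta "):
                key, value = body[5:].split(" = ", 1)
                meta[key] = json.loads(value)
    if sampling_rate is None:
        raise ConfigurationError(f"{path}: missing sampling_rate_hz header")
    data = np.loadtxt(path)
    samples = data[:, 1] if data.ndim == 2 else data
    return EchoTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        start_time=start_time,
        metadata=meta,
    )


def write_trace_binary(trace: EchoTrace, path: str | Path) -> None:
    """Write raw float64 samples plus a ``.hdr`` text sidecar (lossless)."""
    path = Path(path)
    trace.samples.astype("<f8").tofile(path)
    header = {
        "n_samples": int(len(trace)),
        "dtype": "<f8",
        "sampling_rate_hz": trace.sampling_rate,
        "start_time_s": trace.start_time,
        "metadata": dict(trace.metadata),
    }
    path.with_suffix(path.suffix + ".hdr").write_text(
        json.dumps(header, indent=1, sort_keys=True)
    )


def read_trace_binary(path: str | Path) -> EchoTrace:
    path = Path(path)
    header_path = path.with_suffix(path.suffix + ".hdr")
    if not header_path.exists():
        raise ConfigurationError(f"missing sidecar header {header_path}")
    header = json.loads(header_path.read_text())
    samples = np.fromfile(path, dtype=header["dtype"])
    if samples.size != header["n_samples"]:
        raise ConfigurationError(
            f"{path}: expected {header['n_samples']} samples, found {samples.size}"
        )
    return EchoTrace(
        samples=samples,
        sampling_rate=header["sampling_rate_hz"],
        start_time=header.get("start_time_s", 0.0),
        metadata=header.get("metadata", {}),
    )


def write_psd_text(
    psd: PSDEstimate, path: str | Path, method: str = "", order: int | None = None,
    ni: int | None = None,
) -> None:
    """Write a PSD as ``frequency_hz  power`` text with grid metadata."""
    header = [
        f"method = {method}",
        f"order = {order}",
        f"ni = {ni}",
        f"nf = {psd.source_length}",
        f"grid_step_hz = {psd.grid_step!r}",
    ]
    data = np.column_stack([psd.frequencies, psd.power])
    np.savetxt(path, data, fmt="%.17g", header="\n".join(header))
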
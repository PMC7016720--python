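"""Readers/writers for traces, protocols, parameters, landscapes and reports.

All files are plain text. Units are fixed in the headers: time s, voltage
mV, temperature °C, current pA, conductance nS. Parameter documents are
YAML or JSON keyed by extension; analysis reports are JSON with provenance
(package version, seed, input hashes).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gating import PoLandscape
from .kinetics import OccupancyTrace, StimulusProtocol, protocol_from_rows
from .parameters import GatingParameters

TRACE_COLUMNS = ("time_s", "voltage_mv", "temperature_c", "current_pa")
PROTOCOL_COLUMNS = ("duration_s", "voltage_mv", "temp_start_c", "temp_end_c")

#: significant digits preserved by trace round-trips
_FLOAT_FMT = "%.12g"


class TraceFormatError(ValueError):
    """Malformed trace/protocol file (message carries column/line context)."""


def _atomic_write(path, write_fn):
    """Write via a temp file + rename so partial outputs never appear."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- traces ----------------------------------------------------------------

def write_trace(trace, path):
    """Write a recording as CSV (time_s, voltage_mv, temperature_c, current_pa).

    Accepts a :class:`~thermogate.synth.SyntheticRecording`, an
    :class:`OccupancyTrace` (current column zero) or a DataFrame with the
    trace columns.
    """
    if isinstance(trace, pd.DataFrame):
        df = trace[list(TRACE_COLUMNS)]
    elif isinstance(trace, OccupancyTrace):
        df = pd.DataFrame({
            "time_s": trace.times_s, "voltage_mv": trace.voltage_mv,
            "temperature_c": trace.temperature_c,
            "current_pa": np.zeros_like(trace.times_s),
        })
    else:
        df = pd.DataFrame({
            "time_s": trace.time_s, "voltage_mv": trace.voltage_mv,
            "temperature_c": trace.temperature_c, "current_pa": trace.current_pa,
        })
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False, float_format=_FLOAT_FMT))


def read_trace(path, chunksize: int = 100_000) -> pd.DataFrame:
    """Read a trace CSV, validating columns and time monotonicity.

    The file is parsed in bounded-size chunks so arbitrarily long
    recordings stream through fixed parser memory.
    """
    chunks = []
    last_t = -np.inf
    row_offset = 0
    try:
        reader = pd.read_csv(path, chunksize=chunksize)
    except FileNotFoundError:
        raise
    for chunk in reader:
        missing = [c for c in TRACE_COLUMNS if c not in chunk.columns]
        if missing:
            raise TraceFormatError(
                f"{path}: missing required column(s) {missing}; "
                f"found {list(chunk.columns)}"
            )
        if not len(chunk):
            continue
        t = chunk["time_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(np.concatenate([[last_t], t])) <= 0)
        if bad.size:
            line = row_offset + int(bad[0]) + 2  # +1 header, +1 one-based
            raise TraceFormatError(f"{path}: non-monotone time_s at line {line}")
        last_t = t[-1]
        row_offset += len(chunk)
        chunks.append(chunk[list(TRACE_COLUMNS)])
    if not chunks:
        raise TraceFormatError(f"{path}: empty trace file")
    return pd.concat(chunks, ignore_index=True)


# -- protocols -------------------------------------------------------------

def write_protocol(protocol: StimulusProtocol, path):
    df = pd.DataFrame(
        [(s.duration_s, s.voltage_mv, s.temp_start_c, s.temp_end_c)
         for s in protocol.segments],
        columns=list(PROTOCOL_COLUMNS),
    )
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False, float_format=_FLOAT_FMT))


def read_protocol(path, dt_s: float) -> StimulusProtocol:
    df = pd.read_csv(path)
    missing = [c for c in PROTOCOL_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing protocol column(s) {missing}")
    return protocol_from_rows(df[list(PROTOCOL_COLUMNS)].to_numpy(), dt_s=dt_s)


# -- parameter documents ---------------------------------------------------

def write_params(params: GatingParameters, path):
    """Serialize a gating-parameter set as YAML or JSON (by extension)."""
    d = params.to_dict()
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        _atomic_write(path, lambda fh: yaml.safe_dump(d, fh, sort_keys=False))
    else:
        _atomic_write(path, lambda fh: json.dump(d, fh, indent=2))


def read_params(path, normalize_z: bool = True) -> GatingParameters:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    return GatingParameters.from_dict(d, normalize_z=normalize_z)


# -- landscapes ------------------------------------------------------------

def write_landscape(ls: PoLandscape, path):
    """CSV matrix: header row of voltages (mV), first column temperatures (°C)."""
    df = pd.DataFrame(ls.po, columns=[f"{v:g}" for v in ls.voltages_mv])
    df.insert(0, "temperature_c\\voltage_mv", ls.temperatures_c)
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False, float_format=_FLOAT_FMT))


def read_landscape_matrix(path):
    """Return (voltages_mv, temperatures_c, po) from a landscape CSV."""
    df = pd.read_csv(path)
    temps = df.iloc[:, 0].to_numpy(dtype=float)
    volts = np.array([float(c) for c in df.columns[1:]])
    return volts, temps, df.iloc[:, 1:].to_numpy(dtype=float)


# -- reports ---------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_report(results: dict, path, seed=None, inputs=()):
    """JSON analysis report with units metadata and provenance."""
    from . import __version__

    doc = {
        "results": results,
        "provenance": {
            "package": "thermogate",
            "version": __version__,
            "seed": seed,
            "input_hashes": {str(p): file_sha256(p) for p in inputs},
        },
    }
    _atomic_write(path, lambda fh: json.dump(doc, fh, indent=2, default=float))


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
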
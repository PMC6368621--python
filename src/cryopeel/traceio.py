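"""Plain-text trace serialization.

Canonical dialect: tab-separated values with a '#'-prefixed header declaring
the columns and units (Z_nm, F_nN, k_Npm, dfreq_Hz, ...) plus a key-value
metadata block riding the same header.  CSV is accepted on read.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .trace import CHANNELS, Trace

_COLUMN_NAMES = {
    "F": "F_nN",
    "k": "k_Npm",
    "dfreq": "dfreq_Hz",
    "energy": "E_nNnm",
    "dissipation": "D_nNnm",
    "n_adsorbed": "n_adsorbed",
    "zP": "zP_nm",
}
_NAME_TO_CHANNEL = {v: c for c, v in _COLUMN_NAMES.items()}


def write_trace(trace: Trace, path, dialect: str = "tsv", precision: int = 17) -> None:
    """Write a trace as delimited text; lossless at the default precision."""
    if dialect not in ("tsv", "csv"):
        raise InvalidParameterError("dialect must be 'tsv' or 'csv'")
    sep = "\t" if dialect == "tsv" else ","
    cols = ["Z_nm"] + [_COLUMN_NAMES[c] for c in trace.channels()]
    lines = ["# cryopeel trace (lengths nm, forces nN, stiffness N/m, frequency Hz)"]
    lines.append("# columns: " + " ".join(cols))
    for key in sorted(trace.meta):
        lines.append(f"# meta: {key} = {trace.meta[key]!r}")
    fmt = f"%.{precision}g"
    data = np.column_stack([trace.Z] + list(trace.channels().values()))
    for row in data:
        lines.append(sep.join(fmt % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_meta(value: str):
    value = value.strip()
    if value.startswith(("'", '"')) and value.endswith(("'", '"')):
        return value[1:-1]
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def read_trace(path, dialect: str = "tsv") -> Trace:
    """Read a trace written by :func:`write_trace` (round trip is bit-exact).

    Raises :class:`FormatError` on a non-monotone Z column (with the line
    number of the offending sample) or a missing Z column.
    """
    if dialect not in ("tsv", "csv"):
        raise InvalidParameterError("dialect must be 'tsv' or 'csv'")
    sep = "\t" if dialect == "tsv" else ","
    text = Path(path).read_text()
    meta: dict = {}
    columns: list[str] | None = None
    data_lines: list[str] = []
    first_data_lineno = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("columns:"):
                columns = body[len("columns:") :].split()
            elif body.startswith("meta:"):
                key, _, val = body[len("meta:") :].partition("=")
                meta[key.strip()] = _parse_meta(val)
            continue
        if first_data_lineno is None:
            first_data_lineno = lineno
        data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(
        io.StringIO("\n".join(data_lines)),
        sep=sep,
        header=None,
        float_precision="round_trip",
    )
    if columns is None:
        # bare two-column file: assume Z then F
        columns = ["Z_nm", "F_nN"][: df.shape[1]]
    if len(columns) != df.shape[1]:
        raise FormatError(
            f"{path}: header declares {len(columns)} columns, rows have {df.shape[1]}"
        )
    df.columns = columns
    if "Z_nm" not in columns:
        raise FormatError(f"{path}: missing required column Z_nm")
    z = df["Z_nm"].to_numpy(dtype=float)
    bad = np.where(np.diff(z) <= 0)[0]
    if len(bad):
        raise FormatError(
            f"{path}: Z not strictly increasing at line "
            f"{first_data_lineno + int(bad[0]) + 1}"
        )
    kwargs = {}
    for name in columns:
        if name == "Z_nm":
            continue
        ch = _NAME_TO_CHANNEL.get(name)
        if ch in CHANNELS:
            kwargs[ch] = df[name].to_numpy(dtype=float)
    return Trace(Z=z, meta=meta, **kwargs)
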
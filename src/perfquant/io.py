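"""Plain-text formats: ROI curves as CSV, configs as YAML/JSON.

Curves travel as two-column CSV (``time_s,value``) and PET TACs as
three-column CSV (``frame_start_s,frame_duration_s,mean_activity``); the
unit and any provenance (config hash, seed) ride in leading ``#`` comment
lines so a file is self-describing and regenerable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .curves import FramedTAC, FrameScheme, InvalidInputError, SampledCurve

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "write_tac_csv",
    "config_hash",
    "load_config",
]

CURVE_COLUMNS = ("time_s", "value")
TAC_COLUMNS = ("frame_start_s", "frame_duration_s", "mean_activity")


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def _comment_block(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_curve_csv(path, curve: SampledCurve, meta: dict | None = None) -> None:
    path = Path(path)
    header = {"unit": curve.unit, **(meta or {})}
    with open(path, "w") as fh:
        fh.write(_comment_block(header))
        fh.write(",".join(CURVE_COLUMNS) + "\n")
        for t, v in zip(curve.times, curve.values):
            fh.write(f"{t:.10g},{v:.10g}\n")


def write_tac_csv(path, tac: FramedTAC, meta: dict | None = None) -> None:
    path = Path(path)
    header = {
        "unit": tac.unit,
        "decay_corrected": str(tac.decay_corrected).lower(),
        "reference_time_s": f"{tac.reference_time:.10g}",
        **(meta or {}),
    }
    with open(path, "w") as fh:
        fh.write(_comment_block(header))
        fh.write(",".join(TAC_COLUMNS) + "\n")
        for s, d, a in zip(tac.scheme.starts, tac.scheme.durations, tac.mean_activity):
            fh.write(f"{s:.10g},{d:.10g},{a:.10g}\n")


def read_curve_csv(path) -> SampledCurve | FramedTAC:
    """Read a curve or TAC CSV, dispatching on the header columns.

    Raises a parse error naming the offending line for malformed rows and a
    validation error for invariant violations (e.g. non-increasing times).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such curve file: {path}")
    meta = _header_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InvalidInputError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = tuple(df.columns)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header line + 1-based
            raise InvalidInputError(f"{path}: malformed value in column {col!r} at data line {row}")
    if cols == CURVE_COLUMNS:
        unit = meta.get("unit", "1")
        try:
            return SampledCurve(df["time_s"].to_numpy(float), df["value"].to_numpy(float), unit)
        except InvalidInputError as exc:
            raise InvalidInputError(f"{path}: {exc}") from exc
    if cols == TAC_COLUMNS:
        scheme = FrameScheme(df["frame_start_s"].to_numpy(float),
                             df["frame_duration_s"].to_numpy(float))
        return FramedTAC(
            scheme,
            df["mean_activity"].to_numpy(float),
            decay_corrected=meta.get("decay_corrected", "false") == "true",
            reference_time=float(meta.get("reference_time_s", scheme.starts[0])),
            unit=meta.get("unit", "kBq/mL"),
        )
    raise InvalidInputError(
        f"{path}: unrecognized columns {cols}; expected {CURVE_COLUMNS} or {TAC_COLUMNS}"
    )


def load_config(path) -> dict:
    """Load a YAML or JSON configuration document."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")
    return doc
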
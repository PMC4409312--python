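"""CSV/JSON interchange for curves, fits and configurations.

Curves round-trip through plain UTF-8 CSV (comma-separated, '.' decimal,
mandatory header row); missing values are encoded as empty fields. A JSON
sidecar (``<name>.json`` next to ``<name>.csv``) carries the metadata
needed to regenerate the curve: protocol name, configuration, model
parameters and seeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import pandas as pd

from .protocols import CurveData, ProtocolConfig

__all__ = ["write_curve", "read_curve", "write_json", "read_json"]


class CurveFormatError(ValueError):
    pass


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, ProtocolConfig):
        d = dataclasses.asdict(obj)
        d["step_amplitudes"] = np.asarray(d["step_amplitudes"]).tolist()
        return d
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in
                dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2,
                                     default=str))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_curve(curve: CurveData, path, sidecar: bool = True) -> None:
    """Write a curve as CSV (+ JSON sidecar with its metadata).

    Values survive the round trip to at least 12 significant digits
    (full-precision repr is written); NaN becomes an empty field.
    """
    path = Path(path)
    curve.to_frame().to_csv(path, index=False, na_rep="")
    if sidecar:
        meta = dict(curve.meta)
        meta["xlabel"] = curve.xlabel
        meta["ylabel"] = curve.ylabel
        cfg = meta.get("config")
        if cfg is not None and hasattr(cfg, "__dataclass_fields__"):
            meta["config"] = _jsonable(cfg)
        write_json(meta, path.with_suffix(".json"))


def read_curve(path) -> CurveData:
    """Read a curve written by :func:`write_curve`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CurveFormatError(
            f"{path}: need at least two columns, got {list(df.columns)}")
    xlabel, ylabel = df.columns[0], df.columns[1]
    for col in (xlabel, ylabel):
        try:
            float(col)
        except ValueError:
            continue
        raise CurveFormatError(
            f"{path}: numeric header field {col!r} — header row missing?")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    y_repeats = df[rep_cols].to_numpy() if rep_cols else None
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = read_json(sidecar)
        meta.pop("xlabel", None)
        meta.pop("ylabel", None)
    return CurveData(x=df[xlabel].to_numpy(dtype=float),
                     y=df[ylabel].to_numpy(dtype=float),
                     y_repeats=y_repeats, xlabel=xlabel, ylabel=ylabel,
                     meta=meta)
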
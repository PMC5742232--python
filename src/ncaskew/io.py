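"""Reading bivariate tables and writing result artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .errors import InputDataError
from .nca import XYDataset

__all__ = ["read_xy_table", "provenance", "write_json"]

logger = logging.getLogger(__name__)


def _resolve_column(df: pd.DataFrame, col: Union[str, int]) -> str:
    if isinstance(col, int) or (isinstance(col, str) and col.isdigit()
                                and col not in df.columns):
        idx = int(col)
        if not 0 <= idx < df.shape[1]:
            raise InputDataError(f"column index {idx} out of range")
        return df.columns[idx]
    if col not in df.columns:
        raise InputDataError(f"column not found: {col!r} "
                             f"(available: {list(df.columns)})")
    return str(col)


def read_xy_table(path: Union[str, Path], x_col: Union[str, int] = 0,
                  y_col: Union[str, int] = 1,
                  delimiter: Optional[str] = None) -> XYDataset:
    """Read predictor/outcome columns from a delimited text file.

    The delimiter is inferred from the extension (``.tsv`` -> tab,
    otherwise comma) unless given explicitly. Columns may be named or
    0-based indices. Rows with missing or non-numeric entries in either
    column are dropped with a logged count.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # noqa: BLE001 - surface as input error
        raise InputDataError(f"cannot read {path}: {exc}") from exc
    xc = _resolve_column(df, x_col)
    yc = _resolve_column(df, y_col)
    xs = pd.to_numeric(df[xc], errors="coerce")
    ys = pd.to_numeric(df[yc], errors="coerce")
    ok = xs.notna() & ys.notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d rows with missing/non-numeric values", dropped)
    if ok.sum() < 3:
        raise InputDataError(f"insufficient data: {int(ok.sum())} usable rows "
                             "(need at least 3)")
    return XYDataset(xs[ok].to_numpy(), ys[ok].to_numpy())


def provenance(seed: Optional[int] = None, **config) -> dict:
    """Provenance block embedded in every output artifact."""
    cfg = dict(sorted(config.items()))
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return {"version": __version__, "seed": seed, "config": cfg,
            "config_hash": digest}


def write_json(path: Union[str, Path], payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
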
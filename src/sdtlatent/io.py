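"""CSV schemas: response tables in, measure tables out.

All files are UTF-8, comma-delimited, header row required, dot decimal
separator regardless of locale.  Responses are long format — one row per
scored trial — so incomplete designs and mixed m are just absent rows and
per-item constants.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .estimation import ItemEstimate, PersonEstimate, validate_responses

__all__ = [
    "read_responses",
    "write_responses",
    "write_items",
    "write_persons",
    "read_config",
]

RESPONSE_COLUMNS = ["person_id", "item_id", "m", "score"]


def read_responses(path) -> pd.DataFrame:
    """Read and validate a response CSV (person_id,item_id,m,score)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"person_id": str, "item_id": str},
                         comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header must contain {RESPONSE_COLUMNS}, missing {missing}")
    for col in ("m", "score"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric {col} at line {line}")
    try:
        return validate_responses(df[RESPONSE_COLUMNS])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_responses(df: pd.DataFrame, path) -> None:
    validate_responses(df)[RESPONSE_COLUMNS].to_csv(path, index=False)


def write_items(items: Sequence[ItemEstimate], path) -> None:
    """Write the item measure table (measures to 6 decimals)."""
    df = pd.DataFrame(
        [(i.item_id, i.m, i.n_correct, i.n_total, i.b, i.ci_low, i.ci_high,
          int(i.degenerate_flag)) for i in items],
        columns=["item_id", "m", "n_correct", "n_total", "b", "ci_low",
                 "ci_high", "degenerate_flag"],
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_persons(persons: Sequence[PersonEstimate], path) -> None:
    """Write the person measure table (measures to 6 decimals)."""
    df = pd.DataFrame(
        [(p.person_id, p.n_items, p.theta, p.se, int(p.degenerate_flag))
         for p in persons],
        columns=["person_id", "n_items", "theta", "se", "degenerate_flag"],
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_config(path) -> dict[str, str]:
    """Parse a plain key=value config file (comments with #, blank lines ok)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
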
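"""Table rendering and round-trip-safe TSV/JSON output.

Conventions: percentages are rendered to 2 decimals in display tables and
allele frequencies to 5 decimals (matching the published table layout), but
machine outputs keep full precision (12 significant digits), so files
re-parse to the in-process values.  Outputs carry no timestamps: the same
configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "fmt_percent",
    "fmt_freq",
    "write_tsv",
    "read_tsv",
    "write_json",
    "read_json",
    "render_table2",
]


def fmt_percent(p: float) -> str:
    return "" if p is None or (isinstance(p, float) and np.isnan(p)) else f"{100 * p:.2f}%"


def fmt_freq(c: float) -> str:
    return f"{c:.5f}"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else float(f"{f:.12g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def render_table2(df: pd.DataFrame) -> str:
    """Human-readable family/twin table: percents to 2 decimals, allele
    frequencies to 5, one row per locus count."""
    cols = ["RxR", "RxL", "LxL", "RR", "RL", "LL"]
    lines = ["N_loci\tc_i\t" + "\t".join(cols)]
    for _, row in df.iterrows():
        cells = [str(int(row["n_loci"])), fmt_freq(row["c"])]
        cells += [fmt_percent(row[col]) for col in cols]
        lines.append("\t".join(cells))
    return "\n".join(lines)
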
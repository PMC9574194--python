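"""Reading and writing the package's delimited-text interchange formats.

The canonical input is a long-format CSV with header ``period,pollutant,value``
(UTF-8). Pollutant codes must match the canonical enum; periods may be years
or any sortable labels. Reports are written as CSV and/or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .aqi import POLLUTANTS, ConcentrationSeries
from .errors import ValidationError

__all__ = ["read_long_csv", "panel_to_frame", "write_report"]

REQUIRED_COLUMNS = ("period", "pollutant", "value")


def read_long_csv(path: str | Path) -> dict[str, ConcentrationSeries]:
    """Parse a long-format CSV into one ConcentrationSeries per pollutant.

    Raises :class:`ValidationError` with the offending line for malformed
    rows, unknown pollutant codes or negative values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    unknown = sorted(set(df["pollutant"]) - set(POLLUTANTS))
    if unknown:
        raise ValidationError(f"{path}: unknown pollutant codes {unknown}")
    bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
    if not bad.empty:
        lines = [int(i) + 2 for i in bad.index[:5]]  # +2: header + 0-base
        raise ValidationError(f"{path}: non-numeric values at lines {lines}")
    df["value"] = df["value"].astype(float)

    out: dict[str, ConcentrationSeries] = {}
    for code, grp in df.groupby("pollutant", sort=False):
        grp = grp.sort_values("period")
        out[str(code)] = ConcentrationSeries(
            POLLUTANTS[str(code)],
            tuple(grp["period"]),
            tuple(grp["value"]),
        )
    return out


def panel_to_frame(panel: Mapping[str, ConcentrationSeries]) -> pd.DataFrame:
    """Long-format frame (period, pollutant, value) from a panel."""
    rows = [
        {"period": p, "pollutant": code, "value": v}
        for code, series in panel.items()
        for p, v in zip(series.periods, series.values)
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_report(
    records: list[dict], out_dir: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write a list of flat record dicts as ``<stem>.csv`` and ``<stem>.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    pd.DataFrame(records).to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(records, indent=2, default=str) + "\n")
    return csv_path, json_path
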
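"""Tidy CSV interchange for degradation and dose-response tables.

Formats (RFC-4180, UTF-8, "." decimal):

* degradation: columns ``analyte, temperature_C, time_min, replicate, response``
* dose-response: columns ``enzyme, concentration_ug_mL, replicate, inhibition_pct``
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .bioassay import DosePoint, DoseResponseSeries
from .errors import ParseError
from .kinetics import DegradationSeries, Observation

logger = logging.getLogger(__name__)

DEGRADATION_COLUMNS = ["analyte", "temperature_C", "time_min", "replicate", "response"]
DOSE_COLUMNS = ["enzyme", "concentration_ug_mL", "replicate", "inhibition_pct"]


def _roundtrip_repr(value) -> str:
    """Shortest decimal string that parses back to the same float."""
    return repr(float(value))


def degradation_to_frame(series: Sequence[DegradationSeries]) -> pd.DataFrame:
    rows = [
        (s.analyte, s.temperature_c, o.time_min, o.replicate, o.response)
        for s in series
        for o in s.observations
    ]
    return pd.DataFrame(rows, columns=DEGRADATION_COLUMNS)


def write_degradation_csv(series: Sequence[DegradationSeries], path: str | Path) -> None:
    # shortest round-trip repr so write->read preserves values exactly
    degradation_to_frame(series).to_csv(path, index=False, float_format=_roundtrip_repr)


def _load_table(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty input file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at row(s) "
                f"{[int(i) + 2 for i in bad[:5]]}"
            )
        if converted.isna().any():
            raise ParseError(f"{path}: missing value in column {col!r}")
        df[col] = converted
    return df


def read_timeseries_csv(path: str | Path) -> list[DegradationSeries]:
    """Read a tidy degradation CSV into validated series.

    Rows are grouped by (analyte, temperature). Duplicate
    (analyte, temperature, time, replicate) keys are a parse error; negative
    responses are flagged with a warning naming the row but still loaded (the
    kinetic fit excludes them later); a missing t=0 time point only warns,
    because the free-intercept fit does not require it.
    """
    df = _load_table(
        path, DEGRADATION_COLUMNS, ["temperature_C", "time_min", "replicate", "response"]
    )
    dup = df.duplicated(subset=["analyte", "temperature_C", "time_min", "replicate"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise ParseError(f"{path}: duplicate (analyte, T, t, replicate) at row(s) {rows}")
    neg = df.index[df["response"] <= 0]
    for i in neg:
        logger.warning(
            "%s: non-positive response at row %d (excluded from log-linear fits)",
            path, int(i) + 2,
        )
    out: list[DegradationSeries] = []
    for (analyte, temp), grp in df.groupby(["analyte", "temperature_C"], sort=True):
        if 0.0 not in set(grp["time_min"]):
            logger.warning(
                "%s: no t=0 point for %s at %g°C; free-intercept fit proceeds",
                path, analyte, temp,
            )
        obs = [
            Observation(float(r.time_min), float(r.response), int(r.replicate))
            for r in grp.itertuples()
        ]
        out.append(DegradationSeries(str(analyte), float(temp), obs))
    return out


def dose_response_to_frame(series: Sequence[DoseResponseSeries]) -> pd.DataFrame:
    rows = [
        (s.enzyme, p.concentration, p.replicate, p.inhibition_pct)
        for s in series
        for p in s.points
    ]
    return pd.DataFrame(rows, columns=DOSE_COLUMNS)


def write_dose_response_csv(series: Sequence[DoseResponseSeries], path: str | Path) -> None:
    dose_response_to_frame(series).to_csv(path, index=False, float_format=_roundtrip_repr)


def read_dose_response_csv(path: str | Path) -> list[DoseResponseSeries]:
    """Read a tidy dose-response CSV, grouped by enzyme."""
    df = _load_table(
        path, DOSE_COLUMNS, ["concentration_ug_mL", "replicate", "inhibition_pct"]
    )
    out: list[DoseResponseSeries] = []
    for enzyme, grp in df.groupby("enzyme", sort=True):
        pts = [
            DosePoint(float(r.concentration_ug_mL), float(r.inhibition_pct), int(r.replicate))
            for r in grp.itertuples()
        ]
        out.append(DoseResponseSeries(enzyme=str(enzyme), points=pts))
    return out
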
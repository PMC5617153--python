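"""Case-file schema, CSV I/O, validation, anomaly filtering and catch summaries.

A *case* is one site-hour of trap sampling: the meteorological and temporal
covariates measured at the site's weather station plus the pooled count of
each species over the site's traps for that hour.  Case files are plain CSV
with a fixed header; covariates may be missing (empty cells), counts may
not.  Site-days on which a trap fault occurred are excluded from all
modelling views, and biologically implausible positive catches (container
carryover) are flagged and zeroed in the modelling view while the raw
counts are retained for reporting.
"""

from __future__ import annotations

import decimal
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SPECIES: tuple[str, ...] = ("hylurgus", "hylastes", "arhopalus")

#: exact CSV header, in order
CASEFILE_COLUMNS: tuple[str, ...] = (
    "site",
    "date",
    "hour_start",
    "day_of_year",
    "t_sunrise_min",
    "t_sunset_min",
    "max_temp_c",
    "temp_range_c",
    "wind_ms",
    "rh_pct",
    "par_umol",
    "rain_mm",
    "count_hylurgus",
    "count_hylastes",
    "count_arhopalus",
    "fault",
)

#: continuous covariates available to the classifier
COVARIATES: tuple[str, ...] = (
    "day_of_year",
    "t_sunrise_min",
    "t_sunset_min",
    "max_temp_c",
    "temp_range_c",
    "wind_ms",
    "rh_pct",
    "par_umol",
    "rain_mm",
)


class SchemaError(ValueError):
    """Case-file header or column types do not match the schema."""


class IntegrityError(ValueError):
    """Duplicate (site, date, hour_start) keys or other structural damage."""


@dataclass
class CaseFile:
    """Ordered collection of hourly cases with provenance metadata.

    ``data`` holds one row per (site, date, hour_start).  Anomaly flag
    columns ``anomaly_<species>`` are added by :func:`flag_anomalies`; the
    *modelling view* (:meth:`modelling_counts`) zeroes flagged catches.
    """

    data: pd.DataFrame
    species: tuple[str, ...] = SPECIES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate(self.data, self.species)

    def __len__(self) -> int:
        return len(self.data)

    def modelling_counts(self, species: str) -> pd.Series:
        """Counts with anomalous catches zeroed (raw counts if never flagged)."""
        counts = self.data[f"count_{species}"].copy()
        flag_col = f"anomaly_{species}"
        if flag_col in self.data.columns:
            counts[self.data[flag_col]] = 0
        return counts

    def flight_flags(self, species: str) -> pd.Series:
        """Boolean flight target: at least one individual caught in the hour."""
        return self.modelling_counts(species) >= 1

    def copy(self) -> "CaseFile":
        return CaseFile(self.data.copy(), self.species, dict(self.meta))


def _validate(df: pd.DataFrame, species: Iterable[str]) -> None:
    missing = [c for c in CASEFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"case file missing columns: {missing}")
    for sp in species:
        col = df[f"count_{sp}"]
        if col.isna().any():
            raise ValueError(f"count_{sp} has missing values; counts are mandatory")
        if (col < 0).any():
            raise ValueError(f"count_{sp} has negative entries")
        if not np.allclose(col, np.round(col)):
            raise ValueError(f"count_{sp} has non-integer entries")
    dup = df.duplicated(subset=["site", "date", "hour_start"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["site", "date", "hour_start"]].tolist()
        raise IntegrityError(f"duplicate case key {key}")
    if ((df["hour_start"] < 0) | (df["hour_start"] > 23)).any():
        raise ValueError("hour_start outside 0-23")
    for col, lo, hi in [
        ("temp_range_c", 0, None),
        ("wind_ms", 0, None),
        ("par_umol", 0, None),
        ("rain_mm", 0, None),
        ("rh_pct", 0, 100),
    ]:
        vals = df[col].dropna()
        if (vals < lo).any() or (hi is not None and (vals > hi).any()):
            raise ValueError(f"{col} outside valid range")


def read_casefile(path) -> CaseFile:
    """Read and validate a case-file CSV.

    Empty cells are allowed for covariates only and become NaN; a malformed
    header raises :class:`SchemaError`, a negative count :class:`ValueError`
    and a duplicate key :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype={"site": str, "date": str})
    if list(df.columns)[: len(CASEFILE_COLUMNS)] != list(CASEFILE_COLUMNS):
        raise SchemaError(
            f"unexpected header {list(df.columns)}; expected {list(CASEFILE_COLUMNS)}"
        )
    for sp in SPECIES:
        if df[f"count_{sp}"].isna().any():
            raise ValueError(f"count_{sp} has empty cells; counts are mandatory")
        df[f"count_{sp}"] = df[f"count_{sp}"].astype(int)
    df["fault"] = df["fault"].astype(bool)
    for col in ("hour_start", "day_of_year"):
        df[col] = df[col].astype(int)
    return CaseFile(df, SPECIES, {"source": str(path)})


def write_casefile(cf: CaseFile, path) -> None:
    """Write the case file as CSV (reals at 12 significant digits)."""
    out = cf.data[list(CASEFILE_COLUMNS)].copy()
    out["fault"] = out["fault"].astype(int)
    out.to_csv(path, index=False)  # shortest round-trip repr: bit-exact reals


def exclude_fault_days(cf: CaseFile) -> CaseFile:
    """Drop every case of any (site, date) that contains a trap fault.

    Idempotent: the result contains no fault flags, so re-applying it is the
    identity.
    """
    df = cf.data
    faulted = df.loc[df["fault"], ["site", "date"]].drop_duplicates()
    if faulted.empty:
        return cf.copy()
    keys = set(map(tuple, faulted.itertuples(index=False)))
    keep = ~df.apply(lambda r: (r["site"], r["date"]) in keys, axis=1)
    out = df[keep].reset_index(drop=True)
    meta = dict(cf.meta)
    meta["fault_days_removed"] = int(len(keys))
    return CaseFile(out, cf.species, meta)


@dataclass
class AnomalyRules:
    """Plausibility rules for positive catches.

    Scolytids do not fly at near-freezing temperatures, so a positive catch
    below ``min_temp_c`` for those species indicates container carryover.
    The nocturnal cerambycid is never active in bright daylight, so a
    positive catch above ``par_ceiling_umol`` is likewise implausible.
    """

    min_temp_c: Mapping[str, float] = field(
        default_factory=lambda: {"hylurgus": 5.0, "hylastes": 5.0}
    )
    par_ceiling_umol: Mapping[str, float] = field(
        default_factory=lambda: {"arhopalus": 500.0}
    )


def flag_anomalies(cf: CaseFile, rules: AnomalyRules | None = None):
    """Flag positive catches violating plausibility rules.

    Returns ``(flagged_casefile, report)``: the case file gains boolean
    ``anomaly_<species>`` columns feeding the modelling view, and the report
    is a JSON-serializable list of ``{site, date, hour_start, species,
    rule}`` records.  Raw counts are untouched.
    """
    rules = rules or AnomalyRules()
    out = cf.copy()
    report: list[dict] = []
    for sp in cf.species:
        flags = pd.Series(False, index=out.data.index)
        positive = out.data[f"count_{sp}"] > 0
        tmin = rules.min_temp_c.get(sp)
        if tmin is not None:
            hit = positive & (out.data["max_temp_c"] < tmin)
            flags |= hit.fillna(False)
            for _, row in out.data[hit.fillna(False)].iterrows():
                report.append(
                    {
                        "site": row["site"],
                        "date": row["date"],
                        "hour_start": int(row["hour_start"]),
                        "species": sp,
                        "rule": f"max_temp_c < {tmin}",
                    }
                )
        pmax = rules.par_ceiling_umol.get(sp)
        if pmax is not None:
            hit = positive & (out.data["par_umol"] > pmax)
            flags |= hit.fillna(False)
            for _, row in out.data[hit.fillna(False)].iterrows():
                report.append(
                    {
                        "site": row["site"],
                        "date": row["date"],
                        "hour_start": int(row["hour_start"]),
                        "species": sp,
                        "rule": f"par_umol > {pmax}",
                    }
                )
        out.data[f"anomaly_{sp}"] = flags.to_numpy()
    out.meta["anomaly_report"] = report
    return out, report


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero to the printed precision."""
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def summarize_positive_hours(cf: CaseFile, species: str) -> dict:
    """Positive trap-catch hours under the modelling view.

    ``pct`` is 100 * n_positive / n_hours; ``pct_rounded`` rounds half-up to
    the nearest integer, the precision at which such rates are reported.
    """
    if len(cf) == 0:
        raise ValueError("empty case file")
    if species not in cf.species:
        raise KeyError(species)
    n_hours = len(cf)
    n_positive = int(cf.flight_flags(species).sum())
    pct = 100.0 * n_positive / n_hours
    return {
        "n_hours": n_hours,
        "n_positive": n_positive,
        "pct": pct,
        "pct_rounded": round_half_up(pct),
    }


def casefile_hash(cf: CaseFile) -> str:
    """Stable content hash used for provenance manifests."""
    payload = cf.data[list(CASEFILE_COLUMNS)].to_csv(index=False)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def flag_report_json(report: list[dict]) -> str:
    return json.dumps(report, indent=2)
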
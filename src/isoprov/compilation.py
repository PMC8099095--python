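"""Collagen δ³⁴S compilation: ingestion, quality screening, site averaging.

Archaeological collagen δ³⁴S compilations mix records of very uneven
reporting quality. Before an isoscape can be fitted, records are screened
for collagen preservation (atomic C/S < 300 and N/S < 100), for published
diagenesis or contamination notes, for individuals explicitly designated
non-local (origin > 100 km away), and for aquatic animals or fish consumers
whose diet decouples tissue δ³⁴S from the local terrestrial baseline.
Records reporting only sulfur data are kept unscreened. Surviving records
are averaged per site, and the site means become the regression response.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# atomic masses for converting weight-percent to atomic ratios
_MASS = {"C": 12.011, "N": 14.007, "S": 32.06}

REQUIRED_COLUMNS = ("site_id", "latitude", "longitude", "d34S")
FLAG_COLUMNS = ("diagenesis_reported", "nonlocal_reported",
                "aquatic_or_fish_consumer", "s_only")
OPTIONAL_NUMERIC = ("d13C", "d15N", "pctC", "pctN", "pctS",
                    "CS_ratio", "NS_ratio", "CN_ratio")

#: default column-name mapping (canonical -> source column); overridable
#: from the pipeline config for third-party spreadsheets
DEFAULT_COLUMN_MAP = {c: c for c in REQUIRED_COLUMNS + FLAG_COLUMNS + OPTIONAL_NUMERIC}
DEFAULT_COLUMN_MAP["record_id"] = "record_id"


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class RowParseError(ValueError):
    """A row holds an unparseable value; carries the offending row index."""

    def __init__(self, row: int, column: str, value) -> None:
        self.row = row
        self.column = column
        super().__init__(f"row {row}: cannot parse {column}={value!r}")


@dataclass
class CollagenRecord:
    """One analyzed collagen specimen."""

    record_id: str
    site_id: str
    latitude: float
    longitude: float
    d34S: float
    species: str = ""
    period: str = ""
    d13C: float | None = None
    d15N: float | None = None
    pctC: float | None = None
    pctN: float | None = None
    pctS: float | None = None
    CS_ratio: float | None = None
    NS_ratio: float | None = None
    CN_ratio: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range")
        if not math.isfinite(self.d34S):
            raise ValueError("d34S must be finite")
        for r in ("CS_ratio", "NS_ratio", "CN_ratio"):
            v = getattr(self, r)
            if v is not None and v < 0:
                raise ValueError(f"{r} must be non-negative")


@dataclass
class SiteAverage:
    site_id: str
    latitude: float
    longitude: float
    mean_d34S: float
    sd_d34S: float | None  # None for single-record sites
    n_records: int


@dataclass
class CompilationSummary:
    n_sites: int
    n_records: int
    mean_of_site_means: float
    min_site_mean: float
    max_site_mean: float
    mean_site_sd: float | None
    min_site_sd: float | None
    max_site_sd: float | None


def _parse_flag(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "yes", "y", "t"}
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return False
    return bool(v)


def load_compilation(path, fmt: str | None = None,
                     column_map: dict[str, str] | None = None) -> list[CollagenRecord]:
    """Load a δ³⁴S compilation from CSV or XLSX into records.

    ``column_map`` maps canonical field names to the file's column names.
    Raises :class:`SchemaError` if a required column is absent and
    :class:`RowParseError` (with the row index) for malformed coordinates or
    isotope values.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    fmt = fmt or ("xlsx" if str(path).lower().endswith((".xlsx", ".xls")) else "csv")
    if fmt == "xlsx":
        df = pd.read_excel(path, dtype=object)
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=object)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    for canon in REQUIRED_COLUMNS:
        if cmap[canon] not in df.columns:
            raise SchemaError(f"required column {cmap[canon]!r} (for {canon}) "
                              f"is missing from {path}")

    records: list[CollagenRecord] = []
    for i, row in df.iterrows():
        def _num(canon, required=False):
            col = cmap.get(canon)
            if col is None or col not in df.columns:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                if required:
                    raise RowParseError(i, canon, v)
                return None
            try:
                return float(v)
            except (TypeError, ValueError):
                raise RowParseError(i, canon, v) from None

        flags = {f for f in FLAG_COLUMNS
                 if cmap.get(f) in df.columns and _parse_flag(row[cmap[f]])}
        rid_col = cmap.get("record_id")
        rid = (str(row[rid_col]) if rid_col in df.columns
               and not pd.isna(row[rid_col]) else f"r{i}")
        try:
            rec = CollagenRecord(
                record_id=rid,
                site_id=str(row[cmap["site_id"]]),
                latitude=_num("latitude", required=True),
                longitude=_num("longitude", required=True),
                d34S=_num("d34S", required=True),
                species=str(row[cmap["species"]]) if cmap.get("species") in df.columns
                and not pd.isna(row.get(cmap.get("species"))) else "",
                period=str(row[cmap["period"]]) if cmap.get("period") in df.columns
                and not pd.isna(row.get(cmap.get("period"))) else "",
                d13C=_num("d13C"), d15N=_num("d15N"),
                pctC=_num("pctC"), pctN=_num("pctN"), pctS=_num("pctS"),
                CS_ratio=_num("CS_ratio"), NS_ratio=_num("NS_ratio"),
                CN_ratio=_num("CN_ratio"),
                flags=flags,
            )
        except RowParseError:
            raise
        except ValueError as exc:
            raise RowParseError(i, "record", str(exc)) from exc
        records.append(_derive_ratios(rec))
    return records


def _derive_ratios(rec: CollagenRecord) -> CollagenRecord:
    """Fill missing atomic ratios from weight percents when possible."""
    def atomic(pct, el):
        return pct / _MASS[el] if pct is not None else None

    c, n, s = atomic(rec.pctC, "C"), atomic(rec.pctN, "N"), atomic(rec.pctS, "S")
    if rec.CS_ratio is None and c is not None and s not in (None, 0.0):
        rec.CS_ratio = c / s
    if rec.NS_ratio is None and n is not None and s not in (None, 0.0):
        rec.NS_ratio = n / s
    if rec.CN_ratio is None and c is not None and n not in (None, 0.0):
        rec.CN_ratio = c / n
    return rec


#: fixed precedence of rejection reasons; every rejected record carries the
#: first reason in this order that applies
REASON_ORDER = ("diagenesis", "nonlocal", "aquatic", "elemental-ratio")

DEFAULT_THRESHOLDS = {"cs_max": 300.0, "ns_max": 100.0, "nonlocal_km": 100.0}


def screen_records(records: list[CollagenRecord],
                   thresholds: dict | None = None,
                   ) -> tuple[list[CollagenRecord], list[tuple[CollagenRecord, str]]]:
    """Apply the compilation quality screens.

    A record is kept iff its preservation ratios pass the strict thresholds
    (C/S < cs_max and N/S < ns_max) or it carries the sulfur-only flag, and
    none of the diagenesis / non-local / aquatic-consumer flags is set.
    Records with no ratios and no sulfur-only flag are treated as
    sulfur-only (kept, with a warning): such rows predate uniform elemental
    reporting. ``nonlocal_km`` documents the non-locality definition; the
    flag itself comes pre-annotated from the source publications.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    kept: list[CollagenRecord] = []
    rejected: list[tuple[CollagenRecord, str]] = []
    n_unscreened = 0
    for rec in records:
        if "diagenesis_reported" in rec.flags:
            rejected.append((rec, "diagenesis"))
            continue
        if "nonlocal_reported" in rec.flags:
            rejected.append((rec, "nonlocal"))
            continue
        if "aquatic_or_fish_consumer" in rec.flags:
            rejected.append((rec, "aquatic"))
            continue
        s_only = "s_only" in rec.flags
        if not s_only and rec.CS_ratio is None and rec.NS_ratio is None:
            s_only = True
            n_unscreened += 1
        if not s_only:
            cs_ok = rec.CS_ratio is not None and rec.CS_ratio < th["cs_max"]
            ns_ok = rec.NS_ratio is not None and rec.NS_ratio < th["ns_max"]
            if not (cs_ok and ns_ok):
                rejected.append((rec, "elemental-ratio"))
                logger.debug("rejected %s: elemental-ratio C/S=%s N/S=%s",
                             rec.record_id, rec.CS_ratio, rec.NS_ratio)
                continue
        kept.append(rec)
    for rec, reason in rejected:
        logger.debug("rejected %s: %s", rec.record_id, reason)
    if n_unscreened:
        warnings.warn(f"{n_unscreened} record(s) lack elemental ratios and the "
                      "sulfur-only flag; kept unscreened as sulfur-only")
    return kept, rejected


def site_average(records: list[CollagenRecord],
                 coord_tol_deg: float = 0.01) -> list[SiteAverage]:
    """Average δ³⁴S per site (sample SD, n−1 denominator).

    Sites are grouped by ``site_id``; records sharing an id but with
    coordinates spread more than ``coord_tol_deg`` trigger a warning and the
    coordinates are averaged.
    """
    groups: dict[str, list[CollagenRecord]] = {}
    for rec in records:
        key = rec.site_id or f"{round(rec.latitude, 4)},{round(rec.longitude, 4)}"
        groups.setdefault(key, []).append(rec)
    out = []
    for key in groups:
        recs = groups[key]
        lats = np.array([r.latitude for r in recs])
        lons = np.array([r.longitude for r in recs])
        if np.ptp(lats) > coord_tol_deg or np.ptp(lons) > coord_tol_deg:
            warnings.warn(f"site {key!r}: coordinates differ by more than "
                          f"{coord_tol_deg} degrees; averaging")
        vals = np.array([r.d34S for r in recs])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out.append(SiteAverage(site_id=key, latitude=float(lats.mean()),
                               longitude=float(lons.mean()),
                               mean_d34S=float(vals.mean()), sd_d34S=sd,
                               n_records=len(recs)))
    return out


def summarize_compilation(sites: list[SiteAverage]) -> CompilationSummary:
    """Summary statistics of a site-averaged compilation.

    ``mean_site_sd`` (and its min/max) pool only sites with at least two
    records, for which a sample SD exists.
    """
    if not sites:
        raise ValueError("cannot summarize an empty compilation")
    means = np.array([s.mean_d34S for s in sites])
    sds = np.array([s.sd_d34S for s in sites if s.sd_d34S is not None])
    return CompilationSummary(
        n_sites=len(sites),
        n_records=int(sum(s.n_records for s in sites)),
        mean_of_site_means=float(means.mean()),
        min_site_mean=float(means.min()),
        max_site_mean=float(means.max()),
        mean_site_sd=float(sds.mean()) if sds.size else None,
        min_site_sd=float(sds.min()) if sds.size else None,
        max_site_sd=float(sds.max()) if sds.size else None,
    )


def normality_statistic(sites: list[SiteAverage]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value for the site means."""
    means = [s.mean_d34S for s in sites]
    w, p = stats.shapiro(means)
    return float(w), float(p)


def sites_to_frame(sites: list[SiteAverage]) -> pd.DataFrame:
    return pd.DataFrame(
        {"site_id": [s.site_id for s in sites],
         "latitude": [s.latitude for s in sites],
         "longitude": [s.longitude for s in sites],
         "mean_d34S": [s.mean_d34S for s in sites],
         "sd_d34S": [s.sd_d34S if s.sd_d34S is not None else np.nan for s in sites],
         "n_records": [s.n_records for s in sites]}
    ).sort_values("site_id").reset_index(drop=True)


def records_to_frame(records: list[CollagenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in
             ("record_id", "site_id", "latitude", "longitude", "species",
              "period", "d34S", "d13C", "d15N", "pctC", "pctN", "pctS",
              "CS_ratio", "NS_ratio", "CN_ratio")}
        for f in FLAG_COLUMNS:
            d[f] = f in r.flags
        rows.append(d)
    return pd.DataFrame(rows)
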
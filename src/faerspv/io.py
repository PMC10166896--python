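"""Reading and writing FAERS-style quarterly ASCII tables.

The public FAERS quarterly releases ship one dollar-sign-delimited text file
per table (DEMO, DRUG, REAC, THER, OUTC, INDI) with a header row.  This module
parses those files into :class:`RawQuarter` objects, joins them on PRIMARYID
into :class:`SafetyReport` records, and removes duplicate case versions by
keeping, for each CASEID, the report with the latest FDA receipt date
(largest PRIMARYID breaking ties).

Only the modern (2012Q4+) PRIMARYID/CASEID layout is supported; legacy
ISR-era files are out of scope.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI")

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: FAERS outcome codes (death, life-threatening, hospitalization, disability,
#: congenital anomaly, required intervention, other serious).
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

REGIONS = (
    "Europe",
    "Asia",
    "North America",
    "Oceania",
    "South and Central America",
    "Africa",
    "unknown",
)

# AGE_COD -> multiplicative factor converting AGE to years.
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_OCCP_TO_REPORTER = {
    "MD": "physician",
    "PH": "pharmacist",
    "CN": "consumer",
    "HP": "health professional",
    "OT": "other health professional",
}

_SEX_MAP = {"M": "male", "F": "female"}


# ---------------------------------------------------------------------------
# Partial-date helpers
# ---------------------------------------------------------------------------

def pad_date(raw: str | None) -> str:
    """Zero-pad a FAERS date (YYYY, YYYYMM or YYYYMMDD) to 8 digits.

    Missing components are padded with "00" so the padded form is usable for
    lexicographic ordering only, not for calendar arithmetic.  ``None`` or a
    non-numeric value maps to "00000000" (sorts before every real date).
    """
    if raw is None:
        return "00000000"
    s = str(raw).strip()
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return "00000000"
    return s.ljust(8, "0")


def full_date(raw: str | None) -> datetime.date | None:
    """Return a calendar date for a complete YYYYMMDD value, else ``None``.

    Partial dates (year or year-month precision) and invalid dates are
    treated as missing; day-level precision is required for time-to-onset.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugMention:
    """One drug row within a report."""

    verbatim_name: str
    substance: str = "UNMAPPED"
    role: str = "C"
    therapy_start: str | None = None  # raw FAERS date, possibly partial

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role code: {self.role!r}")
        if not self.verbatim_name:
            raise ValueError("verbatim drug name must be non-empty")


@dataclass
class SafetyReport:
    """One FAERS case report (one DEMO row with its joined satellite rows)."""

    primary_id: str
    case_id: str
    fda_date: str | None = None
    event_date: str | None = None
    age_years: float | None = None
    sex: str = "unknown"
    country: str | None = None
    region: str = "unknown"
    reporter_type: str = "unknown"
    reaction_pts: frozenset[tuple[str, int | None]] = frozenset()
    outcomes: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    drugs: list[DrugMention] = field(default_factory=list)

    @property
    def report_year(self) -> int | None:
        p = pad_date(self.fda_date)
        return int(p[:4]) if p[:4] != "0000" else None


@dataclass
class ParseLog:
    """Per-table counts of skipped (malformed) rows plus warning messages."""

    skipped: Counter = field(default_factory=Counter)
    messages: list[str] = field(default_factory=list)

    @property
    def total_skipped(self) -> int:
        return sum(self.skipped.values())

    def warn(self, msg: str) -> None:
        self.messages.append(msg)
        logger.warning(msg)

    def to_text(self) -> str:
        lines = [f"skipped[{t}]={n}" for t, n in sorted(self.skipped.items())]
        return "\n".join(lines + self.messages)


@dataclass
class RawQuarter:
    """Parsed tables of one quarterly release, keyed by table name."""

    quarter_label: str
    tables: dict[str, pd.DataFrame]
    parse_log: ParseLog = field(default_factory=ParseLog)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _read_table(path: Path, table: str, log: ParseLog) -> pd.DataFrame:
    # FAERS files are "$"-delimited without quoting or escapes, so a plain
    # split is the exact grammar; rows whose field count disagrees with the
    # header are skipped and counted rather than NaN-padded.
    rows: list[list[str]] = []
    with open(path, encoding="latin-1") as fh:
        header = fh.readline().rstrip("\r\n")
        cols = [c.strip().upper() for c in header.split("$")]
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != len(cols):
                log.skipped[table] += 1
                continue
            rows.append([p.strip() for p in parts])
    df = pd.DataFrame(rows, columns=cols, dtype=str)
    return df.replace("", pd.NA)


def read_quarter(paths: Mapping[str, str | Path], quarter_label: str) -> RawQuarter:
    """Read one quarter's table files into a :class:`RawQuarter`.

    Parameters
    ----------
    paths
        Mapping from table name (DEMO, DRUG, REAC, THER, OUTC, INDI) to the
        file path.  DEMO is required; absent tables are treated as empty.
    quarter_label
        Label such as ``"2015Q1"``.
    """
    unknown = set(paths) - set(TABLE_NAMES)
    if unknown:
        raise ValueError(f"unknown FAERS table name(s): {sorted(unknown)}")
    if "DEMO" not in paths:
        raise FileNotFoundError(f"DEMO table is required for quarter {quarter_label}")
    demo_path = Path(paths["DEMO"])
    if not demo_path.exists():
        raise FileNotFoundError(f"DEMO file not found: {demo_path}")

    log = ParseLog()
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        if name in paths and Path(paths[name]).exists():
            tables[name] = _read_table(Path(paths[name]), name, log)
        elif name == "DEMO":
            raise FileNotFoundError(f"DEMO file not found: {paths['DEMO']}")
        else:
            tables[name] = pd.DataFrame()
    return RawQuarter(quarter_label=quarter_label, tables=tables, parse_log=log)


def write_quarter(quarter: RawQuarter, out_dir: str | Path) -> dict[str, Path]:
    """Write a :class:`RawQuarter` back to dollar-sign-delimited files.

    Inverse of :func:`read_quarter` for well-formed tables; missing values
    are written as empty strings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        df = quarter.tables.get(name, pd.DataFrame())
        path = out / f"{name}{quarter.quarter_label}.txt"
        with open(path, "w", encoding="latin-1") as fh:
            if df.empty and df.columns.empty:
                fh.write("PRIMARYID\n")
            else:
                fh.write("$".join(df.columns) + "\n")
                for row in df.itertuples(index=False):
                    fh.write("$".join("" if pd.isna(v) else str(v) for v in row) + "\n")
        paths[name] = path
    return paths


def find_quarter_files(directory: str | Path, quarter_label: str) -> dict[str, Path]:
    """Locate ``<TABLE><quarter>.txt`` files under a directory."""
    d = Path(directory)
    found: dict[str, Path] = {}
    for name in TABLE_NAMES:
        candidates = sorted(d.glob(f"{name}{quarter_label}*.txt")) or sorted(
            d.glob(f"{name.lower()}{quarter_label.lower()}*.txt")
        )
        if candidates:
            found[name] = candidates[0]
    return found


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _load_region_map() -> dict[str, str]:
    path = Path(__file__).parent / "data" / "country_region.csv"
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return dict(zip(df["country"].str.upper(), df["region"]))


_REGION_MAP: dict[str, str] | None = None


def country_to_region(country: str | None) -> str:
    """Map an ISO-like country code to one of the six reporting regions."""
    global _REGION_MAP
    if _REGION_MAP is None:
        _REGION_MAP = _load_region_map()
    if country is None:
        return "unknown"
    return _REGION_MAP.get(str(country).strip().upper(), "unknown")


def convert_age(age: str | None, age_cod: str | None, log: ParseLog | None = None) -> float | None:
    """Convert a FAERS AGE/AGE_COD pair to years; out-of-range or unparseable
    values become missing."""
    if age is None or (isinstance(age, float) and pd.isna(age)) or pd.isna(age):
        return None
    try:
        value = float(str(age).strip())
    except ValueError:
        if log is not None:
            log.warn(f"unparseable AGE value {age!r}")
        return None
    cod = "YR" if age_cod is None or pd.isna(age_cod) else str(age_cod).strip().upper()
    factor = _AGE_FACTORS.get(cod)
    if factor is None:
        if log is not None:
            log.warn(f"unknown AGE_COD {age_cod!r}")
        return None
    years = value * factor
    if not (0.0 <= years <= 130.0):
        if log is not None:
            log.warn(f"implausible age {years:.1f} years dropped")
        return None
    return years


def _get(row: Mapping[str, object], key: str) -> str | None:
    v = row.get(key)
    if v is None or pd.isna(v):
        return None
    return str(v)


def _group_by_primaryid(df: pd.DataFrame) -> dict[str, list[dict]]:
    if df.empty or "PRIMARYID" not in df.columns:
        return {}
    grouped: dict[str, list[dict]] = defaultdict(list)
    for rec in df.to_dict("records"):
        pid = rec.get("PRIMARYID")
        if pid is None or pd.isna(pid):
            continue
        grouped[str(pid)].append(rec)
    return grouped


def assemble_reports(quarters: Iterable[RawQuarter]) -> list[SafetyReport]:
    """Join the six tables of each quarter on PRIMARYID into SafetyReports.

    One report is produced per DEMO row.  Satellite rows whose PRIMARYID has
    no DEMO row are ignored (counted in the quarter's parse log).
    """
    reports: list[SafetyReport] = []
    for q in quarters:
        demo = q.tables.get("DEMO", pd.DataFrame())
        if demo.empty:
            continue
        drug = _group_by_primaryid(q.tables.get("DRUG", pd.DataFrame()))
        reac = _group_by_primaryid(q.tables.get("REAC", pd.DataFrame()))
        ther = _group_by_primaryid(q.tables.get("THER", pd.DataFrame()))
        outc = _group_by_primaryid(q.tables.get("OUTC", pd.DataFrame()))
        indi = _group_by_primaryid(q.tables.get("INDI", pd.DataFrame()))
        demo_ids = set()

        for row in demo.to_dict("records"):
            pid = _get(row, "PRIMARYID")
            if pid is None:
                q.parse_log.warn("DEMO row without PRIMARYID skipped")
                continue
            demo_ids.add(pid)
            case_id = _get(row, "CASEID") or pid
            country = _get(row, "OCCR_COUNTRY")
            occp = _get(row, "OCCP_COD")
            reporter = _OCCP_TO_REPORTER.get(
                occp.strip().upper() if occp else "", "unknown"
            )
            sex = _SEX_MAP.get((_get(row, "SEX") or "").strip().upper(), "unknown")

            # therapy start dates keyed by drug sequence number
            starts: dict[str, str] = {}
            for t in ther.get(pid, []):
                seq = _get(t, "DSG_DRUG_SEQ") or _get(t, "DRUG_SEQ")
                start = _get(t, "START_DT")
                if seq is not None and start is not None:
                    starts.setdefault(seq, start)

            mentions: list[DrugMention] = []
            for d in drug.get(pid, []):
                name = _get(d, "DRUGNAME")
                if not name:
                    continue
                role = (_get(d, "ROLE_COD") or "C").strip().upper()
                if role not in ROLE_CODES:
                    role = "C"
                seq = _get(d, "DRUG_SEQ")
                mentions.append(
                    DrugMention(
                        verbatim_name=name,
                        role=role,
                        therapy_start=starts.get(seq) if seq else None,
                    )
                )

            pts = set()
            for r in reac.get(pid, []):
                pt = _get(r, "PT")
                code_raw = _get(r, "PT_CD")
                code = int(code_raw) if code_raw and code_raw.isdigit() else None
                if pt:
                    pts.add((pt, code))

            outcomes = frozenset(
                code
                for o in outc.get(pid, [])
                if (code := (_get(o, "OUTC_COD") or "").strip().upper()) in OUTCOME_CODES
            )
            indications = frozenset(
                ind for i in indi.get(pid, []) if (ind := _get(i, "INDI_PT"))
            )

            reports.append(
                SafetyReport(
                    primary_id=pid,
                    case_id=case_id,
                    fda_date=_get(row, "FDA_DT"),
                    event_date=_get(row, "EVENT_DT"),
                    age_years=convert_age(row.get("AGE"), row.get("AGE_COD"), q.parse_log),
                    sex=sex,
                    country=country,
                    region=country_to_region(country),
                    reporter_type=reporter,
                    reaction_pts=frozenset(pts),
                    outcomes=outcomes,
                    indications=indications,
                    drugs=mentions,
                )
            )

        orphans = sum(
            sum(1 for _ in rows)
            for table in (drug, reac, ther, outc, indi)
            for pid, rows in table.items()
            if pid not in demo_ids
        )
        if orphans:
            q.parse_log.warn(
                f"{q.quarter_label}: {orphans} satellite rows without DEMO row ignored"
            )
    return reports


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _primaryid_sort_key(pid: str) -> tuple[int, str]:
    return (int(pid), "") if pid.isdigit() else (-1, pid)


def deduplicate_cases(reports: Sequence[SafetyReport]) -> list[SafetyReport]:
    """Keep one report per CASEID: the one with the latest FDA_DT.

    Reports tied on (CASEID, FDA_DT) are resolved by the numerically largest
    PRIMARYID.  Output is sorted by CASEID; the operation is idempotent.
    Partial FDA dates order by their zero-padded 8-digit form.
    """
    best: dict[str, SafetyReport] = {}
    for rep in reports:
        key = rep.case_id
        if key not in best:
            best[key] = rep
            continue
        cur = best[key]
        cand = (pad_date(rep.fda_date), _primaryid_sort_key(rep.primary_id))
        incumbent = (pad_date(cur.fda_date), _primaryid_sort_key(cur.primary_id))
        if cand > incumbent:
            best[key] = rep
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# Normalized case table serialization
# ---------------------------------------------------------------------------

def cases_to_frame(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """Flatten reports into one normalized row per case (CSV-friendly)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "primary_id": r.primary_id,
                "case_id": r.case_id,
                "fda_date": r.fda_date,
                "event_date": r.event_date,
                "age_years": r.age_years,
                "sex": r.sex,
                "country": r.country,
                "region": r.region,
                "reporter_type": r.reporter_type,
                "reaction_pts": ";".join(sorted(pt for pt, _ in r.reaction_pts)),
                "outcomes": ";".join(sorted(r.outcomes)),
                "indications": ";".join(sorted(r.indications)),
                "n_drugs": len(r.drugs),
            }
        )
    return pd.DataFrame(rows)


def write_case_table(reports: Sequence[SafetyReport], out_dir: str | Path) -> dict[str, Path]:
    """Serialize the normalized case table as CSV and a parquet cache."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = cases_to_frame(reports)
    csv_path = out / "cases.csv"
    frame.to_csv(csv_path, index=False)
    paths = {"csv": csv_path}
    try:  # columnar cache; optional if no parquet engine is present
        pq_path = out / "cases.parquet"
        frame.to_parquet(pq_path)
        paths["parquet"] = pq_path
    except (ImportError, ValueError):
        pass
    return paths
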
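"""Synthetic FAERS-like data with known ground truth.

Two generators live here:

* :func:`generate` / :func:`simulate_case_truth` — a seeded stochastic
  simulator of spontaneous reports.  Exposure to each ICI is sampled at a
  configurable marginal rate, and the event probability for an exposed case
  is obtained by scaling the background odds by an injected odds ratio
  ``theta``, so the injected ``theta`` is exactly the case-level odds ratio
  the reporting odds ratio estimates.  Dates, demographics, concomitant
  agents, duplicate case versions and partial dates are emulated so every
  pipeline stage can be exercised without downloading FAERS.

* :func:`fixture_table1` — a deterministic 654-case dataset whose marginal
  counts reproduce, row for row, the published clinical-characteristics
  table of ICI-associated hepatic failure (gender, age bins, regions,
  years, reporter types, time-to-onset bins with median 38 and range 1-914,
  indications, outcomes, per-substance and per-combination counts, and
  concomitant-agent burden).

The emitted files use the same dollar-sign-delimited quarterly dialect that
:mod:`faerspv.io` reads.
"""

from __future__ import annotations

import dataclasses
import datetime
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .io import RawQuarter, write_quarter

ICI_SUBSTANCE_CLASS = {
    "nivolumab": "anti-PD-1",
    "pembrolizumab": "anti-PD-1",
    "cemiplimab": "anti-PD-1",
    "atezolizumab": "anti-PD-L1",
    "avelumab": "anti-PD-L1",
    "durvalumab": "anti-PD-L1",
    "ipilimumab": "anti-CTLA-4",
    "tremelimumab": "anti-CTLA-4",
}

HEPATIC_FAILURE_PTS = (
    "Hepatic failure",
    "Acute hepatic failure",
    "Subacute hepatic failure",
    "Acute on chronic liver failure",
    "Chronic hepatic failure",
)

_BACKGROUND_PTS = ("Nausea", "Fatigue", "Pyrexia", "Diarrhoea", "Rash")
_BACKGROUND_DRUGS = ("METFORMIN", "LISINOPRIL", "ATORVASTATIN", "WARFARIN", "SERTRALINE")

_DEFAULT_QUARTERS = tuple(
    f"{y}Q{q}" for y in range(2015, 2022) for q in range(1, 5)
)

#: Default reporting-country mix (maps onto the six regions).
_DEFAULT_COUNTRY_PROBS = {
    "FR": 0.340,
    "JP": 0.330,
    "US": 0.280,
    "AU": 0.029,
    "BR": 0.018,
    "ZA": 0.003,
}


@dataclass(frozen=True)
class InjectedEffect:
    """A planted drug-event association of known strength.

    ``exposure`` is "any" (any ICI), an ICI class name, or a substance;
    ``theta`` is the true case-level odds ratio relative to background.
    """

    exposure: str
    theta: float
    event: str = "hepatic failure"


@dataclass
class SimConfig:
    """Parameters of the stochastic report simulator.

    Defaults emulate the FAERS-wide study conditions: a hepatic-failure
    background reporting rate of 0.19% of cases, ~1.2% of cases exposed to
    an ICI (shares proportional to the published per-substance case counts),
    class-level injected odds ratios matching the published class RORs, a
    log-normal time-to-onset with median 38 days, and a fatality probability
    of 0.6865 given the event.
    """

    n_cases: int = 20_000
    quarters: Sequence[str] = _DEFAULT_QUARTERS
    background_event_rate: float = 0.0019
    drug_exposure_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "nivolumab": 0.0045,
            "pembrolizumab": 0.0035,
            "cemiplimab": 0.0002,
            "atezolizumab": 0.0012,
            "avelumab": 0.0003,
            "durvalumab": 0.0008,
            "ipilimumab": 0.0012,
            "tremelimumab": 0.0001,
        }
    )
    injected_effects: Sequence[InjectedEffect] = field(
        default_factory=lambda: (
            InjectedEffect("anti-PD-1", 2.78),
            InjectedEffect("anti-PD-L1", 3.62),
            InjectedEffect("anti-CTLA-4", 3.31),
        )
    )
    combo_rate: float = 0.10
    concomitant_profiles: Mapping[str, float] = field(
        default_factory=lambda: {
            "ACETAMINOPHEN": 0.08,
            "BEVACIZUMAB": 0.05,
            "PREDNISOLONE": 0.05,
            "CARBOPLATIN": 0.04,
            "PACLITAXEL": 0.03,
            "OMEPRAZOLE": 0.03,
            "FUROSEMIDE": 0.02,
            "LEVOTHYROXINE": 0.02,
        }
    )
    tto_median_days: float = 38.0
    tto_sigma: float = 1.1
    death_given_event: float = 0.6865
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.05
    missing_demographics_rate: float = 0.10
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTRY_PROBS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not self.quarters:
            raise ValueError("at least one quarter label is required")
        probs = {
            "background_event_rate": self.background_event_rate,
            "combo_rate": self.combo_rate,
            "duplicate_rate": self.duplicate_rate,
            "partial_date_rate": self.partial_date_rate,
            "missing_demographics_rate": self.missing_demographics_rate,
            "death_given_event": self.death_given_event,
            **{f"exposure[{k}]": v for k, v in self.drug_exposure_rates.items()},
            **{f"concomitant[{k}]": v for k, v in self.concomitant_profiles.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if sum(self.drug_exposure_rates.values()) > 1.0:
            raise ValueError("drug exposure rates must sum to at most 1")
        for eff in self.injected_effects:
            if eff.theta <= 0:
                raise ValueError("injected odds ratios must be positive")
        unknown = set(self.drug_exposure_rates) - set(ICI_SUBSTANCE_CLASS)
        if unknown:
            raise ValueError(f"unknown ICI substance(s): {sorted(unknown)}")
        if self.tto_median_days <= 0 or self.tto_sigma <= 0:
            raise ValueError("time-to-onset parameters must be positive")


# ---------------------------------------------------------------------------
# Case-level truth
# ---------------------------------------------------------------------------

def _theta_for(
    substances: tuple[str, ...], effects: Sequence[InjectedEffect]
) -> float:
    """Effective odds scaling for one case: matching effects multiply."""
    if not substances:
        return 1.0
    classes = {ICI_SUBSTANCE_CLASS[s] for s in substances}
    theta = 1.0
    for eff in effects:
        if eff.exposure == "any" or eff.exposure in classes or eff.exposure in substances:
            theta *= eff.theta
    return theta


def simulate_case_truth(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the per-case ground truth (no files written).

    One row per case: exposure, injected theta, event/death flags, true
    time-to-onset, demographics, concomitants, duplicate and partial-date
    flags.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cases

    subs = list(config.drug_exposure_rates)
    p = np.array([config.drug_exposure_rates[s] for s in subs])
    p_none = 1.0 - p.sum()
    primary_idx = rng.choice(len(subs) + 1, size=n, p=np.append(p, p_none))
    exposed = primary_idx < len(subs)

    combo = exposed & (rng.random(n) < config.combo_rate) & (len(subs) > 1)
    partner_draw = rng.integers(0, max(len(subs) - 1, 1), size=n)

    substances: list[tuple[str, ...]] = []
    for i in range(n):
        if not exposed[i]:
            substances.append(())
            continue
        prim = subs[primary_idx[i]]
        if combo[i]:
            others = [s for s in subs if s != prim]
            substances.append((prim, others[partner_draw[i] % len(others)]))
        else:
            substances.append((prim,))

    theta = np.array([_theta_for(s, config.injected_effects) for s in substances])
    p0 = config.background_event_rate
    odds = theta * (p0 / (1.0 - p0))
    p_event = odds / (1.0 + odds)
    event = rng.random(n) < p_event

    tto = np.maximum(
        1,
        np.round(
            np.exp(rng.normal(math.log(config.tto_median_days), config.tto_sigma, n))
        ).astype(int),
    )
    died = event & (rng.random(n) < config.death_given_event)

    age = np.clip(rng.normal(64.0, 12.0, n), 14.0, 90.0).round(0)
    age_missing = rng.random(n) < config.missing_demographics_rate
    age = np.where(age_missing, np.nan, age)
    sex_missing = rng.random(n) < config.missing_demographics_rate
    sex = np.where(sex_missing, "", np.where(rng.random(n) < 0.55, "M", "F"))

    countries = list(config.country_probs)
    cprobs = np.array([config.country_probs[c] for c in countries], dtype=float)
    cprobs = cprobs / cprobs.sum()
    country = rng.choice(countries, size=n, p=cprobs)

    agents = list(config.concomitant_profiles)
    aprobs = np.array([config.concomitant_profiles[a] for a in agents])
    agent_matrix = rng.random((n, len(agents))) < aprobs[None, :]
    agent_matrix[~exposed, :] = False
    concomitants = [
        tuple(a for a, hit in zip(agents, row) if hit) for row in agent_matrix
    ]

    quarter = rng.choice(list(config.quarters), size=n)
    duplicate = rng.random(n) < config.duplicate_rate
    partial = rng.random(n) < config.partial_date_rate

    return pd.DataFrame(
        {
            "case_id": [str(1_000_000 + i) for i in range(n)],
            "quarter": quarter,
            "substances": substances,
            "combo": combo,
            "event": event,
            "theta": theta,
            "tto_days": tto,
            "died": died,
            "age_years": age,
            "sex": sex,
            "country": country,
            "concomitants": concomitants,
            "duplicate": duplicate,
            "partial_dates": partial,
        }
    )


def truth_to_case_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Project the simulator's ground truth onto the per-case analysis frame
    consumed by the disproportionality and descriptive modules."""
    rows = []
    for t in truth.itertuples(index=False):
        substances = frozenset(t.substances)
        if not substances:
            regimen, key = "none", "none"
        elif len(substances) == 1:
            regimen, key = "monotherapy", next(iter(substances))
        else:
            regimen, key = "combination", "+".join(sorted(substances))
        classes = frozenset(ICI_SUBSTANCE_CLASS[s] for s in substances)
        has_tto = t.event and bool(substances) and not t.partial_dates
        rows.append(
            {
                "case_id": t.case_id,
                "primary_id": t.case_id + "01",
                "is_event": bool(t.event),
                "regimen": regimen,
                "regimen_key": key,
                "substances": substances,
                "classes": classes,
                "concomitants": frozenset(t.concomitants),
                "n_concomitant": len(t.concomitants),
                "sex": {"M": "male", "F": "female"}.get(t.sex, "unknown"),
                "age_years": t.age_years,
                "region": fio.country_to_region(t.country),
                "reporter_type": "unknown",
                "report_year": int(str(t.quarter)[:4]),
                "outcomes": frozenset({"DE"}) if t.died else frozenset(),
                "died": bool(t.died),
                "indications": frozenset(),
                "tto_days": float(t.tto_days) if has_tto else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def _quarter_date(quarter: str, day: int) -> datetime.date:
    year, qn = int(quarter[:4]), int(quarter[5])
    return datetime.date(year, 3 * (qn - 1) + 1, day)


def _fmt(d: datetime.date) -> str:
    return d.strftime("%Y%m%d")


class _QuarterRows:
    def __init__(self) -> None:
        self.demo: list[dict] = []
        self.drug: list[dict] = []
        self.reac: list[dict] = []
        self.ther: list[dict] = []
        self.outc: list[dict] = []
        self.indi: list[dict] = []

    def to_raw(self, label: str) -> RawQuarter:
        cols = {
            "DEMO": (
                "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
                "SEX", "OCCP_COD", "OCCR_COUNTRY",
            ),
            "DRUG": ("PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"),
            "REAC": ("PRIMARYID", "CASEID", "PT"),
            "THER": ("PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"),
            "OUTC": ("PRIMARYID", "CASEID", "OUTC_COD"),
            "INDI": ("PRIMARYID", "CASEID", "INDI_DRUG_SEQ", "INDI_PT"),
        }
        data = {
            "DEMO": self.demo, "DRUG": self.drug, "REAC": self.reac,
            "THER": self.ther, "OUTC": self.outc, "INDI": self.indi,
        }
        tables = {
            name: pd.DataFrame(rows, columns=list(cols[name])).astype(str).replace(
                {"": pd.NA, "nan": pd.NA, "<NA>": pd.NA}
            )
            if rows
            else pd.DataFrame(columns=list(cols[name]))
            for name, rows in data.items()
        }
        return RawQuarter(quarter_label=label, tables=tables)


def _emit_case(
    rows_by_quarter: dict[str, _QuarterRows],
    t,
    version: int,
    primary_id: str,
    quarter: str,
    fda_dt: str,
    rng: np.random.Generator,
) -> None:
    q = rows_by_quarter[quarter]
    start = _quarter_date(quarter, 5)
    event_date = start + datetime.timedelta(days=int(t.tto_days))
    event_dt = ""
    if t.event:
        event_dt = _fmt(event_date)[:6] if t.partial_dates else _fmt(event_date)

    q.demo.append(
        {
            "PRIMARYID": primary_id,
            "CASEID": t.case_id,
            "FDA_DT": fda_dt,
            "EVENT_DT": event_dt,
            "AGE": "" if np.isnan(t.age_years) else str(int(t.age_years)),
            "AGE_COD": "" if np.isnan(t.age_years) else "YR",
            "SEX": t.sex,
            "OCCP_COD": rng.choice(["MD", "PH", "HP", "OT", "CN"]),
            "OCCR_COUNTRY": t.country,
        }
    )
    seq = 1
    if t.substances:
        for j, sub in enumerate(t.substances):
            q.drug.append(
                {
                    "PRIMARYID": primary_id,
                    "CASEID": t.case_id,
                    "DRUG_SEQ": str(seq),
                    "ROLE_COD": "PS" if j == 0 else "SS",
                    "DRUGNAME": sub.upper(),
                }
            )
            if t.event and not t.partial_dates:
                q.ther.append(
                    {
                        "PRIMARYID": primary_id,
                        "CASEID": t.case_id,
                        "DSG_DRUG_SEQ": str(seq),
                        "START_DT": _fmt(start),
                    }
                )
            seq += 1
    else:
        q.drug.append(
            {
                "PRIMARYID": primary_id,
                "CASEID": t.case_id,
                "DRUG_SEQ": str(seq),
                "ROLE_COD": "PS",
                "DRUGNAME": _BACKGROUND_DRUGS[int(t.case_id) % len(_BACKGROUND_DRUGS)],
            }
        )
        seq += 1
    for agent in t.concomitants:
        q.drug.append(
            {
                "PRIMARYID": primary_id,
                "CASEID": t.case_id,
                "DRUG_SEQ": str(seq),
                "ROLE_COD": "C",
                "DRUGNAME": agent,
            }
        )
        seq += 1

    if t.event:
        pt = HEPATIC_FAILURE_PTS[int(t.case_id) % len(HEPATIC_FAILURE_PTS)]
        q.reac.append({"PRIMARYID": primary_id, "CASEID": t.case_id, "PT": pt})
    q.reac.append(
        {
            "PRIMARYID": primary_id,
            "CASEID": t.case_id,
            "PT": _BACKGROUND_PTS[int(t.case_id) % len(_BACKGROUND_PTS)],
        }
    )
    if t.died:
        q.outc.append({"PRIMARYID": primary_id, "CASEID": t.case_id, "OUTC_COD": "DE"})


def generate(
    config: SimConfig, out_dir: str | Path
) -> tuple[dict[str, dict[str, Path]], pd.DataFrame]:
    """Write the six quarterly tables for a simulated database.

    Returns ``(paths, truth)`` where ``paths`` maps quarter label ->
    table name -> file path and ``truth`` is the case-level ground truth
    (including the duplicate lineage column ``primary_ids``).  Fully
    reproducible: the same config (seed included) yields byte-identical
    files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = simulate_case_truth(config, rng)

    quarters = list(config.quarters)
    rows_by_quarter = {qlab: _QuarterRows() for qlab in quarters}
    lineages: list[tuple[str, ...]] = []
    for t in truth.itertuples(index=False):
        base = int(t.case_id) * 100
        fda = _quarter_date(t.quarter, 15)
        pids = [str(base + 1)]
        _emit_case(rows_by_quarter, t, 1, pids[0], t.quarter, _fmt(fda), rng)
        if t.duplicate:
            # re-emitted case version: later quarter when available, newer
            # FDA_DT, larger PRIMARYID
            qi = quarters.index(t.quarter)
            dup_quarter = quarters[min(qi + 1, len(quarters) - 1)]
            dup_fda = max(
                _quarter_date(dup_quarter, 20), fda + datetime.timedelta(days=30)
            )
            pids.append(str(base + 2))
            _emit_case(
                rows_by_quarter, t, 2, pids[1], dup_quarter, _fmt(dup_fda), rng
            )
        lineages.append(tuple(pids))
    truth = truth.assign(primary_ids=lineages)

    out = Path(out_dir)
    paths: dict[str, dict[str, Path]] = {}
    for qlab in quarters:
        raw = rows_by_quarter[qlab].to_raw(qlab)
        paths[qlab] = write_quarter(raw, out)
    return paths, truth


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    """Serialize the ground truth as CSV (set-like columns ';'-joined)."""
    flat = truth.copy()
    for col in ("substances", "concomitants", "primary_ids"):
        if col in flat.columns:
            flat[col] = flat[col].map(lambda xs: ";".join(xs))
    path = Path(path)
    flat.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Deterministic published-table fixture
# ---------------------------------------------------------------------------

def _blocks(*pairs):
    out = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


def _cycle(lo: int, hi: int, count: int) -> list[int]:
    return list(itertools.islice(itertools.cycle(range(lo, hi + 1)), count))


def _fixture_tto_values() -> list[int]:
    """296 TTO values honoring the published bins (113/64/37/82), the median
    38 and the range 1-914."""
    bin1 = _cycle(1, 28, 113)
    # 34 values below 38 then values >= 38: puts the overall 148th and 149th
    # order statistics at exactly 38
    bin2 = _cycle(29, 37, 34) + [38, 38] + _cycle(39, 56, 28)
    bin3 = _cycle(57, 84, 37)
    bin4 = _cycle(85, 165, 81) + [914]
    return bin1 + bin2 + bin3 + bin4


def _fixture_ages() -> list[float | None]:
    """525 known ages honoring the published bins, median 64, range 14-90."""
    known = (
        [14.0, 17.0]
        + [float(a) for a in _cycle(18, 44, 57)]
        + [float(a) for a in _cycle(45, 63, 203)]
        + [64.0] * 12
        + [float(a) for a in _cycle(65, 74, 164)]
        + [float(a) for a in _cycle(75, 90, 87)]
    )
    return known + [None] * 129


_FIXTURE_EXPOSURES: list[list[tuple[str, str]]] = (
    [[("OPDIVO", "PS"), ("YERVOY", "SS")]] * 126
    + [[("IMFINZI", "PS"), ("TREMELIMUMAB", "SS")]] * 3
    + [[("KEYTRUDA", "PS"), ("TECENTRIQ", "SS"), ("OPDIVO", "SS"), ("IMFINZI", "SS")]] * 2
    + [[("KEYTRUDA", "PS"), ("YERVOY", "SS"), ("OPDIVO", "SS"), ("TECENTRIQ", "SS")]] * 1
    + [[("NIVOLUMAB", "PS")]] * 210
    + [[("PEMBROLIZUMAB", "PS")]] * 135
    + [[("CEMIPLIMAB", "PS")]] * 1
    + [[("ATEZOLIZUMAB", "PS")]] * 130
    + [[("AVELUMAB", "PS")]] * 9
    + [[("DURVALUMAB", "PS")]] * 13
    + [[("IPILIMUMAB", "PS")]] * 24
)

_FIXTURE_AGENT_POOL = (
    "ACETAMINOPHEN", "BEVACIZUMAB", "PREDNISOLONE", "CARBOPLATIN", "PACLITAXEL",
    "OMEPRAZOLE", "FUROSEMIDE", "LEVOTHYROXINE", "PEMETREXED", "CISPLATIN",
    "DEXAMETHASONE", "PANTOPRAZOLE", "METFORMIN", "AMLODIPINE", "ASPIRIN",
)


def fixture_table1_quarters() -> list[RawQuarter]:
    """Build the deterministic 654-case published-table fixture in memory."""
    n = 654
    exposures = _FIXTURE_EXPOSURES
    assert len(exposures) == n

    sexes = _blocks(("M", 382), ("F", 218), ("", 54))
    ages = _fixture_ages()
    countries = _blocks(
        ("FR", 221), ("JP", 215), ("US", 184), ("AU", 19), ("BR", 12), ("ZA", 2), ("", 1)
    )
    years = _blocks(
        (2015, 20), (2016, 36), (2017, 64), (2018, 94), (2019, 101), (2020, 139),
        (2021, 199), (None, 1)
    )
    occp = _blocks(("MD", 330), ("CN", 119), ("HP", 91), ("OT", 77), ("PH", 33), ("", 4))
    # 449 deaths in total, of which 8 fall on the 9-case avelumab block
    # (indices 608-616) to honor the published per-substance fatality;
    # 50 death cases carry a co-occurring hospitalization code to exercise
    # the single-outcome precedence rule.
    death_idx = set(range(441)) | set(range(608, 616))
    non_death_outcomes = iter(
        [("HO",)] * 89 + [("OT",)] * 81 + [("LT",)] * 26 + [("DS",)] * 8 + [()]
    )
    outcome_sets: list[tuple[str, ...]] = []
    n_deaths_seen = 0
    for i in range(n):
        if i in death_idx:
            outcome_sets.append(("DE", "HO") if n_deaths_seen < 50 else ("DE",))
            n_deaths_seen += 1
        else:
            outcome_sets.append(next(non_death_outcomes))
    tto_values: list[int | None] = list(_fixture_tto_values()) + [None] * 358
    indications = _blocks(
        ("Non-small cell lung cancer", 118),
        ("Malignant melanoma", 107),
        ("Hepatocellular carcinoma", 94),
        ("Renal cell carcinoma", 55),
        ("Breast cancer", 18),
        ("Metastases to liver", 5),
        (None, 257),
    )
    n_concomitant = (
        _blocks((0, 128), (1, 128), (2, 128)) + [3] * 101 + [6] * 97 + [11] * 72
    )
    for name, series in [
        ("sex", sexes), ("age", ages), ("country", countries), ("year", years),
        ("occp", occp), ("outcome", outcome_sets), ("tto", tto_values),
        ("indication", indications), ("conc", n_concomitant),
    ]:
        assert len(series) == n, name

    by_year: dict[str, _QuarterRows] = {}
    for i in range(n):
        year = years[i]
        qlab = f"{year}Q2" if year is not None else "2021Q2"
        q = by_year.setdefault(qlab, _QuarterRows())
        case_id = str(10_000_000 + i)
        primary_id = case_id + "1"
        fda_dt = f"{year}0615" if year is not None else ""
        tto = tto_values[i]
        start = datetime.date(year if year is not None else 2021, 1, 15)
        event_dt = _fmt(start + datetime.timedelta(days=tto)) if tto else ""

        age = ages[i]
        # first case exercises the month->year age conversion
        if i == 0:
            age_field, age_cod = str(int(age * 12)), "MON"
        elif age is None:
            age_field, age_cod = "", ""
        else:
            age_field, age_cod = str(int(age)), "YR"

        q.demo.append(
            {
                "PRIMARYID": primary_id, "CASEID": case_id, "FDA_DT": fda_dt,
                "EVENT_DT": event_dt, "AGE": age_field, "AGE_COD": age_cod,
                "SEX": sexes[i], "OCCP_COD": occp[i], "OCCR_COUNTRY": countries[i],
            }
        )
        seq = 1
        for name, role in exposures[i]:
            q.drug.append(
                {
                    "PRIMARYID": primary_id, "CASEID": case_id, "DRUG_SEQ": str(seq),
                    "ROLE_COD": role, "DRUGNAME": name,
                }
            )
            if tto:
                q.ther.append(
                    {
                        "PRIMARYID": primary_id, "CASEID": case_id,
                        "DSG_DRUG_SEQ": str(seq), "START_DT": _fmt(start),
                    }
                )
            seq += 1
        for j in range(n_concomitant[i]):
            q.drug.append(
                {
                    "PRIMARYID": primary_id, "CASEID": case_id, "DRUG_SEQ": str(seq),
                    "ROLE_COD": "C",
                    "DRUGNAME": _FIXTURE_AGENT_POOL[(i + j) % len(_FIXTURE_AGENT_POOL)],
                }
            )
            seq += 1
        q.reac.append(
            {
                "PRIMARYID": primary_id, "CASEID": case_id,
                "PT": HEPATIC_FAILURE_PTS[i % len(HEPATIC_FAILURE_PTS)],
            }
        )
        if i == 0:  # two matching PTs must still count as one case
            q.reac.append(
                {"PRIMARYID": primary_id, "CASEID": case_id, "PT": HEPATIC_FAILURE_PTS[1]}
            )
        for code in outcome_sets[i]:
            q.outc.append({"PRIMARYID": primary_id, "CASEID": case_id, "OUTC_COD": code})
        if indications[i]:
            q.indi.append(
                {
                    "PRIMARYID": primary_id, "CASEID": case_id,
                    "INDI_DRUG_SEQ": "1", "INDI_PT": indications[i],
                }
            )
    return [by_year[k].to_raw(k) for k in sorted(by_year)]


def fixture_table1(out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write the deterministic 654-case fixture as quarterly ASCII files."""
    paths: dict[str, dict[str, Path]] = {}
    for raw in fixture_table1_quarters():
        paths[raw.quarter_label] = write_quarter(raw, out_dir)
    return paths


def fixture_table1_case_table() -> pd.DataFrame:
    """Assemble, deduplicate and classify the fixture into the analysis
    frame (runs the real ingestion path, in memory)."""
    from .casetable import build_case_table
    from .io import assemble_reports, deduplicate_cases

    reports = deduplicate_cases(assemble_reports(fixture_table1_quarters()))
    return build_case_table(reports)
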
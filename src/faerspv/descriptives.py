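"""Descriptive analyses of adverse-event cases.

Covers the clinical-characteristics summary (counts and percentages by
gender, age, region, reporting year, reporter type, indication, outcome,
regimen and concomitant burden), time-to-onset (TTO) computation and its
distributional tests, and the fatality proportion with its monofactor
chi-squared test.

Percentages follow the reporting convention of spontaneous-report studies:
count / total x 100, rounded half-up to 2 decimals; TTO percentages use the
non-missing denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import DrugDictionary, ExposureLabel, SUSPECT_ROLES
from .io import SafetyReport, full_date

logger = logging.getLogger(__name__)

TTO_BINS = ("<=28", "29-56", "57-84", ">84")

AGE_BINS = ("<18", "18-44", "45-64", "65-74", ">=75")

#: Single-outcome tabulation precedence when several outcome codes co-occur.
OUTCOME_PRECEDENCE = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

OUTCOME_LABELS = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention",
    "OT": "other serious",
}

#: Indication preferred terms grouped into the tabulated categories.
INDICATION_GROUPS: dict[str, frozenset[str]] = {
    "lung cancer": frozenset(
        {
            "lung cancer",
            "non-small cell lung cancer",
            "small cell lung cancer",
            "lung neoplasm malignant",
            "lung adenocarcinoma",
        }
    ),
    "malignant melanoma": frozenset({"malignant melanoma", "melanoma"}),
    "hepatocellular carcinoma": frozenset({"hepatocellular carcinoma"}),
    "renal cell carcinoma": frozenset({"renal cell carcinoma", "renal cancer"}),
    "breast cancer": frozenset({"breast cancer"}),
    "liver metastasis": frozenset(
        {"metastases to liver", "liver metastasis", "liver metastases"}
    ),
}


def percent(numerator: float, denominator: float) -> float:
    """count/total*100 rounded half-up to 2 decimals (NaN when total is 0)."""
    if denominator == 0:
        return float("nan")
    value = Decimal(int(numerator)) * 100 / Decimal(int(denominator))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def tto_bin(days: float | None) -> str:
    """Assign a TTO in days to its reporting bin."""
    if days is None or (isinstance(days, float) and math.isnan(days)):
        return "missing"
    if days <= 28:
        return TTO_BINS[0]
    if days <= 56:
        return TTO_BINS[1]
    if days <= 84:
        return TTO_BINS[2]
    return TTO_BINS[3]


def age_bin(age: float | None) -> str:
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return "unknown"
    if age < 18:
        return AGE_BINS[0]
    if age < 45:
        return AGE_BINS[1]
    if age < 65:
        return AGE_BINS[2]
    if age < 75:
        return AGE_BINS[3]
    return AGE_BINS[4]


@dataclass(frozen=True)
class TimeToOnset:
    """Days from first suspect-ICI dose to adverse-event onset (>= 1)."""

    case_id: str
    substance_or_regimen: str
    days: int

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("time to onset is at least 1 day")

    @property
    def bin(self) -> str:
        return tto_bin(self.days)


def compute_tto(
    report: SafetyReport,
    exposure: ExposureLabel,
    dictionary: DrugDictionary | None = None,
) -> TimeToOnset | None:
    """Interval from the earliest suspect-ICI therapy start to event onset.

    Both dates must have day precision; partial or missing dates, and
    negative intervals (event before first dose, logged), yield ``None``.
    Same-day onset is recorded as day 1.
    """
    if dictionary is None:
        dictionary = DrugDictionary.default()
    event = full_date(report.event_date)
    if event is None:
        return None
    starts = []
    for m in report.drugs:
        if m.role not in SUSPECT_ROLES:
            continue
        hit = dictionary.lookup(m.verbatim_name)
        if hit is None or hit[0] not in exposure.ici_substances:
            continue
        d = full_date(m.therapy_start)
        if d is not None:
            starts.append(d)
    if not starts:
        return None
    delta = (event - min(starts)).days
    if delta < 0:
        logger.warning(
            "case %s: event onset precedes first dose by %d days; TTO set missing",
            report.case_id,
            -delta,
        )
        return None
    return TimeToOnset(
        case_id=report.case_id,
        substance_or_regimen=exposure.regimen_key,
        days=max(delta, 1),
    )


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

@dataclass
class DescriptiveSummary:
    """Counts, percentages and medians mirroring a clinical-characteristics
    table for one set of event cases."""

    total: int
    sections: dict[str, pd.DataFrame] = field(default_factory=dict)
    medians: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def section(self, name: str) -> pd.DataFrame:
        return self.sections[name]

    def count(self, section: str, level: str) -> int:
        df = self.sections[section]
        row = df[df["level"] == level]
        return int(row["count"].iloc[0]) if len(row) else 0

    def pct(self, section: str, level: str) -> float:
        df = self.sections[section]
        row = df[df["level"] == level]
        return float(row["pct"].iloc[0]) if len(row) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, df in self.sections.items():
            part = df.copy()
            part.insert(0, "section", name)
            parts.append(part)
        if not parts:
            return pd.DataFrame(columns=["section", "level", "count", "pct"])
        return pd.concat(parts, ignore_index=True)


def _section(counts: Mapping[str, int], denom: int, order: Sequence[str]) -> pd.DataFrame:
    rows = [
        {"level": lvl, "count": int(counts.get(lvl, 0)), "pct": percent(counts.get(lvl, 0), denom)}
        for lvl in order
    ]
    return pd.DataFrame(rows)


def _single_outcome(outcomes: frozenset[str]) -> str:
    for code in OUTCOME_PRECEDENCE:
        if code in outcomes:
            return OUTCOME_LABELS[code]
    return "unknown"


def _concomitant_bin(n: int) -> str:
    if n < 3:
        return "<3"
    if n <= 5:
        return "3-5"
    if n <= 10:
        return "6-10"
    return ">10"


def summarize(case_table: pd.DataFrame) -> DescriptiveSummary:
    """Build the descriptive summary for a set of (event) cases.

    ``case_table`` is the per-case analysis frame produced by
    :func:`faerspv.casetable.build_case_table`.  Every section's counts sum
    to the total, with an explicit "unknown" level absorbing the remainder;
    TTO percentages are over the non-missing cases and the combination
    section's percentages are over combination cases.
    """
    total = len(case_table)
    s = DescriptiveSummary(total=total)
    if total == 0:
        return s

    sex_counts = case_table["sex"].value_counts().to_dict()
    s.sections["gender"] = _section(sex_counts, total, ("male", "female", "unknown"))

    ages = case_table["age_years"].astype(float)
    abins = ages.map(age_bin).value_counts().to_dict()
    s.sections["age"] = _section(abins, total, AGE_BINS + ("unknown",))
    known_age = ages.dropna()
    if len(known_age):
        s.medians["age"] = (
            float(np.median(known_age)),
            float(known_age.min()),
            float(known_age.max()),
        )

    region_counts = case_table["region"].value_counts().to_dict()
    from .io import REGIONS

    s.sections["region"] = _section(region_counts, total, REGIONS)

    years = case_table["report_year"].map(
        lambda y: "unknown" if pd.isna(y) else str(int(y))
    )
    year_counts = years.value_counts().to_dict()
    year_order = sorted(k for k in year_counts if k != "unknown") + ["unknown"]
    s.sections["year"] = _section(year_counts, total, year_order)

    rep_counts = case_table["reporter_type"].value_counts().to_dict()
    s.sections["reporter"] = _section(
        rep_counts,
        total,
        (
            "physician",
            "consumer",
            "health professional",
            "other health professional",
            "pharmacist",
            "unknown",
        ),
    )

    tto = case_table["tto_days"].astype(float)
    known_tto = tto.dropna()
    bins = tto.map(lambda d: tto_bin(None if pd.isna(d) else d)).value_counts().to_dict()
    tto_rows = _section(bins, len(known_tto), TTO_BINS)
    tto_rows = pd.concat(
        [
            tto_rows,
            pd.DataFrame(
                [{"level": "missing", "count": bins.get("missing", 0), "pct": float("nan")}]
            ),
        ],
        ignore_index=True,
    )
    s.sections["tto"] = tto_rows
    if len(known_tto):
        s.medians["tto"] = (
            float(np.median(known_tto)),
            float(known_tto.min()),
            float(known_tto.max()),
        )

    lowered = case_table["indications"].map(
        lambda inds: frozenset(i.lower().strip() for i in inds)
    )
    ind_counts: dict[str, int] = {}
    any_named = pd.Series(False, index=case_table.index)
    for group, names in INDICATION_GROUPS.items():
        mask = lowered.map(lambda inds: bool(inds & names))
        ind_counts[group] = int(mask.sum())
        any_named |= mask
    ind_counts["unknown"] = int((~any_named).sum())
    s.sections["indication"] = _section(
        ind_counts, total, tuple(INDICATION_GROUPS) + ("unknown",)
    )

    outcome_counts = case_table["outcomes"].map(_single_outcome).value_counts().to_dict()
    s.sections["outcome"] = _section(
        outcome_counts,
        total,
        tuple(OUTCOME_LABELS[c] for c in OUTCOME_PRECEDENCE) + ("unknown",),
    )

    cls_counts: dict[str, int] = {}
    for cls in ("anti-PD-1", "anti-PD-L1", "anti-CTLA-4"):
        cls_counts[cls] = int(case_table["classes"].map(lambda cs: cls in cs).sum())
    s.sections["ici_class"] = _section(cls_counts, total, tuple(cls_counts))

    sub_counts: dict[str, int] = {}
    for subs in case_table["substances"]:
        for sub in subs:
            sub_counts[sub] = sub_counts.get(sub, 0) + 1
    s.sections["ici_substance"] = _section(
        sub_counts, total, tuple(sorted(sub_counts, key=lambda k: -sub_counts[k]))
    )

    combos = case_table[case_table["regimen"] == "combination"]
    combo_counts = combos["regimen_key"].value_counts().to_dict()
    s.sections["combination"] = _section(
        combo_counts, len(combos), tuple(sorted(combo_counts, key=lambda k: -combo_counts[k]))
    )

    conc_counts = (
        case_table["n_concomitant"].astype(int).map(_concomitant_bin).value_counts().to_dict()
    )
    s.sections["n_concomitant"] = _section(conc_counts, total, ("<3", "3-5", "6-10", ">10"))

    return s


# ---------------------------------------------------------------------------
# Fatality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FatalityResult:
    deaths: int
    total: int
    proportion: float  # percent, 2 dp
    per_substance: pd.DataFrame


def fatality_proportion(case_table: pd.DataFrame) -> FatalityResult:
    """Deaths / total cases x 100 (2 dp), overall and per ICI substance.

    Death means outcome code DE anywhere among the case's outcomes.
    """
    total = len(case_table)
    if total == 0:
        raise ValueError("fatality proportion is not computable for zero cases")
    died = case_table["outcomes"].map(lambda o: "DE" in o)
    deaths = int(died.sum())
    rows = []
    sub_total: dict[str, list[int]] = {}
    for subs, d in zip(case_table["substances"], died):
        for sub in subs:
            t = sub_total.setdefault(sub, [0, 0])
            t[0] += int(d)
            t[1] += 1
    for sub in sorted(sub_total):
        dd, tt = sub_total[sub]
        rows.append(
            {"substance": sub, "deaths": dd, "total": tt, "proportion": percent(dd, tt)}
        )
    return FatalityResult(
        deaths=deaths,
        total=total,
        proportion=percent(deaths, total),
        per_substance=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def _holm(pvals: Sequence[float]) -> list[float]:
    # Holm step-down adjustment (monotone, capped at 1).
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


@dataclass
class KruskalResult:
    statistic: float
    pvalue: float
    groups: list[str]
    pairwise: pd.DataFrame


def kruskal_wallis_tto(
    tto_by_group: Mapping[str, Sequence[float]],
    min_group_size: int = 20,
) -> KruskalResult | None:
    """Kruskal-Wallis test of TTO distributions across exposure groups.

    Only groups with more than ``min_group_size`` observations enter the
    test; with fewer than two eligible groups the result is not computable
    (``None``).  Pairwise two-group tests are emitted unadjusted, with a
    Holm-adjusted column alongside.  If all observations are identical the
    degenerate H = 0, p = 1 is returned.
    """
    eligible = {
        str(g): np.asarray(v, dtype=float)
        for g, v in tto_by_group.items()
        if len(v) > min_group_size
    }
    if len(eligible) < 2:
        return None
    names = sorted(eligible)
    samples = [eligible[n] for n in names]

    def _kw(*groups):
        # all observations identical: H is 0/0 across scipy versions
        # (ValueError or nan); the degenerate test is H = 0, p = 1
        try:
            with np.errstate(invalid="ignore"):
                h, p = stats.kruskal(*groups)
        except ValueError:
            return 0.0, 1.0
        if math.isnan(h):
            return 0.0, 1.0
        return float(h), float(p)

    h, p = _kw(*samples)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            hij, pij = _kw(samples[i], samples[j])
            pairs.append({"group1": names[i], "group2": names[j], "H": hij, "p": pij})
    pairwise = pd.DataFrame(pairs)
    if len(pairwise):
        pairwise["p_holm"] = _holm(pairwise["p"].tolist())
    return KruskalResult(statistic=float(h), pvalue=float(p), groups=names, pairwise=pairwise)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    drugs: tuple[str, ...]
    low_expected: bool  # any expected cell < 1


def chisq_fatality(
    deaths_by_drug: Mapping[str, tuple[int, int]],
    min_cases: int = 20,
) -> ChiSquareResult | None:
    """Pearson chi-squared homogeneity test of the fatality proportion.

    ``deaths_by_drug`` maps substance to (deaths, total cases); only drugs
    with more than ``min_cases`` cases are tested.  No continuity
    correction; df = (r - 1).  Expected cells below 1 set a warning flag.
    """
    kept = {d: (k, n) for d, (k, n) in deaths_by_drug.items() if n > min_cases}
    if len(kept) < 2:
        return None
    names = sorted(kept)
    table = np.array([[kept[d][0], kept[d][1] - kept[d][0]] for d in names], dtype=float)
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        pvalue=float(p),
        drugs=tuple(names),
        low_expected=bool((expected < 1).any()),
    )


def plot_tto(tto_by_group: Mapping[str, Sequence[float]], path: str | None = None):
    """Box plot of TTO by exposure group (matplotlib required)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted(tto_by_group)
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.boxplot([np.asarray(tto_by_group[n], dtype=float) for n in names], tick_labels=names)
    ax.set_ylabel("time to onset (days)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
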
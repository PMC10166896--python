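"""Disproportionality analysis: 2x2 tables, ROR and IC signal statistics.

A drug-event pair is screened by comparing how often the event is reported
with the drug against a comparator set of reports, via two standard
statistics:

* reporting odds ratio ``ROR = (a/b) / (c/d)`` with the Wald interval
  ``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``;
* information component ``IC = log2((a + 0.5) / (E + 0.5))`` where
  ``E = (a+b)(a+c)/N`` is the count expected under independence, with
  credible bounds from Gamma quantiles, ``IC_q = log2(G_q(a + 0.5) / (E + 0.5))``
  (a closed-form approximation of the bounds is available as an option).

A pair is flagged as a signal when the lower 95% ROR bound exceeds 1 with at
least 3 observed cases, or the lower 95% IC bound exceeds 0.

Four comparison designs are supported: (1) an ICI class versus all other
reports in the database, (2) an ICI monotherapy versus all other reports,
(3) an ICI combination versus monotherapy of a constituent, and (4) ICIs
plus a frequent concomitant agent versus ICI monotherapy without it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import (
    DrugDictionary,
    EventDefinition,
    HEPATIC_FAILURE,
    ICI_CLASSES,
)
from .io import SafetyReport

DESIGNS = (
    "class_vs_all",
    "mono_vs_all",
    "combo_vs_mono",
    "ici_plus_agent_vs_mono",
)

IcMethod = Literal["gamma", "approx"]


# ---------------------------------------------------------------------------
# Contingency table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one target/comparator/event triple.

    a: target-exposed with the event; b: target-exposed without;
    c: comparator with the event; d: comparator without.
    """

    a: int
    b: int
    c: int
    d: int
    design_label: str = ""
    target: str = ""
    comparator: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError("cells must be nonnegative integers")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("table must contain at least one case")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    low: float
    high: float
    corrected: bool = False
    computable: bool = True


@dataclass(frozen=True)
class IcEstimate:
    ic: float
    low: float
    high: float
    expected: float


def compute_ror(table: ContingencyTable, alpha: float = 0.05) -> RorEstimate:
    """Point ROR and two-sided Wald interval.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 to all four
    cells, flagged via ``corrected``).  An empty target or comparator margin
    is not computable (NaNs, ``computable=False``).
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        nan = float("nan")
        return RorEstimate(nan, nan, nan, corrected=False, computable=False)
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = table.has_zero_cell
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    z = stats.norm.ppf(1 - alpha / 2)
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RorEstimate(
        ror=ror,
        low=math.exp(log_ror - z * se),
        high=math.exp(log_ror + z * se),
        corrected=corrected,
    )


def compute_ic(
    table: ContingencyTable, alpha: float = 0.05, method: IcMethod = "gamma"
) -> IcEstimate:
    """Shrunken observed-to-expected information component, in bits.

    ``method="gamma"`` gives two-sided credible bounds from quantiles of a
    Gamma(a + 0.5, scale=1) distribution; ``method="approx"`` uses the
    closed-form expansion ``IC025 = IC - 3.3(a+0.5)^-1/2 - 2(a+0.5)^-3/2``
    (and ``IC975 = IC + 2.4(a+0.5)^-1/2 + 0.5(a+0.5)^-3/2``), which is only
    defined at the conventional 95% level.
    """
    n = table.n_total
    if n <= 0:
        raise ValueError("empty table")
    a = table.a
    expected = (table.a + table.b) * (table.a + table.c) / n
    shrunk = a + 0.5
    denom = expected + 0.5
    ic = math.log2(shrunk / denom)
    if method == "gamma":
        low = math.log2(stats.gamma.ppf(alpha / 2, shrunk) / denom)
        high = math.log2(stats.gamma.ppf(1 - alpha / 2, shrunk) / denom)
    elif method == "approx":
        low = ic - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5
        high = ic + 2.4 * shrunk ** -0.5 + 0.5 * shrunk ** -1.5
    else:
        raise ValueError(f"unknown IC interval method: {method!r}")
    return IcEstimate(ic=ic, low=low, high=high, expected=expected)


def evaluate_signal(n_cases: int, ror_low: float, ic_low: float) -> bool:
    """Signal criterion: (ROR025 > 1 with >= 3 cases) or IC025 > 0.

    NaN bounds (not-computable statistics) never satisfy their branch.
    """
    ror_branch = (not math.isnan(ror_low)) and ror_low > 1 and n_cases >= 3
    ic_branch = (not math.isnan(ic_low)) and ic_low > 0
    return ror_branch or ic_branch


@dataclass(frozen=True)
class SignalResult:
    """ROR and IC estimates with interval bounds for one contrast."""

    design: str
    target: str
    comparator: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic_low: float
    ic_high: float
    expected: float
    signal: bool
    corrected: bool = False
    computable: bool = True
    flags: tuple[str, ...] = ()

    @property
    def n_cases(self) -> int:
        return self.a

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "target": self.target,
            "comparator": self.comparator,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "ROR": self.ror,
            "ROR025": self.ror_low,
            "ROR975": self.ror_high,
            "IC": self.ic,
            "IC025": self.ic_low,
            "IC975": self.ic_high,
            "E": self.expected,
            "signal": self.signal,
        }


def signal_from_table(
    table: ContingencyTable,
    alpha: float = 0.05,
    ic_method: IcMethod = "gamma",
    with_ic: bool = True,
) -> SignalResult:
    """Compute ROR, IC and the signal flag for one 2x2 table."""
    ror = compute_ror(table, alpha)
    if with_ic:
        ic = compute_ic(table, alpha, ic_method)
        ic_vals = (ic.ic, ic.low, ic.high, ic.expected)
    else:
        nan = float("nan")
        ic_vals = (nan, nan, nan, nan)
    return SignalResult(
        design=table.design_label,
        target=table.target,
        comparator=table.comparator,
        a=table.a,
        b=table.b,
        c=table.c,
        d=table.d,
        ror=ror.ror,
        ror_low=ror.low,
        ror_high=ror.high,
        ic=ic_vals[0],
        ic_low=ic_vals[1],
        ic_high=ic_vals[2],
        expected=ic_vals[3],
        signal=evaluate_signal(table.a, ror.low, ic_vals[1]),
        corrected=ror.corrected,
        computable=ror.computable,
        flags=table.flags,
    )


# ---------------------------------------------------------------------------
# Table construction from the case table
# ---------------------------------------------------------------------------

def _mask_class(case_table: pd.DataFrame, cls: str) -> pd.Series:
    if cls == "any":
        return case_table["substances"].map(bool).astype(bool)
    return case_table["classes"].map(lambda cs: cls in cs).astype(bool)


def _mask_mono(case_table: pd.DataFrame, substance: str) -> pd.Series:
    return (case_table["regimen"] == "monotherapy") & (
        case_table["regimen_key"] == substance
    )


def _mask_combo(case_table: pd.DataFrame, combo_key: str) -> pd.Series:
    return (case_table["regimen"] == "combination") & (
        case_table["regimen_key"] == combo_key
    )


def _mask_has_agent(case_table: pd.DataFrame, agent: str) -> pd.Series:
    agent_u = agent.strip().upper()
    return case_table["concomitants"].map(lambda cs: agent_u in cs).astype(bool)


def _table_from_masks(
    case_table: pd.DataFrame,
    target_mask: pd.Series,
    comparator_mask: pd.Series,
    design: str,
    target: str,
    comparator: str,
) -> ContingencyTable:
    event = case_table["is_event"].astype(bool)
    a = int((target_mask & event).sum())
    b = int((target_mask & ~event).sum())
    c = int((comparator_mask & event).sum())
    d = int((comparator_mask & ~event).sum())
    flags = ("empty_target",) if a + b == 0 else ()
    return ContingencyTable(
        a=a, b=b, c=c, d=d, design_label=design, target=target,
        comparator=comparator, flags=flags,
    )


def build_table(
    case_table: pd.DataFrame,
    design: str,
    target: str | tuple[str, str],
) -> ContingencyTable:
    """Build the 2x2 table for one contrast of one comparison design.

    Parameters
    ----------
    case_table
        Per-case analysis frame (deduplicated, classified) from
        :func:`faerspv.casetable.build_case_table`.
    design
        One of ``class_vs_all`` (target: class name or "any"),
        ``mono_vs_all`` (target: substance), ``combo_vs_mono`` (target:
        ``(combination key, comparator substance)``) and
        ``ici_plus_agent_vs_mono`` (target: concomitant agent name).
    """
    if design == "class_vs_all":
        tmask = _mask_class(case_table, str(target))
        return _table_from_masks(
            case_table, tmask, ~tmask, design, str(target), "all other drugs"
        )
    if design == "mono_vs_all":
        tmask = _mask_mono(case_table, str(target))
        return _table_from_masks(
            case_table, tmask, ~tmask, design, str(target), "all other drugs"
        )
    if design == "combo_vs_mono":
        combo_key, constituent = target  # type: ignore[misc]
        tmask = _mask_combo(case_table, combo_key)
        cmask = _mask_mono(case_table, constituent)
        return _table_from_masks(
            case_table, tmask, cmask, design, combo_key, f"{constituent} monotherapy"
        )
    if design == "ici_plus_agent_vs_mono":
        agent = str(target)
        exposed = case_table["substances"].map(bool).astype(bool)
        has_agent = _mask_has_agent(case_table, agent)
        tmask = exposed & has_agent
        cmask = (case_table["regimen"] == "monotherapy") & ~has_agent
        return _table_from_masks(
            case_table, tmask, cmask, design, f"ICI + {agent}",
            "ICI monotherapy without agent",
        )
    raise ValueError(f"unknown design: {design!r}")


def drug_vs_drug_ror(
    case_table: pd.DataFrame,
    target: str | pd.Series,
    comparator: str | pd.Series,
    alpha: float = 0.05,
    ic_method: IcMethod = "gamma",
) -> SignalResult:
    """Head-to-head contrast of two disjoint regimens (by regimen key or
    boolean masks); raises on overlapping definitions."""
    tmask = (
        (case_table["regimen_key"] == target) if isinstance(target, str) else target
    )
    cmask = (
        (case_table["regimen_key"] == comparator)
        if isinstance(comparator, str)
        else comparator
    )
    if (tmask & cmask).any():
        raise ValueError("target and comparator regimens overlap")
    table = _table_from_masks(
        case_table,
        tmask,
        cmask,
        "drug_vs_drug",
        target if isinstance(target, str) else "target",
        comparator if isinstance(comparator, str) else "comparator",
    )
    return signal_from_table(table, alpha=alpha, ic_method=ic_method)


def subgroup_ror(
    case_table: pd.DataFrame,
    stratifier: Literal["sex", "age"],
    alpha: float = 0.05,
) -> SignalResult:
    """ROR contrasting event odds between two subgroups of ICI-exposed cases.

    ``sex``: female vs male (unknown dropped); ``age``: < 65 vs >= 65 years
    (missing dropped).  Only the ROR is reported for subgroup contrasts;
    IC fields are NaN.
    """
    exposed = case_table[case_table["substances"].map(bool).astype(bool)]
    if stratifier == "sex":
        g1 = exposed["sex"] == "female"
        g2 = exposed["sex"] == "male"
        labels = ("female", "male")
    elif stratifier == "age":
        age = exposed["age_years"].astype(float)
        g1 = age < 65
        g2 = age >= 65
        labels = ("age<65", "age>=65")
    else:
        raise ValueError(f"unknown stratifier: {stratifier!r}")
    table = _table_from_masks(
        exposed, g1, g2, f"subgroup_{stratifier}", labels[0], labels[1]
    )
    if table.a + table.b == 0 or table.c + table.d == 0:
        table = replace(table, flags=table.flags + ("empty_stratum",))
    return signal_from_table(table, alpha=alpha, with_ic=False)


def reconstruct_two_by_two(
    a: int,
    event_total: int,
    grand_total: int,
    ror_point: float,
    design_label: str = "reconstructed",
) -> ContingencyTable:
    """Recover the full 2x2 from published margins and the point ROR.

    Given the exposed event count ``a``, the database-wide event count
    ``a + c`` and grand total ``N``, the remaining margin ``b`` solves
    ``ROR = (a/b) / (c/d)`` with ``d = N - a - c - b``; it is rounded to the
    nearest integer case count.
    """
    c = event_total - a
    if c < 0 or a < 0 or grand_total <= event_total:
        raise ValueError("inconsistent margins")
    b = round(a * (grand_total - event_total) / (ror_point * c + a))
    d = grand_total - event_total - b
    return ContingencyTable(a=a, b=int(b), c=c, d=int(d), design_label=design_label)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DisproportionalityModel:
    """Disproportionality screen of an adverse event across ICI regimens.

    Parameters
    ----------
    case_table
        Per-case analysis frame (deduplicated, classified) — see
        :func:`faerspv.casetable.build_case_table` or :meth:`from_reports`.
    designs
        Subset of the four comparison designs to run.
    alpha
        Two-sided significance level for ROR confidence and IC credible
        intervals (default 0.05, i.e. 95% bounds).
    ic_interval
        ``"gamma"`` for Gamma-quantile credible bounds (default) or
        ``"approx"`` for the closed-form expansion.
    top_k
        Number of most frequent concomitant agents screened in design 4.
    include_subgroups
        Whether :meth:`fit` also computes the sex and age subgroup RORs.
    """

    def __init__(
        self,
        case_table: pd.DataFrame,
        designs: Sequence[str] = DESIGNS,
        alpha: float = 0.05,
        ic_interval: IcMethod = "gamma",
        top_k: int = 20,
        include_subgroups: bool = True,
    ):
        unknown = set(designs) - set(DESIGNS)
        if unknown:
            raise ValueError(f"unknown design(s): {sorted(unknown)}")
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if top_k <= 0:
            raise ValueError("top_k must be positive")
        self.case_table = case_table
        self.designs = tuple(designs)
        self.alpha = alpha
        self.ic_interval: IcMethod = ic_interval
        self.top_k = top_k
        self.include_subgroups = include_subgroups

    @classmethod
    def from_reports(
        cls,
        reports: Sequence[SafetyReport],
        event: EventDefinition = HEPATIC_FAILURE,
        dictionary: DrugDictionary | None = None,
        **kwargs,
    ) -> "DisproportionalityModel":
        from .casetable import build_case_table

        return cls(build_case_table(reports, event, dictionary), **kwargs)

    # -- target enumeration -------------------------------------------------

    def _class_targets(self) -> list[str]:
        present = [
            cls for cls in ICI_CLASSES
            if _mask_class(self.case_table, cls).any()
        ]
        return ["any"] + present

    def _mono_targets(self) -> list[str]:
        mono = self.case_table[self.case_table["regimen"] == "monotherapy"]
        return sorted(mono["regimen_key"].unique())

    def _combo_targets(self) -> list[tuple[str, str]]:
        combos = self.case_table[self.case_table["regimen"] == "combination"]
        mono_subs = set(self._mono_targets())
        pairs = []
        for key in sorted(combos["regimen_key"].unique()):
            for constituent in key.split("+"):
                if constituent in mono_subs:
                    pairs.append((key, constituent))
        return pairs

    def _agent_targets(self) -> list[str]:
        from collections import Counter

        counts: Counter[str] = Counter()
        exposed = self.case_table[
            self.case_table["substances"].map(bool).astype(bool)
        ]
        for agents in exposed["concomitants"]:
            counts.update(agents)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [name for name, _ in ranked[: self.top_k]]

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "DisproportionalityResults":
        """Compute ROR/IC for every contrast of the requested designs."""
        results: list[SignalResult] = []
        enumerators: dict[str, Callable[[], Iterable]] = {
            "class_vs_all": self._class_targets,
            "mono_vs_all": self._mono_targets,
            "combo_vs_mono": self._combo_targets,
            "ici_plus_agent_vs_mono": self._agent_targets,
        }
        for design in self.designs:
            for target in enumerators[design]():
                table = build_table(self.case_table, design, target)
                results.append(
                    signal_from_table(
                        table, alpha=self.alpha, ic_method=self.ic_interval
                    )
                )
        subgroups: list[SignalResult] = []
        if self.include_subgroups:
            for strat in ("sex", "age"):
                subgroups.append(
                    subgroup_ror(self.case_table, strat, alpha=self.alpha)
                )
        return DisproportionalityResults(
            model=self, results=results, subgroup_results=subgroups
        )


@dataclass
class DisproportionalityResults:
    """Fitted signal screen: one :class:`SignalResult` per contrast."""

    model: DisproportionalityModel
    results: list[SignalResult]
    subgroup_results: list[SignalResult] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    @property
    def subgroups(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.subgroup_results])
        if len(df):
            df = df.drop(columns=["IC", "IC025", "IC975", "E"])
        return df

    def summary(self) -> str:
        """Human-readable table of all contrasts."""
        lines = [
            "Disproportionality screen "
            f"(alpha={self.model.alpha}, IC interval={self.model.ic_interval})",
            "",
        ]
        df = self.frame
        if len(df):
            with pd.option_context("display.width", 200, "display.max_columns", 50):
                lines.append(
                    df.round(
                        {"ROR": 2, "ROR025": 2, "ROR975": 2, "IC": 2, "IC025": 2,
                         "IC975": 2, "E": 1}
                    ).to_string(index=False)
                )
        sg = self.subgroups
        if len(sg):
            lines += ["", "Subgroup RORs (ICI-exposed cases):"]
            lines.append(
                sg.round({"ROR": 2, "ROR025": 2, "ROR975": 2}).to_string(index=False)
            )
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        """Write one forest-plot-ready CSV per design (plus subgroups)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        df = self.frame
        for design in sorted(df["design"].unique()) if len(df) else []:
            path = out / f"signals_{design}.csv"
            df[df["design"] == design].to_csv(path, index=False)
            paths[design] = path
        sg = self.subgroups
        if len(sg):
            path = out / "signals_subgroups.csv"
            sg.to_csv(path, index=False)
            paths["subgroups"] = path
        return paths
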
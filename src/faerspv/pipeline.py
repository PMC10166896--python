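"""End-to-end orchestration: ingest -> dedup -> classify -> analyze -> report.

A :class:`RunConfig` describes one reproducible run over either real
FAERS-style quarterly files, the seeded simulator, or the deterministic
published-table fixture.  :func:`run` executes the stages in order, writes
the descriptive and per-design signal CSVs plus a JSON manifest with the
case-flow counts (parsed -> deduplicated -> event cases -> ICI event cases),
and aborts with a stage-named error (removing partial outputs) if any stage
fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cases import DrugDictionary, EventDefinition, HEPATIC_FAILURE
from .casetable import build_case_table
from .descriptives import (
    chisq_fatality,
    fatality_proportion,
    kruskal_wallis_tto,
    summarize,
)
from .io import (
    assemble_reports,
    deduplicate_cases,
    find_quarter_files,
    read_quarter,
    write_case_table,
)
from .signals import DESIGNS, DisproportionalityModel
from .simulate import SimConfig, fixture_table1_quarters, generate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str | None = None
    quarters: Sequence[str] = ()
    sim: SimConfig | None = None
    use_fixture: bool = False
    dictionary_path: str | None = None
    designs: Sequence[str] = DESIGNS
    subgroups: bool = True
    ic_variant: str = "gamma"
    alpha: float = 0.05
    top_k: int = 20
    out_dir: str = "faerspv_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.designs) - set(DESIGNS)
        if unknown:
            raise ValueError(f"unknown design(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            effects = sim.pop("injected_effects", None)
            if effects is not None:
                from .simulate import InjectedEffect

                sim["injected_effects"] = [InjectedEffect(**e) for e in effects]
            cfg.sim = SimConfig(**sim)
        return cfg


def _event_from_config() -> EventDefinition:
    return HEPATIC_FAILURE


def run(config: RunConfig) -> dict:
    """Execute the full study; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def track(p) -> None:
        if isinstance(p, dict):
            for v in p.values():
                track(v)
        else:
            created.append(Path(p))

    try:
        return _run_stages(config, out, track)
    except Exception as exc:
        for p in created:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, StageError):
            raise
        raise StageError(f"pipeline failed: {exc}") from exc


def _run_stages(config: RunConfig, out: Path, track) -> dict:
    # -- stage: ingest ------------------------------------------------------
    try:
        if config.use_fixture:
            quarters = fixture_table1_quarters()
        elif config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            input_dir = out / "synthetic_input"
            paths, truth = generate(sim, input_dir)
            track(paths)
            from .simulate import write_ground_truth

            track(write_ground_truth(truth, out / "ground_truth.csv"))
            quarters = [
                read_quarter(qpaths, qlab) for qlab, qpaths in sorted(paths.items())
            ]
        elif config.input_dir is not None:
            if not config.quarters:
                raise ValueError("quarter labels are required with input_dir")
            quarters = [
                read_quarter(find_quarter_files(config.input_dir, q), q)
                for q in config.quarters
            ]
        else:
            raise ValueError("one of input_dir, sim or use_fixture is required")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"ingest: {exc}") from exc

    parse_log = "\n".join(q.parse_log.to_text() for q in quarters if q.parse_log.to_text())
    (out / "parse_log.txt").write_text(parse_log + "\n")
    track(out / "parse_log.txt")

    # -- stage: assemble + dedup -------------------------------------------
    try:
        reports = assemble_reports(quarters)
        n_parsed = len(reports)
        deduped = deduplicate_cases(reports)
        track(write_case_table(deduped, out))
    except Exception as exc:
        raise StageError(f"deduplicate: {exc}") from exc

    # -- stage: classify ----------------------------------------------------
    try:
        dictionary = (
            DrugDictionary.from_csv(config.dictionary_path)
            if config.dictionary_path
            else DrugDictionary.default()
        )
        event = _event_from_config()
        case_table = build_case_table(deduped, event, dictionary)
        event_cases = case_table[case_table["is_event"].astype(bool)]
        ici_event = event_cases[event_cases["substances"].map(bool).astype(bool)]
    except Exception as exc:
        raise StageError(f"classify: {exc}") from exc

    # -- stage: descriptives ------------------------------------------------
    try:
        summary = summarize(ici_event)
        summary_path = out / "descriptives_table1.csv"
        summary.to_frame().to_csv(summary_path, index=False)
        track(summary_path)

        tto_path = out / "tto_cases.csv"
        tto_cases = ici_event[~ici_event["tto_days"].isna()][
            ["case_id", "regimen_key", "tto_days"]
        ]
        tto_cases.to_csv(tto_path, index=False)
        track(tto_path)

        tests: dict = {}
        if len(ici_event):
            fat = fatality_proportion(ici_event)
            tests["fatality"] = {
                "deaths": fat.deaths,
                "total": fat.total,
                "proportion_pct": fat.proportion,
            }
            tto_by_sub: dict[str, list[float]] = {}
            for subs, tto in zip(ici_event["substances"], ici_event["tto_days"]):
                if not pd.isna(tto):
                    for s in subs:
                        tto_by_sub.setdefault(s, []).append(float(tto))
            kw = kruskal_wallis_tto(tto_by_sub)
            if kw is not None:
                tests["kruskal_wallis_tto"] = {
                    "H": kw.statistic,
                    "p": kw.pvalue,
                    "groups": kw.groups,
                    "pairwise": kw.pairwise.to_dict("records"),
                }
            deaths_by_drug = {
                row["substance"]: (int(row["deaths"]), int(row["total"]))
                for _, row in fat.per_substance.iterrows()
            }
            chi = chisq_fatality(deaths_by_drug)
            if chi is not None:
                tests["chisq_fatality"] = {
                    "X2": chi.statistic,
                    "df": chi.df,
                    "p": chi.pvalue,
                    "drugs": list(chi.drugs),
                    "low_expected": chi.low_expected,
                }
        tests_path = out / "tests.json"
        tests_path.write_text(json.dumps(tests, indent=2, default=float) + "\n")
        track(tests_path)
    except Exception as exc:
        raise StageError(f"descriptives: {exc}") from exc

    # -- stage: disproportionality -----------------------------------------
    try:
        signal_paths: dict = {}
        if config.designs:
            model = DisproportionalityModel(
                case_table,
                designs=config.designs,
                alpha=config.alpha,
                ic_interval=config.ic_variant,  # type: ignore[arg-type]
                top_k=config.top_k,
                include_subgroups=config.subgroups,
            )
            results = model.fit()
            signal_paths = results.to_csv(out)
            track(signal_paths)
    except Exception as exc:
        raise StageError(f"disproportionality: {exc}") from exc

    # -- stage: manifest ----------------------------------------------------
    manifest = {
        "faerspv_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "case_flow": {
            "parsed_reports": n_parsed,
            "deduplicated_cases": len(case_table),
            "event_cases": int(case_table["is_event"].sum()),
            "ici_event_cases": len(ici_event),
        },
        "outputs": {
            "descriptives": str(summary_path),
            "tto": str(tto_path),
            "tests": str(tests_path),
            "signals": {k: str(v) for k, v in signal_paths.items()},
        },
    }
    flow = manifest["case_flow"]
    assert flow["deduplicated_cases"] <= flow["parsed_reports"]
    assert flow["event_cases"] <= flow["deduplicated_cases"]
    assert flow["ici_event_cases"] <= flow["event_cases"]
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
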
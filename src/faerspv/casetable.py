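"""Per-case analysis frame.

Flattens deduplicated :class:`~faerspv.io.SafetyReport` records plus their
exposure classification into one pandas row per case — the in-memory
container every downstream analysis (descriptives, disproportionality)
consumes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cases import DrugDictionary, EventDefinition, HEPATIC_FAILURE, classify_exposure, is_event_case
from .descriptives import compute_tto
from .io import SafetyReport

#: Columns of the case table.
CASE_COLUMNS = (
    "case_id",
    "primary_id",
    "is_event",
    "regimen",
    "regimen_key",
    "substances",
    "classes",
    "concomitants",
    "n_concomitant",
    "sex",
    "age_years",
    "region",
    "reporter_type",
    "report_year",
    "outcomes",
    "died",
    "indications",
    "tto_days",
)


def build_case_table(
    reports: Sequence[SafetyReport],
    event: EventDefinition = HEPATIC_FAILURE,
    dictionary: DrugDictionary | None = None,
) -> pd.DataFrame:
    """Classify each report and flatten it into the analysis frame.

    TTO is computed only for event cases with ICI exposure (it is defined
    relative to the first suspect-ICI dose).
    """
    if dictionary is None:
        dictionary = DrugDictionary.default()
    rows = []
    for rep in reports:
        label = classify_exposure(rep, dictionary)
        event_flag = is_event_case(rep, event)
        tto = (
            compute_tto(rep, label, dictionary)
            if event_flag and label.ici_exposed
            else None
        )
        rows.append(
            {
                "case_id": rep.case_id,
                "primary_id": rep.primary_id,
                "is_event": event_flag,
                "regimen": label.regimen,
                "regimen_key": label.regimen_key,
                "substances": label.ici_substances,
                "classes": label.classes,
                "concomitants": label.concomitant_substances,
                "n_concomitant": len(label.concomitant_substances),
                "sex": rep.sex,
                "age_years": np.nan if rep.age_years is None else rep.age_years,
                "region": rep.region,
                "reporter_type": rep.reporter_type,
                "report_year": np.nan if rep.report_year is None else rep.report_year,
                "outcomes": rep.outcomes,
                "died": "DE" in rep.outcomes,
                "indications": rep.indications,
                "tto_days": np.nan if tto is None else float(tto.days),
            }
        )
    return pd.DataFrame(rows, columns=list(CASE_COLUMNS))
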
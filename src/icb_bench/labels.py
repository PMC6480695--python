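"""Dichotomous responder / non-responder labelling.

Source cohorts annotate clinical benefit heterogeneously; everything is first
mapped to six canonical codes (CR, PR, SD, PD, LB, NB) and then collapsed to
two classes with an overall-survival rescue for progressive disease:

* CR, PR, SD, LB -> responder;
* PD with known overall survival strictly greater than the cutoff
  (default 2 years) -> responder;
* PD otherwise (OS <= cutoff, or OS unknown) and NB -> non-responder.

Survival times are converted to days internally (1 year = 365.25 days) so
cohorts reporting different units can share one cutoff.
"""

from __future__ import annotations

import pandas as pd

from .errors import EmptyInputError, VocabularyError

__all__ = [
    "CANONICAL_CODES",
    "RESPONDER",
    "NON_RESPONDER",
    "assign_labels",
    "label_balance",
    "to_days",
]

CANONICAL_CODES = frozenset({"CR", "PR", "SD", "PD", "LB", "NB"})
RESPONDER = "responder"
NON_RESPONDER = "non-responder"

_CATEGORY_RESPONDER = frozenset({"CR", "PR", "SD", "LB"})

_DAYS_PER_UNIT = {
    "days": 1.0,
    "months": 365.25 / 12.0,
    "years": 365.25,
}


def to_days(value: float, unit: str) -> float:
    """Convert a survival time to days (1 year = 365.25 days)."""
    try:
        return float(value) * _DAYS_PER_UNIT[unit]
    except KeyError:
        raise VocabularyError(f"unknown survival unit {unit!r}") from None


def assign_labels(clinical: pd.DataFrame, os_cutoff_years: float = 2.0) -> pd.DataFrame:
    """Label every patient responder / non-responder.

    ``clinical`` needs columns ``patient_id``, ``response_category``,
    ``os_value``, ``os_unit``, ``os_known``. Returns a frame with columns
    ``patient_id``, ``label``, ``basis`` (``category-only`` for the five
    categories decided without survival, ``category+OS`` for PD patients).
    OS exactly equal to the cutoff counts as non-responder (the rescue rule
    is strict).
    """
    bad = clinical.loc[~clinical["response_category"].isin(CANONICAL_CODES)]
    if len(bad):
        rows = bad[["patient_id", "response_category"]].to_dict("records")
        raise VocabularyError(f"unknown response categories: {rows}")

    cutoff_days = os_cutoff_years * 365.25
    out = []
    for row in clinical.itertuples(index=False):
        cat = row.response_category
        if cat in _CATEGORY_RESPONDER:
            label, basis = RESPONDER, "category-only"
        elif cat == "NB":
            label, basis = NON_RESPONDER, "category-only"
        else:  # PD: survival rescue
            basis = "category+OS"
            known = bool(row.os_known) and pd.notna(row.os_value)
            if known and to_days(row.os_value, row.os_unit) > cutoff_days:
                label = RESPONDER
            else:
                label = NON_RESPONDER
        out.append((row.patient_id, label, basis))
    return pd.DataFrame(out, columns=["patient_id", "label", "basis"])


def label_balance(labels: pd.DataFrame | pd.Series) -> float:
    """Fraction of responders among all labelled patients."""
    series = labels["label"] if isinstance(labels, pd.DataFrame) else labels
    if len(series) == 0:
        raise EmptyInputError("no labels given")
    return float((series == RESPONDER).mean())
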
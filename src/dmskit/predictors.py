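"""Binary pathogenicity calls from predictor scores and concordance with DMS.

Three widely used predictors are supported with their published operating
points: CADD scaled PHRED >= 20, REVEL >= 0.75, AlphaMissense >= 0.564
(all non-strict).  Concordance between the screen's functional calls and a
predictor's binary calls is tabulated per mutation class: a variant is
concordant when both agree it is damaging (DMS LOF and predictor
pathogenic) or both agree it is not.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

PATHOGENIC = "pathogenic"
BENIGN = "benign"

#: published classification thresholds (score >= threshold -> pathogenic)
THRESHOLDS: dict[str, float] = {
    "CADD": 20.0,         # scaled PHRED
    "REVEL": 0.75,
    "AlphaMissense": 0.564,
}


def classify_predictor(score: float, tool: str) -> str:
    """Binary call for one predictor score (non-strict ``>=`` threshold)."""
    if tool not in THRESHOLDS:
        raise ValueError(f"unknown tool {tool!r}; expected one of {sorted(THRESHOLDS)}")
    return PATHOGENIC if score >= THRESHOLDS[tool] else BENIGN


def classify_table(pred: pd.DataFrame) -> pd.DataFrame:
    """Add a ``call`` column to a (variant_id, tool, score) table."""
    unknown = set(pred["tool"]) - set(THRESHOLDS)
    if unknown:
        raise ValueError(f"unknown tools {sorted(unknown)}")
    out = pred.copy()
    thresholds = out["tool"].map(THRESHOLDS)
    out["call"] = (out["score"] >= thresholds).map({True: PATHOGENIC, False: BENIGN})
    return out


class Concordance(NamedTuple):
    n_concordant: int
    n_total: int
    percent: float  # rounded to one decimal


def concordance_by_class(
    dms_calls: pd.DataFrame,
    predictor_calls: pd.DataFrame,
    mutation_class: str | None = None,
    pathogenic_only: bool = False,
) -> Concordance:
    """Fraction of variants on which DMS and a predictor agree.

    ``dms_calls`` needs ``variant_id`` and boolean ``lof`` (plus
    ``mutation_class`` if filtering); ``predictor_calls`` needs
    ``variant_id`` and ``call``.  By default agreement is symmetric in both
    directions; with ``pathogenic_only`` a variant counts as concordant only
    when both sides call it damaging.  The percentage is reported to one
    decimal place.
    """
    dms = dms_calls
    if mutation_class is not None:
        dms = dms[dms["mutation_class"] == mutation_class]
    joined = dms.merge(predictor_calls[["variant_id", "call"]], on="variant_id")
    if joined.empty:
        raise ValueError("no variants shared between the DMS and predictor tables")
    pred_path = joined["call"] == PATHOGENIC
    if pathogenic_only:
        concordant = joined["lof"] & pred_path
    else:
        concordant = joined["lof"] == pred_path
    n_conc, n_tot = int(concordant.sum()), len(joined)
    return Concordance(n_conc, n_tot, round(100.0 * n_conc / n_tot, 1))


def pathogenic_fraction(n_pathogenic: int, n_total: int) -> float:
    """Percentage of variants classified pathogenic, ``100 * n / total``.

    Returned at full precision; round to the reporting precision at the
    point of display.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pathogenic <= n_total:
        raise ValueError("need 0 <= n_pathogenic <= n_total")
    return 100.0 * n_pathogenic / n_total
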
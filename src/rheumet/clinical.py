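"""Disease-activity banding and treatment-response classification.

Implements the EULAR DAS28 response rule, the BASDAI (ASAS-style) response
rule, the printed activity bands, and per-disease response-rate summaries.

Remission is not part of the banding rules themselves; the summarizer uses
the conventional external-guideline thresholds DAS28 < 2.6 and BASDAI < 3
by default, both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalRecord", "RemissionThresholds",
    "activity_band", "eular_response", "basdai_response",
    "summarize_response_rates", "records_from_frame",
]

SCORE_TYPES = ("DAS28", "BASDAI")


@dataclass
class ClinicalRecord:
    subject_id: str
    disease: str
    score_type: str
    baseline_score: float
    endpoint_score: float
    timepoint: str

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise ValueError(f"unknown score type {self.score_type!r}")
        if self.disease == "RA" and self.score_type != "DAS28":
            raise ValueError("RA activity is scored with DAS28")
        if self.disease == "AS" and self.score_type != "BASDAI":
            raise ValueError("AS activity is scored with BASDAI")
        if self.baseline_score < 0 or self.endpoint_score < 0:
            raise ValueError("scores must be >= 0")


@dataclass
class RemissionThresholds:
    das28: float = 2.6
    basdai: float = 3.0


def activity_band(score_type: str, value: float) -> str:
    """Disease-activity band.

    DAS28: high > 5.1, moderate 3.2 < x <= 5.1, low <= 3.2.
    BASDAI: high >= 4, moderate 3 <= x < 4, low < 3.
    Boundary handling follows the printed inequalities exactly.
    """
    if value < 0:
        raise ValueError("activity score must be >= 0")
    if score_type == "DAS28":
        if value > 5.1:
            return "high"
        if value > 3.2:
            return "moderate"
        return "low"
    if score_type == "BASDAI":
        if value >= 4:
            return "high"
        if value >= 3:
            return "moderate"
        return "low"
    raise ValueError(f"unknown score type {score_type!r}")


def eular_response(baseline_das28: float, endpoint_das28: float) -> str:
    """EULAR DAS28 response category (delta = baseline - endpoint).

    good:     delta > 1.2 and endpoint <= 3.2
    moderate: delta > 1.2 and endpoint > 3.2, or
              0.6 < delta <= 1.2 and endpoint <= 5.1
    none:     delta <= 0.6, or 0.6 < delta <= 1.2 and endpoint > 5.1
    """
    if baseline_das28 < 0 or endpoint_das28 < 0:
        raise ValueError("scores must be >= 0")
    delta = baseline_das28 - endpoint_das28
    if delta > 1.2:
        return "good" if endpoint_das28 <= 3.2 else "moderate"
    if delta > 0.6:
        return "moderate" if endpoint_das28 <= 5.1 else "none"
    return "none"


def basdai_response(baseline_basdai: float,
                    endpoint_basdai: float) -> tuple[str, bool]:
    """BASDAI response category plus the significant-improvement flag.

    significant improvement: delta >= 2.0
    good:     delta >= 2.0 and endpoint < 3.0
    moderate: delta >= 2.0 and endpoint >= 3.0
    none:     delta < 2.0
    """
    if baseline_basdai < 0 or endpoint_basdai < 0:
        raise ValueError("scores must be >= 0")
    delta = baseline_basdai - endpoint_basdai
    significant = delta >= 2.0
    if not significant:
        return "none", False
    return ("good" if endpoint_basdai < 3.0 else "moderate"), True


def response_category(record: ClinicalRecord) -> str:
    if record.score_type == "DAS28":
        return eular_response(record.baseline_score, record.endpoint_score)
    return basdai_response(record.baseline_score, record.endpoint_score)[0]


def summarize_response_rates(records: list[ClinicalRecord],
                             timepoint: str,
                             thresholds: RemissionThresholds | None = None
                             ) -> pd.DataFrame:
    """Per-disease counts, exact fractions and nearest-integer percentages
    of remission / low-activity / no-response at one follow-up timepoint.

    ``remission``: endpoint score below the remission threshold;
    ``low_activity``: endpoint in the low band but not in remission;
    ``no_response``: response category "none".  Exact fractions are
    reported alongside rounded percentages because rounded percentages
    alone are ambiguous at these denominators.
    """
    thresholds = thresholds or RemissionThresholds()
    recs = [r for r in records if r.timepoint == timepoint]
    if not recs:
        raise ValueError(f"no records at timepoint {timepoint!r}")
    rows = []
    for disease in sorted({r.disease for r in recs}):
        sub = [r for r in recs if r.disease == disease]
        n = len(sub)
        remission = low = none = 0
        for r in sub:
            thr = thresholds.das28 if r.score_type == "DAS28" \
                else thresholds.basdai
            if r.endpoint_score < thr:
                remission += 1
            elif activity_band(r.score_type, r.endpoint_score) == "low":
                low += 1
            if response_category(r) == "none":
                none += 1
        for cat, count in (("remission", remission),
                           ("low_activity", low),
                           ("no_response", none)):
            rows.append({
                "disease": disease, "timepoint": timepoint,
                "category": cat, "count": count, "n": n,
                "fraction": count / n,
                "percent": int(round(100.0 * count / n)),
            })
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    """ClinicalRecords from a tidy table (columns subject_id, disease,
    score_type, baseline_score, endpoint_score, timepoint)."""
    return [ClinicalRecord(r.subject_id, r.disease, r.score_type,
                           float(r.baseline_score), float(r.endpoint_score),
                           r.timepoint)
            for r in df.itertuples(index=False)]
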
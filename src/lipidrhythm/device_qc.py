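"""Reliability and validity statistics for point-of-care lipid self-testing.

Imprecision (unreliability) is the percent coefficient of variation of a
time-paired duplicate self-test: 100 * SD(a, b) / mean(a, b) with the
n-1 sample SD. Inaccuracy (invalidity, "total error" TE) is the percent
disagreement between a self-test and a time-paired clinical venous
value: 100 * |self - reference| / reference. Both follow the simple
definitions used to compare against the meter manufacturer's public
validations — not the CLSI bias + 1.96*CV formulation.

Default pass thresholds: the <8.9% TE standard for lipid measurement
validity, the manufacturer's 4.45% CV and 13% average TE, and the
84-86% correct-risk-category band. Large individual errors (e.g. a
low-triglyceride outlier) are flagged but never removed or clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import Analyte, CohortTable
from .risk_classification import RiskScheme
from .synthetic_cohort import ClinicalPair, PairedTest

__all__ = [
    "QCThresholds",
    "QCReport",
    "paired_cv",
    "total_error",
    "qc_report",
    "pairs_from_cohort",
    "clinical_pairs_from_cohort",
]


@dataclass(frozen=True)
class QCThresholds:
    """Pass/fail standards for device QC, in percent."""

    te_standard: float = 8.9
    manufacturer_cv: float = 4.45
    category_agreement_low: float = 84.0
    category_agreement_high: float = 86.0
    manufacturer_te: float = 13.0

    def __post_init__(self) -> None:
        for f in (
            self.te_standard,
            self.manufacturer_cv,
            self.category_agreement_low,
            self.category_agreement_high,
            self.manufacturer_te,
        ):
            if f < 0:
                raise ValueError("thresholds must be >= 0")


def paired_cv(a: float, b: float) -> float:
    """Percent CV of one duplicate pair: 100 * SD(a, b) / mean(a, b).

    SD uses the n-1 denominator, i.e. SD = |a - b| / sqrt(2).
    """
    if a <= 0 or b <= 0:
        raise ValueError("paired values must be positive")
    mean = 0.5 * (a + b)
    sd = abs(a - b) / math.sqrt(2.0)
    return 100.0 * sd / mean


def total_error(self_value: float, reference_value: float) -> float:
    """Percent disagreement of a self-test vs its clinical reference.

    Asymmetric by construction: the clinical value is the denominator.
    Large errors are returned as-is, never clipped.
    """
    if self_value <= 0 or reference_value <= 0:
        raise ValueError("values must be positive")
    return 100.0 * abs(self_value - reference_value) / reference_value


@dataclass
class QCReport:
    """Aggregated imprecision/inaccuracy statistics with pass flags."""

    pair_rows: pd.DataFrame  # participant, analyte, first, second, cv_pct
    clinical_rows: pd.DataFrame  # participant, analyte, self, reference, te_pct, ...
    per_participant_cv: pd.DataFrame
    cohort_mean_cv: float
    per_analyte_te: pd.DataFrame  # analyte, mean_te, sd_te, n
    mean_te: float
    category_agreement: float  # fraction in [0,1], NaN without clinical pairs
    thresholds: QCThresholds
    passes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_pairs": len(self.pair_rows),
            "n_clinical_pairs": len(self.clinical_rows),
            "cohort_mean_cv_pct": self.cohort_mean_cv,
            "mean_te_pct": self.mean_te,
            "per_analyte_te": self.per_analyte_te.to_dict(orient="records"),
            "category_agreement_pct": 100.0 * self.category_agreement
            if not math.isnan(self.category_agreement)
            else float("nan"),
            "thresholds": {
                "te_standard_pct": self.thresholds.te_standard,
                "manufacturer_cv_pct": self.thresholds.manufacturer_cv,
                "manufacturer_te_pct": self.thresholds.manufacturer_te,
                "category_agreement_band_pct": [
                    self.thresholds.category_agreement_low,
                    self.thresholds.category_agreement_high,
                ],
            },
            "passes": dict(self.passes),
        }


def qc_report(
    pairs: Sequence[PairedTest],
    clinical_pairs: Sequence[ClinicalPair] = (),
    scheme: Optional[RiskScheme] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Aggregate per-pair CV and TE statistics against the thresholds.

    Category agreement is the fraction of clinical pairs whose self-test
    and reference classify into the same risk band of the given scheme.
    """
    if not pairs:
        raise ValueError("need at least one duplicate pair")
    scheme = scheme or RiskScheme.ncep_default()

    pair_rows = pd.DataFrame(
        [
            {
                "participant": p.participant_id,
                "analyte": p.analyte.value,
                "pair_id": p.pair_id,
                "first": p.first,
                "second": p.second,
                "cv_pct": paired_cv(p.first, p.second),
            }
            for p in pairs
        ]
    )
    per_participant_cv = (
        pair_rows.groupby("participant")["cv_pct"].agg(mean_cv="mean", n="count").reset_index()
    )
    cohort_mean_cv = float(pair_rows["cv_pct"].mean())

    clin_records = []
    for c in clinical_pairs:
        te = total_error(c.self_value, c.reference_value)
        same = scheme.category_index(c.analyte, c.self_value) == scheme.category_index(
            c.analyte, c.reference_value
        )
        clin_records.append(
            {
                "participant": c.participant_id,
                "analyte": c.analyte.value,
                "self": c.self_value,
                "reference": c.reference_value,
                "te_pct": te,
                "category_match": same,
                "exceeds_te_standard": te > thresholds.te_standard,
            }
        )
    clinical_rows = pd.DataFrame(
        clin_records,
        columns=[
            "participant",
            "analyte",
            "self",
            "reference",
            "te_pct",
            "category_match",
            "exceeds_te_standard",
        ],
    )
    if len(clinical_rows):
        per_analyte_te = (
            clinical_rows.groupby("analyte")["te_pct"]
            .agg(
                mean_te="mean",
                sd_te=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
                n="count",
            )
            .reset_index()
        )
        mean_te = float(clinical_rows["te_pct"].mean())
        agreement = float(clinical_rows["category_match"].mean())
    else:
        per_analyte_te = pd.DataFrame(columns=["analyte", "mean_te", "sd_te", "n"])
        mean_te = float("nan")
        agreement = float("nan")

    passes = {
        "cv_vs_manufacturer": cohort_mean_cv <= thresholds.manufacturer_cv,
        "te_vs_standard": (not math.isnan(mean_te)) and mean_te <= thresholds.te_standard,
        "te_vs_manufacturer": (not math.isnan(mean_te))
        and mean_te <= thresholds.manufacturer_te,
        "category_agreement": (not math.isnan(agreement))
        and 100.0 * agreement >= thresholds.category_agreement_low,
    }
    return QCReport(
        pair_rows=pair_rows,
        clinical_rows=clinical_rows,
        per_participant_cv=per_participant_cv,
        cohort_mean_cv=cohort_mean_cv,
        per_analyte_te=per_analyte_te,
        mean_te=mean_te,
        category_agreement=agreement,
        thresholds=thresholds,
        passes=passes,
    )


def pairs_from_cohort(cohort: CohortTable) -> list[PairedTest]:
    """Extract duplicate QC pairs linked by an explicit ``pair_id``.

    Pairing is by identifier, never timestamp-proximity inference, so the
    extraction is deterministic and auditable. Groups that do not contain
    exactly two samples of one analyte are skipped.
    """
    by_pair: dict[tuple[str, str, Analyte], list] = {}
    for s in cohort.iter_samples():
        if s.pair_id is not None:
            by_pair.setdefault((s.participant_id, s.pair_id, s.analyte), []).append(s)
    pairs = []
    for (pid, pair_id, analyte), samples in sorted(
        by_pair.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
    ):
        if len(samples) != 2:
            continue
        first, second = sorted(samples, key=lambda s: s.timestamp)
        pairs.append(
            PairedTest(
                participant_id=pid,
                analyte=analyte,
                first=first.value,
                second=second.value,
                pair_id=pair_id,
            )
        )
    return pairs


def clinical_pairs_from_cohort(cohort: CohortTable) -> list[ClinicalPair]:
    """Extract self-vs-clinical pairs from samples carrying a reference value."""
    out = []
    for s in cohort.iter_samples():
        if s.reference_value is not None:
            out.append(
                ClinicalPair(
                    participant_id=s.participant_id,
                    analyte=s.analyte,
                    self_value=s.value,
                    reference_value=s.reference_value,
                )
            )
    return out
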
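"""Obstetric cohort model: patients, swabs, gestational-age arithmetic.

Gestational ages are stored as total days and displayed in the clinical
"weeks + days" notation ("17 + 4" = 123 days).  Delivery before
37 + 0 weeks (259 days) counts as preterm; deliveries are further
categorised as midtrimester miscarriage (< 24 + 0), extreme preterm
(24 + 0 to < 28 + 0), very preterm (28 + 0 to 31 + 6), late preterm
(32 + 0 to 36 + 6) or term (≥ 37 + 0).

Analysis sets follow the study design: the bacterial-vaginosis (BV)
endpoint labels a patient positive if any swab in pregnancy tested
positive; the preterm endpoint excludes iatrogenic deliveries and
unknown outcomes, and each patient contributes one swab — either the
first taken (earliest gestation) or the one taken closest to delivery.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GestationalAge",
    "DeliveryCategory",
    "Swab",
    "Patient",
    "RateField",
    "CohortSummary",
    "GroupComparison",
    "parse_gestation",
    "format_gestation_days",
    "categorize_delivery",
    "select_analysis_swab",
    "build_analysis_set",
    "summarize_cohort",
    "compare_groups",
    "median_iqr",
    "read_cohort",
    "write_cohort",
]

PRETERM_CUTOFF_DAYS = 259  # 37 + 0 weeks

_GA_RE = re.compile(r"^\s*(\d+)\s*\+\s*(\d+)\s*$")


@dataclass(frozen=True, order=True)
class GestationalAge:
    """A gestational age in total days, displayed as 'weeks + days'."""

    days: int

    def __post_init__(self) -> None:
        if self.days < 0:
            raise ValueError("gestational age cannot be negative")

    @property
    def weeks(self) -> int:
        return self.days // 7

    @property
    def remainder_days(self) -> int:
        return self.days % 7

    def __str__(self) -> str:
        return f"{self.weeks} + {self.remainder_days}"

    @classmethod
    def from_weeks_days(cls, weeks: int, days: int) -> "GestationalAge":
        if not (0 <= days <= 6) or weeks < 0:
            raise ValueError(f"invalid weeks + days: {weeks} + {days}")
        return cls(7 * weeks + days)


def parse_gestation(text: str) -> GestationalAge:
    """Parse 'W + D' clinical notation; D must lie in 0..6."""
    m = _GA_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse gestational age {text!r} (expected 'W + D')")
    weeks, days = int(m.group(1)), int(m.group(2))
    if days > 6:
        raise ValueError(f"day component must be 0..6 in {text!r}")
    return GestationalAge.from_weeks_days(weeks, days)


def format_gestation_days(days: float) -> str:
    """Render a (possibly fractional) day count as 'W + D', nearest day."""
    d = int(round(days))
    return str(GestationalAge(d))


class DeliveryCategory(str, Enum):
    MIDTRIMESTER_MISCARRIAGE = "midtrimester_miscarriage"
    EXTREME_PRETERM = "extreme_preterm"
    VERY_PRETERM = "very_preterm"
    LATE_PRETERM = "late_preterm"
    TERM = "term"


def categorize_delivery(ga: GestationalAge) -> DeliveryCategory:
    """Map delivery gestation to its clinical category (partition of days)."""
    d = ga.days
    if d < 168:  # 24 + 0
        return DeliveryCategory.MIDTRIMESTER_MISCARRIAGE
    if d < 196:  # 28 + 0
        return DeliveryCategory.EXTREME_PRETERM
    if d < 224:  # 32 + 0
        return DeliveryCategory.VERY_PRETERM
    if d < PRETERM_CUTOFF_DAYS:  # 37 + 0
        return DeliveryCategory.LATE_PRETERM
    return DeliveryCategory.TERM


@dataclass(frozen=True)
class Swab:
    """One vaginal swab with its linked spectrum and BV culture result."""

    patient_id: str
    sample_id: str
    gestation_at_sampling: GestationalAge
    bv_status: str = "untested"  # positive | negative | untested

    def __post_init__(self) -> None:
        if self.bv_status not in ("positive", "negative", "untested"):
            raise ValueError(f"invalid bv_status {self.bv_status!r}")
        d = self.gestation_at_sampling.days
        if not (70 <= d <= 209):  # sampling window weeks 10-29
            warnings.warn(
                f"swab {self.sample_id}: gestation {self.gestation_at_sampling} "
                "outside the 10-29 week sampling window",
                stacklevel=2,
            )


@dataclass
class Patient:
    """One study participant with her ordered swab series and outcome."""

    patient_id: str
    swabs: list[Swab] = field(default_factory=list)
    age_years: float | None = None
    bmi: float | None = None
    ethnicity: str | None = None
    smoking: str = "unknown"
    indication: str | None = None
    gestation_at_delivery: GestationalAge | None = None
    outcome: str = "unknown"  # spontaneous | iatrogenic | unknown

    def __post_init__(self) -> None:
        if self.outcome not in ("spontaneous", "iatrogenic", "unknown"):
            raise ValueError(f"invalid outcome {self.outcome!r}")
        if self.outcome == "spontaneous" and self.gestation_at_delivery is None:
            raise ValueError(
                f"patient {self.patient_id}: spontaneous outcome requires "
                "gestation_at_delivery"
            )
        self.swabs = sorted(self.swabs, key=lambda s: s.gestation_at_sampling.days)

    @property
    def bv_positive(self) -> bool:
        """BV-positive on any swab during pregnancy (per-woman labelling)."""
        return any(s.bv_status == "positive" for s in self.swabs)

    @property
    def preterm(self) -> bool | None:
        """Spontaneous delivery before 37 + 0; None if not evaluable."""
        if self.outcome != "spontaneous" or self.gestation_at_delivery is None:
            return None
        return self.gestation_at_delivery.days < PRETERM_CUTOFF_DAYS


def select_analysis_swab(patient: Patient, mode: str) -> Swab:
    """The patient's one analysis swab: earliest, or closest to delivery.

    Ties are resolved by the earlier position in the stored (sorted)
    order; ``min`` is stable so that falls out naturally.
    """
    if not patient.swabs:
        raise ValueError(f"patient {patient.patient_id} has no swabs")
    if mode == "first":
        return min(patient.swabs, key=lambda s: s.gestation_at_sampling.days)
    if mode == "closest_to_delivery":
        if patient.gestation_at_delivery is None:
            raise ValueError(
                f"patient {patient.patient_id}: closest_to_delivery needs a "
                "known delivery gestation"
            )
        delivery = patient.gestation_at_delivery.days
        return min(patient.swabs, key=lambda s: delivery - s.gestation_at_sampling.days)
    raise ValueError(f"unknown swab mode {mode!r}")


def build_analysis_set(
    patients: Sequence[Patient], endpoint: str, swab_mode: str = "first"
) -> tuple[list[str], np.ndarray]:
    """Sample ids + binary labels for one analysis, one swab per patient.

    ``endpoint="bv"``: all patients with swabs; label = BV-positive on
    any swab.  ``endpoint="preterm"``: iatrogenic and unknown-outcome
    patients are excluded; label = spontaneous delivery before 37 + 0.
    """
    ids: list[str] = []
    labels: list[int] = []
    for p in patients:
        if not p.swabs:
            continue
        if endpoint == "bv":
            label = int(p.bv_positive)
        elif endpoint == "preterm":
            if p.preterm is None:
                continue
            label = int(p.preterm)
        else:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        ids.append(select_analysis_swab(p, swab_mode).sample_id)
        labels.append(label)
    if not ids:
        raise ValueError(f"analysis set for endpoint {endpoint!r} is empty")
    return ids, np.array(labels, dtype=int)


def _pct(count: int, denom: int) -> float:
    """Percentage to one decimal, round half up (clinical convention)."""
    if denom == 0:
        return float("nan")
    return float(
        (Decimal(count) * 100 / Decimal(denom)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class RateField:
    """A reported rate: count, denominator and rounded percentage."""

    count: int
    denominator: int
    pct: float

    @classmethod
    def of(cls, count: int, denominator: int) -> "RateField":
        if denominator == 0:
            warnings.warn("rate with zero denominator", stacklevel=3)
        return cls(count, denominator, _pct(count, denominator))


@dataclass(frozen=True)
class CohortSummary:
    """The headline cohort rates reported for the study population."""

    bv_positive: RateField
    preterm: RateField
    before_32_weeks: RateField
    preterm_given_bv_positive: RateField
    preterm_given_bv_negative: RateField

    @classmethod
    def from_counts(
        cls,
        bv_positive: tuple[int, int],
        preterm: tuple[int, int],
        before_32_weeks: tuple[int, int],
        preterm_given_bv_positive: tuple[int, int],
        preterm_given_bv_negative: tuple[int, int],
    ) -> "CohortSummary":
        """Summary from published (count, denominator) pairs.

        Each percentage recomputes from its own printed pair; no
        cross-field consistency is imposed, because tabulated clinical
        counts are not always mutually consistent.
        """
        return cls(
            RateField.of(*bv_positive),
            RateField.of(*preterm),
            RateField.of(*before_32_weeks),
            RateField.of(*preterm_given_bv_positive),
            RateField.of(*preterm_given_bv_negative),
        )

    def to_dict(self) -> dict:
        return {
            name: {"count": f.count, "denominator": f.denominator, "pct": f.pct}
            for name, f in vars(self).items()
        }


def summarize_cohort(patients: Sequence[Patient]) -> CohortSummary:
    """Headline rates from patient-level records.

    BV positivity is over all patients; preterm and before-32-week
    rates are over the spontaneous-outcome cohort with known delivery;
    the BV-stratified preterm rates use the same evaluable denominator
    split by BV status.
    """
    if not patients:
        raise ValueError("empty cohort")
    n = len(patients)
    bv_pos = [p for p in patients if p.bv_positive]
    evaluable = [p for p in patients if p.preterm is not None]
    preterm = [p for p in evaluable if p.preterm]
    before32 = [p for p in evaluable if p.gestation_at_delivery.days < 224]
    bv_pos_eval = [p for p in evaluable if p.bv_positive]
    bv_neg_eval = [p for p in evaluable if not p.bv_positive]
    return CohortSummary(
        bv_positive=RateField.of(len(bv_pos), n),
        preterm=RateField.of(len(preterm), len(evaluable)),
        before_32_weeks=RateField.of(len(before32), len(evaluable)),
        preterm_given_bv_positive=RateField.of(
            sum(bool(p.preterm) for p in bv_pos_eval), len(bv_pos_eval)
        ),
        preterm_given_bv_negative=RateField.of(
            sum(bool(p.preterm) for p in bv_neg_eval), len(bv_neg_eval)
        ),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Which test fired, its statistic and p-value, per-group summaries."""

    test: str  # t_test | mann_whitney | chi_square | degenerate
    p_value: float
    statistic: float | None = None
    summaries: tuple[dict, dict] | None = None


def compare_groups(values, groups, categorical: bool | None = None) -> GroupComparison:
    """Two-group comparison with a normality gate, as in clinical tables.

    Numeric data: Shapiro–Wilk at alpha = 0.05 in *both* groups selects
    a pooled two-sample t-test (mean ± SD reported), otherwise a
    Mann–Whitney U test (median and IQR reported).  Categorical data:
    chi-square on the contingency table, without continuity correction
    (a warning is issued when any expected count is below 5).
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    if categorical is None:
        categorical = not np.issubdtype(values.dtype, np.number)
    if categorical:
        table = pd.crosstab(pd.Series(groups), pd.Series(values)).to_numpy()
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 5).any():
            warnings.warn("chi-square with expected count < 5", stacklevel=2)
        return GroupComparison("chi_square", float(p), float(chi2))
    a = values[groups == uniq[0]].astype(float)
    b = values[groups == uniq[1]].astype(float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need >= 3 observations per group for numeric comparison")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return GroupComparison("degenerate", 1.0)
    normal = stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
    if normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        summaries = tuple(
            {"mean": float(np.mean(g)), "sd": float(np.std(g, ddof=1))} for g in (a, b)
        )
        return GroupComparison("t_test", float(res.pvalue), float(res.statistic), summaries)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    summaries = tuple(
        {
            "median": float(np.median(g)),
            "q1": float(np.percentile(g, 25)),
            "q3": float(np.percentile(g, 75)),
        }
        for g in (a, b)
    )
    return GroupComparison("mann_whitney", float(res.pvalue), float(res.statistic), summaries)


def median_iqr(values: Iterable) -> tuple[float, float, float]:
    """Median and quartiles (linear-interpolation convention).

    Accepts reals or :class:`GestationalAge` (converted to days); the
    results can be rendered back to 'W + D' with
    :func:`format_gestation_days`.
    """
    arr = np.array(
        [v.days if isinstance(v, GestationalAge) else float(v) for v in values], dtype=float
    )
    if arr.size == 0:
        raise ValueError("median_iqr of empty list")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# CSV I/O: patients.csv (one row per patient) + swabs.csv (one row per swab)

def write_cohort(patients: Sequence[Patient], patients_csv, swabs_csv) -> None:
    prow = []
    srow = []
    for p in patients:
        prow.append(
            {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "bmi": p.bmi,
                "ethnicity": p.ethnicity,
                "smoking": p.smoking,
                "indication": p.indication,
                "gestation_at_delivery": (
                    str(p.gestation_at_delivery) if p.gestation_at_delivery else ""
                ),
                "outcome": p.outcome,
            }
        )
        for s in p.swabs:
            srow.append(
                {
                    "patient_id": s.patient_id,
                    "sample_id": s.sample_id,
                    "gestation_at_sampling": str(s.gestation_at_sampling),
                    "bv_status": s.bv_status,
                }
            )
    pd.DataFrame(prow).to_csv(patients_csv, index=False)
    pd.DataFrame(srow).to_csv(swabs_csv, index=False)


def read_cohort(patients_csv, swabs_csv) -> list[Patient]:
    pdf = pd.read_csv(patients_csv, dtype={"patient_id": str}, keep_default_na=False)
    sdf = pd.read_csv(swabs_csv, dtype={"patient_id": str, "sample_id": str})
    swabs_by_patient: dict[str, list[Swab]] = {}
    for row in sdf.itertuples(index=False):
        swab = Swab(
            patient_id=row.patient_id,
            sample_id=row.sample_id,
            gestation_at_sampling=parse_gestation(row.gestation_at_sampling),
            bv_status=row.bv_status,
        )
        swabs_by_patient.setdefault(row.patient_id, []).append(swab)
    patients = []
    for row in pdf.itertuples(index=False):
        ga = row.gestation_at_delivery
        patients.append(
            Patient(
                patient_id=row.patient_id,
                swabs=swabs_by_patient.get(row.patient_id, []),
                age_years=float(row.age_years) if str(row.age_years) != "" else None,
                bmi=float(row.bmi) if str(row.bmi) != "" else None,
                ethnicity=row.ethnicity or None,
                smoking=row.smoking or "unknown",
                indication=row.indication or None,
                gestation_at_delivery=parse_gestation(ga) if str(ga).strip() else None,
                outcome=row.outcome,
            )
        )
    return patients


def ensure_parent(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path
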
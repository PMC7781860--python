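"""Cohort-level effectiveness statistics.

Target-attainment classification against the therapeutic hemoglobin window,
clinical success rate (CSR), out-of-target proportions, risk differences, and
the Mann-Whitney rank-sum comparison used for between-arm contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .exceptions import UndefinedRateError, ValidationError

__all__ = [
    "HbTargetBand",
    "ArmEffectiveness",
    "classify_target",
    "clinical_success_rate",
    "risk_difference_pct",
    "relative_risk_reduction",
    "event_rate",
    "format_pct",
    "mann_whitney",
    "MannWhitneyResult",
    "patient_in_target",
    "summarize_arm",
    "write_arm_summary_csv",
]

#: Significance threshold used throughout the between-arm comparisons.
ALPHA = 0.05


@dataclass(frozen=True)
class HbTargetBand:
    """Therapeutic serum-Hb window, closed at both ends (default [10.5, 12] g/dL)."""

    low: float = 10.5
    high: float = 12.0

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValidationError("target band requires 0 < low < high")

    def contains(self, hb: float) -> bool:
        return self.low <= hb <= self.high


def classify_target(hb: float, band: HbTargetBand = HbTargetBand()) -> str:
    """Classify a single Hb measurement as ``"in_target"`` or ``"out_of_target"``.

    The band is closed at both ends: out-of-target means Hb > high or Hb < low.
    """
    if hb <= 0:
        raise ValidationError("Hb must be positive")
    return "in_target" if band.contains(hb) else "out_of_target"


def clinical_success_rate(n_success: int, n: int) -> float:
    """CSR: proportion of patients achieving the targeted Hb concentration."""
    if n == 0:
        raise UndefinedRateError("CSR undefined for an empty group")
    if not 0 <= n_success <= n:
        raise ValidationError("need 0 <= n_success <= n")
    return n_success / n


def event_rate(n_events: int, n: int) -> float:
    """Simple event proportion, e.g. cardiovascular events per arm."""
    if n == 0:
        raise UndefinedRateError("event rate undefined for an empty group")
    if not 0 <= n_events <= n:
        raise ValidationError("need 0 <= n_events <= n")
    return n_events / n


def format_pct(proportion: float, decimals: int = 2) -> str:
    """Render a proportion as a percentage string, rounding half-up."""
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    return str(Decimal(repr(proportion * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def risk_difference_pct(p_out_control: float, p_out_treat: float) -> float:
    """Absolute difference of two out-of-target percentages, in percentage points.

    This is the quantity the study reports under the name "relative risk
    reduction"; the conventional ratio-based RRR is
    :func:`relative_risk_reduction`.
    """
    for p in (p_out_control, p_out_treat):
        if not 0.0 <= p <= 100.0:
            raise ValidationError("percentages must lie in [0, 100]")
    return p_out_control - p_out_treat


def relative_risk_reduction(p_out_control: float, p_out_treat: float) -> float:
    """Textbook RRR on proportions: (p_c - p_t) / p_c."""
    if p_out_control <= 0:
        raise UndefinedRateError("RRR undefined for zero control risk")
    return (p_out_control - p_out_treat) / p_out_control


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float               # rank-sum U statistic of the first sample
    p_two_sided: float
    method: str            # "exact" | "asymptotic"

    @property
    def significant(self) -> bool:
        return self.p_two_sided < ALPHA


def _exact_mw_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumeration of all C(n, n_a) rank splits.

    Mid-ranks handle ties; p = P(|U - mu| >= |U_obs - mu|) over the uniform
    distribution on splits.
    """
    n = len(ranks)
    n_b = n - n_a
    mu = n_a * n_b / 2.0
    obs_dev = abs(u_obs - mu) - 1e-12
    offset = n_a * (n_a + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= obs_dev:
            hits += 1
    return hits / total


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U test with mid-ranks for ties.

    Exact enumeration over all rank splits when ``n_a * n_b <= 20``; the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    if a.size * b.size <= 20:
        p = _exact_mw_p(ranks, a.size, u_a)
        return MannWhitneyResult(U=u_a, p_two_sided=p, method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p_two_sided=float(res.pvalue),
                             method="asymptotic")


def patient_in_target(record: PatientRecord, band: HbTargetBand = HbTargetBand(),
                      mode: str = "final3") -> bool:
    """Patient-level success indicator.

    ``"final3"`` (default): the last three monthly Hb values all lie in the
    band — treatment has settled into the window by end of follow-up.
    ``"all"``: every monthly value in the band.
    """
    hb = record.monthly_hb
    if mode == "final3":
        tail = hb[-3:] if len(hb) >= 3 else hb
        return all(band.contains(h) for h in tail)
    if mode == "all":
        return all(band.contains(h) for h in hb)
    raise ValidationError(f"unknown success mode {mode!r}")


@dataclass(frozen=True)
class ArmEffectiveness:
    """Per-arm target-attainment summary (success/out-of-target partition)."""

    arm: str
    n: int
    n_success: int
    csr: float
    n_out: int
    p_out: float
    cv_event_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_success + self.n_out != self.n:
            raise ValidationError("n_success + n_out must equal n")
        if not 0.0 <= self.csr <= 1.0:
            raise ValidationError("csr must lie in [0, 1]")


def summarize_arm(records: Iterable[PatientRecord],
                  band: HbTargetBand = HbTargetBand(),
                  mode: str = "final3") -> ArmEffectiveness:
    """Aggregate per-patient classification into an arm summary.

    In ``"per_measurement"`` mode the unit of analysis is the single monthly
    measurement rather than the patient.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot summarize an empty arm")
    arm = records[0].arm
    n_cv = sum(r.cv_event for r in records)
    if mode == "per_measurement":
        flat = [h for r in records for h in r.monthly_hb]
        n = len(flat)
        n_success = sum(band.contains(h) for h in flat)
    else:
        n = len(records)
        n_success = sum(patient_in_target(r, band, mode) for r in records)
    n_out = n - n_success
    return ArmEffectiveness(
        arm=arm, n=n, n_success=n_success, csr=n_success / n,
        n_out=n_out, p_out=n_out / n, cv_event_rate=n_cv / len(records),
    )


def write_arm_summary_csv(summaries: Sequence[ArmEffectiveness], path) -> None:
    rows = [
        {
            "arm": s.arm,
            "n": s.n,
            "n_success": s.n_success,
            "csr_pct": format_pct(s.csr),
            "n_out": s.n_out,
            "p_out_pct": format_pct(s.p_out),
            "cv_event_pct": "" if math.isnan(s.cv_event_rate) else format_pct(s.cv_event_rate),
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
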
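"""Synthetic patient-level cohort generator for the two ESA treatment arms.

The generator emulates the summary structure of a two-arm retrospective
hemodialysis cohort: monthly serum hemoglobin (Hb) draws around an arm mean,
Bernoulli cardiovascular events, log-normal annual per-patient costs, and the
usual demographic descriptors (age, sex, vascular access).  It reproduces
summary statistics, not erythropoietin pharmacology: there is no dose
titration and, by default, no within-patient Hb autocorrelation (an AR(1)
coefficient is available for sensitivity work).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import CohortParseError, ValidationError

__all__ = [
    "ArmProfile",
    "PatientRecord",
    "DARBEPOETIN_PROFILE",
    "EPOETIN_PROFILE",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]


@dataclass(frozen=True)
class ArmProfile:
    """Statistical profile of one treatment arm.

    Parameters
    ----------
    name:
        Arm label, e.g. ``"epoetin-beta"``.
    n_patients:
        Number of patients to generate.
    hb_mean, hb_sd:
        Mean and SD of the monthly serum Hb draws, g/dL.
    cv_event_rate:
        Annual probability of a cardiovascular event.
    annual_cost_mean:
        Mean annual per-patient cost, USD.
    annual_cost_cv:
        Coefficient of variation of the log-normal annual cost.
    months_followed:
        Length of the monthly Hb series per patient.
    age_mean, age_sd:
        Normal age distribution, years; truncated below at ``age_floor``.
    male_fraction, fistula_fraction:
        Bernoulli probabilities for sex and vascular access.
    hb_ar1:
        Lag-1 autocorrelation of the monthly Hb series (0 = i.i.d. draws).
    hb_floor:
        Physiological lower truncation of Hb draws, g/dL.
    """

    name: str
    n_patients: int
    hb_mean: float
    hb_sd: float
    cv_event_rate: float
    annual_cost_mean: float
    annual_cost_cv: float = 0.10
    months_followed: int = 12
    age_mean: float = 55.0
    age_sd: float = 10.0
    age_floor: float = 18.0
    male_fraction: float = 0.51
    fistula_fraction: float = 0.93
    hb_ar1: float = 0.0
    hb_floor: float = 4.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if self.hb_sd < 0 or self.age_sd < 0 or self.annual_cost_cv < 0:
            raise ValidationError("standard deviations / CV must be >= 0")
        if not 0.0 <= self.cv_event_rate <= 1.0:
            raise ValidationError("cv_event_rate must be in [0, 1]")
        if self.annual_cost_mean < 0:
            raise ValidationError("annual_cost_mean must be >= 0")
        if self.months_followed < 1:
            raise ValidationError("months_followed must be >= 1")
        if not -1.0 < self.hb_ar1 < 1.0:
            raise ValidationError("hb_ar1 must lie in (-1, 1)")


#: Long-acting arm: darbepoetin-alfa once monthly (n=194).
DARBEPOETIN_PROFILE = ArmProfile(
    name="darbepoetin-alfa",
    n_patients=194,
    hb_mean=10.68,
    hb_sd=0.98,
    cv_event_rate=0.0979,
    annual_cost_mean=12319.41,
    age_mean=56.3,
    age_sd=11.2,
    male_fraction=0.51,
    fistula_fraction=0.938,
)

#: Short-acting arm: epoetin-beta thrice weekly (n=97).
EPOETIN_PROFILE = ArmProfile(
    name="epoetin-beta",
    n_patients=97,
    hb_mean=11.63,
    hb_sd=0.32,
    cv_event_rate=0.0309,
    annual_cost_mean=919.47,
    age_mean=55.2,
    age_sd=7.8,
    male_fraction=0.5155,
    fistula_fraction=0.907,
)


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient: arm assignment, demographics, Hb series, outcomes."""

    patient_id: str
    arm: str
    age_years: float
    sex: str  # "M" | "F"
    monthly_hb: tuple[float, ...]
    cv_event: bool
    vascular_access: str  # "fistula" | "catheter"
    annual_cost_usd: float

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.monthly_hb):
            raise ValidationError("monthly Hb values must be positive")
        if self.annual_cost_usd < 0:
            raise ValidationError("annual_cost_usd must be >= 0")
        if self.sex not in ("M", "F"):
            raise ValidationError("sex must be 'M' or 'F'")
        if self.vascular_access not in ("fistula", "catheter"):
            raise ValidationError("vascular_access must be 'fistula' or 'catheter'")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, size) -> np.ndarray:
    """Normal draws re-sampled (not clipped) until all lie at or above floor."""
    out = rng.normal(mean, sd, size=size)
    if sd == 0:
        return out
    bad = out < floor
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < floor
    return out


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float,
                       size) -> np.ndarray:
    """Log-normal draws moment-matched on the natural scale (mean, CV)."""
    if mean == 0 or cv == 0:
        return np.full(size, mean, dtype=float)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def generate_cohort(profile: ArmProfile, seed: int) -> list[PatientRecord]:
    """Generate ``profile.n_patients`` records; deterministic for a fixed seed.

    Monthly Hb is stationary AR(1) with marginal N(hb_mean, hb_sd) (i.i.d.
    when ``hb_ar1 == 0``), truncated below at ``hb_floor`` by re-sampling.
    Cardiovascular events are Bernoulli; annual costs log-normal
    moment-matched on (mean, CV); ages normal truncated at ``age_floor``.
    """
    rng = np.random.default_rng(seed)
    n, m = profile.n_patients, profile.months_followed
    if n == 0:
        return []

    rho = profile.hb_ar1
    z = rng.standard_normal((n, m))
    hb = np.empty((n, m))
    hb[:, 0] = profile.hb_mean + profile.hb_sd * z[:, 0]
    innov_sd = profile.hb_sd * math.sqrt(1.0 - rho * rho)
    for t in range(1, m):
        hb[:, t] = profile.hb_mean + rho * (hb[:, t - 1] - profile.hb_mean) + innov_sd * z[:, t]
    # tail event for realistic profiles; replacement from the marginal law
    bad = hb < profile.hb_floor
    while bad.any():
        hb[bad] = rng.normal(profile.hb_mean, profile.hb_sd, size=int(bad.sum()))
        bad = hb < profile.hb_floor

    ages = _truncated_normal(rng, profile.age_mean, profile.age_sd, profile.age_floor, n)
    male = rng.random(n) < profile.male_fraction
    fistula = rng.random(n) < profile.fistula_fraction
    cv = rng.random(n) < profile.cv_event_rate
    costs = _lognormal_mean_cv(rng, profile.annual_cost_mean, profile.annual_cost_cv, n)

    return [
        PatientRecord(
            patient_id=f"{profile.name}-{i + 1:05d}",
            arm=profile.name,
            age_years=float(ages[i]),
            sex="M" if male[i] else "F",
            monthly_hb=tuple(float(x) for x in hb[i]),
            cv_event=bool(cv[i]),
            vascular_access="fistula" if fistula[i] else "catheter",
            annual_cost_usd=float(costs[i]),
        )
        for i in range(n)
    ]


def _hb_columns(months: int) -> list[str]:
    return [f"hb_m{t + 1:02d}" for t in range(months)]


_FIXED_COLUMNS = ["patient_id", "arm", "age_years", "sex", "vascular_access",
                  "cv_event", "annual_cost_usd"]


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    """Write records to CSV; floats at 6 significant digits; header always present."""
    months = records[0].monthly_hb.__len__() if records else 12
    cols = _FIXED_COLUMNS + _hb_columns(months)
    rows = []
    for r in records:
        if len(r.monthly_hb) != months:
            raise ValidationError("all records must share the same follow-up length")
        row = {
            "patient_id": r.patient_id,
            "arm": r.arm,
            "age_years": f"{r.age_years:.6g}",
            "sex": r.sex,
            "vascular_access": r.vascular_access,
            "cv_event": int(r.cv_event),
            "annual_cost_usd": f"{r.annual_cost_usd:.6g}",
        }
        for c, h in zip(_hb_columns(months), r.monthly_hb):
            row[c] = f"{h:.6g}"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Malformed numeric fields raise :class:`CohortParseError` naming the
    1-based data row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(0, f"missing required columns: {missing}")
    hb_cols = sorted(c for c in df.columns if c.startswith("hb_m"))
    if not hb_cols:
        raise CohortParseError(0, "no hb_mNN columns present")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        try:
            hb = tuple(float(d[c]) for c in hb_cols)
        except ValueError as exc:
            raise CohortParseError(i, f"non-numeric Hb value ({exc})") from exc
        try:
            age = float(d["age_years"])
            cost = float(d["annual_cost_usd"])
            cv_raw = d["cv_event"].strip().lower()
            if cv_raw in ("0", "1"):
                cv = bool(int(cv_raw))
            elif cv_raw in ("true", "false"):
                cv = cv_raw == "true"
            else:
                raise ValueError(f"bad cv_event {d['cv_event']!r}")
        except ValueError as exc:
            raise CohortParseError(i, str(exc)) from exc
        try:
            records.append(PatientRecord(
                patient_id=d["patient_id"], arm=d["arm"], age_years=age,
                sex=d["sex"], monthly_hb=hb, cv_event=cv,
                vascular_access=d["vascular_access"], annual_cost_usd=cost,
            ))
        except ValidationError as exc:
            raise CohortParseError(i, str(exc)) from exc
    return records
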
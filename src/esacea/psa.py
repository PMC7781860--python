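"""Deterministic and probabilistic sensitivity analysis.

One-way analysis pins a single parameter at its low/high values; multi-way
evaluates the Cartesian corners of up to four parameter ranges.  The
probabilistic sensitivity analysis (PSA) draws every uncertain parameter
from its declared distribution — log-normal moment-matched on the natural
scale for costs, truncated normal for clinical parameters and
probabilities — re-evaluates the full decision model per sample, and
summarizes the incremental cloud on the cost-effectiveness plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .cea import CEAResult
from .exceptions import ConfigError, ValidationError

__all__ = [
    "DistributionSpec",
    "TornadoEntry",
    "PSAResult",
    "OutcomeModel",
    "sample_distribution",
    "one_way",
    "multi_way",
    "psa",
    "classify_quadrant",
    "write_psa_csv",
    "write_tornado_csv",
]

_FAMILIES = ("normal", "lognormal", "beta", "fixed")


class OutcomeModel(Protocol):
    """Anything that can re-evaluate the decision model under parameter overrides."""

    base_params: Mapping[str, float]

    def evaluate(self, overrides: Mapping[str, float] | None = None) -> CEAResult: ...


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution for one model parameter.

    ``path`` references a parameter of the model (dotted, e.g.
    ``"arms.epoetin-beta.annual_cost_usd"``).  Spread is given as ``sd`` or
    as a coefficient of variation ``cv`` (sd = cv * mean).  ``bounds``
    truncate by rejection sampling (never by clipping).
    """

    path: str
    family: str
    mean: float
    sd: float | None = None
    cv: float | None = None
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        errs = []
        if self.family not in _FAMILIES:
            errs.append(f"{self.path}: unknown family {self.family!r}")
        if self.family != "fixed" and self.sd is None and self.cv is None:
            errs.append(f"{self.path}: need sd or cv for family {self.family!r}")
        if self.sd is not None and self.sd < 0:
            errs.append(f"{self.path}: sd must be >= 0")
        if self.cv is not None and self.cv < 0:
            errs.append(f"{self.path}: cv must be >= 0")
        if self.bounds is not None and not self.bounds[0] < self.bounds[1]:
            errs.append(f"{self.path}: truncation bounds must be ordered")
        if self.family in ("lognormal", "beta") and self.mean <= 0:
            errs.append(f"{self.path}: {self.family} requires a positive mean")
        if errs:
            raise ConfigError(errs)

    @property
    def effective_sd(self) -> float:
        if self.family == "fixed":
            return 0.0
        return self.sd if self.sd is not None else self.cv * abs(self.mean)


def sample_distribution(spec: DistributionSpec, rng: np.random.Generator,
                        size: int) -> np.ndarray:
    """Draw ``size`` values; truncation bounds enforced by rejection."""
    sd = spec.effective_sd
    if spec.family == "fixed" or sd == 0.0:
        return np.full(size, spec.mean, dtype=float)

    if spec.family == "normal":
        def draw(k): return rng.normal(spec.mean, sd, size=k)
    elif spec.family == "lognormal":
        cv = sd / spec.mean
        sigma2 = math.log1p(cv * cv)
        mu = math.log(spec.mean) - sigma2 / 2.0
        def draw(k): return rng.lognormal(mu, math.sqrt(sigma2), size=k)
    elif spec.family == "beta":
        var = sd * sd
        m = spec.mean
        if not 0 < m < 1 or var >= m * (1 - m):
            raise ConfigError([f"{spec.path}: beta needs mean in (0,1) and sd^2 < mean(1-mean)"])
        k = m * (1 - m) / var - 1.0
        def draw(kk): return rng.beta(m * k, (1 - m) * k, size=kk)
    else:  # pragma: no cover - guarded by __post_init__
        raise ConfigError([f"{spec.path}: unknown family"])

    out = draw(size)
    if spec.bounds is not None:
        lo, hi = spec.bounds
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = draw(int(bad.sum()))
            bad = (out < lo) | (out > hi)
    return out


def _outcome_value(result: CEAResult, outcome: str) -> float:
    if outcome == "delta_cost":
        return result.delta_cost
    if outcome == "delta_effect":
        return result.delta_effect
    if outcome == "icur":
        return result.icur if result.icur is not None else float("nan")
    if outcome == "icer":
        return result.icer if result.icer is not None else float("nan")
    if outcome == "acer":
        return result.acer[result.intervention]
    raise ValidationError(f"unknown outcome {outcome!r}")


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of a tornado diagram: outcome swing over a parameter's range."""

    path: str
    low: float
    high: float
    outcome: str
    outcome_low: float
    outcome_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _check_path(model: OutcomeModel, path: str) -> None:
    if path not in model.base_params:
        raise ConfigError([f"unresolvable parameter path {path!r}"])


def one_way(model: OutcomeModel, path: str, low: float, high: float,
            outcome: str = "delta_cost") -> TornadoEntry:
    """Re-evaluate the model with one parameter pinned at low, then high."""
    if low > high:
        raise ValidationError("one_way requires low <= high")
    _check_path(model, path)
    r_low = model.evaluate({path: low})
    r_high = model.evaluate({path: high})
    return TornadoEntry(path, low, high, outcome,
                        _outcome_value(r_low, outcome),
                        _outcome_value(r_high, outcome))


def multi_way(model: OutcomeModel,
              params: Sequence[tuple[str, float, float]],
              outcome: str = "delta_cost") -> list[dict]:
    """Evaluate the outcome at all 2^k corners of up to four parameter ranges.

    Returns one record per corner: the corner assignment (parameter -> value)
    plus the outcome.  An empty parameter list yields the single base case.
    """
    if len(params) > 4:
        raise ValidationError(
            "multi_way supports at most 4 parameters (2^k corner explosion); "
            "use psa() for higher-dimensional uncertainty")
    for path, low, high in params:
        _check_path(model, path)
        if low > high:
            raise ValidationError(f"{path}: low must be <= high")
    results = []
    k = len(params)
    for mask in range(2 ** k):
        overrides = {}
        corner = {}
        for j, (path, low, high) in enumerate(params):
            v = high if (mask >> j) & 1 else low
            overrides[path] = v
            corner[path] = v
        res = model.evaluate(overrides)
        results.append({"corner": corner, outcome: _outcome_value(res, outcome)})
    return results


def classify_quadrant(delta_cost: float, delta_effect: float) -> str:
    """Partition of the CE plane into the four quadrants (ties broken so the
    four fractions always sum to one; boundary points on the favorable axis
    count toward the adjacent lower quadrant)."""
    if delta_effect > 0:
        return "lower_right" if delta_cost <= 0 else "upper_right"
    return "upper_left" if delta_cost > 0 else "lower_left"


_QUADRANTS = ("lower_right", "upper_right", "upper_left", "lower_left")


@dataclass
class PSAResult:
    """Monte Carlo output: incremental cloud and its CE-plane summaries."""

    n_samples: int
    seed: int
    points: np.ndarray               # (n_samples, 2): delta_cost, delta_effect
    quadrant_fractions: dict[str, float]
    percentiles: dict[str, tuple[float, float]]  # 2.5/97.5 for each delta

    def __post_init__(self) -> None:
        if self.points.shape != (self.n_samples, 2):
            raise ValidationError("points must be (n_samples, 2)")
        if abs(sum(self.quadrant_fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("quadrant fractions must sum to 1")


def _summarize_points(points: np.ndarray, n: int, seed: int) -> PSAResult:
    dc, de = points[:, 0], points[:, 1]
    labels = np.where(de > 0,
                      np.where(dc <= 0, "lower_right", "upper_right"),
                      np.where(dc > 0, "upper_left", "lower_left"))
    fractions = {q: float((labels == q).mean()) for q in _QUADRANTS}
    pct = {
        "delta_cost": (float(np.percentile(dc, 2.5)), float(np.percentile(dc, 97.5))),
        "delta_effect": (float(np.percentile(de, 2.5)), float(np.percentile(de, 97.5))),
    }
    return PSAResult(n_samples=n, seed=seed, points=points,
                     quadrant_fractions=fractions, percentiles=pct)


def psa(model: OutcomeModel, dists: Sequence[DistributionSpec],
        n_samples: int, seed: int) -> PSAResult:
    """Probabilistic sensitivity analysis.

    A single pseudo-random stream is derived from ``seed``; parameters are
    drawn in sorted-path order so results are invariant to configuration
    ordering.  Each sample re-evaluates the full decision model.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    specs = sorted(dists, key=lambda s: s.path)
    seen = set()
    errs = []
    for s in specs:
        if s.path in seen:
            errs.append(f"duplicate distribution for {s.path!r}")
        seen.add(s.path)
        if s.path not in model.base_params:
            errs.append(f"unresolvable parameter path {s.path!r}")
    if errs:
        raise ConfigError(errs)

    rng = np.random.default_rng(seed)
    draws = {s.path: sample_distribution(s, rng, n_samples) for s in specs}
    points = np.empty((n_samples, 2))
    for i in range(n_samples):
        overrides = {p: float(v[i]) for p, v in draws.items()}
        res = model.evaluate(overrides)
        points[i, 0] = res.delta_cost
        points[i, 1] = res.delta_effect
    return _summarize_points(points, n_samples, seed)


def write_psa_csv(result: PSAResult, path) -> None:
    df = pd.DataFrame(result.points, columns=["delta_cost", "delta_effect"])
    df.insert(0, "sample_id", np.arange(result.n_samples))
    df["quadrant"] = [classify_quadrant(dc, de) for dc, de in result.points]
    df.to_csv(path, index=False)


def write_tornado_csv(entries: Sequence[TornadoEntry], path) -> None:
    pd.DataFrame([
        {
            "parameter": e.path, "low": e.low, "high": e.high,
            "outcome": e.outcome, "outcome_low": e.outcome_low,
            "outcome_high": e.outcome_high, "bar_width": e.bar_width,
        }
        for e in entries
    ]).to_csv(path, index=False)
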
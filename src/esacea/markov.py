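"""Four-state hemoglobin-banded Markov cohort engine.

The cohort model advances a state-occupancy vector through four-week cycles.
Health states are defined by serum Hb bands:

* ``alive_anemia``  — alive on hemodialysis with anemia complications, Hb [9, 10) g/dL
* ``alive_other``   — alive with other complications, Hb [10, 12)
* ``dying_other``   — dying with other complications, Hb [12, 13)
* ``dying_anemia``  — dying with anemia/stroke complications, Hb [13, inf)

plus an explicit absorbing ``death`` state that the two dying states reach
with a configurable per-cycle probability (default 1).  Hb below 9 g/dL (the
severe-anemia comparator band) maps to ``alive_anemia`` by default.  Costs
and utilities accrue per cycle on the occupancy at the start of the cycle;
QALYs and costs are discounted at a configurable annual rate (default 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import PatientRecord
from .exceptions import ValidationError

__all__ = [
    "MarkovState",
    "MarkovSpec",
    "MarkovTrace",
    "DAYS_PER_YEAR",
    "default_states",
    "build_states",
    "state_for_hb",
    "validate_transition_matrix",
    "run_cohort",
    "qalys",
    "lifetime_horizon_cycles",
    "transition_matrix_from_hb",
    "estimate_transitions_from_cohort",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class MarkovState:
    id: str
    description: str
    hb_band: tuple[float, float] | None  # half-open [low, high); None for death
    is_terminal: bool = False


def default_states() -> list[MarkovState]:
    """The four Hb-banded health states plus the absorbing death state."""
    return [
        MarkovState("alive_anemia", "alive, anemia/stroke complications", (9.0, 10.0)),
        MarkovState("alive_other", "alive, other complications", (10.0, 12.0)),
        MarkovState("dying_other", "dying, other complications", (12.0, 13.0)),
        MarkovState("dying_anemia", "dying, anemia/stroke complications", (13.0, math.inf)),
        MarkovState("death", "dead (absorbing)", None, is_terminal=True),
    ]


def build_states(config: dict | None = None) -> list[MarkovState]:
    """Build and validate the ordered state list.

    ``config`` may supply a ``states`` list of mappings with keys
    ``id, description, hb_low, hb_high, is_terminal``; otherwise the default
    five-state layout is returned.  Bands must be pairwise disjoint and
    exactly one terminal (absorbing death) state must exist.
    """
    if config and "states" in config:
        states = [
            MarkovState(
                s["id"], s.get("description", s["id"]),
                None if s.get("is_terminal") else (float(s["hb_low"]), float(s["hb_high"])),
                bool(s.get("is_terminal", False)),
            )
            for s in config["states"]
        ]
    else:
        states = default_states()

    terminals = [s for s in states if s.is_terminal]
    if len(terminals) != 1:
        raise ValidationError("exactly one absorbing death state is required")
    bands = sorted((s.hb_band for s in states if s.hb_band is not None))
    for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
        if lo2 < hi1:
            raise ValidationError(f"overlapping Hb bands: [{lo1},{hi1}) and [{lo2},...)")
    return states


def state_for_hb(hb: float, states: Sequence[MarkovState] | None = None,
                 severe_state: str = "alive_anemia") -> str:
    """Map a serum Hb value to its state id (bands half-open [low, high)).

    Hb below the lowest band (the severe-anemia comparator, < 9 g/dL) maps to
    ``severe_state``.
    """
    if hb <= 0:
        raise ValidationError("Hb must be positive")
    states = list(states) if states is not None else default_states()
    lowest = min(s.hb_band[0] for s in states if s.hb_band is not None)
    if hb < lowest:
        return severe_state
    for s in states:
        if s.hb_band is not None and s.hb_band[0] <= hb < s.hb_band[1]:
            return s.id
    raise ValidationError(f"Hb {hb} falls in no state band")


def validate_transition_matrix(matrix: np.ndarray, n_states: int,
                               terminal_index: int | None = None,
                               tol: float = 1e-9) -> np.ndarray:
    """Check row-stochasticity and the absorbing-death row; return as ndarray."""
    P = np.asarray(matrix, dtype=float)
    if P.shape != (n_states, n_states):
        raise ValidationError(f"transition matrix must be {n_states}x{n_states}, got {P.shape}")
    if (P < -tol).any() or (P > 1 + tol).any():
        raise ValidationError("transition probabilities must lie in [0, 1]")
    sums = P.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > tol)[0]
    if bad.size:
        raise ValidationError(
            f"transition matrix rows {bad.tolist()} sum to {sums[bad].tolist()}, expected 1")
    if terminal_index is not None:
        row = np.zeros(n_states)
        row[terminal_index] = 1.0
        if not np.allclose(P[terminal_index], row, atol=tol):
            raise ValidationError("absorbing death row must be the unit vector on itself")
    return P


@dataclass
class MarkovSpec:
    """Complete specification of one arm's cohort model."""

    states: list[MarkovState]
    transitions: np.ndarray
    state_cost: np.ndarray       # USD per cycle, per state
    state_utility: np.ndarray    # utility weight in [0, 1], per state
    cycle_length_days: float = 28.0
    discount_rate_annual: float = 0.0
    start_age_years: float = 55.0

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValidationError("cycle length must be positive")
        n = len(self.states)
        term = [i for i, s in enumerate(self.states) if s.is_terminal]
        if len(term) != 1:
            raise ValidationError("exactly one absorbing death state is required")
        self.terminal_index = term[0]
        self.transitions = validate_transition_matrix(
            self.transitions, n, self.terminal_index)
        self.state_cost = np.asarray(self.state_cost, dtype=float)
        self.state_utility = np.asarray(self.state_utility, dtype=float)
        if self.state_cost.shape != (n,) or self.state_utility.shape != (n,):
            raise ValidationError("state_cost and state_utility must have one entry per state")
        if (self.state_cost < 0).any():
            raise ValidationError("state costs must be non-negative")
        if (self.state_utility < 0).any() or (self.state_utility > 1).any():
            raise ValidationError("utility weights must lie in [0, 1]")
        if self.discount_rate_annual < 0:
            raise ValidationError("discount rate must be non-negative")

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def alive_mask(self) -> np.ndarray:
        return np.array([not s.is_terminal for s in self.states])


@dataclass
class MarkovTrace:
    """Cycle-by-cycle occupancy and cumulative (discounted) accruals."""

    state_ids: list[str]
    occupancy: np.ndarray        # (n_cycles+1, n_states); row 0 = initial
    cum_cost: np.ndarray         # (n_cycles+1,), discounted USD
    cum_life_years: np.ndarray   # undiscounted
    cum_qalys: np.ndarray        # discounted

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def total_cost(self) -> float:
        return float(self.cum_cost[-1])

    @property
    def total_life_years(self) -> float:
        return float(self.cum_life_years[-1])

    @property
    def total_qalys(self) -> float:
        return float(self.cum_qalys[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=self.state_ids)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["cum_cost"] = self.cum_cost
        df["cum_ly"] = self.cum_life_years
        df["cum_qaly"] = self.cum_qalys
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(spec: MarkovSpec, initial: Sequence[float], max_cycles: int,
               absorption_tol: float = 1e-6) -> MarkovTrace:
    """Advance the cohort occupancy for up to ``max_cycles`` cycles.

    Costs and utilities accrue on the occupancy at the start of each cycle,
    discounted by ``(1 + r)^(-t * cycle_years)``; life-years are undiscounted.
    The run stops early once death occupancy exceeds ``1 - absorption_tol``.
    """
    occ = np.asarray(initial, dtype=float)
    n = len(spec.states)
    if occ.shape != (n,):
        raise ValidationError("initial occupancy must have one entry per state")
    if (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
        raise ValidationError("initial occupancy must be a probability vector")
    if max_cycles < 0:
        raise ValidationError("max_cycles must be non-negative")

    P = spec.transitions
    cyc_years = spec.cycle_years
    r = spec.discount_rate_annual
    alive = spec.alive_mask

    occ_hist = [occ.copy()]
    cost = [0.0]
    ly = [0.0]
    qaly = [0.0]
    for t in range(max_cycles):
        disc = (1.0 + r) ** (-(t * cyc_years)) if r > 0 else 1.0
        cost.append(cost[-1] + disc * float(occ @ spec.state_cost))
        ly.append(ly[-1] + float(occ[alive].sum()) * cyc_years)
        qaly.append(qaly[-1] + disc * float(occ @ spec.state_utility) * cyc_years)
        occ = occ @ P
        occ_hist.append(occ.copy())
        if occ[spec.terminal_index] > 1.0 - absorption_tol:
            break
    return MarkovTrace(
        state_ids=[s.id for s in spec.states],
        occupancy=np.vstack(occ_hist),
        cum_cost=np.asarray(cost),
        cum_life_years=np.asarray(ly),
        cum_qalys=np.asarray(qaly),
    )


def qalys(life_years: float, utility: float) -> float:
    """Quality-adjusted life-years: life-years weighted by a utility in [0, 1]."""
    if not 0.0 <= utility <= 1.0:
        raise ValidationError("utility must lie in [0, 1]")
    if life_years < 0:
        raise ValidationError("life_years must be non-negative")
    return life_years * utility


def lifetime_horizon_cycles(start_age: float, max_age: float = 100.0,
                            cycle_length_days: float = 28.0,
                            days_per_year: float = DAYS_PER_YEAR) -> int:
    """Number of cycles spanning start_age..max_age: ceil(span_days / cycle_days)."""
    if max_age <= start_age:
        raise ValidationError("max_age must exceed start_age")
    if cycle_length_days <= 0:
        raise ValidationError("cycle length must be positive")
    return math.ceil((max_age - start_age) * days_per_year / cycle_length_days)


def _band_masses(mean: float, sd: float, states: Sequence[MarkovState],
                 severe_state: str) -> np.ndarray:
    """Probability mass of each state's Hb band under N(mean, sd); the mass
    below the lowest band folds into ``severe_state``."""
    n = len(states)
    masses = np.zeros(n)
    lowest = min(s.hb_band[0] for s in states if s.hb_band is not None)
    severe_idx = [i for i, s in enumerate(states) if s.id == severe_state][0]
    for i, s in enumerate(states):
        if s.hb_band is None:
            continue
        lo, hi = s.hb_band
        hi_cdf = 1.0 if math.isinf(hi) else norm.cdf(hi, mean, sd)
        masses[i] = hi_cdf - norm.cdf(lo, mean, sd)
    masses[severe_idx] += norm.cdf(lowest, mean, sd)
    return masses


def _embed_dying_to_death(rows: np.ndarray, states: Sequence[MarkovState],
                          p_death_dying: float) -> np.ndarray:
    """Route the two dying states to death with probability ``p_death_dying``,
    scaling their remaining transitions; make death absorbing."""
    P = rows.copy()
    death_idx = [i for i, s in enumerate(states) if s.is_terminal][0]
    for i, s in enumerate(states):
        if s.is_terminal:
            P[i] = 0.0
            P[i, death_idx] = 1.0
        elif s.id.startswith("dying"):
            P[i] *= (1.0 - p_death_dying)
            P[i, death_idx] += p_death_dying
    return P


def transition_matrix_from_hb(mean: float, sd: float,
                              states: Sequence[MarkovState] | None = None,
                              p_death_dying: float = 1.0,
                              severe_state: str = "alive_anemia") -> np.ndarray:
    """Derive a transition matrix from an arm's monthly Hb distribution.

    With i.i.d. monthly Hb ~ N(mean, sd), the next-cycle band is independent
    of the current one, so every alive row equals the band-mass vector; the
    dying states then exit to death with ``p_death_dying`` per cycle.
    """
    if sd <= 0:
        raise ValidationError("hb sd must be positive")
    if not 0.0 <= p_death_dying <= 1.0:
        raise ValidationError("p_death_dying must lie in [0, 1]")
    states = list(states) if states is not None else default_states()
    masses = _band_masses(mean, sd, states, severe_state)
    n = len(states)
    P = np.tile(masses, (n, 1))
    P = _embed_dying_to_death(P, states, p_death_dying)
    P /= P.sum(axis=1, keepdims=True)
    term = [i for i, s in enumerate(states) if s.is_terminal][0]
    return validate_transition_matrix(P, n, term)


def estimate_transitions_from_cohort(records: Iterable[PatientRecord],
                                     states: Sequence[MarkovState] | None = None,
                                     p_death_dying: float = 1.0,
                                     severe_state: str = "alive_anemia") -> np.ndarray:
    """Estimate transitions by row-normalized counts of consecutive-month
    Hb-band moves, then route dying states to death as in
    :func:`transition_matrix_from_hb`.

    Bands never observed as a source keep a self-loop row.
    """
    states = list(states) if states is not None else default_states()
    idx = {s.id: i for i, s in enumerate(states)}
    n = len(states)
    counts = np.zeros((n, n))
    for r in records:
        path = [idx[state_for_hb(h, states, severe_state)] for h in r.monthly_hb]
        for a, b in zip(path, path[1:]):
            counts[a, b] += 1
    P = np.zeros((n, n))
    for i in range(n):
        tot = counts[i].sum()
        if tot > 0:
            P[i] = counts[i] / tot
        else:
            P[i, i] = 1.0
    P = _embed_dying_to_death(P, states, p_death_dying)
    P /= P.sum(axis=1, keepdims=True)
    term = [i for i, s in enumerate(states) if s.is_terminal][0]
    return validate_transition_matrix(P, n, term)
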
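"""Decision-tree roll-back and cost-effectiveness statistics.

The decision tree has a single decision root whose children are the
treatment strategies; chance nodes carry branch probabilities (e.g. reaching
the Hb target or not) and terminals carry payoffs (cost, effectiveness,
QALYs), possibly produced by a Markov sub-model run beforehand.  Roll-back
returns each strategy's expected payoff, from which ACER, incremental cost
and effect, ICER/ICUR and dominance are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import UndefinedRateError, ValidationError

__all__ = [
    "Payoff",
    "DecisionNode",
    "IncrementalResult",
    "CEAResult",
    "rollback",
    "expected_payoff",
    "acer",
    "incremental",
    "ce_quadrant",
    "cost_utility_ratio",
    "compare_strategies",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class Payoff:
    """Terminal payoff: cost (USD), effectiveness (proportion), QALYs."""

    cost: float
    effectiveness: float
    qalys: float = 0.0

    def __add__(self, other: "Payoff") -> "Payoff":
        return Payoff(self.cost + other.cost,
                      self.effectiveness + other.effectiveness,
                      self.qalys + other.qalys)

    def scaled(self, w: float) -> "Payoff":
        return Payoff(w * self.cost, w * self.effectiveness, w * self.qalys)


@dataclass(frozen=True)
class DecisionNode:
    """Node of the decision tree.

    ``children`` holds ``(probability, node)`` pairs; probabilities are
    required on chance-node branches and ignored elsewhere.
    """

    kind: str  # "decision" | "chance" | "terminal"
    label: str
    children: tuple[tuple[float | None, "DecisionNode"], ...] = ()
    payoff: Payoff | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("decision", "chance", "terminal"):
            raise ValidationError(f"unknown node kind {self.kind!r}")
        if self.kind == "terminal":
            if self.payoff is None:
                raise ValidationError(f"terminal {self.label!r} needs a payoff")
            if self.children:
                raise ValidationError(f"terminal {self.label!r} cannot have children")
        if self.kind == "decision" and len(self.children) < 1:
            raise ValidationError(f"decision node {self.label!r} needs >= 1 child")
        if self.kind == "chance":
            if not self.children:
                raise ValidationError(f"chance node {self.label!r} needs children")
            probs = [p for p, _ in self.children]
            if any(p is None for p in probs):
                raise ValidationError(
                    f"chance node {self.label!r} has a branch without probability")
            if any(p < 0 or p > 1 for p in probs):
                raise ValidationError(
                    f"chance node {self.label!r} has probabilities outside [0, 1]")
            if abs(sum(probs) - 1.0) > _PROB_TOL:
                raise ValidationError(
                    f"chance node {self.label!r} branch probabilities sum to "
                    f"{sum(probs)}, expected 1")


def expected_payoff(node: DecisionNode) -> Payoff:
    """Expected payoff of a chance/terminal subtree (probability-weighted sum)."""
    if node.kind == "terminal":
        return node.payoff
    if node.kind == "chance":
        total = Payoff(0.0, 0.0, 0.0)
        for p, child in node.children:
            total = total + expected_payoff(child).scaled(p)
        return total
    raise ValidationError("decision nodes are only allowed at the tree root")


def rollback(tree: DecisionNode) -> dict[str, Payoff]:
    """Roll back the tree: expected (cost, effectiveness, QALYs) per strategy.

    A decision root yields one entry per child strategy; a chance or terminal
    root yields a single entry under its own label.
    """
    if tree.kind == "decision":
        return {child.label: expected_payoff(child) for _, child in tree.children}
    return {tree.label: expected_payoff(tree)}


def acer(cost: float, effectiveness: float) -> float:
    """Average cost-effectiveness ratio: cost per unit of effectiveness."""
    if effectiveness == 0:
        raise UndefinedRateError("ACER undefined for zero effectiveness")
    return cost / effectiveness


def cost_utility_ratio(cost: float, qalys: float) -> float:
    """Cost per QALY for a single strategy."""
    if qalys == 0:
        raise UndefinedRateError("cost-utility ratio undefined for zero QALYs")
    return cost / qalys


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison (strategy 1 minus strategy 0)."""

    delta_cost: float
    delta_effect: float
    flag: str            # "dominant" | "dominated" | "icer" | "undefined"
    icer: float | None   # only set when flag == "icer"


def incremental(cost_1: float, cost_0: float,
                eff_1: float, eff_0: float) -> IncrementalResult:
    """Incremental cost and effect of strategy 1 over strategy 0.

    Strict dominance (cheaper and more effective) or strict domination
    suppress the ratio; a zero effect difference yields an ``undefined``
    flag rather than an exception.
    """
    dc = cost_1 - cost_0
    de = eff_1 - eff_0
    if dc < 0 and de > 0:
        return IncrementalResult(dc, de, "dominant", None)
    if dc > 0 and de < 0:
        return IncrementalResult(dc, de, "dominated", None)
    if de == 0:
        return IncrementalResult(dc, de, "undefined", None)
    return IncrementalResult(dc, de, "icer", dc / de)


def ce_quadrant(delta_cost: float, delta_effect: float) -> str:
    """Cost-effectiveness-plane quadrant of an incremental point.

    More effective and cheaper is ``lower-right`` (dominance of the new
    strategy); less effective and costlier is ``upper-left`` (dominated);
    an exactly zero point is ``origin``.
    """
    if delta_cost == 0 and delta_effect == 0:
        return "origin"
    if delta_effect > 0:
        return "lower-right" if delta_cost <= 0 else "upper-right"
    return "upper-left" if delta_cost > 0 else "lower-left"


@dataclass(frozen=True)
class CEAResult:
    """Full pairwise CEA: per-strategy expectations plus incremental statistics."""

    reference: str
    intervention: str
    cost: dict[str, float]
    effectiveness: dict[str, float]
    qalys: dict[str, float]
    acer: dict[str, float]
    delta_cost: float
    delta_effect: float
    delta_qalys: float
    flag: str
    icer: float | None
    icur: float | None
    icur_flag: str
    quadrant: str


def compare_strategies(payoffs: dict[str, Payoff], reference: str,
                       intervention: str) -> CEAResult:
    """Assemble the pairwise CEA of ``intervention`` against ``reference``."""
    for name in (reference, intervention):
        if name not in payoffs:
            raise ValidationError(f"strategy {name!r} missing from rolled-back payoffs")
    ref, new = payoffs[reference], payoffs[intervention]
    inc = incremental(new.cost, ref.cost, new.effectiveness, ref.effectiveness)
    inc_q = incremental(new.cost, ref.cost, new.qalys, ref.qalys)
    acers = {
        name: (acer(p.cost, p.effectiveness) if p.effectiveness != 0 else float("nan"))
        for name, p in ((reference, ref), (intervention, new))
    }
    return CEAResult(
        reference=reference,
        intervention=intervention,
        cost={reference: ref.cost, intervention: new.cost},
        effectiveness={reference: ref.effectiveness, intervention: new.effectiveness},
        qalys={reference: ref.qalys, intervention: new.qalys},
        acer=acers,
        delta_cost=inc.delta_cost,
        delta_effect=inc.delta_effect,
        delta_qalys=inc_q.delta_effect,
        flag=inc.flag,
        icer=inc.icer,
        icur=inc_q.icer,
        icur_flag=inc_q.flag,
        quadrant=ce_quadrant(inc.delta_cost, inc.delta_effect),
    )
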
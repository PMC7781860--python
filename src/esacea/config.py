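"""Model configuration: schema, loading, and validation.

Configuration is a YAML or JSON document (dispatched on file extension)
holding the two treatment arms (success counts, costs, utilities, Hb
distribution), the Markov block (cycle length, horizon, discount rate),
the decision-tree block, the PSA distribution block, one-way sensitivity
ranges, and run options.  Validation collects *every* violation found
before raising, so a broken config reports all problems at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .cea import DecisionNode, Payoff
from .costs import ArmCostProfile, SAR_PER_USD
from .exceptions import ConfigError
from .markov import (MarkovSpec, default_states, lifetime_horizon_cycles,
                     transition_matrix_from_hb, validate_transition_matrix)
from .psa import DistributionSpec

__all__ = [
    "ArmSettings",
    "ModelConfig",
    "load_config",
    "basecase_config_path",
    "tree_from_dict",
]

#: Default per-state utility weights in state order
#: (alive_anemia, alive_other, dying_other, dying_anemia, death); the alive
#: values bracket the hemodialysis EQ-5D range, dying states are lower.
DEFAULT_STATE_UTILITY = (0.55, 0.70, 0.50, 0.45, 0.0)


@dataclass
class ArmSettings:
    """Per-arm model inputs."""

    name: str
    csr: float
    annual_cost_usd: float
    cv_event_rate: float = 0.0
    utility_success: float = 0.70
    utility_failure: float = 0.55
    csr_counts: tuple[int, int] | None = None       # (n_success, n)
    cv_event_counts: tuple[int, int] | None = None  # (n_events, n)
    cost_profile: ArmCostProfile | None = None
    hb_mean: float | None = None
    hb_sd: float | None = None
    transitions: np.ndarray | None = None           # explicit 5x5, row-major
    p_death_dying: float = 1.0
    state_cost_per_cycle: tuple[float, ...] | None = None
    state_utility: tuple[float, ...] = DEFAULT_STATE_UTILITY


@dataclass
class ModelConfig:
    """Validated model configuration."""

    arms: dict[str, ArmSettings]
    reference: str
    intervention: str
    cycle_length_days: float = 28.0
    discount_rate_annual: float = 0.0
    start_age_years: float = 55.0
    max_age_years: float = 100.0
    horizon_years: float = 1.0
    use_markov_payoffs: bool = False
    sar_per_usd: float = SAR_PER_USD
    distributions: list[DistributionSpec] = field(default_factory=list)
    one_way_ranges: list[dict] = field(default_factory=list)
    seed: int = 0
    n_samples: int = 50_000
    raw: dict = field(default_factory=dict)
    explicit_tree: dict | None = None

    def markov_spec(self, arm_name: str) -> MarkovSpec:
        """Build the Markov specification for one arm."""
        arm = self.arms[arm_name]
        states = default_states()
        if arm.transitions is not None:
            P = arm.transitions
        else:
            if arm.hb_mean is None or arm.hb_sd is None:
                raise ConfigError(
                    [f"arm {arm_name!r}: need either explicit transitions or hb mean/sd"])
            P = transition_matrix_from_hb(arm.hb_mean, arm.hb_sd,
                                          states, arm.p_death_dying)
        cyc_years = self.cycle_length_days / 365.25
        if arm.state_cost_per_cycle is not None:
            costs = np.asarray(arm.state_cost_per_cycle, dtype=float)
        else:
            per_cycle = arm.annual_cost_usd * cyc_years
            costs = np.array([per_cycle if not s.is_terminal else 0.0 for s in states])
        return MarkovSpec(
            states=states,
            transitions=P,
            state_cost=costs,
            state_utility=np.asarray(arm.state_utility, dtype=float),
            cycle_length_days=self.cycle_length_days,
            discount_rate_annual=self.discount_rate_annual,
            start_age_years=self.start_age_years,
        )

    def horizon_cycles(self) -> int:
        return lifetime_horizon_cycles(self.start_age_years, self.max_age_years,
                                       self.cycle_length_days)


def basecase_config_path() -> Path:
    """Path to the bundled base-case configuration."""
    return Path(resources.files("esacea").joinpath("data/basecase.yaml"))


def _proportion(d: dict, errs: list[str], ctx: str) -> float | None:
    num = d.get("n_success", d.get("n_events"))
    den = d.get("n")
    if num is None or den is None:
        errs.append(f"{ctx}: counts need n_success/n_events and n")
        return None
    if den <= 0 or not 0 <= num <= den:
        errs.append(f"{ctx}: need 0 <= count <= n and n > 0")
        return None
    return num / den


def _parse_arm(name: str, d: dict, errs: list[str]) -> ArmSettings | None:
    ctx = f"arms.{name}"
    csr = d.get("csr")
    csr_counts = None
    if isinstance(csr, dict):
        p = _proportion(csr, errs, f"{ctx}.csr")
        if p is None:
            return None
        csr_counts = (csr.get("n_success"), csr.get("n"))
        csr = p
    if csr is None:
        errs.append(f"{ctx}: missing csr")
        return None
    if not 0.0 <= csr <= 1.0:
        errs.append(f"{ctx}: csr must lie in [0, 1]")
        return None

    cv = d.get("cv_event", 0.0)
    cv_counts = None
    if isinstance(cv, dict):
        p = _proportion(cv, errs, f"{ctx}.cv_event")
        if p is None:
            return None
        cv_counts = (cv.get("n_events"), cv.get("n"))
        cv = p
    if not 0.0 <= cv <= 1.0:
        errs.append(f"{ctx}: cv_event rate must lie in [0, 1]")
        return None

    cost = d.get("annual_cost_usd")
    if cost is None or cost < 0:
        errs.append(f"{ctx}: annual_cost_usd missing or negative")
        return None

    util = d.get("utilities", {})
    u_s = util.get("success", 0.70)
    u_f = util.get("failure", 0.55)
    for label, u in (("success", u_s), ("failure", u_f)):
        if not 0.0 <= u <= 1.0:
            errs.append(f"{ctx}.utilities.{label}: utility must lie in [0, 1]")

    profile = None
    cp = d.get("cost_profile")
    if cp is not None:
        try:
            profile = ArmCostProfile(
                arm=name,
                staffing=tuple((k, float(v)) for k, v in cp.get("staffing", {}).items()),
                drug_cost=float(cp.get("drug_cost", 0.0)),
                hospitalization=float(cp.get("hospitalization", 0.0)),
            )
        except Exception as exc:
            errs.append(f"{ctx}.cost_profile: {exc}")

    hb = d.get("hb", {})
    mk = d.get("markov", {})
    transitions = None
    if "transitions" in mk:
        try:
            transitions = validate_transition_matrix(
                np.asarray(mk["transitions"], dtype=float), 5, terminal_index=4)
        except Exception as exc:
            errs.append(f"{ctx}.markov.transitions: {exc}")
    p_dd = mk.get("p_death_dying", 1.0)
    if not 0.0 <= p_dd <= 1.0:
        errs.append(f"{ctx}.markov.p_death_dying must lie in [0, 1]")
    su = tuple(mk.get("state_utility", DEFAULT_STATE_UTILITY))
    if len(su) != 5 or any(not 0.0 <= u <= 1.0 for u in su):
        errs.append(f"{ctx}.markov.state_utility must be 5 weights in [0, 1]")
    sc = mk.get("state_cost_per_cycle")
    if sc is not None and (len(sc) != 5 or any(c < 0 for c in sc)):
        errs.append(f"{ctx}.markov.state_cost_per_cycle must be 5 non-negative values")

    return ArmSettings(
        name=name, csr=float(csr), annual_cost_usd=float(cost),
        cv_event_rate=float(cv), utility_success=float(u_s), utility_failure=float(u_f),
        csr_counts=csr_counts, cv_event_counts=cv_counts, cost_profile=profile,
        hb_mean=hb.get("mean"), hb_sd=hb.get("sd"),
        transitions=transitions, p_death_dying=float(p_dd),
        state_cost_per_cycle=tuple(sc) if sc is not None else None,
        state_utility=su,
    )


def _parse_distributions(raw: list, arms: dict[str, ArmSettings],
                         errs: list[str]) -> list[DistributionSpec]:
    from .pipeline import base_params_for  # late import to avoid a cycle

    params = base_params_for(arms)
    out = []
    for i, d in enumerate(raw):
        ctx = f"distributions[{i}]"
        path = d.get("path")
        if path is None:
            errs.append(f"{ctx}: missing path")
            continue
        if path not in params:
            errs.append(f"{ctx}: unresolvable parameter path {path!r}")
            continue
        mean = d.get("mean", params[path])
        bounds = d.get("bounds")
        try:
            out.append(DistributionSpec(
                path=path, family=d.get("family", "fixed"), mean=float(mean),
                sd=d.get("sd"), cv=d.get("cv"),
                bounds=tuple(bounds) if bounds is not None else None,
            ))
        except ConfigError as exc:
            errs.extend(f"{ctx}: {e}" for e in exc.errors)
    return out


def _parse_config_dict(raw: dict) -> ModelConfig:
    errs: list[str] = []
    arms_raw = raw.get("arms")
    arms: dict[str, ArmSettings] = {}
    if not isinstance(arms_raw, dict) or not arms_raw:
        errs.append("config must define a non-empty 'arms' mapping")
    else:
        for name, d in arms_raw.items():
            a = _parse_arm(name, d or {}, errs)
            if a is not None:
                arms[name] = a

    tree = raw.get("tree", {})
    reference = tree.get("reference")
    intervention = tree.get("intervention")
    for role, nm in (("reference", reference), ("intervention", intervention)):
        if nm is None:
            errs.append(f"tree.{role} is required")
        elif arms and nm not in arms:
            errs.append(f"tree.{role} {nm!r} does not match any configured arm")

    mk = raw.get("markov", {})
    run = raw.get("run", {})
    n_samples = run.get("n_samples", 50_000)
    if n_samples < 1:
        errs.append("run.n_samples must be >= 1")
    dists = _parse_distributions(raw.get("distributions", []) or [], arms, errs)

    one_way = []
    for i, d in enumerate(raw.get("sensitivity", {}).get("one_way", []) or []):
        ctx = f"sensitivity.one_way[{i}]"
        if "path" not in d or "low" not in d or "high" not in d:
            errs.append(f"{ctx}: needs path, low, high")
            continue
        one_way.append({"path": d["path"], "low": float(d["low"]),
                        "high": float(d["high"]),
                        "outcome": d.get("outcome", "delta_cost")})

    if errs:
        raise ConfigError(errs)
    return ModelConfig(
        arms=arms,
        reference=reference,
        intervention=intervention,
        cycle_length_days=float(mk.get("cycle_length_days", 28.0)),
        discount_rate_annual=float(mk.get("discount_rate_annual", 0.0)),
        start_age_years=float(mk.get("start_age_years", 55.0)),
        max_age_years=float(mk.get("max_age_years", 100.0)),
        horizon_years=float(tree.get("horizon_years", 1.0)),
        use_markov_payoffs=bool(tree.get("use_markov_payoffs", False)),
        sar_per_usd=float(raw.get("currency", {}).get("sar_per_usd", SAR_PER_USD)),
        distributions=dists,
        one_way_ranges=one_way,
        seed=int(run.get("seed", 0)),
        n_samples=int(n_samples),
        raw=raw,
        explicit_tree=tree.get("root"),
    )


def load_config(path) -> ModelConfig:
    """Load and fully validate a YAML/JSON model configuration.

    All schema violations found are collected into a single
    :class:`ConfigError` rather than stopping at the first.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError([f"config file not found: {p}"])
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() == ".json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError([f"JSON parse error: {exc}"]) from exc
    else:
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError([f"YAML parse error: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError([f"config file {p} is empty or not a mapping"])
    return _parse_config_dict(raw)


def tree_from_dict(d: dict) -> DecisionNode:
    """Parse an explicit nested tree block into a :class:`DecisionNode`.

    Node mappings carry ``kind``, ``label``, ``children`` (each child may
    carry ``probability``), and for terminals a ``payoff`` mapping with
    ``cost``, ``effectiveness`` and optional ``qalys``.
    """
    kind = d.get("kind")
    label = d.get("label", kind or "node")
    if kind == "terminal":
        po = d.get("payoff", {})
        return DecisionNode("terminal", label, payoff=Payoff(
            float(po.get("cost", 0.0)), float(po.get("effectiveness", 0.0)),
            float(po.get("qalys", 0.0))))
    children = tuple(
        (c.get("probability"), tree_from_dict(c)) for c in d.get("children", [])
    )
    return DecisionNode(kind, label, children=children)
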
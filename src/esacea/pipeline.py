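"""End-to-end pipeline: cohort statistics → decision model → CEA → PSA → report.

`TreeModel` is the re-evaluatable decision model used by the sensitivity
module: it rebuilds the two-strategy decision tree from a flat parameter
dictionary (per-arm success probability, annual cost, branch utilities) so
any parameter can be overridden per evaluation.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .analysis import HbTargetBand, format_pct, summarize_arm
from .cea import CEAResult, DecisionNode, Payoff, compare_strategies, rollback
from .cohort import read_cohort_csv
from .config import ArmSettings, ModelConfig, tree_from_dict
from .exceptions import ValidationError
from .markov import MarkovTrace, run_cohort
from .psa import PSAResult, TornadoEntry, one_way, psa, write_psa_csv, write_tornado_csv

log = logging.getLogger("esacea")

__all__ = ["TreeModel", "RunReport", "run_pipeline", "base_params_for"]


def base_params_for(arms: Mapping[str, ArmSettings]) -> dict[str, float]:
    """Flat parameter dictionary addressed by dotted paths."""
    params: dict[str, float] = {}
    for name, a in arms.items():
        params[f"arms.{name}.csr"] = a.csr
        params[f"arms.{name}.annual_cost_usd"] = a.annual_cost_usd
        params[f"arms.{name}.utility_success"] = a.utility_success
        params[f"arms.{name}.utility_failure"] = a.utility_failure
    return params


class TreeModel:
    """Two-strategy decision tree over per-arm success chance nodes.

    Each strategy is a chance node: with probability CSR the patient reaches
    the Hb target (effectiveness 1, success utility), otherwise stays out of
    target (effectiveness 0, failure utility).  Cost accrues identically on
    both branches (the arm's annual cost over the tree horizon).  With
    ``use_markov_payoffs`` the branch costs/QALYs come instead from the
    arm's Markov trace started in the in-target or anemia state.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.base_params = base_params_for(config.arms)

    def build_tree(self, params: Mapping[str, float]) -> DecisionNode:
        children = []
        for name in (self.config.reference, self.config.intervention):
            p_succ = params[f"arms.{name}.csr"]
            cost = params[f"arms.{name}.annual_cost_usd"] * self.config.horizon_years
            u_s = params[f"arms.{name}.utility_success"]
            u_f = params[f"arms.{name}.utility_failure"]
            h = self.config.horizon_years
            if self.config.use_markov_payoffs:
                succ_po, fail_po = self._markov_payoffs(name, params)
            else:
                succ_po = Payoff(cost, 1.0, u_s * h)
                fail_po = Payoff(cost, 0.0, u_f * h)
            node = DecisionNode(
                "chance", name,
                children=(
                    (p_succ, DecisionNode("terminal", f"{name}/in_target", payoff=succ_po)),
                    (1.0 - p_succ, DecisionNode("terminal", f"{name}/out_of_target",
                                                payoff=fail_po)),
                ),
            )
            children.append((None, node))
        return DecisionNode("decision", "strategy", children=tuple(children))

    def _markov_payoffs(self, name: str, params: Mapping[str, float]):
        cfg = self.config
        arm = cfg.arms[name]
        spec = cfg.markov_spec(name)
        scale = params[f"arms.{name}.annual_cost_usd"] / arm.annual_cost_usd \
            if arm.annual_cost_usd else 1.0
        spec.state_cost = spec.state_cost * scale
        cycles = cfg.horizon_cycles()
        succ = run_cohort(spec, [0, 1, 0, 0, 0], cycles)
        fail = run_cohort(spec, [1, 0, 0, 0, 0], cycles)
        return (Payoff(succ.total_cost, 1.0, succ.total_qalys),
                Payoff(fail.total_cost, 0.0, fail.total_qalys))

    def evaluate(self, overrides: Mapping[str, float] | None = None) -> CEAResult:
        params = dict(self.base_params)
        if overrides:
            unknown = set(overrides) - set(params)
            if unknown:
                raise ValidationError(f"unknown parameter paths: {sorted(unknown)}")
            params.update(overrides)
        payoffs = rollback(self.build_tree(params))
        return compare_strategies(payoffs, self.config.reference, self.config.intervention)


@dataclass
class RunReport:
    """Assembled pipeline outputs plus provenance."""

    arm_summaries: list[dict]
    cea: CEAResult
    tornado: list[TornadoEntry]
    psa_result: PSAResult | None
    traces: dict[str, MarkovTrace]
    config_hash: str
    seed: int
    version: str
    timestamp: str

    def to_dict(self, include_timestamp: bool = True) -> dict:
        psa_block = None
        if self.psa_result is not None:
            psa_block = {
                "n_samples": self.psa_result.n_samples,
                "seed": self.psa_result.seed,
                "quadrant_fractions": self.psa_result.quadrant_fractions,
                "percentiles": {k: list(v) for k, v in self.psa_result.percentiles.items()},
                "mean_delta_cost": float(self.psa_result.points[:, 0].mean()),
                "mean_delta_effect": float(self.psa_result.points[:, 1].mean()),
            }
        d = {
            "arm_summaries": self.arm_summaries,
            "cea": {
                "reference": self.cea.reference,
                "intervention": self.cea.intervention,
                "cost": self.cea.cost,
                "effectiveness": self.cea.effectiveness,
                "qalys": self.cea.qalys,
                "acer": self.cea.acer,
                "delta_cost": self.cea.delta_cost,
                "delta_effect": self.cea.delta_effect,
                "delta_qalys": self.cea.delta_qalys,
                "flag": self.cea.flag,
                "icer": self.cea.icer,
                "icur": self.cea.icur,
                "icur_flag": self.cea.icur_flag,
                "quadrant": self.cea.quadrant,
            },
            "tornado": [
                {"parameter": e.path, "low": e.low, "high": e.high,
                 "outcome": e.outcome, "outcome_low": e.outcome_low,
                 "outcome_high": e.outcome_high, "bar_width": e.bar_width}
                for e in self.tornado
            ],
            "psa": psa_block,
            "markov": {
                name: {"cycles": t.n_cycles, "total_cost": t.total_cost,
                       "total_life_years": t.total_life_years,
                       "total_qalys": t.total_qalys}
                for name, t in self.traces.items()
            },
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "package_version": self.version,
            },
        }
        if include_timestamp:
            d["provenance"]["timestamp"] = self.timestamp
        return d

    def to_json(self, include_timestamp: bool = True) -> str:
        return json.dumps(self.to_dict(include_timestamp), sort_keys=True, indent=2)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n", encoding="utf-8")
        import pandas as pd
        pd.DataFrame(self.arm_summaries).to_csv(out / "arm_summary.csv", index=False)
        for name, t in self.traces.items():
            t.to_csv(out / f"trace_{name}.csv")
        write_tornado_csv(self.tornado, out / "tornado.csv")
        if self.psa_result is not None:
            write_psa_csv(self.psa_result, out / "psa_points.csv")


def _config_hash(config: ModelConfig) -> str:
    canonical = json.dumps(config.raw, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def run_pipeline(config: ModelConfig, cohort_csv=None, seed: int | None = None,
                 n_samples: int | None = None, outdir=None,
                 run_psa: bool = True) -> RunReport:
    """Run the full pipeline deterministically for a given config and seed.

    If ``cohort_csv`` is supplied, CSRs and cardiovascular event rates are
    estimated from the patient-level data and override the config values.
    """
    seed = config.seed if seed is None else seed
    n_samples = config.n_samples if n_samples is None else n_samples
    band = HbTargetBand()

    arm_summaries = []
    csr_overrides: dict[str, float] = {}
    if cohort_csv is not None:
        log.info("estimating arm statistics from cohort %s", cohort_csv)
        records = read_cohort_csv(cohort_csv)
        by_arm: dict[str, list] = {}
        for r in records:
            by_arm.setdefault(r.arm, []).append(r)
        for name, recs in by_arm.items():
            s = summarize_arm(recs, band)
            csr_overrides[f"arms.{name}.csr"] = s.csr
            arm_summaries.append({
                "arm": name, "n": s.n, "n_success": s.n_success,
                "csr_pct": format_pct(s.csr), "n_out": s.n_out,
                "p_out_pct": format_pct(s.p_out),
                "cv_event_pct": format_pct(s.cv_event_rate),
            })
    else:
        for name, a in config.arms.items():
            n = a.csr_counts[1] if a.csr_counts else None
            n_succ = a.csr_counts[0] if a.csr_counts else None
            arm_summaries.append({
                "arm": name, "n": n, "n_success": n_succ,
                "csr_pct": format_pct(a.csr),
                "n_out": (n - n_succ) if n is not None else None,
                "p_out_pct": format_pct(1.0 - a.csr),
                "cv_event_pct": format_pct(a.cv_event_rate),
            })

    model = TreeModel(config)
    if config.explicit_tree is not None:
        log.info("rolling back explicit tree block")
        payoffs = rollback(tree_from_dict(config.explicit_tree))
        cea = compare_strategies(payoffs, config.reference, config.intervention)
    else:
        cea = model.evaluate(csr_overrides or None)

    traces = {}
    cycles = config.horizon_cycles()
    for name in config.arms:
        spec = config.markov_spec(name)
        states = spec.states
        init = np.zeros(len(states))
        init[[s.id for s in states].index("alive_other")] = 1.0
        traces[name] = run_cohort(spec, init, cycles)

    tornado = [
        one_way(model, r["path"], r["low"], r["high"], r["outcome"])
        for r in config.one_way_ranges
    ]

    psa_result = None
    if run_psa and config.distributions:
        log.info("running PSA: %d samples, seed %d", n_samples, seed)
        psa_result = psa(model, config.distributions, n_samples, seed)

    report = RunReport(
        arm_summaries=sorted(arm_summaries, key=lambda d: d["arm"]),
        cea=cea,
        tornado=tornado,
        psa_result=psa_result,
        traces=traces,
        config_hash=_config_hash(config),
        seed=seed,
        version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    if outdir is not None:
        report.write(outdir)
    return report
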
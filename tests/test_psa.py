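"""Deterministic and probabilistic sensitivity analysis."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from esacea.cea import CEAResult
from esacea.exceptions import ConfigError, ValidationError
from esacea.pipeline import TreeModel
from esacea.psa import (DistributionSpec, classify_quadrant, multi_way,
                        one_way, psa, sample_distribution)


@pytest.fixture()
def model(basecase):
    return TreeModel(basecase)


EPO_COST = "arms.epoetin-beta.annual_cost_usd"
DARBE_COST = "arms.darbepoetin-alfa.annual_cost_usd"
EPO_CSR = "arms.epoetin-beta.csr"


class TestDistributions:
    def test_fixed_family_is_constant(self):
        spec = DistributionSpec("p", "fixed", mean=3.5)
        assert (sample_distribution(spec, np.random.default_rng(0), 100) == 3.5).all()

    def test_lognormal_moment_matching(self):
        # sigma^2 = ln(1+cv^2), mu = ln(mean) - sigma^2/2 reproduces (mean, cv)
        spec = DistributionSpec("p", "lognormal", mean=12_319.41, cv=0.10)
        x = sample_distribution(spec, np.random.default_rng(1), 200_000)
        assert x.mean() == pytest.approx(12_319.41, rel=0.005)
        assert x.std() / x.mean() == pytest.approx(0.10, rel=0.02)

    def test_normal_mean_recovery_within_3se(self):
        n = 10_000
        spec = DistributionSpec("p", "normal", mean=0.64, sd=0.05)
        x = sample_distribution(spec, np.random.default_rng(2), n)
        assert abs(x.mean() - 0.64) < 3 * 0.05 / math.sqrt(n)

    def test_truncation_by_rejection_stays_inside(self):
        spec = DistributionSpec("p", "normal", mean=0.95, sd=0.2, bounds=(0.0, 1.0))
        x = sample_distribution(spec, np.random.default_rng(3), 20_000)
        assert x.min() >= 0.0 and x.max() <= 1.0
        # rejection, not clipping: no point mass at the bound
        assert (x == 1.0).sum() == 0

    def test_beta_from_mean_sd(self):
        spec = DistributionSpec("p", "beta", mean=0.8, sd=0.04)
        x = sample_distribution(spec, np.random.default_rng(4), 100_000)
        assert x.mean() == pytest.approx(0.8, abs=0.001)
        assert x.std() == pytest.approx(0.04, abs=0.001)

    @pytest.mark.parametrize("kw", [
        dict(family="gamma", mean=1.0, sd=1.0),
        dict(family="normal", mean=1.0),              # no spread given
        dict(family="normal", mean=1.0, sd=-0.1),
        dict(family="lognormal", mean=-1.0, cv=0.1),
        dict(family="normal", mean=1.0, sd=0.1, bounds=(1.0, 0.0)),
    ])
    def test_invalid_specs_rejected_before_sampling(self, kw):
        with pytest.raises(ConfigError):
            DistributionSpec("p", **kw)


class TestOneWay:
    def test_degenerate_range_zero_width(self, model):
        base = model.base_params[EPO_COST]
        e = one_way(model, EPO_COST, base, base, outcome="delta_cost")
        assert e.bar_width == 0.0

    def test_linear_cost_parameter_moves_outcome_exactly(self, model):
        # delta_cost is linear in the intervention's annual cost, slope = horizon
        base = model.base_params[EPO_COST]
        e = one_way(model, EPO_COST, 0.75 * base, 1.25 * base, outcome="delta_cost")
        base_dc = model.evaluate().delta_cost
        assert e.outcome_low == pytest.approx(base_dc - 0.25 * base, abs=1e-9)
        assert e.outcome_high == pytest.approx(base_dc + 0.25 * base, abs=1e-9)

    def test_irrelevant_parameter_zero_width(self, model):
        # utilities do not enter delta_cost
        e = one_way(model, "arms.epoetin-beta.utility_success", 0.5, 0.9,
                    outcome="delta_cost")
        assert e.bar_width == 0.0

    def test_unresolvable_path_is_config_error(self, model):
        with pytest.raises(ConfigError):
            one_way(model, "arms.nobody.csr", 0.1, 0.2)


class TestMultiWay:
    def test_single_parameter_reduces_to_one_way(self, model):
        base = model.base_params[EPO_COST]
        corners = multi_way(model, [(EPO_COST, 0.8 * base, 1.2 * base)])
        e = one_way(model, EPO_COST, 0.8 * base, 1.2 * base)
        got = sorted(c["delta_cost"] for c in corners)
        assert got == sorted([e.outcome_low, e.outcome_high])

    def test_two_linear_parameters_corner_additivity(self, model):
        b1, b2 = model.base_params[EPO_COST], model.base_params[DARBE_COST]
        corners = multi_way(model, [(EPO_COST, 0.9 * b1, 1.1 * b1),
                                    (DARBE_COST, 0.9 * b2, 1.1 * b2)])
        assert len(corners) == 4
        base_dc = model.evaluate().delta_cost
        for c in corners:
            off1 = c["corner"][EPO_COST] - b1
            off2 = c["corner"][DARBE_COST] - b2
            assert c["delta_cost"] == pytest.approx(base_dc + off1 - off2, abs=1e-9)

    def test_empty_list_is_base_case(self, model):
        corners = multi_way(model, [])
        assert len(corners) == 1
        assert corners[0]["delta_cost"] == pytest.approx(model.evaluate().delta_cost)

    def test_five_parameters_refused(self, model):
        params = [(EPO_COST, 1.0, 2.0)] * 5
        with pytest.raises(ValidationError, match="psa"):
            multi_way(model, params)


class _DirectModel:
    """Direct-sampling harness: deltas read straight from the parameters."""

    base_params = {"delta_cost": -100.0, "delta_effect": 0.03}

    def evaluate(self, overrides=None):
        p = dict(self.base_params)
        if overrides:
            p.update(overrides)
        return CEAResult(
            reference="ref", intervention="new",
            cost={"ref": 0.0, "new": p["delta_cost"]},
            effectiveness={"ref": 0.0, "new": p["delta_effect"]},
            qalys={"ref": 0.0, "new": 0.0}, acer={"ref": 0.0, "new": 0.0},
            delta_cost=p["delta_cost"], delta_effect=p["delta_effect"],
            delta_qalys=0.0, flag="dominant", icer=None, icur=None,
            icur_flag="undefined", quadrant="lower-right",
        )


class TestPsa:
    def test_all_fixed_collapses_to_base_case(self, model):
        dists = [DistributionSpec(p, "fixed", mean=model.base_params[p])
                 for p in (EPO_COST, DARBE_COST)]
        res = psa(model, dists, n_samples=50, seed=5)
        base = model.evaluate()
        assert np.allclose(res.points[:, 0], base.delta_cost)
        assert np.allclose(res.points[:, 1], base.delta_effect)
        assert res.quadrant_fractions["lower_right"] == 1.0
        lo, hi = res.percentiles["delta_cost"]
        assert lo == pytest.approx(base.delta_cost) and hi == pytest.approx(base.delta_cost)

    def test_same_seed_bitwise_identical(self, basecase):
        model = TreeModel(basecase)
        a = psa(model, basecase.distributions, n_samples=500, seed=77)
        b = psa(model, basecase.distributions, n_samples=500, seed=77)
        assert (a.points == b.points).all()

    def test_draw_order_invariant_to_config_ordering(self, basecase):
        model = TreeModel(basecase)
        fwd = psa(model, basecase.distributions, 200, seed=9)
        rev = psa(model, list(reversed(basecase.distributions)), 200, seed=9)
        assert (fwd.points == rev.points).all()

    def test_quadrant_fractions_sum_to_one(self, basecase):
        model = TreeModel(basecase)
        res = psa(model, basecase.distributions, 1000, seed=10)
        assert sum(res.quadrant_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_dominant_fraction_matches_normal_cdf(self):
        # delta_effect ~ N(0.03, 0.01), delta_cost fixed negative:
        # P(dominant) = P(delta_effect > 0) = Phi(3)
        dists = [
            DistributionSpec("delta_cost", "fixed", mean=-100.0),
            DistributionSpec("delta_effect", "normal", mean=0.03, sd=0.01),
        ]
        res = psa(_DirectModel(), dists, n_samples=50_000, seed=11)
        expected = norm.cdf(3.0)
        tol = 3 * math.sqrt(expected * (1 - expected) / 50_000)
        assert abs(res.quadrant_fractions["lower_right"] - expected) < tol

    def test_input_means_recovered(self, basecase):
        model = TreeModel(basecase)
        n = 10_000
        res = psa(model, basecase.distributions, n, seed=12)
        # mean delta_effect equals the difference of the csr spec means
        csr_e = next(d for d in basecase.distributions if d.path == EPO_CSR)
        csr_d = next(d for d in basecase.distributions
                     if d.path == "arms.darbepoetin-alfa.csr")
        want = csr_e.mean - csr_d.mean
        se = math.sqrt(csr_e.effective_sd ** 2 + csr_d.effective_sd ** 2) / math.sqrt(n)
        assert abs(res.points[:, 1].mean() - want) < 3 * se

    def test_duplicate_or_unknown_paths_rejected(self, model):
        dup = [DistributionSpec(EPO_COST, "fixed", mean=1.0)] * 2
        with pytest.raises(ConfigError):
            psa(model, dup, 10, seed=1)
        with pytest.raises(ConfigError):
            psa(model, [DistributionSpec("nope", "fixed", mean=1.0)], 10, seed=1)


def test_quadrant_partition_is_exhaustive():
    pts = [(-1, 1), (1, 1), (1, -1), (-1, -1), (0.0, 0.0), (0.0, 1.0), (1.0, 0.0)]
    labels = {classify_quadrant(dc, de) for dc, de in pts}
    assert labels <= {"lower_right", "upper_right", "upper_left", "lower_left"}
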
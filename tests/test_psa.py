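"""Probabilistic sensitivity analysis: sampling, plane summaries, NMB."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oacea import (
    ConfigError,
    DistributionSpec,
    ceac,
    compute_icer,
    net_monetary_benefit,
    quadrant_summary,
    run_psa,
    symmetric_triangular_specs,
)


def point_specs(model):
    return {n: DistributionSpec.point(p.base) for n, p in model.parameters.items()}


class TestDistributionSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            DistributionSpec("triangular", low=1.0, mode=0.0, high=2.0)
        with pytest.raises(ConfigError):
            DistributionSpec("uniform", low=2.0, high=1.0)
        with pytest.raises(ConfigError):
            DistributionSpec("gamma", low=0.0, high=1.0)

    def test_probability_role_bounds_enforced_before_sampling(self, knee_model):
        bad = {"p_sam_success": DistributionSpec("uniform", low=0.5, high=1.5)}
        with pytest.raises(ConfigError, match="p_sam_success"):
            run_psa(knee_model, dists=bad, n=2, seed=0)


class TestRunPSA:
    def test_point_masses_reproduce_base_case(self, knee_model):
        base = knee_model.incremental()
        res = run_psa(knee_model, dists=point_specs(knee_model), n=10, seed=7)
        assert np.all(res.delta_cost == base.delta_cost)
        assert np.all(res.delta_effect == base.delta_effect)
        # centroid agrees with the base case up to summation rounding
        assert res.centroid[0] == pytest.approx(base.delta_cost, rel=1e-15)
        assert res.centroid[1] == pytest.approx(base.delta_effect, rel=1e-15)
        assert max(res.quadrant_proportions.values()) == 1.0

    def test_same_seed_gives_identical_results(self, knee_model):
        a = run_psa(knee_model, n=500, seed=42)
        b = run_psa(knee_model, n=500, seed=42)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)
        assert a.quadrant_proportions == b.quadrant_proportions
        c = run_psa(knee_model, n=500, seed=43)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_adding_a_parameter_does_not_perturb_other_draws(self):
        """Each parameter gets its own stream keyed by declared order,
        so declaring an extra parameter leaves existing draws intact."""
        from oacea import model_from_config

        def two_arm(params, std_cost):
            return model_from_config({
                "name": "stream_check",
                "parameters": params,
                "tree": {"kind": "decision", "label": "r", "children": [
                    {"node": {"kind": "terminal", "label": "new",
                              "cost": "a", "effect": 0.6}},
                    {"node": {"kind": "terminal", "label": "std",
                              "cost": std_cost, "effect": 0.4}},
                ]},
                "strategies": ["new", "std"],
            })

        a_spec = {"name": "a", "base": 50.0, "low": 0.0, "high": 100.0,
                  "role": "cost"}
        b_point = {"name": "b", "base": 10.0, "low": 10.0, "high": 10.0,
                   "role": "cost"}
        m1 = two_arm([a_spec], "0")
        m2 = two_arm([a_spec, b_point], "b")
        r1 = run_psa(m1, n=100, seed=5)   # delta cost = a draws
        r2 = run_psa(m2, n=100, seed=5)   # delta cost = a draws - 10
        assert np.allclose(r1.delta_cost, r2.delta_cost + 10.0,
                           rtol=0, atol=1e-9)

    def test_symmetric_specs_centroid_matches_base_case(self, knee_model):
        """With symmetric triangular distributions centred at base, the
        n = 10,000 centroid lies within 3 Monte-Carlo standard errors of
        the base-case increments (rollback is multilinear in the
        parameters, so the estimator is unbiased)."""
        res = run_psa(knee_model, dists=symmetric_triangular_specs(knee_model),
                      n=10_000, seed=2)
        base = knee_model.incremental()
        se_cost = res.delta_cost.std(ddof=1) / np.sqrt(res.iterations)
        se_eff = res.delta_effect.std(ddof=1) / np.sqrt(res.iterations)
        assert abs(res.centroid[0] - base.delta_cost) <= 3 * se_cost
        assert abs(res.centroid[1] - base.delta_effect) <= 3 * se_eff

    def test_n_must_be_positive(self, knee_model):
        with pytest.raises(ValueError):
            run_psa(knee_model, n=0)


class TestQuadrantSummary:
    def test_trivial_patterns(self):
        assert quadrant_summary([1.0], [1.0])["NE"] == 1.0
        props = quadrant_summary([1.0, -1.0], [1.0, -1.0])
        assert props["NE"] == 0.5 and props["SW"] == 0.5

    def test_recount_oracle_on_large_sample(self, knee_model):
        res = run_psa(knee_model, dists=symmetric_triangular_specs(knee_model),
                      n=10_000, seed=9)
        ne = sum(1 for dc, de in res.pairs if dc > 0 and de > 0)
        assert res.quadrant_proportions["NE"] == pytest.approx(ne / 10_000)

    def test_proportions_sum_to_one_and_permutation_invariant(self, knee_model):
        res = run_psa(knee_model, n=777, seed=3)
        assert sum(res.quadrant_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(777)
        shuffled = quadrant_summary(res.delta_cost[perm], res.delta_effect[perm])
        assert shuffled == res.quadrant_proportions

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            quadrant_summary([], [])


class TestNMB:
    def test_base_case_value(self):
        assert net_monetary_benefit(50_000, 2359.0, 0.13) == pytest.approx(4141.0)

    def test_zero_wtp_is_negative_cost(self):
        assert net_monetary_benefit(0.0, 123.0, 0.5) == -123.0

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            net_monetary_benefit(-1.0, 0.0, 0.0)

    def test_sign_agrees_with_icer_rule(self):
        """NMB > 0 at willingness-to-pay w is equivalent to ICER < w
        whenever the effect difference is positive (1,000 random pairs)."""
        rng = np.random.default_rng(12345)
        dc = rng.uniform(-10_000, 10_000, 1000)
        de = rng.uniform(1e-6, 1.0, 1000)
        wtp = 50_000.0
        for c, e in zip(dc, de):
            assert (net_monetary_benefit(wtp, c, e) > 0) == (
                compute_icer(c, 0.0, e, 0.0) < wtp
            )

    @given(wtps=st.lists(st.floats(0, 2e5), min_size=2, max_size=6))
    def test_ceac_nondecreasing_when_all_effects_positive(self, wtps, knee_model):
        res = run_psa(knee_model, n=300, seed=4)
        if not np.all(res.delta_effect > 0):  # pragma: no cover - guard
            res.delta_effect = np.abs(res.delta_effect) + 1e-9
        curve = ceac(res.delta_cost, res.delta_effect, sorted(wtps))
        values = [curve[w] for w in sorted(curve)]
        assert all(a <= b for a, b in zip(values, values[1:]))
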
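"""Inverse-variance pooling, QC filters, heterogeneity and genomic control."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metagwas.meta_engine import (FilterPolicy, apply_stratum_filters,
                                  heterogeneity, ivw_fixed, ivw_random,
                                  lambda_1000, lambda_gc, meta_pipeline)
from metagwas.sumstats_io import StratumRecord


def _rec(variant="rs1", beta=0.1, se=0.05, eaf=0.3, info=1.0, stratum="s0"):
    return StratumRecord(variant, "1", 100, "A", "G", eaf, beta, se, info,
                         1000, 1000, stratum)


class TestStratumFilters:
    def test_low_info_excluded_with_reason(self):
        keep, reasons = apply_stratum_filters(_rec(info=0.39, eaf=0.2))
        assert not keep and reasons == ["low_info"]

    def test_boundaries_are_retained_under_strict_inequalities(self):
        rec = _rec(info=0.40, eaf=0.005, beta=math.log(3.0))
        keep, reasons = apply_stratum_filters(rec)
        assert keep and reasons == []

    def test_high_eaf_folds_to_low_maf(self):
        keep, reasons = apply_stratum_filters(_rec(eaf=0.997))
        assert not keep and reasons == ["low_maf"]

    def test_reciprocal_or_bound_is_symmetric(self):
        keep, reasons = apply_stratum_filters(_rec(beta=math.log(1 / 3.01)))
        assert not keep and "extreme_or" in reasons

    def test_all_triggered_reasons_reported(self):
        keep, reasons = apply_stratum_filters(
            _rec(info=0.1, eaf=0.001, beta=math.log(5)))
        assert set(reasons) == {"low_info", "low_maf", "extreme_or"}


class TestIvwFixed:
    def test_single_stratum_is_identity(self):
        assert ivw_fixed([0.2], [0.1])[:2] == pytest.approx((0.2, 0.1))

    def test_two_stratum_hand_example(self):
        beta, se, z, p = ivw_fixed([0.2, 0.0], [0.1, 0.1])
        assert beta == pytest.approx(0.1)
        assert se == pytest.approx(0.1 / math.sqrt(2))

    def test_k_identical_strata_shrink_se_by_sqrt_k(self):
        for k in (2, 5, 10):
            beta, se, *_ = ivw_fixed([0.3] * k, [0.08] * k)
            assert beta == pytest.approx(0.3)
            assert se == pytest.approx(0.08 / math.sqrt(k))

    def test_matches_gls_oracle_to_machine_precision(self, rng):
        # oracle: generalized least squares with design = column of ones
        for _ in range(50):
            k = rng.integers(2, 12)
            b = rng.normal(0, 0.3, k)
            s = rng.uniform(0.01, 0.5, k)
            w = np.diag(s**-2.0)
            x = np.ones((k, 1))
            gls_beta = np.linalg.solve(x.T @ w @ x, x.T @ w @ b).item()
            gls_se = (np.linalg.inv(x.T @ w @ x) ** 0.5).item()
            beta, se, *_ = ivw_fixed(b, s)
            assert abs(beta - gls_beta) < 1e-12
            assert abs(se - gls_se) < 1e-12

    def test_pooled_estimate_bounded_by_inputs(self, rng):
        for _ in range(30):
            k = rng.integers(1, 10)
            b = rng.normal(0, 1, k)
            s = rng.uniform(0.01, 1, k)
            beta, se, *_ = ivw_fixed(b, s)
            assert b.min() - 1e-12 <= beta <= b.max() + 1e-12
            assert se <= s.min() + 1e-12

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ivw_fixed([], [])


class TestHeterogeneity:
    def test_identical_betas_give_zero_q_and_i2(self):
        q, df, het_p, i2 = heterogeneity([0.1, 0.1, 0.1], [0.05, 0.1, 0.2])
        assert q == pytest.approx(0.0, abs=1e-20) and i2 == 0.0

    def test_hand_example_q2_i50(self):
        q, df, het_p, i2 = heterogeneity([0.2, 0.0], [0.1, 0.1])
        assert q == pytest.approx(2.0) and df == 1
        assert i2 == pytest.approx(50.0)

    def test_scale_invariance_of_q(self, rng):
        b = rng.normal(0, 0.2, 6)
        s = rng.uniform(0.02, 0.3, 6)
        q1 = heterogeneity(b, s)[0]
        q2 = heterogeneity(3.7 * b, 3.7 * s)[0]
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_fewer_than_two_strata_signalled(self):
        with pytest.raises(ValueError):
            heterogeneity([0.1], [0.05])


class TestIvwRandom:
    def test_homogeneous_reduces_to_fixed(self):
        b, s = [0.1, 0.1, 0.1], [0.05, 0.05, 0.05]
        fixed = ivw_fixed(b, s)
        rand = ivw_random(b, s)
        assert rand[2] == 0.0
        assert rand[0] == pytest.approx(fixed[0])
        assert rand[1] == pytest.approx(fixed[1])

    def test_heterogeneous_se_never_below_fixed(self, rng):
        for _ in range(20):
            b = rng.normal(0, 0.5, 5)
            s = rng.uniform(0.02, 0.2, 5)
            assert ivw_random(b, s)[1] >= ivw_fixed(b, s)[1] - 1e-12

    def test_matches_direct_dersimonian_laird_evaluation(self):
        # oracle: explicit scalar DerSimonian-Laird arithmetic
        b = [0.30, 0.10, -0.05]
        s = [0.08, 0.12, 0.10]
        w = [1 / se**2 for se in s]
        bp = sum(wi * bi for wi, bi in zip(w, b)) / sum(w)
        q = sum(wi * (bi - bp) ** 2 for wi, bi in zip(w, b))
        tau2 = max(0.0, (q - 2) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
        w2 = [1 / (se**2 + tau2) for se in s]
        exp_beta = sum(wi * bi for wi, bi in zip(w2, b)) / sum(w2)
        exp_se = sum(w2) ** -0.5
        beta, se, t2, p = ivw_random(b, s)
        assert beta == pytest.approx(exp_beta, rel=1e-12)
        assert se == pytest.approx(exp_se, rel=1e-12)
        assert t2 == pytest.approx(tau2, rel=1e-12)


class TestMetaPipeline:
    def test_single_stratum_variant_dropped_with_audit_reason(self):
        strata = {"s0": [_rec("rs_only", stratum="s0")],
                  "s1": [_rec("rs_both", stratum="s1")],
                  "s2": [_rec("rs_both", stratum="s2")]}
        out, audit = meta_pipeline(strata)
        assert [r.variant_id for r in out] == ["rs_both"]
        dropped = audit[audit.variant_id == "rs_only"]
        assert list(dropped.reason) == ["min_strata"]

    def test_extreme_heterogeneity_dropped(self):
        # two strata with wildly opposite effects: het P < 5e-8
        strata = {"s0": [_rec(beta=0.5, se=0.02, stratum="s0")],
                  "s1": [_rec(beta=-0.5, se=0.02, stratum="s1")]}
        out, audit = meta_pipeline(strata)
        assert out == []
        assert "heterogeneity" in set(audit.reason)

    def test_output_invariant_to_stratum_ordering(self):
        recs = {f"s{k}": [_rec("rs1", beta=0.1 + 0.01 * k, stratum=f"s{k}")]
                for k in range(4)}
        fwd, _ = meta_pipeline(recs)
        rev, _ = meta_pipeline(dict(reversed(list(recs.items()))))
        assert fwd[0].beta == pytest.approx(rev[0].beta, rel=1e-15)
        assert fwd[0].n_strata_used == rev[0].n_strata_used

    def test_null_simulation_calibrated(self):
        from metagwas.synthetic_data import (SimulationConfig,
                                             simulate_stratum_sumstats)
        cfg = SimulationConfig(seed=11, n_variants=2000, fraction_causal=0.0,
                               stratum_sizes=[(500, 500)] * 5)
        strata, _ = simulate_stratum_sumstats(cfg)
        out, _ = meta_pipeline(strata)
        frac = np.mean([r.p < 0.05 for r in out])
        band = 3 * math.sqrt(0.05 * 0.95 / len(out))
        assert abs(frac - 0.05) <= band


class TestLambda:
    def test_reference_median_gives_unity(self):
        lam = lambda_gc(chi2_stats=[0.4549364231195728] * 201)
        assert lam == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        x = rng.chisquare(1, 5000)
        assert lambda_gc(chi2_stats=2 * x) == pytest.approx(
            2 * lambda_gc(chi2_stats=x), rel=1e-12)

    def test_lambda1000_identities(self):
        assert lambda_1000(1.0, 123, 45678) == 1.0
        assert lambda_1000(1.1, 1000, 1000) == pytest.approx(1.1)
        assert lambda_1000(1.1, 2000, 2000) == pytest.approx(1.05)


@given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.01, 1)),
                min_size=1, max_size=12))
def test_ivw_fixed_pooled_se_never_exceeds_best_stratum(pairs):
    betas, ses = zip(*pairs)
    _, se, _, _ = ivw_fixed(betas, ses)
    assert se <= min(ses) + 1e-12
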
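"""Locus clumping, conditional analysis, credible sets and BFDP."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from metagwas.locus_mapper import (CollinearityError, bfdp, conditional_joint,
                                   credible_set, define_loci,
                                   select_secondary_signals)
from metagwas.sumstats_io import LDReference, MetaRecord
from metagwas.synthetic_data import simulate_ld_block


def _meta(vid, chrom="1", pos=1000, beta=0.2, se=0.02, eaf=0.3):
    z = beta / se
    return MetaRecord(vid, chrom, pos, "A", "G", eaf, beta, se, z,
                      float(2 * norm.sf(abs(z))), 0.0, 0.0, 1.0, 5)


def _meta_from_sumstats(row):
    return MetaRecord(row.variant_id, "1", 1000, "A", "G", row.eaf,
                      row.beta, row.se, row.z, row.p, 0.0, 0.0, 1.0, 5)


class TestDefineLoci:
    def test_nearby_significant_variants_merge(self):
        records = [_meta("rs_a", pos=1_000_000), _meta("rs_b", pos=1_400_000)]
        loci = define_loci(records)
        assert len(loci) == 1
        assert {m.variant_id for m in loci[0].members} == {"rs_a", "rs_b"}

    def test_distant_variants_form_separate_loci(self):
        records = [_meta("rs_a", pos=1_000_000), _meta("rs_b", pos=3_000_000)]
        assert len(define_loci(records)) == 2

    def test_known_region_flank_excluded(self):
        records = [_meta("rs_new", pos=1_100_000)]
        loci = define_loci(records, exclude_regions=[("1", 1_000_000)])
        assert loci == []

    def test_lead_is_minimum_p_with_deterministic_ties(self):
        records = [_meta("rs_weak", pos=1_000_000, beta=0.12),
                   _meta("rs_strong", pos=1_200_000, beta=0.30)]
        (locus,) = define_loci(records)
        assert locus.lead.variant_id == "rs_strong"

    def test_planted_independent_signals_all_recovered(self):
        rng = np.random.default_rng(17)
        records = []
        # 9 strong signals 5 Mb apart plus null background
        planted = []
        for k in range(9):
            pos = 5_000_000 * (k + 1)
            planted.append(pos)
            records.append(_meta(f"rs_sig{k}", pos=pos, beta=0.3, se=0.03))
        for k in range(300):
            z = rng.normal()
            records.append(MetaRecord(f"rs_null{k}", "1",
                                      int(rng.integers(1, 5 * 10**7)),
                                      "A", "G", 0.3, 0.01 * z, 0.01, z,
                                      float(2 * norm.sf(abs(z))),
                                      0, 0, 1, 5))
        loci = define_loci(records)
        assert len(loci) == 9
        assert sorted(l.lead.pos for l in loci) == planted


class TestConditionalJoint:
    def test_orthogonal_ld_leaves_marginals_unchanged(self):
        ld = LDReference(["rs_a", "rs_b"], np.eye(2), 4000)
        members = [_meta("rs_a"), _meta("rs_b", beta=0.1)]
        (res,) = [r for r in conditional_joint(members, ld, ["rs_a"])
                  if r.variant_id == "rs_b"]
        assert res.beta == pytest.approx(0.1, rel=1e-10)
        assert res.se == pytest.approx(members[1].se, rel=1e-10)

    def test_conditioning_on_itself_is_degenerate(self):
        ld = LDReference(["rs_a"], np.eye(1), 4000)
        (res,) = conditional_joint([_meta("rs_a")], ld, ["rs_a"])
        assert res.degenerate and res.beta == 0.0

    def test_collinear_conditioning_pair_raises(self):
        r = np.array([[1.0, 0.99, 0.1], [0.99, 1.0, 0.1], [0.1, 0.1, 1.0]])
        ld = LDReference(["a", "b", "c"], r, 4000)
        members = [_meta("a"), _meta("b"), _meta("c")]
        with pytest.raises(CollinearityError, match="a.*b"):
            conditional_joint(members, ld, ["a", "b"])

    def test_matches_individual_level_joint_regression(self):
        # oracle: multiple regression on the simulated genotypes
        true = np.array([0.15, 0.0, 0.0, 0.12, 0.0])
        geno, pheno, sumstats, ld = simulate_ld_block(
            5, 0.4, 8000, true, seed=21)
        members = [_meta_from_sumstats(r) for r in sumstats.itertuples()]
        X = np.column_stack([np.ones(len(pheno)), geno])
        coef, *_ = np.linalg.lstsq(X, pheno, rcond=None)
        resid = pheno - X @ coef
        s2 = resid @ resid / (len(pheno) - X.shape[1])
        cov = s2 * np.linalg.inv(X.T @ X)
        ses = np.sqrt(np.diag(cov))[1:]
        results = conditional_joint(members, ld, ["ld000"])
        for j, res in enumerate(results):
            if res.degenerate:
                continue
            # conditional estimate within 3 joint-model se of the joint fit
            assert abs(res.beta - coef[1 + j]) < 3 * ses[j]


class TestSecondarySignals:
    def _locus(self, sumstats, lead_id):
        members = [_meta_from_sumstats(r) for r in sumstats.itertuples()]
        lead = min(members, key=lambda m: m.p)
        from metagwas.locus_mapper import Locus
        return Locus(lead=lead, start=0, end=10_000, members=members)

    def test_single_signal_locus_admits_no_secondary(self):
        true = np.array([0.2, 0.0, 0.0, 0.0, 0.0])
        _, _, sumstats, ld = simulate_ld_block(5, 0.3, 6000, true, seed=31)
        locus = select_secondary_signals(self._locus(sumstats, "ld000"), ld)
        assert locus.secondary_signals == []

    def test_two_uncorrelated_signals_both_reported(self):
        true = np.array([0.2, 0.0, 0.0, 0.2, 0.0])
        _, _, sumstats, ld = simulate_ld_block(5, 0.1, 8000, true, seed=33)
        assert ld.correlation[0, 3] ** 2 < 0.05
        locus = select_secondary_signals(self._locus(sumstats, "ld000"), ld)
        ids = {locus.lead.variant_id} | {
            s.variant_id for s in locus.secondary_signals}
        assert ids == {"ld000", "ld003"}

    def test_correlated_pair_collapses_to_one_signal(self):
        # adjacent variants with dosage r^2 well above 0.05
        true = np.array([0.25, 0.25])
        _, _, sumstats, ld = simulate_ld_block(2, 0.75, 8000, true, seed=35)
        assert ld.correlation[0, 1] ** 2 > 0.05
        locus = select_secondary_signals(self._locus(sumstats, None), ld)
        assert locus.secondary_signals == []


class TestCredibleSet:
    def _toy_locus(self, zs, positions=None):
        from metagwas.locus_mapper import Locus
        members = []
        for i, z in enumerate(zs):
            pos = positions[i] if positions else 1000 + i
            se = 0.02
            members.append(MetaRecord(f"rs{i}", "1", pos, "A", "G", 0.3,
                                      z * se, se, z, float(2 * norm.sf(abs(z))),
                                      0, 0, 1, 5))
        lead = min(members, key=lambda m: m.p)
        return Locus(lead=lead, start=0, end=10**7, members=members)

    def test_lead_has_unit_likelihood_and_is_always_ccr(self):
        cs = credible_set(self._toy_locus([6.0, 3.0]))
        assert cs.lam[0] == 1.0 and cs.ccr[0]

    def test_boundary_likelihood_exactly_one_hundredth_included(self):
        z_boundary = math.sqrt(36 - 2 * math.log(100))
        cs = credible_set(self._toy_locus([6.0, z_boundary]))
        assert cs.lam[1] == pytest.approx(0.01, rel=1e-12)
        assert cs.ccr[1]

    def test_null_variant_excluded(self):
        cs = credible_set(self._toy_locus([6.0, 0.0]))
        assert cs.lam[1] == pytest.approx(math.exp(-18.0))
        assert not cs.ccr[1]

    def test_distant_variant_outside_window_dropped(self):
        cs = credible_set(self._toy_locus([6.0, 5.9],
                                          positions=[1_000_000, 2_000_000]))
        assert cs.variant_ids == ["rs0"]

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            zs = rng.uniform(0, 7, rng.integers(2, 15))
            zs[rng.integers(len(zs))] = zs.max() + 0.5  # unique lead
            locus = self._toy_locus(list(zs))
            cs = credible_set(locus)
            z_lead = max(zs)
            expected = {f"rs{i}" for i, z in enumerate(zs)
                        if math.exp((z**2 - z_lead**2) / 2) >= 0.01}
            assert set(cs.ccr_variants) == expected

    def test_set_size_non_increasing_in_threshold(self):
        locus = self._toy_locus([6.0, 5.5, 5.0, 4.0, 2.0])
        sizes = [len(credible_set(locus, likelihood_ratio=t).ccr_variants)
                 for t in (0.001, 0.01, 0.1, 0.5)]
        assert sizes == sorted(sizes, reverse=True)


class TestBfdp:
    def test_attenuated_signal_has_high_bfdp(self):
        # OR 1.07 at P 6.3e-5: overwhelmingly likely a false discovery
        res = bfdp(math.log(1.07), p=6.3e-5)
        assert res.bfdp == pytest.approx(0.98, abs=0.01)

    def test_genome_wide_signal_has_low_bfdp(self):
        res = bfdp(math.log(1.23), p=3.6e-8)
        assert res.bfdp == pytest.approx(0.02, abs=0.005)

    def test_limits_in_z(self):
        assert bfdp(1e-9, se=0.02).bfdp > 1 - 1e-4  # z ~ 0
        assert bfdp(1.0, se=0.02).bfdp < 1e-12       # |z| huge

    def test_strictly_decreasing_in_abs_z_at_fixed_v(self):
        se = 0.02
        vals = [bfdp(z * se, se=se).bfdp for z in np.linspace(0.1, 9, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_w_prior_convention(self):
        res = bfdp(0.1, se=0.02)
        assert res.w == pytest.approx((math.log(1.5) / 1.959964) ** 2)
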
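import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncmeta.errors import InputError, InsufficientStudiesError
from lncmeta.meta import (
    GeneEffect,
    MetaConfig,
    aw_fisher,
    bh_fdr,
    cochran_q,
    hedges_g,
    pool_fixed,
    pool_random,
    run_meta,
    _meta_from_effect_matrix,
)
from lncmeta.simulate import SimulationConfig, generate_multistudy_counts


def eff(y, v):
    return pd.DataFrame({"y": list(y), "v": list(v)})


class TestHedgesG:
    def test_closed_form_means_two_vs_one(self):
        # arms with means 2 and 1 and pooled SD exactly 1 (n = 10 per arm)
        e = np.array([-1.0, 1.0] * 5) * 3.0 / np.sqrt(10.0)  # sample SD 1
        case, ctrl = 2.0 + e, 1.0 + e
        g = hedges_g(case, ctrl)
        assert g.y == pytest.approx(1.0 * (1 - 3 / 71), abs=1e-10)
        assert g.y == pytest.approx(0.9577, abs=1e-4)
        assert g.v == pytest.approx(20 / 100 + g.y**2 / 40, abs=1e-12)
        assert g.v == pytest.approx(0.2229, abs=1e-4)

    def test_identical_arms_give_zero_effect_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        g = hedges_g(vals, vals)
        assert g.y == 0.0
        assert g.p_study == pytest.approx(1.0)

    def test_swapping_arms_negates_g_keeps_v(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 12)
        g1, g2 = hedges_g(a, b), hedges_g(b, a)
        assert g1.y == pytest.approx(-g2.y, abs=1e-12)
        assert g1.v == pytest.approx(g2.v, abs=1e-12)

    def test_degenerate_zero_sd_rejected(self):
        with pytest.raises(InputError, match="degenerate"):
            hedges_g([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestCochranQ:
    def test_two_study_closed_form_homogeneous(self):
        q, df, p_q, i2 = cochran_q(eff([0.5, 0.7], [0.04, 0.04]))
        assert q == pytest.approx(0.5, abs=1e-12)
        assert df == 1
        assert p_q == pytest.approx(0.4795, abs=1e-4)
        assert i2 == 0.0

    def test_two_study_closed_form_heterogeneous(self):
        q, df, p_q, i2 = cochran_q(eff([0.0, 1.0], [0.04, 0.04]))
        assert q == pytest.approx(12.5, abs=1e-12)
        assert p_q == pytest.approx(4.07e-4, rel=1e-2)
        assert i2 == pytest.approx(92.0, abs=1e-9)

    def test_equal_effects_zero_q(self):
        q, _, _, i2 = cochran_q(eff([0.3, 0.3, 0.3], [0.1, 0.2, 0.3]))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q(eff([0.5], [0.04]))


class TestPooling:
    def test_fixed_closed_form(self):
        pooled, lo, hi, z, p = pool_fixed(eff([0.5, 0.7], [0.04, 0.04]))
        assert pooled == pytest.approx(0.6, abs=1e-12)
        assert lo == pytest.approx(0.3228, abs=1e-4)
        assert hi == pytest.approx(0.8772, abs=1e-4)

    def test_dominant_weight_limit(self):
        pooled, *_ = pool_fixed(eff([0.2, 5.0], [1e-8, 1e4]))
        assert pooled == pytest.approx(0.2, abs=1e-6)

    def test_ci_narrows_with_more_studies(self):
        widths = []
        for k in (2, 5, 10):
            _, lo, hi, _, _ = pool_fixed(eff([0.4] * k, [0.09] * k))
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_random_closed_form(self):
        tau2, pooled, lo, hi, z, p = pool_random(eff([0.0, 1.0], [0.04, 0.04]))
        assert tau2 == pytest.approx(0.46, abs=1e-12)
        assert pooled == pytest.approx(0.5, abs=1e-12)
        assert lo == pytest.approx(-0.48, abs=1e-2)
        assert hi == pytest.approx(1.48, abs=1e-2)
        assert lo < 0 < hi  # no DE call from this CI

    def test_collapses_to_fixed_when_q_below_df(self):
        e = eff([0.30, 0.31], [0.1, 0.1])
        tau2, pooled, lo, hi, z, p = pool_random(e)
        f_pooled, f_lo, f_hi, f_z, f_p = pool_fixed(e)
        assert tau2 == 0.0
        assert (pooled, lo, hi, z, p) == (f_pooled, f_lo, f_hi, f_z, f_p)

    def test_matches_wls_rederivation(self, rng):
        """Inverse-variance pooling equals an explicit WLS intercept fit."""
        for _ in range(300):
            k = rng.integers(2, 8)
            y = rng.normal(0, 1, k)
            v = rng.uniform(0.01, 1.0, k)
            pooled, lo, hi, z, p = pool_fixed(eff(y, v))
            # independent route: weighted least squares on a constant design
            sw = np.sqrt(1.0 / v)
            beta, *_ = np.linalg.lstsq(sw[:, None], sw * y, rcond=None)
            assert pooled == pytest.approx(float(beta[0]), abs=1e-10)
            # random effects: DL tau2 recomputed longhand, then same WLS route
            w = 1.0 / v
            q = float(np.sum(w * (y - np.sum(w * y) / np.sum(w)) ** 2))
            c = np.sum(w) - np.sum(w**2) / np.sum(w)
            tau2_ref = max(0.0, (q - (k - 1)) / c)
            sw2 = np.sqrt(1.0 / (v + tau2_ref))
            beta2, *_ = np.linalg.lstsq(sw2[:, None], sw2 * y, rcond=None)
            tau2, pooled_r, *_ = pool_random(eff(y, v))
            assert tau2 == pytest.approx(tau2_ref, abs=1e-10)
            assert pooled_r == pytest.approx(float(beta2[0]), abs=1e-10)


class TestAwFisher:
    def test_single_small_p_dominates(self):
        stat, w = aw_fisher([0.001, 0.9])
        assert stat == pytest.approx(0.001, abs=1e-12)
        assert list(w) == [1, 0]

    def test_all_ones_give_statistic_one(self):
        stat, _ = aw_fisher([1.0, 1.0, 1.0])
        assert stat == pytest.approx(1.0)

    def test_single_study_weight_identity(self, rng):
        for p in rng.uniform(1e-6, 1.0, 20):
            stat, w = aw_fisher([p])
            assert stat == pytest.approx(p, abs=1e-12)

    def test_restricted_search_equals_exhaustive(self, rng):
        """The m-smallest-p search visits the global optimum for k <= 10."""
        for _ in range(60):
            k = int(rng.integers(2, 9))
            p = rng.uniform(1e-8, 1.0, k)
            stat, _ = aw_fisher(p)
            best = np.inf
            for r in range(1, k + 1):
                for combo in itertools.combinations(range(k), r):
                    u = -2.0 * np.sum(np.log(p[list(combo)]))
                    best = min(best, stats.chi2.sf(u, 2 * r))
            assert stat == pytest.approx(best, rel=1e-12)


class TestBhFdr:
    def test_hand_step_up(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_bounds_and_monotonicity(self, rng):
        p = rng.uniform(0, 1, 200)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])


class TestSwitchingRule:
    @pytest.mark.parametrize(
        "i2, p_q, expect_rem",
        [(60.0, 0.005, True), (60.0, 0.02, False), (40.0, 0.001, False)],
    )
    def test_rem_iff_joint_rule(self, i2, p_q, expect_rem):
        """REM is used only when I2 > 50 AND p_Q < 0.01 jointly hold."""
        # craft a two-study effect pair achieving the requested (I2, p_Q)
        # via Q: I2 = (1 - 1/Q)*100 and p_Q = chi2.sf(Q, 1); pick Q from p_Q
        q = stats.chi2.isf(p_q, 1)
        v = np.array([0.04, 0.04])
        # two equal-variance studies: Q = (y1-y2)^2/(2v)
        gap = np.sqrt(q * 2 * v[0])
        y = np.array([0.0, gap])
        i2_actual = max(0.0, (q - 1) / q) * 100
        res = _meta_from_effect_matrix(y[None, :], v[None, :], MetaConfig())
        if expect_rem:
            assert i2_actual > 50 and p_q < 0.01
            assert res.loc[0, "model"] == "REM"
        else:
            # the crafted pair may violate the I2 half of the request; apply
            # the rule to the realized statistics instead
            should_rem = (i2_actual > 50) and (p_q < 0.01)
            assert res.loc[0, "model"] == ("REM" if should_rem else "FEM")

    def test_de_call_requires_ci_and_fdr(self):
        y = np.array([[0.55, 0.63, 0.6, 0.59]])
        v = np.full((1, 4), 0.01)
        res = _meta_from_effect_matrix(y, v, MetaConfig())
        assert bool(res.loc[0, "de_call"])
        assert res.loc[0, "direction"] == "up"
        assert res.loc[0, "ci_low"] > 0


class TestRunMeta:
    def test_null_calibration(self):
        """Under a global null the heterogeneity and DE rates stay nominal."""
        cfg = SimulationConfig(
            n_studies=5, n_genes=2000, study_sizes=((20, 20),) * 5,
            frac_de=0.0, delta=0.0, tau2=0.0, seed=5,
        )
        studies, _ = generate_multistudy_counts(cfg)
        res = run_meta(studies, MetaConfig(aw_permutations=0))
        het = ((res["I2"] > 50) & (res["p_Q"] < 0.01)).mean()
        assert het <= 0.01
        assert res["de_call"].mean() <= 0.05

    def test_subgroup_effects_consistent_with_whole(self, rng):
        """Study k-counts add across disjoint subgroups and FEM pooling of
        the union lies between the subgroup FEM estimates."""
        from conftest import make_study

        studies = [make_study(rng, f"s{i}", n_genes=30) for i in range(4)]
        whole = run_meta(studies, MetaConfig(aw_permutations=0))
        sub_a = run_meta(studies[:2], MetaConfig(aw_permutations=0))
        sub_b = run_meta(studies[2:], MetaConfig(aw_permutations=0))
        assert (sub_a["k"] + sub_b["k"]).equals(whole["k"])
        fem = whole["model"] == "FEM"
        lo = np.minimum(sub_a["smd_pooled"], sub_b["smd_pooled"])
        hi = np.maximum(sub_a["smd_pooled"], sub_b["smd_pooled"])
        ok = (whole["smd_pooled"] >= lo - 1e-9) & (whole["smd_pooled"] <= hi + 1e-9)
        assert ok[fem].all()

    def test_aw_permutation_p_in_unit_interval(self, small_studies):
        res = run_meta(small_studies, MetaConfig(aw_permutations=5, seed=1))
        assert res["aw_p"].between(0, 1).all()
        assert (res["aw_weights"].str.len() > 0).all()

    def test_gene_missing_from_all_but_one_study_untested(self, small_studies):
        # drop gene g0 from two of the three studies
        s0, s1, s2 = small_studies
        s1 = type(s1)(s1.study_id, s1.counts.drop(index="g0"), s1.design)
        s2 = type(s2)(s2.study_id, s2.counts.drop(index="g0"), s2.design)
        res = run_meta([s0, s1, s2], MetaConfig(aw_permutations=0))
        assert res.loc["g0", "model"] == "untested"
        assert res.loc["g0", "reason"] == "insufficient_studies"
        assert not bool(res.loc["g0", "de_call"])
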
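"""Tetrachoric estimation, the WLS ACE fit and the family-cluster bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famcoaggr import quantgen
from famcoaggr.quantgen import (
    AceFit,
    BootstrapSummary,
    ContingencyTable2x2,
    QuantgenError,
    SiblingMoments,
    TetraEstimate,
    ace_bootstrap,
    bootstrap,
    bvn_cdf,
    compute_moments,
    decompose,
    estimate_threshold,
    fit_bivariate_ace,
    pair_tables,
    pooled_tetrachoric,
    tetrachoric,
)


def bvn_table(rho, p1, p2, n, seed):
    """Threshold a bivariate normal sample into a 2x2 table."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
    x = (z1 > stats.norm.ppf(1 - p1)).astype(int)
    y = (z2 > stats.norm.ppf(1 - p2)).astype(int)
    return ContingencyTable2x2.from_arrays(x, y)


def exact_moments(truth_like, relation, se=0.01):
    """Noise-free SiblingMoments implied by a parameter set."""
    a1, c1, e1, a2, c2, e2, rA, rC, rE = truth_like
    phi = {"full": 0.5, "maternal_half": 0.25}[relation]
    cov_a, cov_c, cov_e = a1 * a2 * rA, c1 * c2 * rC, e1 * e2 * rE
    vals = {
        "cross_sib_trait1": phi * a1 * a1 + c1 * c1,
        "cross_sib_trait2": phi * a2 * a2 + c2 * c2,
        "within_person": cov_a + cov_c + cov_e,
        "cross_sib_cross": phi * cov_a + cov_c,
    }
    tau = (2.0, 1.6)
    return SiblingMoments(
        relation=relation,
        **{
            k: TetraEstimate(rho=v, tau1=tau[0], tau2=tau[1], se_rho=se, n=10000)
            for k, v in vals.items()
        },
    )


THETA = (math.sqrt(0.5), math.sqrt(0.2), math.sqrt(0.3),
         math.sqrt(0.4), math.sqrt(0.2), math.sqrt(0.4),
         0.5, 0.4, 0.2)


class TestThresholds:
    @pytest.mark.parametrize(
        "prev,expected",
        [(0.5, 0.0), (0.0129, 2.2296), (0.0257, 1.9482)],
    )
    def test_known_values(self, prev, expected):
        assert estimate_threshold(prev) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("prev", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_prevalence(self, prev):
        with pytest.raises(ValueError):
            estimate_threshold(prev)


class TestBvnCdf:
    def test_against_scipy_implementation(self):
        """Owen's-T formula agrees with scipy's independent Phi2 integrator."""
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(0)
        for _ in range(60):
            h, k = rng.uniform(-3, 3, 2)
            rho = rng.uniform(-0.98, 0.98)
            ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=5e-11)

    def test_edge_cases(self):
        # zero thresholds: closed form 1/4 + arcsin(rho)/(2 pi)
        for rho in (-0.7, 0.0, 0.4):
            expected = 0.25 + math.asin(rho) / (2 * math.pi)
            assert bvn_cdf(0.0, 0.0, rho) == pytest.approx(expected, abs=1e-9)
        assert bvn_cdf(8.0, 8.0, 0.5) == pytest.approx(1.0, abs=1e-12)


class TestTetrachoric:
    def test_independence_table(self):
        tab = ContingencyTable2x2(100, 400, 400, 1600)  # margins 0.2/0.2, OR=1
        est = tetrachoric(tab)
        assert abs(est.rho) < 1e-4
        assert est.tau1 == pytest.approx(stats.norm.ppf(0.8), abs=1e-12)

    def test_recovers_generating_correlation(self):
        tab = bvn_table(0.23, 0.0129, 0.0257, 1_000_000, seed=1)
        est = tetrachoric(tab)
        assert est.rho == pytest.approx(0.23, abs=3 * est.se_rho)

    def test_agrees_with_grid_search_oracle(self):
        """MLE matches an argmax over a fine rho grid using scipy's Phi2."""
        from scipy.stats import multivariate_normal

        def grid_oracle(tab):
            tau1 = stats.norm.ppf(1 - tab.margin_x)
            tau2 = stats.norm.ppf(1 - tab.margin_y)
            # coarse pass, then 1e-4 grid around the peak (profile is unimodal)
            def ll(rhos):
                out = np.empty(len(rhos))
                for i, r in enumerate(rhos):
                    phi2 = multivariate_normal(cov=[[1, r], [r, 1]]).cdf([tau1, tau2])
                    p00 = phi2
                    p01 = stats.norm.cdf(tau1) - phi2
                    p10 = stats.norm.cdf(tau2) - phi2
                    p11 = 1 - stats.norm.cdf(tau1) - stats.norm.cdf(tau2) + phi2
                    ps = np.maximum([p11, p10, p01, p00], 1e-300)
                    out[i] = np.dot([tab.n11, tab.n10, tab.n01, tab.n00], np.log(ps))
                return out

            coarse = np.linspace(-0.99, 0.99, 199)
            c0 = coarse[np.argmax(ll(coarse))]
            fine = np.arange(max(-0.999, c0 - 0.02), min(0.999, c0 + 0.02), 1e-4)
            return fine[np.argmax(ll(fine))]

        rng = np.random.default_rng(3)
        for _ in range(12):
            rho = rng.uniform(-0.9, 0.9)
            p1, p2 = rng.uniform(0.05, 0.5, 2)
            tab = bvn_table(rho, p1, p2, 4000, seed=int(rng.integers(1e6)))
            est = tetrachoric(tab)
            assert est.rho == pytest.approx(grid_oracle(tab), abs=2e-4)

    def test_zero_margin_errors_zero_cell_flagged(self):
        with pytest.raises(QuantgenError, match="margin"):
            tetrachoric(ContingencyTable2x2(0, 0, 50, 50))
        est = tetrachoric(ContingencyTable2x2(40, 10, 0, 50))
        assert est.continuity_corrected

    def test_pooled_strata_close_to_common_rho(self):
        tabs = [bvn_table(0.3, 0.3, 0.4, 20000, seed=s) for s in range(4)]
        pooled = pooled_tetrachoric(tabs)
        assert pooled.rho == pytest.approx(0.3, abs=3 * pooled.se_rho)
        assert pooled.se_rho < min(tetrachoric(t).se_rho for t in tabs)


class TestPairTables:
    def test_hand_built_counts(self):
        pairs = pd.DataFrame(
            {
                "exposure_id": [1, 2, 3, 4, 5, 6],
                "outcome_id": [2, 1, 4, 3, 6, 5],
                "relation": "full",
                "birth_year_gap": 0,
            }
        )
        ph = pd.DataFrame(
            {
                "person_id": [1, 2, 3, 4, 5, 6],
                "adhd":      [1, 0, 0, 0, 1, 1],
                "cond":      [0, 1, 0, 0, 1, 0],
            }
        )
        tabs = pair_tables(pairs, ph, "full", "cond")
        t = tabs["cross_sib_trait1"]  # adhd x adhd over ordered pairs
        assert (t.n11, t.n10, t.n01, t.n00) == (2, 1, 1, 2)
        w = tabs["within_person"]  # per distinct person
        assert (w.n11, w.n10, w.n01, w.n00) == (1, 2, 1, 2)
        x = tabs["cross_sib_cross"]  # adhd(exposure) x cond(outcome)
        assert (x.n11, x.n10, x.n01, x.n00) == (2, 1, 0, 3)

    def test_counts_match_enumeration_oracle(self, small_cohort):
        from famcoaggr import cohort as cohort_mod

        persons = cohort_mod.apply_exclusions(small_cohort.persons)
        pairs = cohort_mod.build_pairs(persons).head(5000)
        lat = small_cohort.latent.set_index("person_id")
        ph = lat.reset_index()[["person_id", "trait1", "trait2"]].rename(
            columns={"trait1": "adhd", "trait2": "cond"}
        )
        tabs = pair_tables(pairs[pairs["relation"] == "full"], ph, "full", "cond")
        # brute force over rows
        counts = np.zeros(4)
        sub = pairs[pairs["relation"] == "full"]
        for e, o in zip(sub["exposure_id"], sub["outcome_id"]):
            x, y = lat.loc[e, "trait1"], lat.loc[o, "trait2"]
            counts[3 - (2 * x + y)] += 1
        t = tabs["cross_sib_cross"]
        assert (t.n11, t.n10, t.n01, t.n00) == tuple(counts)


class TestAceFit:
    def test_self_consistency_on_exact_moments(self):
        fs = exact_moments(THETA, "full")
        hs = exact_moments(THETA, "maternal_half")
        fit = fit_bivariate_ace(fs, hs)
        for mom, rel in ((fs, "full"), (hs, "maternal_half")):
            implied = fit.implied_correlations(rel)
            for name, val in implied.items():
                assert val == pytest.approx(getattr(mom, name).rho, abs=2e-6)
        assert fit.wls_discrepancy < 1e-7

    def test_share_identity_and_standardization(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a2, c2 = rng.uniform(0.05, 0.6), rng.uniform(0.05, 0.35)
            if a2 + c2 > 0.95:
                continue
            b2, d2 = rng.uniform(0.05, 0.6), rng.uniform(0.05, 0.35)
            if b2 + d2 > 0.95:
                continue
            theta = (
                math.sqrt(a2), math.sqrt(c2), math.sqrt(1 - a2 - c2),
                math.sqrt(b2), math.sqrt(d2), math.sqrt(1 - b2 - d2),
                rng.uniform(-0.9, 0.9), rng.uniform(-0.9, 0.9), rng.uniform(-0.9, 0.9),
            )
            fit = AceFit(
                a1=theta[0], c1=theta[1], e1=theta[2],
                a2=theta[3], c2=theta[4], e2=theta[5],
                rA=theta[6], rC=theta[7], rE=theta[8],
                thresholds={}, wls_discrepancy=0.0, n_starts=0, boundary=False,
            )
            if abs(fit.r_ph) < 1e-3:
                continue
            d = decompose(fit)
            assert d["share_a"] + d["share_c"] + d["share_e"] == pytest.approx(
                1.0, abs=1e-12
            )
            assert fit.a1**2 + fit.c1**2 + fit.e1**2 == pytest.approx(1.0, abs=1e-12)

    def test_pure_a_and_pure_c_sibling_ratio(self):
        # pure A: FS cross-sib correlation is twice the HS one
        theta_a = (math.sqrt(0.6), 0.0, math.sqrt(0.4),
                   math.sqrt(0.5), 0.0, math.sqrt(0.5), 0.6, 0.0, 0.1)
        fit = fit_bivariate_ace(
            exact_moments(theta_a, "full"), exact_moments(theta_a, "maternal_half")
        )
        fs_i = fit.implied_correlations("full")
        hs_i = fit.implied_correlations("maternal_half")
        assert fs_i["cross_sib_trait1"] / hs_i["cross_sib_trait1"] == pytest.approx(2.0, abs=0.01)
        # pure C: ratio 1
        theta_c = (0.0, math.sqrt(0.5), math.sqrt(0.5),
                   0.0, math.sqrt(0.4), math.sqrt(0.6), 0.0, 0.5, 0.1)
        fit_c = fit_bivariate_ace(
            exact_moments(theta_c, "full"), exact_moments(theta_c, "maternal_half")
        )
        assert fit_c.implied_correlations("full")["cross_sib_trait1"] == pytest.approx(
            fit_c.implied_correlations("maternal_half")["cross_sib_trait1"], abs=0.01
        )

    def test_perfect_genetic_overlap_decomposes_to_pure_a(self):
        theta = (1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0)
        fit = AceFit(a1=1, c1=0, e1=0, a2=1, c2=0, e2=0, rA=1, rC=0, rE=0,
                     thresholds={}, wls_discrepancy=0.0, n_starts=0, boundary=True)
        d = decompose(fit)
        assert d["share_a"] == pytest.approx(1.0, abs=1e-15)
        assert d["r_ph"] == pytest.approx(1.0)

    def test_a_c_not_separable_with_equal_sharing(self):
        """With the genetic sharing coefficient forced equal across groups the
        discrepancy surface is flat along a^2 + c^2 = const: two parameter sets
        on that ridge imply identical moments and both fit perfectly."""
        theta1 = THETA
        # move variance from A to C keeping phi*a^2+c^2 and phi*covA+covC fixed
        fs1 = exact_moments(theta1, "full")
        # with phi equal in both groups only the aggregates enter the moments
        fit = fit_bivariate_ace(
            exact_moments(theta1, "full"), exact_moments(theta1, "full"),
            phi_fs=0.5, phi_hs=0.5,
        )
        assert fit.wls_discrepancy < 1e-8
        # the fitted (a1, c1) need not equal the generating ones; only the
        # aggregate phi*a^2 + c^2 is pinned
        agg_true = 0.5 * theta1[0] ** 2 + theta1[1] ** 2
        agg_fit = 0.5 * fit.a1**2 + fit.c1**2
        assert agg_fit == pytest.approx(agg_true, abs=1e-4)

    def test_non_finite_se_rejected(self):
        fs = exact_moments(THETA, "full")
        bad = SiblingMoments(
            relation="maternal_half",
            cross_sib_trait1=TetraEstimate(0.3, 2, 1.6, float("inf"), 100),
            cross_sib_trait2=fs.cross_sib_trait2,
            within_person=fs.within_person,
            cross_sib_cross=fs.cross_sib_cross,
        )
        with pytest.raises(QuantgenError, match="SE"):
            fit_bivariate_ace(fs, bad)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        ids = np.arange(30)
        fit_fn = lambda sampled: {"m": float(np.mean(sampled))}
        a = bootstrap(fit_fn, ids, n_reps=5, seed=3)
        b = bootstrap(fit_fn, ids, n_reps=5, seed=3)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_identical_clusters_give_zero_width_ci(self):
        ids = np.arange(50)
        fit_fn = lambda sampled: {"stat": 1.23}  # every resample identical
        s = bootstrap(fit_fn, ids, n_reps=40, seed=0)
        assert s.ci_low["stat"] == s.ci_high["stat"] == 1.23

    def test_failure_ceiling_enforced(self):
        def flaky(sampled):
            if np.mean(sampled) > 24:
                raise RuntimeError("boom")
            return {"m": 0.0}

        with pytest.raises(QuantgenError, match="failure fraction"):
            bootstrap(flaky, np.arange(50), n_reps=40, seed=1, max_failure_frac=0.01)

    def test_ace_bootstrap_runs_and_brackets_r_ph(self, small_cohort):
        from famcoaggr import cohort as cohort_mod
        from famcoaggr import phenotyping
        from famcoaggr.catalog import default_catalog

        coh = small_cohort
        ph = phenotyping.build_phenotypes(
            coh.persons, coh.diagnoses, coh.prescriptions, default_catalog()
        )
        persons = cohort_mod.apply_exclusions(coh.persons)
        pairs = cohort_mod.build_pairs(persons)
        clusters = cohort_mod.build_clusters(persons)
        summary = ace_bootstrap(
            pairs, ph, clusters, "sleep_disorders", n_reps=25, seed=7
        )
        assert summary.n_replicates + summary.n_failed == 25
        assert (summary.ci_low["r_ph"] <= summary.ci_high["r_ph"])
        # truth r_ph for the fixture generator
        true_rph = coh.truth.r_ph
        assert summary.ci_low["r_ph"] - 0.1 < true_rph < summary.ci_high["r_ph"] + 0.1
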
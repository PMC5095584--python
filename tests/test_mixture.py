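"""Pooled distributions, Rician mixture EM/BIC, and species fractions."""

import numpy as np
import pytest
from scipy import stats

from flimp.geometry import SpeciesInterval, expected_interval
from flimp.inference import separation_posterior
from flimp.mixture import (
    RicianMixture,
    bootstrap_fraction,
    compile_distribution,
    species_fraction,
    tail_fraction,
)


def make_measurements(ds, sigmas):
    return [separation_posterior(d, s) for d, s in zip(ds, sigmas)]


def rice_sample(rng, r, sigma, n):
    sig = np.broadcast_to(sigma, (n,)).astype(float)
    rr = np.broadcast_to(r, (n,)).astype(float)
    return stats.rice.rvs(rr / sig, scale=sig, random_state=rng), sig


class TestCompileDistribution:
    def test_counts_and_curve_integral(self):
        ms = make_measurements([12.0, 19.0, 25.0], [1.5, 1.5, 1.5])
        dist = compile_distribution(ms, 6.0)
        assert dist.n == 3
        assert np.trapezoid(dist.curve, dist.grid_nm) == pytest.approx(3.0, abs=1e-6)

    def test_duplicates_add(self):
        m = make_measurements([12.0], [1.5])[0]
        dist = compile_distribution([m, m], 6.0)
        assert dist.n == 2
        assert np.trapezoid(dist.curve, dist.grid_nm) == pytest.approx(2.0, abs=1e-6)

    def test_filter_applied(self):
        ms = make_measurements([12.0, 19.0], [0.5, 3.0])  # widths ~2 and ~12
        dist = compile_distribution(ms, 4.8)
        assert dist.n == 1

    def test_none_passing_raises(self):
        ms = make_measurements([12.0], [3.0])
        with pytest.raises(ValueError):
            compile_distribution(ms, 0.5)
        with pytest.raises(ValueError):
            compile_distribution(ms, 0.0)


class TestRicianMixtureFit:
    def test_single_species_recovery(self):
        rng = np.random.default_rng(0)
        d, sig = rice_sample(rng, 12.5, 1.5, 100)
        res = RicianMixture(d, sig).fit(1, seed=0)
        assert res.positions_nm[0] == pytest.approx(12.5, abs=0.5)
        assert res.weights[0] == 1.0

    def test_two_species_recovery(self):
        rng = np.random.default_rng(1)
        r = np.where(rng.random(200) < 0.5, 12.5, 19.6)
        sig = rng.uniform(1.2, 1.8, 200)
        d = stats.rice.rvs(r / sig, scale=sig, random_state=rng)
        res = RicianMixture(d, sig).fit(2, seed=1)
        assert res.positions_nm == pytest.approx([12.5, 19.6], abs=1.0)
        assert res.weights == pytest.approx([0.5, 0.5], abs=0.1)

    def test_k1_loglik_matches_direct_evaluation(self):
        rng = np.random.default_rng(2)
        d, sig = rice_sample(rng, 15.0, 1.5, 60)
        m = RicianMixture(d, sig)
        res = m.fit(1, seed=0)
        assert res.loglik == pytest.approx(
            m.loglik(res.positions_nm, res.weights), abs=1e-6
        )

    def test_em_never_decreases_loglik(self):
        """Monotone EM: successive iterates never lower the likelihood."""
        rng = np.random.default_rng(3)
        r = np.where(rng.random(120) < 0.5, 12.5, 19.6)
        sig = rng.uniform(1.2, 1.8, 120)
        d = stats.rice.rvs(r / sig, scale=sig, random_state=rng)
        m = RicianMixture(d, sig)
        lls = []
        r_cur = np.array([10.0, 21.0])
        w_cur = np.array([0.5, 0.5])
        for _ in range(25):
            lls.append(m.loglik(r_cur, w_cur))
            r_new, w_new, _, _ = m._em(r_cur, max_iter=2, tol=0.0)
            r_cur, w_cur = r_new, w_new
        # tolerance covers float round-off between evaluation code paths
        assert all(b >= a - 1e-8 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_preconditions(self):
        rng = np.random.default_rng(4)
        d, sig = rice_sample(rng, 15.0, 1.5, 5)
        with pytest.raises(ValueError):
            RicianMixture(d, sig).fit(3)  # n < 2K
        with pytest.raises(ValueError):
            RicianMixture(d, sig).fit(0)


class TestBICSelection:
    def test_no_overfit_on_single_component(self):
        rng = np.random.default_rng(5)
        d, sig = rice_sample(rng, 19.6, 1.5, 200)
        res = RicianMixture(d, sig).fit_select(K_max=8, seed=0)
        assert res.K == 1

    def test_k_capped_by_sample_size(self):
        rng = np.random.default_rng(6)
        d, sig = rice_sample(rng, 15.0, 1.5, 4)
        res = RicianMixture(d, sig).fit_select(K_max=8, seed=0)
        assert res.K <= 2

    def test_consistency_with_growing_n(self):
        """Selected K settles on the truth as n grows (6+ nm spacing)."""
        rng = np.random.default_rng(7)
        hits = []
        for n in (50, 150, 500):
            r = rng.choice([12.5, 19.6, 27.1], n)
            sig = rng.uniform(1.2, 1.8, n)
            d = stats.rice.rvs(r / sig, scale=sig, random_state=rng)
            res = RicianMixture(d, sig).fit_select(K_max=6, seed=int(n))
            hits.append(res.K == 3)
        assert hits[-1]
        assert sum(hits) >= 2

    def test_bias_region_report(self):
        rng = np.random.default_rng(8)
        r = np.where(rng.random(150) < 0.5, 3.0, 12.0)
        sig = rng.uniform(1.2, 1.8, 150)
        d = stats.rice.rvs(r / sig, scale=sig, random_state=rng)
        res = RicianMixture(d, sig).fit(2, seed=0)
        report = res.bias_region_report(bias_limit_nm=6.5)
        assert report[0]["bias_flagged"] and report[0]["position_nm"] is None
        assert not report[1]["bias_flagged"]
        assert report[1]["position_nm"] == pytest.approx(12.0, abs=1.0)
        # bias limit 0: every position reported
        all_rep = res.bias_region_report(bias_limit_nm=0.0)
        assert all(item["position_nm"] is not None for item in all_rep)


class TestSpeciesFractions:
    @staticmethod
    def _dist(ds, sigmas, threshold=6.0):
        return compile_distribution(make_measurements(ds, sigmas), threshold)

    def test_counting_rule(self):
        # 6 of 10 overlap the dimer window, all overlap the region
        ds = [12.5] * 6 + [19.0] * 4
        dist = self._dist(ds, [1.0] * 10)
        est = species_fraction(dist, expected_interval("dimer"),
                               expected_interval("region"))
        assert est.fraction == pytest.approx(0.6)

    def test_all_inside_target(self):
        dist = self._dist([12.5] * 5, [0.5] * 5)
        est = species_fraction(dist, expected_interval("dimer"),
                               expected_interval("region"))
        assert est.fraction == 1.0

    def test_invariant_to_duplication(self):
        ds = [12.5] * 3 + [19.6] * 7
        dist1 = self._dist(ds, [1.0] * 10)
        dist2 = self._dist(ds * 2, [1.0] * 20)
        t, r = expected_interval("dimer"), expected_interval("region")
        assert species_fraction(dist1, t, r).fraction == \
            species_fraction(dist2, t, r).fraction

    def test_undefined_fraction_signalled(self):
        dist = self._dist([40.0] * 4, [1.0] * 4)
        with pytest.raises(ZeroDivisionError):
            species_fraction(dist, expected_interval("dimer"),
                             expected_interval("region"))

    def test_bootstrap_identical_measurements_sd_zero(self):
        dist = self._dist([12.5] * 8, [1.0] * 8)
        est = bootstrap_fraction(dist, expected_interval("dimer"),
                                 expected_interval("region"), B=200, seed=0)
        assert est.bootstrap_sd == 0.0

    def test_bootstrap_matches_binomial_se(self):
        """Bernoulli-like data (measurements wholly in or out of the target):
        bootstrap sd approximates sqrt(p(1-p)/n)."""
        rng = np.random.default_rng(9)
        n, p = 120, 0.4
        ds = [12.5 if rng.random() < p else 18.5 for _ in range(n)]
        dist = self._dist(ds, [0.3] * n)
        target = SpeciesInterval("dimer", 12.2, 12.8)
        region = SpeciesInterval("region", 0.0, 20.1)
        est = bootstrap_fraction(dist, target, region, B=1000, seed=1)
        expected_se = np.sqrt(est.fraction * (1 - est.fraction) / n)
        assert est.bootstrap_sd == pytest.approx(expected_se, rel=0.2)

    def test_bootstrap_b_minimum(self):
        dist = self._dist([12.5] * 4, [1.0] * 4)
        with pytest.raises(ValueError):
            bootstrap_fraction(dist, expected_interval("dimer"),
                               expected_interval("region"), B=50)

    def test_tail_fraction(self):
        dist = self._dist([10.0, 12.0, 14.0], [0.5] * 3)
        tails = tail_fraction(dist, cut_nm=20.1)
        assert tails["below"].fraction == 1.0
        assert tails["above"].fraction == 0.0
        # hexamer-like sample sits wholly above the cut
        dist2 = self._dist([27.1] * 5, [0.5] * 5)
        tails2 = tail_fraction(dist2, cut_nm=20.1)
        assert tails2["above"].fraction == 1.0
        assert tails2["below"].fraction == 0.0

    def test_straddling_measurement_counts_in_both(self):
        dist = self._dist([20.0], [1.5])  # interval straddles 20.1
        tails = tail_fraction(dist, cut_nm=20.1)
        assert tails["below"].fraction + tails["above"].fraction > 1.0
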
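import numpy as np
import pytest
from scipy import integrate, stats

from peakpattern.multinomial import EventCounts, NullPattern, dirmult_log_pmf
from peakpattern.ffx import CredibleSpec, posterior_intervals
from peakpattern.rfx import (
    SubjectCounts, RFXPrior, MCMCConfig, RFXPosterior,
    rfx_log_posterior, rfx_sample, rfx_intervals, informed_rfx_evidence,
)


def make_data(rng, I=10, k=50, n=3, c=30.0, m=None, a=None):
    m = np.asarray(m) if m is not None else rng.dirichlet(np.ones(n))
    a = np.asarray(a) if a is not None else m
    theta = rng.dirichlet(c * m, size=I)
    d = np.array([rng.multinomial(k, t) for t in theta])
    return SubjectCounts(counts=tuple(EventCounts(r) for r in d),
                         nulls=(NullPattern(a),))


class TestLogPosterior:
    def test_single_subject_matches_dirmult_marginal(self, rng):
        d = np.array([4, 2, 6])
        data = SubjectCounts(counts=(EventCounts(d),),
                             nulls=(NullPattern(np.ones(3) / 3),))
        # with a flat prior on m, the difference from the DirMult log pmf
        # must be constant in (m, c)
        flat = RFXPrior(alpha_m=np.ones(3))
        diffs = []
        for _ in range(5):
            m = rng.dirichlet(np.ones(3))
            c = rng.uniform(1, 100)
            diffs.append(rfx_log_posterior(m, c, data, prior=flat)
                         - dirmult_log_pmf(d, c * m))
        assert np.ptp(diffs) < 1e-10

    def test_region_permutation_symmetry(self, rng):
        data = make_data(rng, I=4, n=4)
        m = rng.dirichlet(np.ones(4))
        c = 12.0
        perm = rng.permutation(4)
        data_p = SubjectCounts(
            counts=tuple(EventCounts(cc.d[perm]) for cc in data.counts),
            nulls=tuple(NullPattern(a.a[perm]) for a in data.nulls))
        assert rfx_log_posterior(m[perm], c, data_p) == \
            pytest.approx(rfx_log_posterior(m, c, data))

    def test_outside_support_is_minus_inf(self, rng):
        data = make_data(rng, I=2, n=2)
        assert rfx_log_posterior(np.array([0.5, 0.5]), -1.0, data) == -np.inf
        assert rfx_log_posterior(np.array([0.7, 0.2]), 5.0, data) == -np.inf

    def test_dirmult_matches_quadrature_two_regions(self):
        # per-subject marginal over theta equals the conjugate closed form
        d = np.array([7, 3])
        for c, m1 in [(5.0, 0.4), (50.0, 0.7)]:
            alpha = np.array([c * m1, c * (1 - m1)])

            def integrand(t):
                return stats.binom.pmf(d[0], d.sum(), t) * \
                    stats.beta.pdf(t, alpha[0], alpha[1])

            val, _ = integrate.quad(integrand, 0, 1, epsabs=1e-12)
            assert dirmult_log_pmf(d, alpha) == \
                pytest.approx(np.log(val), abs=1e-6)


class TestSampler:
    def test_deterministic_given_seed(self, rng):
        data = make_data(rng, I=5, n=3)
        cfg = MCMCConfig(chains=2, iters=1500, burn_in=400, seed=99)
        p1 = rfx_sample(data, cfg=cfg)
        p2 = rfx_sample(data, cfg=cfg)
        np.testing.assert_array_equal(p1.m_samples, p2.m_samples)
        np.testing.assert_array_equal(p1.c_samples, p2.c_samples)

    def test_parameter_recovery(self, rng):
        data = make_data(rng, I=50, k=200, n=2, c=50.0, m=[0.3, 0.7])
        cfg = MCMCConfig(chains=2, iters=4000, burn_in=1500, seed=7)
        post = rfx_sample(data, cfg=cfg)
        assert post.converged
        assert abs(post.m_pooled[:, 0].mean() - 0.3) < 0.05

    def test_marginal_matches_grid_posterior(self, rng):
        """On 2 regions the MCMC marginal of m_1 must agree with a dense
        (m_1, c) grid posterior (smoke-scale version of the audit)."""
        data = make_data(rng, I=12, k=40, n=2, c=20.0, m=[0.35, 0.65])
        cfg = MCMCConfig(chains=2, iters=82_000, burn_in=2_000, seed=5,
                         thin=8)
        post = rfx_sample(data, cfg=cfg)
        samples = post.m_pooled[:, 0]
        assert samples.size == 20_000

        m_grid = np.linspace(1e-4, 1 - 1e-4, 400)
        lc_grid = np.linspace(*RFXPrior().logc_bounds, 300)
        logp = np.empty((m_grid.size, lc_grid.size))
        for i, m1 in enumerate(m_grid):
            for j, lc in enumerate(lc_grid):
                logp[i, j] = rfx_log_posterior(
                    np.array([m1, 1 - m1]), np.exp(lc), data)
        w = np.exp(logp - logp.max())
        marg = w.sum(axis=1)
        marg /= marg.sum()
        cdf_grid = np.cumsum(marg)
        emp_sorted = np.sort(samples)
        grid_cdf_at = np.interp(emp_sorted, m_grid, cdf_grid)
        emp_cdf = np.arange(1, emp_sorted.size + 1) / emp_sorted.size
        ks = np.abs(grid_cdf_at - emp_cdf).max()
        assert ks < 0.02

    def test_single_subject_warns(self, rng, caplog):
        import logging
        data = make_data(rng, I=1, n=2)
        with caplog.at_level(logging.WARNING):
            rfx_sample(data, cfg=MCMCConfig(chains=2, iters=1200,
                                            burn_in=150, seed=1))
        assert "single subject" in caplog.text

    def test_seed_required(self, rng):
        with pytest.raises(ValueError, match="seed"):
            MCMCConfig(chains=2, iters=100, burn_in=10)


class TestIntervals:
    def _degenerate_posterior(self, a, draws=1200):
        m = np.tile(a, (1, draws, 1))
        return RFXPosterior(
            m_samples=m, c_samples=np.full((1, draws), 10.0),
            acceptance=np.array([0.3]), rhat=np.ones(a.size + 1),
            converged=True)

    def test_degenerate_samples_no_flags(self):
        a = np.array([0.2, 0.3, 0.5])
        post = self._degenerate_posterior(a)
        _, flags = rfx_intervals(post, NullPattern(a))
        assert flags == ("null", "null", "null")

    def test_quantiles_match_sort_oracle(self, rng):
        samples = rng.dirichlet(np.ones(3) * 2, size=2000)
        post = RFXPosterior(
            m_samples=samples[None], c_samples=np.ones((1, 2000)),
            acceptance=np.array([0.3]), rhat=np.ones(4), converged=True)
        spec = CredibleSpec(x=0.95, n=3)
        intervals, _ = rfx_intervals(post, np.ones(3) / 3, spec,
                                     method="empirical")
        eps = spec.epsilon
        for j in range(3):
            s = np.sort(samples[:, j])
            for target, got in [(eps / 2, intervals[j, 0]),
                                (1 - eps / 2, intervals[j, 1])]:
                h = target * (s.size - 1)
                lo_i = int(np.floor(h))
                want = s[lo_i] + (h - lo_i) * (s[min(lo_i + 1, s.size - 1)]
                                               - s[lo_i])
                assert got == pytest.approx(want, abs=1e-12)

    def test_width_nondecreasing_in_penalty(self, rng):
        samples = rng.dirichlet(np.ones(3) * 2, size=5000)
        post = RFXPosterior(
            m_samples=samples[None], c_samples=np.ones((1, 5000)),
            acceptance=np.array([0.3]), rhat=np.ones(4), converged=True)
        widths = []
        for n_pen in (2, 5, 19):
            iv, _ = rfx_intervals(post, np.ones(3) / 3,
                                  CredibleSpec(x=0.99, n=n_pen))
            widths.append(iv[:, 1] - iv[:, 0])
        assert np.all(widths[0] <= widths[1] + 1e-12)
        assert np.all(widths[1] <= widths[2] + 1e-12)

    def test_too_few_samples_errors(self):
        a = np.array([0.5, 0.5])
        post = self._degenerate_posterior(a, draws=200)
        with pytest.raises(ValueError, match="1000"):
            rfx_intervals(post, NullPattern(a))


class TestInformedEvidence:
    def test_self_comparison_bf_one(self, rng):
        data = make_data(rng, I=4, n=3)
        m = np.array([0.2, 0.3, 0.5])
        e1 = informed_rfx_evidence(data, m)
        e0 = informed_rfx_evidence(data, m)
        assert e1 == pytest.approx(e0)

    def test_concentrated_limit_is_multinomial(self, rng):
        from peakpattern.multinomial import multinomial_log_pmf
        d = np.array([6, 4])
        data = SubjectCounts(counts=(EventCounts(d),),
                             nulls=(NullPattern(np.array([0.5, 0.5])),))
        m = np.array([0.6, 0.4])
        ev = informed_rfx_evidence(data, m, c_bounds=(1e7, 1.01e7))
        assert ev == pytest.approx(multinomial_log_pmf(d, m), abs=1e-4)

    def test_matches_trapezoid_grid(self, rng):
        data = make_data(rng, I=6, k=30, n=3)
        m = np.array([0.25, 0.35, 0.40])
        got = informed_rfx_evidence(data, m)
        lo, hi = np.log(0.1), np.log(1e4)
        lc = np.linspace(lo, hi, 20_001)
        g = np.array([sum(dirmult_log_pmf(cc.d, np.exp(x) * m)
                          for cc in data.counts) for x in lc])
        gmax = g.max()
        val = np.trapezoid(np.exp(g - gmax), lc)
        want = gmax + np.log(val) - np.log(hi - lo)
        assert got == pytest.approx(want, abs=1e-6)


def test_ffx_is_low_heterogeneity_limit_of_rfx(rng):
    """With essentially no between-subject variation the RFX population
    mean posterior and the pooled FFX pattern posterior coincide."""
    a = np.array([0.25, 0.35, 0.40])
    data = make_data(rng, I=20, k=200, n=3, c=1e6, m=a, a=a)
    post = rfx_sample(data, cfg=MCMCConfig(chains=2, iters=6000,
                                           burn_in=2000, seed=21))
    pooled = np.sum([c.d for c in data.counts], axis=0)
    iv_ffx, _ = posterior_intervals(pooled, CredibleSpec(x=0.99, n=3))
    iv_rfx, _ = rfx_intervals(post, a, CredibleSpec(x=0.99, n=3))
    mid_ffx = iv_ffx.mean(axis=1)
    mid_rfx = iv_rfx.mean(axis=1)
    np.testing.assert_allclose(mid_rfx, mid_ffx, atol=0.02)
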
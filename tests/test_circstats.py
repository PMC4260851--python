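"""Circular summaries and uniformity tests, checked against closed forms,
brute-force oracles, Monte-Carlo nulls and pingouin."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from gaitsync import circstats as cs


def uniform_grid(n):
    return np.arange(n) * 360.0 / n


class TestMeanResultant:
    def test_phase_locked(self):
        mean, R = cs.mean_resultant([0.0, 0.0, 0.0])
        assert (mean, R) == (pytest.approx(0.0), pytest.approx(1.0))

    def test_perfect_uniformity_has_no_mean(self):
        mean, R = cs.mean_resultant([0.0, 90.0, 180.0, 270.0])
        assert R == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(mean)

    def test_two_point_sample(self):
        mean, R = cs.mean_resultant([0.0, 90.0])
        assert mean == pytest.approx(45.0)
        assert R == pytest.approx(np.sqrt(2) / 2)

    def test_empty_sample_raises(self):
        with pytest.raises(cs.EmptySampleError):
            cs.mean_resultant([])


class TestVarianceDeviation:
    @pytest.mark.parametrize("R, V", [(0.17, 0.83), (1.0, 0.0), (0.92, 0.08)])
    def test_variance(self, R, V):
        assert cs.circ_variance(R) == pytest.approx(V)

    @pytest.mark.parametrize("R, s", [(0.92, 0.4), (1.0, 0.0), (0.73, 0.7348)])
    def test_angular_deviation(self, R, s):
        assert cs.angular_deviation(R) == pytest.approx(s, abs=5e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cs.circ_variance(1.2)
        with pytest.raises(ValueError):
            cs.angular_deviation(-0.1)


class TestSkewKurt:
    def test_symmetric_sample_has_zero_skew(self):
        b, _ = cs.circ_skew_kurt([-20.0, 0.0, 20.0])
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_kurtosis(self):
        _, k = cs.circ_skew_kurt([0.0, 0.0, 0.0])
        assert k == pytest.approx(1.0)

    def test_two_atom_closed_form(self):
        """All eight summary fields against direct evaluation of the
        defining sums on an 80/20 two-atom sample."""
        angles = np.concatenate([np.zeros(800), np.full(200, 90.0)])
        a = np.deg2rad(angles)
        C, S = np.cos(a).mean(), np.sin(a).mean()
        R_ref = np.hypot(C, S)
        theta_ref = np.arctan2(S, C)
        b_ref = np.mean(np.sin(2 * (a - theta_ref)))
        k_ref = np.mean(np.cos(2 * (a - theta_ref)))

        s = cs.summarize(angles)
        assert s.n == 1000
        assert s.mean_angle_deg == pytest.approx(np.rad2deg(theta_ref))
        assert s.R == pytest.approx(R_ref)
        assert s.V == pytest.approx(1 - R_ref)
        assert s.s == pytest.approx(np.sqrt(2 * (1 - R_ref)))
        assert s.b == pytest.approx(b_ref)
        assert s.k == pytest.approx(k_ref)
        assert s.ci95_low_deg < s.mean_angle_deg < s.ci95_high_deg


class TestSummaryInvariants:
    @settings(max_examples=50, derandomize=True)
    @given(
        shift=st.floats(min_value=-360, max_value=360),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_rotation_equivariance(self, shift, seed):
        """Rotating the sample shifts the mean and CI and leaves the
        shape statistics (R, V, s, b, k) and test statistics unchanged."""
        rng = np.random.default_rng(seed)
        angles = np.rad2deg(rng.vonmises(0.5, 2.0, size=40))
        s0, s1 = cs.summarize(angles), cs.summarize(angles + shift)
        d = (s1.mean_angle_deg - s0.mean_angle_deg - shift) % 360.0
        assert min(d, 360 - d) == pytest.approx(0.0, abs=1e-6)
        for f in ("R", "V", "s", "b", "k"):
            assert getattr(s1, f) == pytest.approx(getattr(s0, f), abs=1e-9)
        assert cs.rayleigh_test(angles + shift).statistic == pytest.approx(
            cs.rayleigh_test(angles).statistic)
        assert cs.hodges_ajne_test(angles + shift).statistic == pytest.approx(
            cs.hodges_ajne_test(angles).statistic)

    def test_summary_internal_relations_on_constructed_R(self):
        """A sample constructed to have a given R yields V = 1-R and
        s = sqrt(2(1-R)) through the full estimator path."""
        for target in (0.17, 0.44, 0.92):
            k = int(round(100 * target))
            angles = np.concatenate([np.zeros(k), uniform_grid(100 - k)])
            s = cs.summarize(angles)
            assert s.R == pytest.approx(target, abs=1e-12)
            assert s.V == pytest.approx(1 - target, abs=1e-12)
            assert s.s == pytest.approx(np.sqrt(2 * (1 - target)), abs=1e-12)

    def test_matches_pingouin(self, rng):
        angles = np.rad2deg(rng.vonmises(1.0, 1.5, size=200))
        mean, R = cs.mean_resultant(angles)
        a = np.deg2rad(angles)
        assert R == pytest.approx(float(pg.circ_r(a)))
        d = (mean - np.rad2deg(float(pg.circ_mean(a)))) % 360
        assert min(d, 360 - d) == pytest.approx(0.0, abs=1e-9)


class TestRayleigh:
    def test_concentrated(self):
        res = cs.rayleigh_test(np.zeros(50))
        assert res.p_value < 1e-6

    def test_uniform_grid(self):
        res = cs.rayleigh_test(uniform_grid(100))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_small_sample_rejected(self):
        with pytest.raises(cs.EmptySampleError):
            cs.rayleigh_test([0.0, 10.0])

    def test_matches_pingouin(self, rng):
        angles = np.rad2deg(rng.vonmises(0.0, 0.5, size=80))
        ours = cs.rayleigh_test(angles)
        z, p = pg.circ_rayleigh(np.deg2rad(angles))
        assert ours.statistic == pytest.approx(float(z))
        assert ours.p_value == pytest.approx(float(p), abs=2e-3)

    def test_p_matches_monte_carlo_null(self, rng):
        """Analytic p agrees with a simulated-null oracle at n = 60."""
        n, reps = 60, 10_000
        null = rng.uniform(0, 2 * np.pi, size=(reps, n))
        Rnull = np.hypot(np.cos(null).mean(axis=1), np.sin(null).mean(axis=1))
        Znull = n * Rnull**2
        sample = np.rad2deg(rng.vonmises(0.0, 0.25, size=n))
        res = cs.rayleigh_test(sample)
        p_mc = np.mean(Znull >= res.statistic)
        assert res.p_value == pytest.approx(p_mc, abs=4 * np.sqrt(0.25 / reps) + 0.01)


class TestHodgesAjne:
    def test_half_circle_concentration(self):
        angles = np.linspace(10, 150, 30)
        res = cs.hodges_ajne_test(angles)
        assert res.statistic == 0
        assert res.p_value < 1e-4

    def test_detects_asymmetric_bimodal(self, rng):
        angles = np.concatenate([
            rng.normal(0, 5, size=40), rng.normal(180, 5, size=10)])
        assert cs.hodges_ajne_test(angles).p_value < 0.01

    def test_blind_to_balanced_antipodal(self, rng):
        """A perfectly balanced antipodal mixture fills every half-circle
        (m ~ n/2), so the emptiest-half-circle statistic has no power —
        the known limitation of this omnibus test."""
        angles = np.concatenate([
            rng.normal(0, 5, size=25), rng.normal(180, 5, size=25)])
        res = cs.hodges_ajne_test(angles)
        assert res.statistic >= 20
        assert res.p_value > 0.5
        assert cs.rayleigh_test(angles).p_value > 0.2  # R ~ 0 too

    def test_uniform_grid(self):
        assert cs.hodges_ajne_test(uniform_grid(100)).p_value > 0.9

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(9, 40))
    def test_statistic_matches_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0, 360, size=n)
        res = cs.hodges_ajne_test(angles)
        a = np.deg2rad(angles)
        # brute force: scan half-circles anchored on a fine grid + data
        bounds = np.concatenate([a, np.linspace(0, 2 * np.pi, 720)])
        rel = (a[None, :] - bounds[:, None]) % (2 * np.pi)
        counts = (rel < np.pi).sum(axis=1)
        m_ref = int(np.minimum(counts, n - counts).min())
        assert res.statistic == m_ref

    def test_p_matches_monte_carlo_null(self, rng):
        n, reps = 40, 10_000
        msim = np.empty(reps)
        for i in range(reps):
            msim[i] = cs._hodges_ajne_m(rng.uniform(0, 2 * np.pi, size=n))
        sample = np.rad2deg(rng.vonmises(0.0, 0.35, size=n))
        res = cs.hodges_ajne_test(sample)
        # mid-p oracle: same quantity the implementation reports
        p_mc = np.mean(msim < res.statistic) + 0.5 * np.mean(msim == res.statistic)
        assert res.p_value == pytest.approx(p_mc, abs=4 * np.sqrt(0.25 / reps) + 0.01)


class TestWatsonU2:
    def test_identical_samples_not_significant(self, rng):
        a = np.rad2deg(rng.vonmises(0.0, 1.0, size=40))
        res = cs.watson_u2_two_sample(a, a)
        assert res.p_value > 0.5

    def test_separated_samples(self, rng):
        a = rng.normal(0, 5, size=50)
        b = rng.normal(180, 5, size=50)
        assert cs.watson_u2_two_sample(a, b).p_value < 0.001

    def test_matches_permutation_oracle(self, rng):
        """Asymptotic p within Monte-Carlo error of a 10^4-shuffle
        permutation oracle for a moderate separation."""
        a = np.rad2deg(rng.vonmises(0.0, 1.0, size=45))
        b = np.rad2deg(rng.vonmises(np.pi / 4, 1.0, size=55))
        res = cs.watson_u2_two_sample(a, b)
        pooled = np.concatenate([a, b])
        reps = 10_000
        count = 0
        for _ in range(reps):
            perm = rng.permutation(pooled)
            stat = cs.watson_u2_two_sample(perm[:45], perm[45:]).statistic
            count += stat >= res.statistic
        p_perm = count / reps
        assert res.p_value == pytest.approx(p_perm, abs=4 * np.sqrt(0.25 / reps) + 0.015)


class TestMeanCI:
    def test_identical_angles_zero_width(self):
        lo, hi = cs.mean_ci95(np.full(20, 30.0))
        assert lo == pytest.approx(hi) == pytest.approx(30.0)

    def test_rotation_shifts_limits(self, rng):
        angles = np.rad2deg(rng.vonmises(0.0, 3.0, size=50))
        lo, hi = cs.mean_ci95(angles)
        lo2, hi2 = cs.mean_ci95(angles + 30.0)
        assert lo2 - lo == pytest.approx(30.0, abs=1e-9)
        assert hi2 - hi == pytest.approx(30.0, abs=1e-9)

    def test_dispersed_sample_rejected(self):
        with pytest.raises(cs.UndefinedMeanError):
            cs.mean_ci95(uniform_grid(40))

    def test_agrees_with_bootstrap(self, rng):
        angles = np.rad2deg(rng.vonmises(0.3, 8.0, size=1000))
        lo, hi = cs.mean_ci95(angles)
        a = np.deg2rad(angles)
        idx = rng.integers(0, 1000, size=(10_000, 1000))
        C = np.cos(a)[idx].mean(axis=1)
        S = np.sin(a)[idx].mean(axis=1)
        means = np.rad2deg(np.arctan2(S, C))
        blo, bhi = np.percentile(means, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.5)
        assert hi == pytest.approx(bhi, abs=0.5)


class TestParticipantsAndHistogram:
    def test_sync_fraction_phase_locked(self, rng):
        group = {f"p{i}": rng.normal(0, 1, size=50) for i in range(5)}
        assert cs.participant_sync_fraction(group) == 1.0

    def test_sync_fraction_mixed(self, rng):
        group = {f"lock{i}": rng.normal(0, 2, size=400) for i in range(7)}
        group.update({f"unif{i}": uniform_grid(400) + rng.uniform(0, 360)
                      for i in range(3)})
        assert cs.participant_sync_fraction(group) == pytest.approx(0.7)

    def test_histogram_conservation_and_binning(self, rng):
        angles = rng.uniform(-180, 180, size=137)
        edges, counts = cs.angular_histogram(angles, 20.0)
        assert counts.sum() == 137
        assert len(counts) == 18

        _, counts0 = cs.angular_histogram(np.zeros(10), 20.0)
        assert counts0.max() == 10 and (counts0 > 0).sum() == 1

        _, cu = cs.angular_histogram(uniform_grid(360), 20.0)
        assert np.all(cu == 20)

        with pytest.raises(ValueError):
            cs.angular_histogram(angles, 25.0)
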
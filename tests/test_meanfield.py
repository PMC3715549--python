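"""Mean-field model tests: shape-function estimation, piecewise power-law
fitting, closed-form population factors against quadrature oracles, reach,
offset quadrature and depth profiles."""

import numpy as np
import pytest
import scipy.integrate
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpreach.meanfield import (MeanFieldError, PiecewisePowerLaw,
                                ShapeFunctionTable, a0, a0_offset, a1,
                                a1_offset, compute_reach,
                                depth_profile_prediction, estimate_shape,
                                fit_piecewise, predict_offset_psd,
                                predict_population_psd,
                                predict_population_psd_discrete,
                                reach_from_laws)

RHO = 1e-3  # cells/um^2 (~1000 per mm^2)


def quad_a0(R, law, rho):
    val, _ = scipy.integrate.quad(lambda r: law(r) ** 2 * r, 0, R,
                                  points=[law.r0, law.eps], limit=200,
                                  epsabs=0, epsrel=1e-12)
    return 2 * np.pi * rho * val


def quad_a1(R, law, rho):
    val, _ = scipy.integrate.quad(lambda r: law(r) * r, 0, R,
                                  points=[law.r0, law.eps], limit=200,
                                  epsabs=0, epsrel=1e-12)
    return (2 * np.pi * rho * val) ** 2


def table_from_law(law, distances, freqs, noise=None, rng=None):
    F = np.tile(law(distances)[:, None], (1, len(freqs)))
    if noise is not None:
        F = F * rng.lognormal(0.0, noise, size=F.shape)
    return ShapeFunctionTable(distances=distances, freqs=freqs, F=F)


class TestEstimateShape:
    def test_white_input_shape_squared_proportional_to_psd(self):
        dist = np.array([10.0, 100.0, 1000.0])
        freqs = np.array([0.0, 250.0])
        S = np.array([[4.0, 1.0], [0.04, 0.01], [4e-4, 1e-4]])
        S_in = np.array([2.0, 2.0])
        tab = estimate_shape(S, S_in, dist, freqs)
        np.testing.assert_allclose(tab.F**2 * S_in[None, :], S, rtol=1e-12)

    def test_input_normalization_cancels_amplitude(self):
        dist = np.array([10.0, 100.0])
        freqs = np.array([0.0])
        S = np.array([[1.0], [0.01]])
        t1 = estimate_shape(S, np.array([1.0]), dist, freqs)
        t2 = estimate_shape(4 * S, np.array([4.0]), dist, freqs)
        np.testing.assert_allclose(t1.F, t2.F, rtol=1e-12)

    def test_zero_input_bin_excluded(self):
        with pytest.warns(UserWarning, match="zero"):
            tab = estimate_shape(
                np.ones((2, 2)), np.array([1.0, 0.0]),
                np.array([1.0, 2.0]), np.array([0.0, 100.0]),
            )
        assert tab.excluded_bins[1]
        assert np.isnan(tab.F[:, 1]).all()


class TestPiecewisePowerLaw:
    def test_invalid_parameters(self):
        with pytest.raises(MeanFieldError):
            PiecewisePowerLaw(1.0, r0=50.0, eps=10.0)
        with pytest.raises(MeanFieldError):
            PiecewisePowerLaw(1.0, r0=0.0, eps=10.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        r0=st.floats(1.0, 50.0),
        ratio=st.floats(1.0, 100.0),
        A=st.floats(1e-3, 1e3),
    )
    def test_continuity_at_breakpoints(self, r0, ratio, A):
        law = PiecewisePowerLaw(A, r0=r0, eps=r0 * ratio)
        for b in (law.r0, law.eps):
            below, above = law(b * (1 - 1e-9)), law(b * (1 + 1e-9))
            assert below == pytest.approx(above, rel=1e-6)

    def test_regime_values(self):
        law = PiecewisePowerLaw(2.0, r0=10.0, eps=100.0)
        assert law(5.0) == pytest.approx(0.2)       # plateau A/r0
        assert law(50.0) == pytest.approx(0.04)     # A/r
        assert law(1000.0) == pytest.approx(2e-4)   # A eps / r^2


class TestFitPiecewise:
    dist = np.geomspace(10.0, 3000.0, 30)
    freqs = np.array([0.0, 100.0, 500.0])

    def test_noiseless_self_consistency(self):
        law = PiecewisePowerLaw(1.0, r0=10.0, eps=300.0)
        tab = table_from_law(law, self.dist, self.freqs)
        fits = fit_piecewise(tab, r0=10.0)
        for f in fits:
            assert f.eps == pytest.approx(300.0, rel=0.01)
            assert f.amplitude == pytest.approx(1.0, rel=0.01)

    def test_noisy_recovery_median_within_ten_percent(self):
        """5% multiplicative noise, 50 replicates: median eps within 10%."""
        law = PiecewisePowerLaw(1.0, r0=10.0, eps=300.0)
        rng = np.random.default_rng(42)
        recovered = []
        for _ in range(50):
            tab = table_from_law(law, self.dist, self.freqs[:1],
                                 noise=0.05, rng=rng)
            recovered.append(fit_piecewise(tab, r0=10.0)[0].eps)
        assert np.median(recovered) == pytest.approx(300.0, rel=0.10)

    def test_order_preserved_for_decreasing_cutoffs(self):
        eps_true = [500.0, 300.0, 120.0]
        F = np.stack(
            [PiecewisePowerLaw(1.0, 10.0, e)(self.dist) for e in eps_true],
            axis=1,
        )
        tab = ShapeFunctionTable(distances=self.dist, freqs=self.freqs, F=F)
        fits = fit_piecewise(tab, r0=10.0)
        eps_fit = [f.eps for f in fits]
        assert eps_fit[0] > eps_fit[1] > eps_fit[2]

    def test_single_regime_warns_and_pins_boundary(self):
        # all sampled points in the near-field regime
        dist = np.geomspace(20.0, 80.0, 8)
        law = PiecewisePowerLaw(1.0, 10.0, 5000.0)
        tab = table_from_law(law, dist, np.array([0.0]))
        with pytest.warns(UserWarning, match="one power-law regime"):
            fits = fit_piecewise(tab, r0=10.0)
        assert fits[0].eps <= 80.0 * (1 + 1e-9)

    def test_too_few_distances_rejected(self):
        law = PiecewisePowerLaw(1.0, 10.0, 300.0)
        dist = np.array([10.0, 100.0, 1000.0])
        tab = table_from_law(law, dist, np.array([0.0]))
        with pytest.raises(MeanFieldError):
            fit_piecewise(tab)


class TestClosedForms:
    sweep = [
        (50.0, 1.0), (300.0, 10.0), (1000.0, 50.0), (150.0, 25.0),
    ]

    @pytest.mark.parametrize("eps,r0", sweep)
    def test_a0_a1_match_quadrature_over_sweep(self, eps, r0):
        law = PiecewisePowerLaw(0.7, r0=r0, eps=eps)
        for R in [r0 / 2, r0, (r0 + eps) / 2, eps, 3 * eps, 1e4]:
            assert a0(R, law, RHO) == pytest.approx(
                quad_a0(R, law, RHO), rel=1e-8
            )
            assert a1(R, law, RHO) == pytest.approx(
                quad_a1(R, law, RHO), rel=1e-8
            )

    def test_a0_saturates_a1_grows_log_squared(self):
        law = PiecewisePowerLaw(1.0, r0=10.0, eps=300.0)
        A0 = [a0(R, law, RHO) for R in (10 * 300, 100 * 300, 1000 * 300)]
        assert A0[2] / A0[0] < 1.01  # converged
        A1 = [a1(R, law, RHO) for R in (10 * 300, 100 * 300, 1000 * 300)]
        # sqrt(A1) grows by the same log increment per decade
        inc1 = np.sqrt(A1[1]) - np.sqrt(A1[0])
        inc2 = np.sqrt(A1[2]) - np.sqrt(A1[1])
        assert inc1 == pytest.approx(inc2, rel=1e-6)
        assert A1[2] > A1[1] > A1[0]

    def test_density_scaling(self):
        law = PiecewisePowerLaw(1.0, r0=10.0, eps=300.0)
        assert a0(500.0, law, 2 * RHO) == pytest.approx(
            2 * a0(500.0, law, RHO), rel=1e-12
        )
        assert a1(500.0, law, 2 * RHO) == pytest.approx(
            4 * a1(500.0, law, RHO), rel=1e-12
        )


class TestPredictPopulationPsd:
    law = PiecewisePowerLaw(1.0, r0=10.0, eps=300.0)
    S_in = np.array([2.0, 1.0, 0.5])

    def laws(self):
        return [self.law] * 3

    def test_uncorrelated_limit_is_variance_addition(self):
        pred = predict_population_psd(1000.0, self.laws(), 0.0, RHO, self.S_in)
        np.testing.assert_allclose(pred.S_pop, self.S_in * pred.A0, rtol=1e-12)

    def test_coherent_limit_is_amplitude_addition(self):
        pred = predict_population_psd(1000.0, self.laws(), 1.0, RHO, self.S_in)
        np.testing.assert_allclose(pred.S_pop, self.S_in * pred.A1, rtol=1e-12)

    def test_discrete_combiner_equals_double_sum(self, rng):
        """50-cell toy: the combiner equals the brute-force pairwise double
        sum with equal pairwise coherence, to float precision."""
        r = 1000.0 * np.sqrt(rng.uniform(size=50))
        F = np.tile(self.law(r)[:, None], (1, 3))
        cbar = np.array([0.7, 0.3, 0.05])
        pred = predict_population_psd_discrete(F, cbar, self.S_in)
        brute = np.empty(3)
        for b in range(3):
            acc = 0.0
            for i in range(50):
                for j in range(50):
                    w = 1.0 if i == j else cbar[b]
                    acc += w * F[i, b] * F[j, b]
            brute[b] = self.S_in[b] * acc
        np.testing.assert_allclose(pred, brute, rtol=1e-10)

    def test_out_of_range_coherence_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            pred = predict_population_psd(
                500.0, self.laws(), np.array([1.5, 0.5, 0.2]), RHO, self.S_in
            )
        assert pred.cbar[0] == 1.0


class TestReach:
    law = PiecewisePowerLaw(1.0, r0=10.0, eps=300.0)

    def test_fraction_one_gives_rmax(self):
        radii = np.arange(100.0, 1001.0, 100.0)
        amp = np.sqrt(np.array([a0(R, self.law, RHO) for R in radii]))
        assert compute_reach(amp, radii, fraction=1.0) == 1000.0

    def test_uncorrelated_reach_matches_bisection_oracle(self):
        """Grid reach brackets the root of A0(R) = 0.95^2 A0(R_max)."""
        R_max, dr = 1000.0, 100.0
        radii = np.arange(dr, R_max + dr / 2, dr)
        amp = np.sqrt(np.array([a0(R, self.law, RHO) for R in radii]))
        reach = compute_reach(amp, radii)
        target = 0.95**2 * a0(R_max, self.law, RHO)
        root = scipy.optimize.brentq(
            lambda R: a0(R, self.law, RHO) - target, 1.0, R_max
        )
        # smallest grid point at or above the true crossing
        assert reach == radii[np.searchsorted(radii, root)]

    def test_correlated_reach_at_least_uncorrelated(self):
        laws = [self.law] * 5
        r_unc = reach_from_laws(laws, 0.0, RHO, 1000.0)
        r_coh = reach_from_laws(laws, 1.0, RHO, 1000.0)
        assert np.all(r_coh >= r_unc)

    def test_first_upward_crossing_on_noisy_amplitude(self):
        radii = np.arange(100.0, 601.0, 100.0)
        amp = np.array([0.5, 0.97, 0.93, 0.96, 0.99, 1.0])
        assert compute_reach(amp, radii, fraction=0.95) == 200.0


class TestOffsetModel:
    law = PiecewisePowerLaw(1.0, r0=10.0, eps=300.0)
    S_in = np.array([1.0])

    def test_center_matches_population_prediction(self):
        pred0 = predict_population_psd(1000.0, [self.law], 0.3, RHO, self.S_in)
        predX = predict_offset_psd(0.0, 1000.0, [self.law], 0.3, RHO, self.S_in)
        np.testing.assert_allclose(predX.S_pop, pred0.S_pop, rtol=1e-6)

    def test_far_field_uncorrelated_point_population_scaling(self):
        """X >> R: the disc acts as N point sources at distance X, so the
        amplitude approaches F(X) sqrt(N)."""
        R = 100.0
        N = RHO * np.pi * R**2
        for X in (5000.0, 20000.0):
            pred = predict_offset_psd(X, R, [self.law], 0.0, RHO, self.S_in)
            expected = self.law(X) ** 2 * N
            assert pred.S_pop[0] == pytest.approx(expected, rel=0.05)

    def test_edge_to_center_power_ratios_in_large_population_limit(self):
        """X = R: power ratio -> 1/2 for incoherent and 1/4 for coherent
        populations as R/eps grows, approaching monotonically."""
        ratios0, ratios1 = [], []
        for RoverEps in (10, 100, 1000):
            R = RoverEps * self.law.eps
            c0_edge = a0_offset(R, R, self.law, RHO)
            c0_cent = a0(R, self.law, RHO)
            c1_edge = a1_offset(R, R, self.law, RHO)
            c1_cent = a1(R, self.law, RHO)
            ratios0.append(c0_edge / c0_cent)
            ratios1.append(c1_edge / c1_cent)
        assert ratios0[-1] == pytest.approx(0.5, rel=0.05)
        assert ratios1[-1] == pytest.approx(0.25, rel=0.05)
        assert np.all(np.diff(np.abs(np.array(ratios0) - 0.5)) < 0)
        assert np.all(np.diff(np.abs(np.array(ratios1) - 0.25)) < 0)

    def test_offset_coherence_decay_steepens_far_field(self):
        """With cbar(X) ~ 1/X the far-field power falls faster than with
        constant coherence (log-log slope comparison)."""
        R = 300.0
        X = np.array([1000.0, 2000.0, 4000.0, 8000.0])
        const = np.array([
            predict_offset_psd(x, R, [self.law], 0.5, RHO, self.S_in).S_pop[0]
            for x in X
        ])
        decayed = np.array([
            predict_offset_psd(x, R, [self.law], 0.5 * (X[0] / x), RHO,
                               self.S_in).S_pop[0]
            for x in X
        ])
        s_const = np.polyfit(np.log(X), np.log(const), 1)[0]
        s_dec = np.polyfit(np.log(X), np.log(decayed), 1)[0]
        assert s_dec < s_const - 0.5


class TestDepthProfile:
    def test_identical_depths_give_flat_profile(self):
        law = PiecewisePowerLaw(1.0, 10.0, 300.0)
        laws = {z: [law] * 2 for z in (-200.0, 0.0, 400.0)}
        cbar = {z: 0.4 for z in laws}
        prof = depth_profile_prediction(laws, cbar, 500.0, RHO,
                                        np.array([1.0, 1.0]))
        vals = np.array(list(prof.values()))
        assert np.ptp(vals) < 1e-12

    def test_uncorrelated_profile_proportional_to_a0(self):
        laws = {
            0.0: [PiecewisePowerLaw(1.0, 10.0, 300.0)],
            500.0: [PiecewisePowerLaw(0.3, 10.0, 150.0)],
        }
        cbar = {0.0: 0.0, 500.0: 0.0}
        prof = depth_profile_prediction(laws, cbar, 800.0, RHO, np.array([2.0]))
        for z, lw in laws.items():
            assert prof[z][0] == pytest.approx(2.0 * a0(800.0, lw[0], RHO),
                                               rel=1e-12)

    def test_two_depth_hand_computed_values(self):
        lawA = PiecewisePowerLaw(1.0, 10.0, 200.0)
        lawB = PiecewisePowerLaw(2.0, 10.0, 400.0)
        R, S_in = 600.0, np.array([3.0])
        prof = depth_profile_prediction(
            {0.0: [lawA], 300.0: [lawB]}, {0.0: 0.25, 300.0: 0.75},
            R, RHO, S_in,
        )
        for z, law, c in ((0.0, lawA, 0.25), (300.0, lawB, 0.75)):
            hand = 3.0 * ((1 - c) * a0(R, law, RHO) + c * a1(R, law, RHO))
            assert prof[z][0] == pytest.approx(hand, rel=1e-12)

    def test_missing_depth_rejected(self):
        law = PiecewisePowerLaw(1.0, 10.0, 300.0)
        with pytest.raises(MeanFieldError):
            depth_profile_prediction({0.0: [law]}, {}, 500.0, RHO,
                                     np.array([1.0]))

    def test_per_depth_normalization(self):
        law = PiecewisePowerLaw(1.0, 10.0, 300.0)
        prof = depth_profile_prediction(
            {0.0: [law, law]}, {0.0: np.array([0.0, 1.0])}, 500.0, RHO,
            np.array([1.0, 1.0]), normalize_per_depth=True,
        )
        assert prof[0.0].max() == pytest.approx(1.0)
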
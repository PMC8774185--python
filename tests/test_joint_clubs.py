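import numpy as np
import pytest

from bundlesans import (JointClubsParams, ScatteringCurve, guinier_fit,
                        joint_clubs_fit, joint_clubs_intensity)
from bundlesans.joint_clubs import intensity_from_axes, sample_axes
from bundlesans.synthetic import cylinder_intensity


class TestIntensity:
    def test_single_club_matches_cylinder_form_factor(self):
        """n = 1 reduces to the classical orientationally averaged cylinder
        form factor (Gauss-Legendre quadrature oracle) within 1%."""
        q = np.linspace(0.01, 0.4, 40)
        params = JointClubsParams(n_clubs=1, club_length=31.5,
                                  club_diameter=10.6)
        mc = joint_clubs_intensity(params, q, n_conformations=20000, seed=2)
        exact = cylinder_intensity(q, 31.5, 10.6)
        assert np.max(np.abs(mc.intensity - exact) / exact) < 0.01

    def test_forward_limit_is_scale_plus_background(self):
        q = np.array([1e-5, 1e-4, 1e-3])
        params = JointClubsParams(scale=0.37, background=0.05)
        tc = joint_clubs_intensity(params, q, n_conformations=500, seed=0)
        assert tc.intensity[0] == pytest.approx(0.42, rel=1e-4)

    def test_thin_rod_asymptotics(self):
        """Long thin club (Q R_radial << 1) follows the Neugebauer rod
        form factor 2 Si(x)/x - sinc^2(x/2) within 3%."""
        from scipy.special import sici
        L = 200.0
        q = np.linspace(0.01, 0.4, 30)
        params = JointClubsParams(n_clubs=1, club_length=L, club_diameter=1.0)
        mc = joint_clubs_intensity(params, q, n_conformations=40000, seed=5)
        x = q * L
        rod = 2 * sici(x)[0] / x - (np.sin(x / 2) / (x / 2)) ** 2
        assert np.max(np.abs(mc.intensity - rod) / rod) < 0.03

    def test_same_seed_bit_identical(self):
        q = np.linspace(0.01, 0.3, 30)
        p = JointClubsParams()
        a = joint_clubs_intensity(p, q, n_conformations=500, seed=9).intensity
        b = joint_clubs_intensity(p, q, n_conformations=500, seed=9).intensity
        assert np.array_equal(a, b)

    def test_monte_carlo_convergence(self):
        """Doubling the ensemble changes the curve by less than
        1/sqrt(n_conformations) relative RMS."""
        q = np.linspace(0.01, 0.4, 60)
        p = JointClubsParams()
        n = 2000
        a = joint_clubs_intensity(p, q, n_conformations=n, seed=10).intensity
        b = joint_clubs_intensity(p, q, n_conformations=2 * n, seed=11).intensity
        rel_rms = np.sqrt(np.mean(((a - b) / b) ** 2))
        assert rel_rms < 1.0 / np.sqrt(n)

    def test_club_order_reversal_symmetry(self):
        """Traversing the chain from either end gives the same intensity
        for the same conformations (congruent geometry)."""
        q = np.linspace(0.01, 0.4, 30)
        axes = sample_axes(4, 400, seed=3)
        a = intensity_from_axes(axes, 31.5, 10.6, 5.0, q)
        b = intensity_from_axes(axes[:, ::-1, :], 31.5, 10.6, 5.0, q)
        np.testing.assert_allclose(a, b, rtol=0.05)
        # and statistically identical under matched ensembles
        assert np.sqrt(np.mean(((a - b) / b) ** 2)) < 2.0 / np.sqrt(400)

    def test_open_bundle_is_larger_than_compact_bundle(self):
        """The Guinier Rg of the noiseless model curve at the open-bundle
        geometry (n=4, L=31.5, R=10.6) well exceeds the ~18 A of the
        compactly folded dimer."""
        q = np.linspace(0.01, 0.1, 60)
        tc = joint_clubs_intensity(JointClubsParams(), q,
                                   n_conformations=8000, seed=1)
        g = guinier_fit(ScatteringCurve(q=q, intensity=tc.intensity),
                        1e-4, 2e-3, enforce_qrg=False)
        assert g.rg > 18.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            JointClubsParams(n_clubs=0)
        with pytest.raises(ValueError):
            JointClubsParams(club_length=-1.0)
        with pytest.raises(ValueError, match="n_conformations"):
            joint_clubs_intensity(JointClubsParams(), [0.01, 0.1],
                                  n_conformations=10, seed=0)


class TestFit:
    def test_self_recovery_with_noise(self):
        """2% noise on a synthetic open-bundle curve: the fit returns
        L within +/-2 A of 31.5 and R within +/-1 A of 10.6."""
        q = np.linspace(0.01, 0.4, 100)
        truth = JointClubsParams(club_length=31.5, club_diameter=10.6)
        tc = joint_clubs_intensity(truth, q, n_conformations=10000, seed=3)
        rng = np.random.default_rng(42)
        sigma = 0.02 * tc.intensity
        curve = ScatteringCurve(
            q=q, intensity=tc.intensity + rng.standard_normal(len(q)) * sigma,
            sigma=sigma)
        fit = joint_clubs_fit(curve, n_conformations=1500, seed=11)
        assert fit.params.club_length == pytest.approx(31.5, abs=2.0)
        assert fit.params.club_diameter == pytest.approx(10.6, abs=1.0)
        assert fit.param_errors["club_length"] >= 0.0
        assert fit.seed == 11

    def test_single_cylinder_identity_fit(self):
        """Fitting a pure cylinder curve with n_clubs = 1 recovers the
        generating dimensions within the noise."""
        q = np.linspace(0.01, 0.4, 80)
        exact = cylinder_intensity(q, 35.0, 12.0)
        rng = np.random.default_rng(7)
        sigma = 0.01 * exact
        curve = ScatteringCurve(
            q=q, intensity=exact + rng.standard_normal(len(q)) * sigma,
            sigma=sigma)
        init = JointClubsParams(n_clubs=1, club_length=30.0,
                                club_diameter=10.0)
        fit = joint_clubs_fit(curve, init=init, n_conformations=3000, seed=1)
        assert fit.params.club_length == pytest.approx(35.0, abs=2.0)
        assert fit.params.club_diameter == pytest.approx(12.0, abs=1.0)

    def test_too_few_points(self):
        q = np.linspace(0.01, 0.1, 10)
        with pytest.raises(ValueError, match=">= 20"):
            joint_clubs_fit(ScatteringCurve(q=q, intensity=np.ones(10)))
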
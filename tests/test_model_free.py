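import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bundlesans import (ScatteringCurve, aggregate_fraction, debye_fit,
                        debye_function, guinier_fit, kratky_transform,
                        mw_ratio)
from bundlesans.synthetic import (SyntheticSpec, generate_curve,
                                  sphere_intensity)


class TestGuinier:
    def test_exact_guinier_law(self):
        """A curve generated from the Guinier law inverts exactly."""
        q = np.linspace(0.01, 0.06, 50)
        curve = ScatteringCurve(q=q, intensity=7.0 * np.exp(-q ** 2 * 20 ** 2 / 3))
        res = guinier_fit(curve, 1e-4, 3.6e-3, enforce_qrg=False)
        assert res.rg == pytest.approx(20.0, rel=1e-6)
        assert res.i0 == pytest.approx(7.0, rel=1e-6)
        assert res.r_squared > 1 - 1e-12

    @given(rg=st.floats(10.0, 40.0), i0=st.floats(0.01, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_exact_inversion_property(self, rg, i0):
        q = np.linspace(0.005, 1.0 / rg, 40)
        curve = ScatteringCurve(q=q, intensity=i0 * np.exp(-q ** 2 * rg ** 2 / 3))
        res = guinier_fit(curve, q[0] ** 2, q[-1] ** 2, enforce_qrg=False)
        assert res.rg == pytest.approx(rg, rel=1e-6)
        assert res.i0 == pytest.approx(i0, rel=1e-6)

    def test_sphere_rg_is_sqrt_three_fifths_radius(self, sphere_curve):
        """Guinier Rg of a uniform sphere = sqrt(3/5) R within 1% when the
        window respects the Q*Rg <= 1.0 regime."""
        curve, radius = sphere_curve
        rg_true = np.sqrt(3.0 / 5.0) * radius
        res = guinier_fit(curve, curve.q[0] ** 2, (0.9 / rg_true) ** 2,
                          enforce_qrg=False)
        assert res.rg / radius == pytest.approx(np.sqrt(3.0 / 5.0), rel=0.01)
        assert res.rg == pytest.approx(20.0, abs=0.2)

    def test_qrg_warning_flag(self):
        q = np.linspace(0.01, 0.2, 80)
        curve = ScatteringCurve(q=q, intensity=np.exp(-q ** 2 * 25 ** 2 / 3))
        with pytest.warns(UserWarning, match="guideline"):
            res = guinier_fit(curve, 1e-4, 0.04, enforce_qrg=True)
        assert res.qrg_warning

    def test_rising_curve_errors(self):
        q = np.linspace(0.01, 0.1, 30)
        curve = ScatteringCurve(q=q, intensity=np.exp(+q ** 2 * 100))
        with pytest.raises(ValueError, match="no Guinier decay"):
            guinier_fit(curve, 1e-4, 0.01, enforce_qrg=False)

    def test_too_few_positive_points(self):
        q = np.linspace(0.01, 0.1, 30)
        inten = -np.ones(30)
        inten[:2] = 1.0
        with pytest.raises(ValueError, match=">= 3 points"):
            guinier_fit(ScatteringCurve(q=q, intensity=inten), 1e-4, 0.01)


class TestDebye:
    def test_noiseless_self_recovery(self):
        q = np.linspace(0.01, 0.3, 100)
        curve = ScatteringCurve(q=q, intensity=debye_function(q, 25.0))
        res = debye_fit(curve)
        assert res.rg == pytest.approx(25.0, rel=1e-6)
        assert res.i0 == pytest.approx(1.0, rel=1e-6)

    def test_bead_chain_ensemble_oracle(self):
        """Ensemble-averaged Debye sum over a 1000-bead freely jointed
        chain is fit by the Debye function to within 2% of the ensemble
        coordinate Rg (brute-force pairwise sinc sum as the oracle)."""
        rng = np.random.default_rng(12)
        b, n, reps = 3.8, 1000, 60
        edges = np.arange(0, 2000.5, 0.5)
        hist = np.zeros(len(edges) - 1)
        rg2 = []
        for _ in range(reps):
            steps = rng.standard_normal((n, 3))
            steps *= b / np.linalg.norm(steps, axis=1, keepdims=True)
            pos = np.cumsum(steps, axis=0)
            rg2.append(np.mean(np.sum((pos - pos.mean(0)) ** 2, axis=1)))
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            hist += np.histogram(d[np.triu_indices(n, 1)], bins=edges)[0]
        rg_ref = float(np.sqrt(np.mean(rg2)))
        centers = 0.5 * (edges[:-1] + edges[1:])
        q = np.linspace(0.004, 0.08, 60)
        inten = (reps * n + 2 * (hist @ np.sinc(np.outer(centers, q) / np.pi))) \
            / (reps * n ** 2)
        res = debye_fit(ScatteringCurve(q=q, intensity=inten))
        assert res.rg == pytest.approx(rg_ref, rel=0.02)

    def test_scale_equivariance(self):
        """Multiplying intensities by k multiplies I(0) by k, Rg unchanged."""
        q = np.linspace(0.01, 0.25, 80)
        base = debye_function(q, 22.0) * 0.5
        r1 = debye_fit(ScatteringCurve(q=q, intensity=base))
        r2 = debye_fit(ScatteringCurve(q=q, intensity=1000.0 * base))
        assert r2.rg == pytest.approx(r1.rg, rel=1e-9)
        assert r2.i0 == pytest.approx(1000.0 * r1.i0, rel=1e-9)

    def test_too_few_points(self):
        q = np.linspace(0.01, 0.05, 5)
        with pytest.raises(ValueError, match=">= 10"):
            debye_fit(ScatteringCurve(q=q, intensity=np.ones(5)))


class TestKratky:
    def test_coil_classified_random_coil_with_analytic_plateau(self):
        """Kratky of a Gaussian coil rises monotonically onto the plateau
        2 I(0)/Rg^2 (analytic large-u limit of Q^2 D(Q))."""
        rg, i0 = 25.0, 0.078
        q = np.linspace(0.01, 0.45, 150)
        prof = kratky_transform(ScatteringCurve(q=q, intensity=i0 * debye_function(q, rg)))
        assert prof.classification == "random_coil"
        assert prof.bell_peak_q is None
        assert prof.plateau_level == pytest.approx(2 * i0 / rg ** 2, rel=0.05)

    def test_plateau_limit_at_large_qrg(self):
        """Q^2 I at Q Rg = 10 is within 1% of the analytic plateau."""
        rg, i0 = 25.0, 1.0
        q = np.array([10.0 / rg])
        y = q ** 2 * i0 * debye_function(q, rg)
        assert y[0] == pytest.approx(2 * i0 / rg ** 2, rel=0.01)

    def test_compact_globule_classified_folded(self):
        """Sphere form factor plus a flat incoherent floor shows the bell
        without a coil-like plateau."""
        q = np.linspace(0.01, 0.4, 120)
        inten = 0.156 * sphere_intensity(q, 18.0 / np.sqrt(0.6)) + 2e-4
        prof = kratky_transform(ScatteringCurve(q=q, intensity=inten))
        assert prof.classification == "folded"
        assert prof.bell_peak_q is not None and prof.bell_peak_q < 0.15

    def test_negative_intensities_do_not_fail(self):
        q = np.linspace(0.01, 0.4, 60)
        inten = np.linspace(1.0, -0.01, 60)
        prof = kratky_transform(ScatteringCurve(q=q, intensity=inten))
        assert prof.classification in ("folded", "random_coil",
                                       "partially_flexible")


class TestMwRatio:
    @pytest.mark.parametrize("i0,c,expected", [
        (0.165, 5.5, 2.1),   # folded-dimer condition
        (0.141, 5.3, 1.9),   # partially dissociated condition
        (0.088, 5.3, 1.2),   # open-bundle monomer condition
        (0.078, 5.5, 1.0),   # the standard against itself
    ])
    def test_printed_table_ratios(self, i0, c, expected):
        """I(0)/C ratios against the pD 1.7 standard round to the printed
        one-decimal molecular-weight ratios."""
        res = mw_ratio(i0, c, 0.078, 5.5)
        assert res.ratio_rounded == pytest.approx(expected)

    @given(a=st.floats(1e-6, 1e3), b=st.floats(1e-6, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_self_ratio_is_unity(self, a, b):
        assert mw_ratio(a, b, a, b).ratio == pytest.approx(1.0, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            mw_ratio(0.0, 5.5, 0.078, 5.5)


class TestAggregateFraction:
    def test_synthetic_mixture_recovered_within_factor_two(self):
        """A 0.2% number-fraction of 100 A particles added to a 25.5 A
        monomer is recovered within a factor of 2 from the low-Q excess."""
        spec = SyntheticSpec(
            "two_population",
            {"rg_monomer": 25.54, "rg_aggregate": 100.0,
             "i0_monomer": 0.088, "number_fraction": 0.002},
            q_grid=(0.005, 0.3, 150, "linear"), seed=4)
        curve, truth = generate_curve(spec)
        mono = guinier_fit(curve, 0.002, 0.004, enforce_qrg=False)
        est = aggregate_fraction(curve, mono, aggregate_rg=100.0)
        assert truth["number_fraction"] / 2 < est.fraction \
            < truth["number_fraction"] * 2

    def test_pure_monomer_gives_zero(self):
        q = np.linspace(0.005, 0.2, 100)
        inten = 0.08 * np.exp(-q ** 2 * 20 ** 2 / 3)
        curve = ScatteringCurve(q=q, intensity=inten)
        mono = guinier_fit(curve, 1e-4, 2e-3, enforce_qrg=False)
        est = aggregate_fraction(curve, mono, aggregate_rg=100.0)
        assert est.fraction == 0.0
        assert "no low-Q excess" in est.note
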
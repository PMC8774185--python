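import numpy as np
import pytest

from bundlesans import (ContrastModel, HelixDefinition, average_helix_metrics,
                        coordinate_rg, debye_sum_curve, helix_axis_length)
from bundlesans.atomistic import atom_contrasts
from bundlesans.synthetic import build_ideal_helix

from conftest import toy_model


@pytest.fixture
def random_points():
    rng = np.random.default_rng(0)
    return rng.uniform(0.0, 30.0, (50, 3))


class TestDebyeSum:
    def test_two_point_closed_form(self, contrast):
        """Two equal scatterers at separation d: I(Q)/I(0) = (1 + sinc(Qd))/2."""
        d = 10.0
        model = toy_model([[0, 0, 0], [0, 0, d]])
        q = np.linspace(0.01, 0.5, 60)
        tc = debye_sum_curve(model, contrast, q, method="direct")
        f = atom_contrasts(model, contrast)[0]
        expected = 2 * f ** 2 * (1 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(tc.intensity, expected, rtol=1e-10)

    def test_histogram_matches_direct(self, contrast, random_points):
        """Distance-histogram acceleration agrees with the brute-force
        double sum to 0.1% on 50 random points."""
        model = toy_model(random_points)
        q = np.linspace(0.01, 0.5, 60)
        a = debye_sum_curve(model, contrast, q, method="direct").intensity
        b = debye_sum_curve(model, contrast, q, method="histogram").intensity
        assert np.max(np.abs(a - b) / np.abs(a)) < 1e-3

    def test_rigid_motion_invariance(self, contrast, random_points):
        """Rotation + translation leaves the Debye sum unchanged."""
        from scipy.spatial.transform import Rotation
        q = np.linspace(0.01, 0.5, 40)
        a = debye_sum_curve(toy_model(random_points), contrast, q,
                            method="direct").intensity
        moved = random_points @ Rotation.random(random_state=1).as_matrix().T \
            + np.array([5.0, -3.0, 8.0])
        b = debye_sum_curve(toy_model(moved), contrast, q,
                            method="direct").intensity
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_dimer_forward_intensity_is_four_times_monomer(self, contrast,
                                                           random_points):
        """I(0) scales with (sum f)^2: two identical copies -> 4x."""
        q = np.array([1e-4, 1e-3])
        mono = toy_model(random_points)
        dim = toy_model(np.vstack([random_points,
                                   random_points + [100.0, 0.0, 0.0]]))
        i_m = debye_sum_curve(mono, contrast, q, method="direct").intensity[0]
        i_d = debye_sum_curve(dim, contrast, q, method="direct").intensity[0]
        assert i_d / i_m == pytest.approx(4.0, rel=1e-3)

    def test_empty_model_rejected(self, contrast):
        with pytest.raises(ValueError):
            debye_sum_curve(toy_model(np.empty((0, 3))), contrast, [0.01, 0.1])

    def test_exchange_fraction_changes_contrast(self):
        helix = build_ideal_helix(10)
        f_no = atom_contrasts(helix, ContrastModel(exchange_fraction=0.0))
        f_full = atom_contrasts(helix, ContrastModel(exchange_fraction=1.0))
        # deuterating labile H raises b of the backbone amide nitrogens
        n_mask = helix.atom_name == "N"
        assert np.all(f_full[n_mask] > f_no[n_mask])


class TestCoordinateRg:
    def test_unit_cube(self):
        cube = toy_model([[x, y, z] for x in (0, 1) for y in (0, 1)
                          for z in (0, 1)])
        assert coordinate_rg(cube) == pytest.approx(np.sqrt(3) / 2, rel=1e-12)

    def test_equal_contrast_weights_match_uniform(self, random_points):
        """All-carbon model: contrast weighting equals uniform weighting."""
        model = toy_model(random_points)
        assert coordinate_rg(model, "contrast") == \
            pytest.approx(coordinate_rg(model, "uniform"), rel=1e-9)

    def test_consistent_with_guinier_of_debye_sum(self, contrast):
        """Coordinate Rg (contrast weights) tracks the Guinier Rg of the
        model's own scattering curve within 1 A."""
        from bundlesans import ScatteringCurve, guinier_fit
        helix = build_ideal_helix(30)
        rg_c = coordinate_rg(helix, "contrast", contrast)
        q = np.linspace(0.005, 0.6 / rg_c, 60)
        tc = debye_sum_curve(helix, contrast, q, method="direct")
        g = guinier_fit(ScatteringCurve(q=q, intensity=tc.intensity),
                        q[0] ** 2, q[-1] ** 2, enforce_qrg=False)
        assert g.rg == pytest.approx(rg_c, abs=1.0)


class TestHelixGeometry:
    def test_ideal_helix_length(self):
        """20 residues at 1.5 A rise -> axis length 19 * 1.5 = 28.5 A."""
        helix = build_ideal_helix(20)
        hd = HelixDefinition("T", "A", 1, 20)
        assert helix_axis_length(helix, hd) == pytest.approx(28.5, abs=0.5)

    def test_ideal_helix_diameter_tracks_build_radius(self):
        helix = build_ideal_helix(20)
        hd = HelixDefinition("T", "A", 1, 20)
        _, diam = average_helix_metrics(helix, [hd])
        assert diam == pytest.approx(2 * 2.3, rel=0.15)

    def test_single_helix_identity(self):
        helix = build_ideal_helix(25)
        hd = HelixDefinition("T", "A", 1, 25)
        mean_len, _ = average_helix_metrics(helix, [hd])
        assert mean_len == pytest.approx(helix_axis_length(helix, hd))

    def test_mean_over_two_helices(self):
        import numpy as np
        from bundlesans.sas_io import AtomicModel
        h1 = build_ideal_helix(20)
        h2 = build_ideal_helix(30, first_res=101,
                               axis_origin=(30.0, 0.0, 0.0))
        merged = AtomicModel(
            element=np.concatenate([h1.element, h2.element]),
            atom_name=np.concatenate([h1.atom_name, h2.atom_name]),
            res_name=np.concatenate([h1.res_name, h2.res_name]),
            res_seq=np.concatenate([h1.res_seq, h2.res_seq]),
            chain_id=np.concatenate([h1.chain_id, h2.chain_id]),
            coords=np.vstack([h1.coords, h2.coords]))
        defs = [HelixDefinition("1", "A", 1, 20),
                HelixDefinition("2", "A", 101, 130)]
        mean_len, _ = average_helix_metrics(merged, defs)
        expect = 0.5 * (19 * 1.5 + 29 * 1.5)
        assert mean_len == pytest.approx(expect, abs=0.7)

    def test_degenerate_range_errors(self):
        helix = build_ideal_helix(20)
        with pytest.raises(ValueError, match="C-alpha"):
            helix_axis_length(helix, HelixDefinition("T", "A", 1, 2))
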
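"""Shape-based alignment tensors and RDC prediction."""

import numpy as np
import pytest

import ensemblefit as ef
from ensemblefit import fixtures as fx
from ensemblefit.errors import GeometryError
from ensemblefit.rdc import (
    alignment_tensors,
    predict_rdc,
    rdc_effective_error,
    steric_alignment_tensor,
)


def fibonacci_sphere(n, radius=5.0):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=-1,
    )


class TestAlignmentTensor:
    def test_traceless(self, strepto_template, truth_model):
        X = ef.sample_ensemble(truth_model, strepto_template, n=5, seed=0).coords
        radii = np.ones(X.shape[1])
        S = alignment_tensors(X, radii=radii, normalize=True)
        assert np.abs(np.trace(S, axis1=1, axis2=2)).max() < 1e-10
        assert np.abs(S - S.transpose(0, 2, 1)).max() < 1e-12

    def test_spherical_point_set_is_isotropic(self):
        pts = fibonacci_sphere(500)
        S = alignment_tensors(pts[None], radii=np.full(500, 0.3), normalize=False)[0]
        assert np.linalg.norm(S) < 1e-2

    def test_prolate_rod_axially_symmetric(self):
        # oracle: gyration tensor of a rod of spheres along z
        z = np.linspace(-6, 6, 13)
        pts = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=-1)
        S = alignment_tensors(pts[None], radii=np.full(13, 1.5), normalize=True)[0]
        w, V = np.linalg.eigh(S)
        # two equal (degenerate) eigenvalues within 5%, unique axis along z
        assert abs(w[0] - w[1]) < 0.05 * abs(w[2])
        axis = V[:, 2]
        assert abs(axis[2]) > 0.999

    def test_collinear_geometry_guard(self):
        with pytest.raises(GeometryError):
            alignment_tensors(np.zeros((1, 3, 3)), radii=np.ones(3))


class TestPredictRDC:
    def test_linear_in_scale(self, strepto_template, truth_model):
        X = ef.sample_ensemble(truth_model, strepto_template, n=10, seed=1).coords
        elements = [a.element for a in strepto_template.atoms]
        T = alignment_tensors(X, elements=elements)
        ci = np.array([strepto_template.index("S1_C1")])
        hi = np.array([strepto_template.index("S1_H1")])
        d1 = predict_rdc(X, T, ci, hi, scale=1.0)
        d2 = predict_rdc(X, T, ci, hi, scale=2.0)
        assert np.allclose(d2, 2 * d1)

    def test_magic_angle_zero(self):
        # axially symmetric tensor, bond at the magic angle -> D = 0
        lam = np.diag([-0.5, -0.5, 1.0]) / np.linalg.norm(np.diag([-0.5, -0.5, 1.0]))
        theta = np.arccos(1 / np.sqrt(3))
        b = np.array([np.sin(theta), 0.0, np.cos(theta)])
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = b
        d = predict_rdc(coords, lam[None], np.array([0]), np.array([1]), scale=7.3)
        assert abs(d[0]) < 1e-9

    def test_two_conformer_average(self, strepto_template, truth_model):
        ens = ef.sample_ensemble(truth_model, strepto_template, n=2, seed=2)
        X = ens.coords
        elements = [a.element for a in strepto_template.atoms]
        T = alignment_tensors(X, elements=elements)
        ci = np.array([strepto_template.index("G3_C1")])
        hi = np.array([strepto_template.index("G3_H1")])
        both = predict_rdc(X, T, ci, hi)
        single = [
            predict_rdc(X[k : k + 1], T[k : k + 1], ci, hi)[0] for k in range(2)
        ]
        assert both[0] == pytest.approx(np.mean(single), abs=1e-12)

    def test_rigid_body_rotation_invariance(self, strepto_template, truth_model, rng):
        X = ef.sample_ensemble(truth_model, strepto_template, n=4, seed=3).coords
        elements = [a.element for a in strepto_template.atoms]
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        Xr = X @ Q.T
        ci = np.array([strepto_template.index(c) for c in ("S1_C1", "G3_C3")])
        hi = np.array([strepto_template.index(h) for h in ("S1_H1", "G3_H3")])
        d = predict_rdc(X, alignment_tensors(X, elements=elements), ci, hi)
        dr = predict_rdc(Xr, alignment_tensors(Xr, elements=elements), ci, hi)
        assert np.allclose(d, dr, atol=1e-9)

    def test_single_conformer_wrapper(self, strepto_template, table_mean_torsions):
        c = ef.build_conformer(strepto_template, table_mean_torsions)
        at = steric_alignment_tensor(c, medium_id="gel")
        assert abs(np.trace(at.S)) < 1e-10
        assert np.linalg.norm(at.S) == pytest.approx(1.0, abs=1e-9)


class TestEffectiveError:
    def test_zero_fraction_identity(self):
        assert rdc_effective_error(1.5, 10.0, model_fraction=0.0) == pytest.approx(1.5)

    def test_three_four_five(self):
        assert rdc_effective_error(1.5, 20.0, model_fraction=0.1) == pytest.approx(2.5)

    def test_never_below_base_error(self, rng):
        for _ in range(50):
            e = rng.uniform(0.1, 3)
            d = rng.uniform(0, 50)
            assert rdc_effective_error(e, d) >= e


class TestClosure:
    def test_generated_rdcs_exactly_refit_scale(self, strepto_template, truth_model):
        """RDCs simulated at a known scale are refit to that scale."""
        from ensemblefit.forward import Predictor

        rs, manifest = fx.simulate_restraints(
            strepto_template, truth_model,
            noise=fx.NoiseSpec(noe_fraction=0, j_sigma=0, rdc_sigma=1e-12, seed=5),
            rdc_scales={"gel": 21.0},
            ensemble_size=400,
        )
        rs.noes = []
        rs.jcouplings = []
        pred = Predictor(strepto_template, rs, rdc_model_fraction=0.0)
        ens = ef.sample_ensemble(truth_model, strepto_template, n=400, seed=5)
        ev = pred.evaluate(ens.coords, tau_c=1.5e-9)
        assert ev.rdc_scales["gel"] == pytest.approx(21.0, rel=1e-6)
        assert ev.chi2_total < 1e-10
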
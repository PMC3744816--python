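"""Relaxation-matrix NOESY prediction against analytic and series oracles."""

import numpy as np
import pytest

import ensemblefit as ef
from ensemblefit import fixtures as fx
from ensemblefit.errors import SingularityError, ValidationError
from ensemblefit.noe import (
    DIPOLAR_CONSTANT,
    SpinSystem,
    cross_relaxation_rate,
    ensemble_r6,
    predict_noesy,
    relaxation_matrix,
)


def two_spin_system():
    t = fx.butane_template()
    return SpinSystem.from_template(t)  # H1, H4


def coords_with_r(r):
    """One conformer with the two butane protons exactly r apart."""
    X = np.zeros((1, 6, 3))
    X[0, 0] = [10, 0, 0]
    X[0, 1] = [20, 0, 0]
    X[0, 2] = [30, 0, 0]
    X[0, 3] = [40, 0, 0]
    X[0, 4] = [0, 0, 0]  # H1
    X[0, 5] = [r, 0, 0]  # H4
    return X


class TestEnsembleR6:
    def test_single_conformer_r3(self):
        s = two_spin_system()
        S = ensemble_r6(coords_with_r(3.0), s)
        assert S[0, 1] == pytest.approx(3.0**-6, rel=1e-12)

    def test_two_conformer_average(self):
        s = two_spin_system()
        X = np.concatenate([coords_with_r(2.0), coords_with_r(4.0)])
        S = ensemble_r6(X, s)
        want = 0.5 * (2.0**-6 + 4.0**-6)
        assert S[0, 1] == pytest.approx(want, rel=1e-12)
        assert (S[0, 1]) ** (-1 / 6) == pytest.approx(2.2391, abs=5e-4)

    def test_conformer_order_irrelevant(self, strepto_template, truth_model):
        spins = SpinSystem.from_template(strepto_template)
        ens = ef.sample_ensemble(truth_model, strepto_template, n=20, seed=0)
        X = ens.coords
        a = ensemble_r6(X, spins)
        b = ensemble_r6(X[::-1], spins)
        assert np.allclose(a, b, rtol=1e-12)

    def test_symmetric(self, strepto_template, truth_model):
        spins = SpinSystem.from_template(strepto_template)
        X = ef.sample_ensemble(truth_model, strepto_template, n=10, seed=1).coords
        S = ensemble_r6(X, spins)
        assert np.allclose(S, S.T)

    def test_coincident_protons_raise(self):
        s = two_spin_system()
        with pytest.raises(SingularityError):
            ensemble_r6(coords_with_r(1e-6), s)

    def test_jensen_direction(self):
        # <r^-6> of a 2-conformer ensemble >= r^-6 at the mean distance
        s = two_spin_system()
        X = np.concatenate([coords_with_r(2.0), coords_with_r(4.0)])
        S = ensemble_r6(X, s)
        assert S[0, 1] >= 3.0**-6


class TestRelaxationMatrix:
    def test_sigma_sign_crossover(self):
        # sigma > 0 for w*tau << 1, < 0 for >> 1, zero at w*tau = sqrt(5)/2
        r6 = 2.5**-6
        f = 600.0
        w = 2 * np.pi * f * 1e6
        assert cross_relaxation_rate(r6, 1e-12, f) > 0
        assert cross_relaxation_rate(r6, 1e-8, f) < 0
        tau0 = np.sqrt(5) / 2 / w
        assert abs(cross_relaxation_rate(r6, tau0, f)) < 1e-10 * abs(
            cross_relaxation_rate(r6, 1e-9, f)
        )

    def test_rates_linear_in_r6(self):
        R1 = relaxation_matrix(np.array([[0.0, 1e-3], [1e-3, 0.0]]), 1e-9, 600.0)
        R2 = relaxation_matrix(np.array([[0.0, 2e-3], [2e-3, 0.0]]), 1e-9, 600.0)
        assert np.allclose(R2.R, 2 * R1.R)

    def test_two_spin_sigma_matches_textbook_formula(self):
        # independent oracle: sigma = (mu0/4pi)^2 hbar^2 g^4 /(10 r^6)
        #                             * (6 J(2w) - J(0))
        r = 2.2
        tau = 0.8e-9
        f = 900.0
        w = 2 * np.pi * f * 1e6
        g = 2.6752218744e8
        hbar = 1.054571817e-34
        q = (1e-7 * hbar * g**2) ** 2 / (r * 1e-10) ** 6 / 10.0
        want = q * (6 * tau / (1 + (2 * w * tau) ** 2) - tau)
        got = cross_relaxation_rate(r**-6, tau, f)
        assert got == pytest.approx(want, rel=1e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValidationError):
            relaxation_matrix(np.eye(2) * 1e-3, -1e-9, 600.0)


class TestPredictNoesy:
    def test_zero_mixing_time_identity(self):
        R = relaxation_matrix(np.array([[0.0, 1e-3], [1e-3, 0.0]]), 1e-9, 600.0)
        H = predict_noesy(R, 0.0)
        assert np.allclose(H, np.eye(2), atol=1e-14)

    def test_short_time_ratio_follows_r6(self):
        s = two_spin_system()
        tau_m = 1e-4
        heights = {}
        for r in (2.0, 2.5):
            S = ensemble_r6(coords_with_r(r), s)
            R = relaxation_matrix(S, 1e-9, 600.0)
            heights[r] = abs(predict_noesy(R, tau_m)[0, 1])
        assert heights[2.0] / heights[2.5] == pytest.approx((2.5 / 2.0) ** 6, rel=1e-2)

    def test_ispa_limit_matches_sigma(self):
        # cross peak / tau_m -> -sigma as tau_m -> 0 (within 1% at 1 ms)
        s = two_spin_system()
        S = ensemble_r6(coords_with_r(2.5), s)
        tau_c, f = 1.5e-9, 600.0
        R = relaxation_matrix(S, tau_c, f)
        sigma = cross_relaxation_rate(S[0, 1], tau_c, f)
        tau_m = 1e-3
        H = predict_noesy(R, tau_m)
        assert H[0, 1] / tau_m == pytest.approx(-sigma, rel=1e-2)

    def test_four_spin_matches_taylor_series(self, strepto_template, truth_model):
        # oracle: truncated Taylor expansion of exp(-R tau)
        spins = SpinSystem.from_template(strepto_template)
        X = ef.sample_ensemble(truth_model, strepto_template, n=5, seed=2).coords
        S = ensemble_r6(X, spins)
        # use a 4-spin sub-block to keep the series well-conditioned
        sub = S[:4, :4].copy()
        R = relaxation_matrix(sub, 1.0e-9, 600.0)
        tau_m = 0.3
        H = predict_noesy(R, tau_m)
        A = -R.sym * tau_m
        series = np.eye(4)
        term = np.eye(4)
        for k in range(1, 40):
            term = term @ A / k
            series = series + term
        assert np.abs(H - series).max() < 1e-8

    def test_detailed_balance_symmetry(self, strepto_template, truth_model):
        spins = SpinSystem.from_template(strepto_template)
        X = ef.sample_ensemble(truth_model, strepto_template, n=10, seed=3).coords
        S = ensemble_r6(X, spins)
        R = relaxation_matrix(S, 1.5e-9, 900.0, multiplicity=spins.multiplicity)
        H = predict_noesy(R, 0.7)
        assert np.abs(H - H.T).max() < 1e-10


class TestSpinSystem:
    def test_equivalence_groups_collapse(self, strepto_template):
        spins = SpinSystem.from_template(strepto_template)
        assert "R2_Me" in spins.names
        k = spins.spin_of("R2_Me")
        assert spins.multiplicity[k] == 3
        # member atoms resolve to the group's spin
        assert spins.spin_of("R2_H51") == k

    def test_every_proton_maps_to_one_spin(self, strepto_template):
        spins = SpinSystem.from_template(strepto_template)
        n_h = sum(1 for a in strepto_template.atoms if a.element == "H")
        assert sum(spins.multiplicity) == n_h
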
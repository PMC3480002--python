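"""Finite-strain kinematics, passive stress and the diffusion tensor."""

import numpy as np
import pytest

import cardioem as cm
from cardioem.errors import InvertedElementError

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])


def rand_rotation(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


class TestKinematics:
    def test_reference_state(self):
        kin = cm.compute_kinematics(np.eye(3), EX)
        assert kin.stretch == pytest.approx(1.0)
        assert kin.delta == 0.0
        assert kin.A == pytest.approx(1.0)
        assert kin.B == pytest.approx(1.0)
        assert np.allclose(kin.kappa, kin.kappa0)

    def test_uniaxial_fiber_stretch(self):
        F = np.diag([1.2, 1.0, 1.0])
        kin = cm.compute_kinematics(F, EX)
        assert kin.stretch == pytest.approx(1.2)
        assert kin.delta == 1.0
        assert kin.B == pytest.approx(1.44)
        assert kin.A == pytest.approx(1.44)

    def test_isotropic_scaling_determinant(self):
        c = 1.07
        kin = cm.compute_kinematics(c * np.eye(3), EY)
        assert kin.A == pytest.approx(c ** 6, rel=1e-12)

    def test_kappa_is_pushforward(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            F = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            a0 = rng.normal(size=3)
            a0 /= np.linalg.norm(a0)
            kin = cm.compute_kinematics(F, a0)
            assert np.allclose(kin.kappa, F @ kin.kappa0 @ F.T, atol=1e-13)
            assert kin.B == pytest.approx(kin.stretch ** 2, rel=1e-13)
            assert kin.A == pytest.approx(np.linalg.det(F) ** 2, rel=1e-12)

    def test_objectivity_under_rotation(self):
        rng = np.random.default_rng(5)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        Q = rand_rotation(rng)
        k1 = cm.compute_kinematics(F, EY)
        k2 = cm.compute_kinematics(Q @ F, EY)
        assert k2.stretch == pytest.approx(k1.stretch, rel=1e-12)
        assert k2.delta == k1.delta
        assert k2.A == pytest.approx(k1.A, rel=1e-12)
        assert k2.B == pytest.approx(k1.B, rel=1e-12)
        assert np.allclose(k2.kappa, Q @ k1.kappa @ Q.T, atol=1e-12)

    def test_inverted_deformation_rejected(self):
        with pytest.raises(InvertedElementError):
            cm.compute_kinematics(np.diag([-1.0, 1.0, 1.0]), EX)

    def test_non_unit_fiber_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            cm.compute_kinematics(np.eye(3), np.array([1.0, 1.0, 0.0]))


class TestPassiveStress:
    def test_stress_free_reference(self):
        kin = cm.compute_kinematics(np.eye(3), EY)
        sig = cm.passive_stress(kin, cm.MaterialParams())
        assert np.all(sig == 0.0)

    def test_small_volumetric_strain_linearization(self):
        # (1+e)I gives sigma ~ (3 chi + 2 zeta) e I to first order in the
        # isotropic part; for e > 0 the fiber engages (|a| > 1) and adds
        # 4 xi e along the fiber, for e < 0 it stays disengaged
        m = cm.MaterialParams()
        iso = lambda e: (3 * m.chi + 2 * m.zeta) * e
        e = -1e-6
        sig = cm.passive_stress(cm.compute_kinematics((1 + e) * np.eye(3), EY), m)
        assert np.allclose(np.diag(sig), iso(e), rtol=1e-4)
        assert abs(sig[0, 1]) < 1e-15
        e = 1e-6
        sig = cm.passive_stress(cm.compute_kinematics((1 + e) * np.eye(3), EY), m)
        assert sig[0, 0] == pytest.approx(iso(e), rel=1e-4)
        assert sig[1, 1] == pytest.approx(iso(e) + 4 * m.xi * e, rel=1e-4)

    def test_fiber_reinforcement_term(self):
        # F = diag(1.2, 1, 1), a0 = e_x: the fiber term adds
        # 2 xi (B-1) B = 2 * 0.1 * 0.44 * 1.44 = 0.12672 MPa to sigma_xx
        m = cm.MaterialParams()
        kin = cm.compute_kinematics(np.diag([1.2, 1.0, 1.0]), EX)
        sig = cm.passive_stress(kin, m)
        iso = 0.5 * m.chi * np.log(1.44) - m.zeta
        assert sig[0, 0] == pytest.approx(iso + m.zeta * 1.44 + 0.12672, rel=1e-12)
        assert sig[1, 1] == pytest.approx(iso + m.zeta, rel=1e-12)

    def test_symmetry_for_random_deformations(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            F = np.eye(3) + 0.15 * rng.normal(size=(3, 3))
            if np.linalg.det(F) <= 0.2:
                continue
            kin = cm.compute_kinematics(F, EY)
            sig = cm.passive_stress(kin, cm.MaterialParams())
            assert np.allclose(sig, sig.T, atol=1e-13)

    def test_matches_energy_finite_differences(self):
        """Oracle: the stress must be the push-forward of the gradient of the
        compressible fiber-reinforced strain energy

            W = chi/2 (ln J)^2 - zeta ln J + zeta/2 (tr(F F^T) - 3)
                + [B > 1] xi/2 (B - 1)^2,

        i.e. tau = (dW/dF) F^T, evaluated here by central differences."""
        m = cm.MaterialParams()

        def energy(F, a0):
            J = np.linalg.det(F)
            W = 0.5 * m.chi * np.log(J) ** 2 - m.zeta * np.log(J) \
                + 0.5 * m.zeta * (np.trace(F @ F.T) - 3.0)
            B = a0 @ (F.T @ F) @ a0
            if B > 1.0:
                W += 0.5 * m.xi * (B - 1.0) ** 2
            return W

        rng = np.random.default_rng(42)
        h = 1e-7
        checked = 0
        while checked < 100:
            F = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
            a0 = rng.normal(size=3)
            a0 /= np.linalg.norm(a0)
            B = a0 @ (F.T @ F) @ a0
            if np.linalg.det(F) <= 0.5 or abs(B - 1.0) < 1e-3:
                continue  # avoid the non-smooth fiber-engagement point
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (energy(Fp, a0) - energy(Fm, a0)) / (2 * h)
            tau_fd = P @ F.T
            sig = cm.passive_stress(cm.compute_kinematics(F, a0), m)
            assert np.allclose(sig, tau_fd, atol=1e-6)
            checked += 1


class TestDiffusionTensor:
    def test_reference_values_along_fiber(self):
        kin = cm.compute_kinematics(np.eye(3), EY)
        D = cm.diffusion_tensor(kin, cm.MaterialParams())
        assert np.allclose(D, np.diag([0.001, 0.0011, 0.001]), atol=1e-15)

    def test_scar_kills_conduction(self):
        kin = cm.compute_kinematics(np.diag([1.3, 0.9, 1.0]), EY)
        D = cm.diffusion_tensor(kin, cm.MaterialParams(), is_scar=True)
        assert np.all(D == 0.0)

    def test_stretch_raises_fiber_conductivity(self):
        kin = cm.compute_kinematics(np.diag([1.0, 1.2, 1.0]), EY)
        D = cm.diffusion_tensor(kin, cm.MaterialParams())
        assert D[1, 1] == pytest.approx(0.001 + 0.0001 * 1.44, rel=1e-12)

    def test_symmetric_positive_definite(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            F = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
            if np.linalg.det(F) <= 0.2:
                continue
            kin = cm.compute_kinematics(F, EY)
            D = cm.diffusion_tensor(kin, cm.MaterialParams())
            assert np.allclose(D, D.T)
            assert np.linalg.eigvalsh(D).min() > 0
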
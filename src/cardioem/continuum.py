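"""Finite-strain kinematics and constitutive laws for myocardial tissue.

Given the total deformation gradient F = dx/dX (accumulated from the original
configuration) and a unit reference fiber direction a0, this module computes:

* the deformed fiber vector a = F a0, the fiber stretch |a|, and the
  engagement switch delta = 1 iff |a| > 1;
* the left Cauchy-Green tensor p = F F^T, the invariants A = det(F^T F) and
  B = a0 . (F^T F) a0 = |a|^2 (fourth pseudo-invariant), and the structural
  tensors kappa0 = a0 (x) a0 and kappa = a (x) a = F kappa0 F^T;
* the passive Kirchhoff stress of a fiber-reinforced compressible
  neo-Hookean solid,

      sigma_pass = (chi/2 * ln A - zeta) I + zeta p + 2 delta xi (B - 1) kappa,

  which is identically zero in the reference configuration (tension-only
  fiber reinforcement: the fiber term engages only for |a| > 1);
* the deformation-dependent diffusion tensor of the monodomain equation,

      D = d_iso I + d_ani kappa,

  which stiffens conduction along the *deformed* fiber direction and is set
  to zero inside scar tissue (scar conducts no excitation).

All operations accept batched inputs: F of shape (..., 3, 3) and a0 of shape
(..., 3) broadcast over the leading axes, which is how the FEM assembly
evaluates them at every quadrature point of every element at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvertedElementError

_EYE = np.eye(3)


@dataclass
class MaterialParams:
    chi: float = 0.5        # Lame-type modulus, MPa
    zeta: float = 0.2       # Lame-type modulus, MPa
    xi: float = 0.1         # passive fiber stiffness, MPa
    d_iso: float = 0.001    # isotropic conductivity, cm^2/ms
    d_ani: float = 0.0001   # additional fiber-direction conductivity, cm^2/ms

    def validate(self):
        errs = []
        if self.chi < 0 or self.zeta < 0:
            errs.append(f"material.chi/zeta must be >= 0, got {self.chi}, {self.zeta}")
        if self.xi < 0:
            errs.append(f"material.xi must be >= 0, got {self.xi}")
        if not self.d_iso > 0:
            errs.append(f"material.d_iso must be > 0, got {self.d_iso}")
        if self.d_ani < 0:
            errs.append(f"material.d_ani must be >= 0, got {self.d_ani}")
        return errs


@dataclass
class Kinematics:
    """Per-point deformation quantities (all fields batched alike)."""

    F: np.ndarray        # deformation gradient, (..., 3, 3)
    p: np.ndarray        # left Cauchy-Green tensor F F^T
    a: np.ndarray        # deformed fiber vector, (..., 3)
    stretch: np.ndarray  # |a|
    delta: np.ndarray    # 1.0 where |a| > 1, else 0.0
    A: np.ndarray        # det(F^T F) = (det F)^2
    B: np.ndarray        # fourth pseudo-invariant a0.(F^T F) a0 = |a|^2
    kappa: np.ndarray    # deformed structural tensor a (x) a
    kappa0: np.ndarray   # reference structural tensor a0 (x) a0


def compute_kinematics(F, a0, element_ids=None) -> Kinematics:
    """Derive all kinematic quantities from F and the unit fiber a0.

    Raises :class:`InvertedElementError` if det F <= 0 anywhere; when
    ``element_ids`` is given the offending element ids are named.
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    norm0 = np.linalg.norm(a0, axis=-1)
    if np.any(np.abs(norm0 - 1.0) > 1e-10):
        raise ValueError("a0 must be a unit vector (|a0| = 1 within 1e-10)")
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        bad = np.argwhere(np.atleast_1d(detF) <= 0)
        if element_ids is not None:
            # leading batch axis indexes elements
            ids = np.asarray(element_ids).reshape(-1)
            bad_el = sorted({int(ids[i[0]]) for i in bad})
            raise InvertedElementError(
                f"inverted element(s) {bad_el[:10]}: det F <= 0; "
                "consider reducing dt_pde")
        raise InvertedElementError(
            f"det F <= 0 at batch indices {bad[:10].tolist()}")
    a = np.einsum("...ij,...j->...i", F, a0)
    B = np.einsum("...i,...i->...", a, a)
    stretch = np.sqrt(B)
    delta = (stretch > 1.0).astype(float)
    kappa = np.einsum("...i,...j->...ij", a, a)
    kappa0 = np.einsum("...i,...j->...ij", a0, a0)
    p = np.einsum("...ik,...jk->...ij", F, F)
    return Kinematics(F=F, p=p, a=a, stretch=stretch, delta=delta,
                      A=detF ** 2, B=B, kappa=kappa, kappa0=kappa0)


def passive_stress(kin: Kinematics, params: MaterialParams) -> np.ndarray:
    """Passive Kirchhoff stress (MPa), symmetric, zero at F = I."""
    iso = (0.5 * params.chi * np.log(kin.A) - params.zeta)
    fib = 2.0 * params.xi * kin.delta * (kin.B - 1.0)
    return (np.asarray(iso)[..., None, None] * _EYE
            + params.zeta * kin.p
            + np.asarray(fib)[..., None, None] * kin.kappa)


def diffusion_tensor(kin: Kinematics, params: MaterialParams,
                     is_scar=False) -> np.ndarray:
    """Monodomain conductivity D = d_iso I + d_ani kappa (cm^2/ms).

    kappa is the deformed structural tensor, so conduction follows the fibers
    as the tissue reshapes.  Scar tissue conducts nothing: D = 0 there.
    """
    D = params.d_iso * np.broadcast_to(_EYE, kin.kappa.shape).copy() \
        + params.d_ani * kin.kappa
    is_scar = np.asarray(is_scar)
    if is_scar.ndim:
        D = np.where(is_scar[..., None, None], 0.0, D)
    elif is_scar:
        D = np.zeros_like(D)
    return D
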
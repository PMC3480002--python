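"""Hexahedral mesh container with reference and current configurations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hex8
from .errors import InvertedElementError, WellPosednessError


@dataclass
class Mesh:
    """Reference/current nodal coordinates, connectivity, fibers and node sets.

    Coordinates are in cm.  ``a0_field`` holds one unit fiber vector per
    element (fibers and material are homogeneous per element).  Nodes in
    ``fixed_nodes`` have all three displacement components pinned (the
    essential boundary; the remaining surface is traction-free and no-flux);
    ``fixed_dofs`` lists additional single-component pins as (node, component)
    pairs — used e.g. to suppress out-of-plane motion of the thin tissue.
    """

    X_ref: np.ndarray                    # (n_nodes, 3)
    hexes: np.ndarray                    # (n_elems, 8) int
    a0_field: np.ndarray                 # (n_elems, 3) unit vectors
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    scar_elements: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    fixed_dofs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    x_cur: np.ndarray = None

    def __post_init__(self):
        self.X_ref = np.asarray(self.X_ref, dtype=float)
        self.hexes = np.asarray(self.hexes, dtype=np.int64)
        self.a0_field = np.asarray(self.a0_field, dtype=float)
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.scar_elements = np.asarray(self.scar_elements, dtype=np.int64)
        self.fixed_dofs = np.asarray(self.fixed_dofs, dtype=np.int64).reshape(-1, 2)
        if self.x_cur is None:
            self.x_cur = self.X_ref.copy()
        else:
            self.x_cur = np.asarray(self.x_cur, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.X_ref.shape[0]

    @property
    def n_elems(self) -> int:
        return self.hexes.shape[0]

    def reference_jacobians(self):
        """Jacobian dX/dxi at every Gauss point: (detJ (E, G), dN/dX (E, G, 8, 3))."""
        Xe = self.X_ref[self.hexes]                      # (E, 8, 3)
        J = np.einsum("eai,gaj->egij", Xe, hex8.DN_GP)   # J_ij = dX_i/dxi_j
        detJ = np.linalg.det(J)
        Jinv = np.linalg.inv(J)
        dNdX = np.einsum("gaj,egji->egai", hex8.DN_GP, Jinv)
        return detJ, dNdX

    def check(self):
        """Validate element orientation and fiber normalization."""
        detJ, _ = self.reference_jacobians()
        if np.any(detJ <= 0):
            bad = sorted(set(np.argwhere(detJ <= 0)[:, 0].tolist()))
            raise InvertedElementError(
                f"non-positive reference Jacobian in element(s) {bad[:10]}")
        norms = np.linalg.norm(self.a0_field, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("fiber field must be unit-norm per element")
        return self

    def require_fixed_nodes(self):
        if self.fixed_nodes.size == 0:
            raise WellPosednessError(
                "mechanics enabled but no fixed nodes: the stiffness operator "
                "has a rigid-body null space")

    def scar_element_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_elems, dtype=bool)
        mask[self.scar_elements] = True
        return mask

    def scar_node_mask(self) -> np.ndarray:
        """Nodes all of whose incident elements are scar (held at rest)."""
        emask = self.scar_element_mask()
        touched = np.zeros(self.n_nodes, dtype=bool)
        touched[np.unique(self.hexes[~emask])] = True
        in_scar = np.zeros(self.n_nodes, dtype=bool)
        if emask.any():
            in_scar[np.unique(self.hexes[emask])] = True
        return in_scar & ~touched

    def node_near(self, point) -> int:
        """Index of the reference node closest to ``point``."""
        d = np.linalg.norm(self.X_ref - np.asarray(point, dtype=float), axis=1)
        return int(np.argmin(d))

    def displacement(self) -> np.ndarray:
        """Total displacement from the original configuration (cm)."""
        return self.x_cur - self.X_ref
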
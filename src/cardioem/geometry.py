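"""Mesh and fiber-field generators: tissue slab and idealized half-ellipsoid ventricle.

Two geometries cover the simulated experiments:

* ``slab`` — a thin rectangular tissue (default 0.4 x 0.4 x 0.001 cm), one
  element through the thickness, centered in x and y so that the probe corner
  sits at (-Lx/2, -Ly/2).  Fibers are a uniform vector (default vertical,
  e_y); the top-left and bottom-right corner node columns are pinned.

* ``ellipsoid_ventricle`` — a structured hexahedral shell of a truncated
  half-ellipsoid (base open at z = 0, truncated slightly above the apex so
  every hex keeps a positive Jacobian).  Per-element fibers are
  circumferential: exactly orthogonal to the radial direction toward the
  geometric center, so the fiber *normals* point centerward and the fibers
  form layered sheets.  Within a small angle of the apex axis the
  circumferential rule degenerates and a fixed tangent fallback is used.
  Base-plane nodes are pinned; an optional spherical scar region flags
  full-wall-thickness elements.

All generators are deterministic: identical specs produce bit-identical
meshes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .mesh import Mesh


@dataclass
class StimulusSpec:
    """Where and when the external stimulus is applied.

    ``kind='ball'`` selects nodes within ``radius`` of ``center``;
    ``kind='box'`` selects nodes with max(|x - cx|, |y - cy|) <= radius (an
    in-plane square patch, exactly representable on every commensurate grid,
    which keeps the stimulated region identical across mesh refinements);
    ``kind='base_patch'`` (ventricle) selects nodes within ``radius`` below
    the base plane z = 0 (the superior section).
    """

    kind: str = "ball"
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0005)
    radius: float = 0.05
    onset: float = 0.0

    def validate(self):
        errs = []
        if self.kind not in ("ball", "box", "base_patch"):
            errs.append(
                f"stimulus.kind must be 'ball', 'box' or 'base_patch', got {self.kind!r}")
        if not self.radius > 0:
            errs.append(f"stimulus.radius must be > 0, got {self.radius}")
        if self.onset < 0:
            errs.append(f"stimulus.onset must be >= 0, got {self.onset}")
        return errs


@dataclass
class ScarSpec:
    center: Optional[Tuple[float, float, float]] = None  # None: outer-wall mid-height
    radius: float = 1.0

    def validate(self):
        return [] if self.radius > 0 else [f"scar.radius must be > 0, got {self.radius}"]


@dataclass
class GeometrySpec:
    kind: str = "slab"                      # "slab" | "ellipsoid_ventricle"
    dimensions: Tuple[float, ...] = (0.4, 0.4, 0.001)  # slab (Lx,Ly,Lz) or ellipsoid radii (cm)
    mesh_size: float = 0.01                 # target edge length, cm
    fiber_rule: str = "uniform_vector"      # "uniform_vector" | "circumferential"
    fiber_vector: Tuple[float, float, float] = (0.0, 1.0, 0.0)
    wall_thickness: float = 0.8             # ventricle wall, cm
    apex_gap: float = 0.25                  # ventricle apex truncation angle, rad
    apex_axis_angle: float = 5.0            # deg; fiber fallback cone about the apex axis
    scar: Optional[ScarSpec] = None
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    pinned: str = "corners"                 # slab: "corners"|"none"; ventricle: "base"|"none"

    def validate(self):
        errs = []
        if self.kind not in ("slab", "ellipsoid_ventricle"):
            errs.append(f"geometry.kind must be 'slab' or 'ellipsoid_ventricle', got {self.kind!r}")
        if not self.mesh_size > 0:
            errs.append(f"geometry.mesh_size must be > 0, got {self.mesh_size}")
        if len(self.dimensions) != 3 or any(d <= 0 for d in self.dimensions):
            errs.append(f"geometry.dimensions must be 3 positive lengths, got {self.dimensions}")
        if self.fiber_rule not in ("uniform_vector", "circumferential"):
            errs.append(f"geometry.fiber_rule unknown: {self.fiber_rule!r}")
        if self.scar is not None:
            errs.extend(self.scar.validate())
            if self.kind == "ellipsoid_ventricle" and self.scar.radius >= min(self.dimensions):
                errs.append("scar.radius must be smaller than the smallest geometric radius")
        errs.extend(self.stimulus.validate())
        return errs


def _edge_count(length, h, label):
    n = length / h
    n_round = max(1, int(round(n)))
    if abs(n - n_round) > 1e-9 * max(1.0, n):
        warnings.warn(
            f"mesh_size {h} does not divide {label}={length}; "
            f"using {n_round} elements", stacklevel=3)
    return n_round


def make_slab(spec: GeometrySpec) -> Mesh:
    """Regular hex grid slab, one element through the thickness (z)."""
    if spec.kind != "slab":
        raise ValueError("make_slab requires kind='slab'")
    Lx, Ly, Lz = spec.dimensions
    nx = _edge_count(Lx, spec.mesh_size, "Lx")
    ny = _edge_count(Ly, spec.mesh_size, "Ly")
    nz = 1  # thin tissue: one element through thickness
    xs = np.linspace(-Lx / 2, Lx / 2, nx + 1)
    ys = np.linspace(-Ly / 2, Ly / 2, ny + 1)
    zs = np.linspace(0.0, Lz, nz + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(ix, iy, iz):
        return (iz * (ny + 1) + iy) * (nx + 1) + ix

    hexes = []
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                hexes.append([
                    nid(ix, iy, iz), nid(ix + 1, iy, iz),
                    nid(ix + 1, iy + 1, iz), nid(ix, iy + 1, iz),
                    nid(ix, iy, iz + 1), nid(ix + 1, iy, iz + 1),
                    nid(ix + 1, iy + 1, iz + 1), nid(ix, iy + 1, iz + 1),
                ])
    hexes = np.asarray(hexes, dtype=np.int64)

    if spec.fiber_rule != "uniform_vector":
        raise ValueError("slab supports fiber_rule='uniform_vector' only")
    fib = np.asarray(spec.fiber_vector, dtype=float)
    fib = fib / np.linalg.norm(fib)
    a0 = np.tile(fib, (len(hexes), 1))

    fixed = np.empty(0, dtype=np.int64)
    fixed_dofs = np.empty((0, 2), dtype=np.int64)
    if spec.pinned == "corners":
        # top-left and bottom-right corner node columns (all z layers)
        cols = []
        for (cx, cy) in ((-Lx / 2, Ly / 2), (Lx / 2, -Ly / 2)):
            for iz in range(nz + 1):
                d = np.linalg.norm(nodes[:, :2] - [cx, cy], axis=1) \
                    + np.abs(nodes[:, 2] - zs[iz])
                cols.append(int(np.argmin(d)))
        fixed = np.unique(np.asarray(cols, dtype=np.int64))
        # quasi-2D thin tissue: suppress out-of-plane (z) motion everywhere
        fixed_dofs = np.column_stack([
            np.arange(len(nodes), dtype=np.int64),
            np.full(len(nodes), 2, dtype=np.int64)])
    elif spec.pinned != "none":
        raise ValueError(f"slab pinned rule {spec.pinned!r} unknown")

    scar_elems = np.empty(0, dtype=np.int64)
    if spec.scar is not None:
        center = spec.scar.center if spec.scar.center is not None else (0.0, 0.0, Lz / 2)
        cent = nodes[hexes].mean(axis=1)
        scar_elems = np.flatnonzero(
            np.linalg.norm(cent - np.asarray(center), axis=1) <= spec.scar.radius)

    return Mesh(X_ref=nodes, hexes=hexes, a0_field=a0,
                fixed_nodes=fixed, scar_elements=scar_elems,
                fixed_dofs=fixed_dofs).check()


def _ventricle_counts(spec: GeometrySpec):
    rx, ry, rz = spec.dimensions
    h = spec.mesh_size
    # floor of 40 keeps the circumferential fiber rotation between adjacent
    # elements below 10 degrees regardless of the requested edge length
    n_circ = max(40, int(round(2 * np.pi * 0.75 * max(rx, ry) / h)))
    arc = (np.pi / 2 - spec.apex_gap) * rz
    n_long = max(3, int(round(arc / h)))
    n_thick = max(1, int(round(spec.wall_thickness / h)))
    return n_circ, n_long, min(n_thick, 4)


def make_ventricle(spec: GeometrySpec) -> Mesh:
    """Structured hex shell of a truncated half-ellipsoid ventricle."""
    if spec.kind != "ellipsoid_ventricle":
        raise ValueError("make_ventricle requires kind='ellipsoid_ventricle'")
    rx, ry, rz = spec.dimensions
    t = spec.wall_thickness
    if t >= min(rx, ry, rz):
        raise ValueError("wall_thickness must be smaller than every radius")
    n_circ, n_long, n_thick = _ventricle_counts(spec)

    lam_max = np.pi / 2 - spec.apex_gap   # latitude below the equator (base)
    lams = np.linspace(0.0, lam_max, n_long + 1)
    phis = 2 * np.pi * np.arange(n_circ) / n_circ
    ss = np.linspace(0.0, 1.0, n_thick + 1)

    n_layer = (n_long + 1) * n_circ
    nodes = np.empty(((n_thick + 1) * n_layer, 3))
    for k, s in enumerate(ss):
        Rx, Ry, Rz = rx - t * s, ry - t * s, rz - t * s
        for j, lam in enumerate(lams):
            cz = -Rz * np.sin(lam)
            rho_x = Rx * np.cos(lam)
            rho_y = Ry * np.cos(lam)
            base = k * n_layer + j * n_circ
            nodes[base:base + n_circ, 0] = rho_x * np.cos(phis)
            nodes[base:base + n_circ, 1] = rho_y * np.sin(phis)
            nodes[base:base + n_circ, 2] = cz

    def nid(c, j, k):
        return k * n_layer + j * n_circ + (c % n_circ)

    hexes = []
    for k in range(n_thick):
        for j in range(n_long):
            for c in range(n_circ):
                hexes.append([
                    nid(c, j, k), nid(c + 1, j, k),
                    nid(c + 1, j + 1, k), nid(c, j + 1, k),
                    nid(c, j, k + 1), nid(c + 1, j, k + 1),
                    nid(c + 1, j + 1, k + 1), nid(c, j + 1, k + 1),
                ])
    hexes = np.asarray(hexes, dtype=np.int64)

    # orient consistently: flip bottom/top faces if the parameterization is left-handed
    probe = Mesh(X_ref=nodes, hexes=hexes[:1], a0_field=np.array([[1.0, 0, 0]]))
    detJ, _ = probe.reference_jacobians()
    if detJ.mean() < 0:
        hexes = hexes[:, [4, 5, 6, 7, 0, 1, 2, 3]]

    center = nodes.mean(axis=0)
    cent = nodes[hexes].mean(axis=1)
    a0 = _circumferential_fibers(cent, center, np.deg2rad(spec.apex_axis_angle))

    fixed = np.empty(0, dtype=np.int64)
    if spec.pinned == "base":
        fixed = np.flatnonzero(np.abs(nodes[:, 2]) < 1e-9 * max(rx, ry, rz) + 1e-12)
    elif spec.pinned != "none":
        raise ValueError(f"ventricle pinned rule {spec.pinned!r} unknown")

    scar_elems = np.empty(0, dtype=np.int64)
    if spec.scar is not None:
        sc = spec.scar.center
        if sc is None:
            # outer wall, mid-height of the truncated shell
            lam_mid = lam_max / 2
            sc = ((rx - t / 2) * np.cos(lam_mid), 0.0,
                  -(rz - t / 2) * np.sin(lam_mid))
        scar_elems = np.flatnonzero(
            np.linalg.norm(cent - np.asarray(sc), axis=1) <= spec.scar.radius)

    return Mesh(X_ref=nodes, hexes=hexes, a0_field=a0,
                fixed_nodes=fixed, scar_elements=scar_elems).check()


def _circumferential_fibers(points, center, axis_cone):
    """Unit fibers orthogonal to the centerward radial direction.

    a0 = normalize(z_hat x r_hat); within ``axis_cone`` of the apex axis the
    cross product degenerates and e_x is projected onto the plane
    perpendicular to r_hat instead.
    """
    r = center - points
    r_hat = r / np.linalg.norm(r, axis=1, keepdims=True)
    z_hat = np.array([0.0, 0.0, 1.0])
    a = np.cross(np.broadcast_to(z_hat, r_hat.shape), r_hat)
    norm = np.linalg.norm(a, axis=1)
    near_axis = norm < np.sin(axis_cone)
    if near_axis.any():
        ex = np.array([1.0, 0.0, 0.0])
        proj = ex - r_hat[near_axis] * (r_hat[near_axis] @ ex)[:, None]
        a[near_axis] = proj
        norm = np.linalg.norm(a, axis=1)
    return a / norm[:, None]


def make_mesh(spec: GeometrySpec) -> Mesh:
    """Dispatch on geometry kind."""
    if spec.kind == "slab":
        return make_slab(spec)
    return make_ventricle(spec)


def select_stimulus_nodes(mesh: Mesh, spec: StimulusSpec) -> np.ndarray:
    """Node indices of the stimulated region; raises on an empty selection."""
    if spec.kind == "ball":
        d = np.linalg.norm(mesh.X_ref - np.asarray(spec.center, dtype=float), axis=1)
        sel = np.flatnonzero(d <= spec.radius)
    elif spec.kind == "box":
        c = np.asarray(spec.center, dtype=float)
        d = np.abs(mesh.X_ref[:, :2] - c[:2]).max(axis=1)
        sel = np.flatnonzero(d <= spec.radius + 1e-12)
    elif spec.kind == "base_patch":
        zmax = mesh.X_ref[:, 2].max()
        sel = np.flatnonzero(mesh.X_ref[:, 2] >= zmax - spec.radius)
    else:
        raise ValueError(f"unknown stimulus kind {spec.kind!r}")
    if sel.size == 0:
        raise ValueError(
            f"stimulus region {spec.kind} (center={spec.center}, "
            f"radius={spec.radius}) selects no nodes")
    return sel
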
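"""Trilinear 8-node hexahedron: shape functions and 2x2x2 Gauss quadrature.

Node ordering follows the VTK_HEXAHEDRON convention: the bottom face
(zeta = -1) counter-clockwise, then the top face (zeta = +1) counter-clockwise.
"""

from __future__ import annotations

import numpy as np

#: natural coordinates of the 8 nodes, VTK ordering
NODE_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def shape_functions(xi):
    """N_a(xi) for a point xi = (xi, eta, zeta), shape (8,)."""
    xi = np.asarray(xi, dtype=float)
    return 0.125 * (1 + NODE_XI[:, 0] * xi[0]) \
        * (1 + NODE_XI[:, 1] * xi[1]) * (1 + NODE_XI[:, 2] * xi[2])


def shape_gradients(xi):
    """dN_a/dxi_j at xi, shape (8, 3)."""
    xi = np.asarray(xi, dtype=float)
    g = np.empty((8, 3))
    g[:, 0] = 0.125 * NODE_XI[:, 0] * (1 + NODE_XI[:, 1] * xi[1]) * (1 + NODE_XI[:, 2] * xi[2])
    g[:, 1] = 0.125 * NODE_XI[:, 1] * (1 + NODE_XI[:, 0] * xi[0]) * (1 + NODE_XI[:, 2] * xi[2])
    g[:, 2] = 0.125 * NODE_XI[:, 2] * (1 + NODE_XI[:, 0] * xi[0]) * (1 + NODE_XI[:, 1] * xi[1])
    return g


_g = 1.0 / np.sqrt(3.0)
#: 2x2x2 Gauss points (8, 3) and unit weights (8,)
GAUSS_XI = NODE_XI * _g
GAUSS_W = np.ones(8)

#: shape functions at the Gauss points, (n_gauss=8, n_node=8)
N_GP = np.stack([shape_functions(x) for x in GAUSS_XI])
#: natural shape gradients at the Gauss points, (8, 8, 3)
DN_GP = np.stack([shape_gradients(x) for x in GAUSS_XI])
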
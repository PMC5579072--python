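"""Independent test oracles, kept out of the production package.

Vertex enumeration works only in 2-D (sorting generators by angle walks
the boundary of the centrally symmetric polygon); exponential vertex
counts rule it out as a production primitive, but in the plane it gives
exact geometry to check the matrix-algebra implementations against.
"""

import numpy as np


def vertices_2d(Z) -> np.ndarray:
    """Exact vertex cycle of a 2-D zonotope (counter-clockwise)."""
    assert Z.dimension == 2
    G = Z.generators
    keep = np.abs(G).sum(axis=0) > 0
    G = G[:, keep]
    if G.shape[1] == 0:
        return Z.centre.reshape(1, 2)
    flip = (G[1] < 0) | ((G[1] == 0) & (G[0] < 0))
    Gf = np.where(flip, -G, G)
    order = np.argsort(np.arctan2(Gf[1], Gf[0]), kind="stable")
    Gs = Gf[:, order]
    v = Z.centre - Gs.sum(axis=1)
    verts = [v]
    for k in range(Gs.shape[1]):
        v = v + 2 * Gs[:, k]
        verts.append(v)
    for k in range(Gs.shape[1]):
        v = v - 2 * Gs[:, k]
        verts.append(v)
    return np.array(verts[:-1])


def polygon_contains(verts: np.ndarray, point, tol: float = 1e-9) -> bool:
    """Point-in-convex-polygon by half-plane checks (CCW vertex cycle)."""
    p = np.asarray(point, dtype=float)
    n = len(verts)
    if n == 1:
        return bool(np.allclose(verts[0], p, atol=tol))
    scale = max(1.0, np.abs(verts).max())
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        edge = b - a
        cross = edge[0] * (p[1] - a[1]) - edge[1] * (p[0] - a[0])
        if cross < -tol * scale:
            return False
    return True
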
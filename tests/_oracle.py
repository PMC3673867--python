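"""Independent brute-force oracle: polytope vertex enumeration for tiny LPs.

Enumerates the vertices of the flux polytope ``{v : S v = 0, lb <= v <= ub}``
(optionally intersected with the optimal-objective face) by parametrizing the
null space of S and solving every d-subset of the bound inequalities.  It
shares no code path with the package's LP engine, so agreement between the
two is a genuine cross-check.  Only tractable for small degrees of freedom
(d <= ~5) and reaction counts (<= ~20).
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.linalg import null_space


def _polytope_vertices(
    G: np.ndarray, h: np.ndarray, tol: float = 1e-7
) -> np.ndarray:
    """All vertices of {t : G t <= h} (must be bounded), shape (k, d)."""
    d = G.shape[1]
    vertices = []
    for rows in combinations(range(G.shape[0]), d):
        A = G[list(rows)]
        if np.linalg.matrix_rank(A) < d:
            continue
        t = np.linalg.lstsq(A, h[list(rows)], rcond=None)[0]
        if np.all(G @ t <= h + tol):
            vertices.append(t)
    if not vertices:
        return np.empty((0, d))
    return np.array(vertices)


def vertex_fva(
    model,
    objective: Optional[Mapping[str, float]] = None,
    fix: bool = True,
    tol: float = 1e-7,
) -> Tuple[float, Dict[str, Tuple[float, float]]]:
    """Objective optimum and per-reaction flux ranges by vertex enumeration.

    Returns ``(z_opt, ranges)`` where ``z_opt`` is the maximum of the
    objective over the polytope vertices (the LP optimum, since a linear
    maximum is attained at a vertex) and ``ranges`` the coordinate-wise
    min/max over the vertices of the polytope intersected (when ``fix``)
    with the face ``objective >= z_opt - tol``.
    """
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    obj = dict(objective) if objective is not None else dict(model.objective)
    c = np.zeros(n)
    for rid, w in obj.items():
        c[rxn_ids.index(rid)] = w
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    N = null_space(S)
    d = N.shape[1]
    if d == 0:
        v = np.zeros(n)
        return 0.0, {rid: (0.0, 0.0) for rid in rxn_ids}
    G = np.vstack([N, -N])
    h = np.concatenate([ub, -lb])
    verts_t = _polytope_vertices(G, h, tol)
    assert verts_t.shape[0] > 0, "polytope has no vertices (unbounded or empty?)"
    z_opt = float(np.max(verts_t @ (N.T @ c)))
    if fix:
        G = np.vstack([G, -(c @ N)[None, :]])
        h = np.concatenate([h, [-(z_opt - 1e-9)]])
        verts_t = _polytope_vertices(G, h, tol)
    verts_v = verts_t @ N.T
    ranges = {
        rid: (float(np.min(verts_v[:, j])), float(np.max(verts_v[:, j])))
        for j, rid in enumerate(rxn_ids)
    }
    return z_opt, ranges
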
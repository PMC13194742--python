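"""Brute-force finite-difference Laplace oracle for the sphere-inclusion model.

Test-only, independent of the analytic code path it checks.  Solves
div(k grad phi) = 0 on a cell-centered cubic grid with a unit applied field
along z (Dirichlet phi = -z on the box boundary), where k is the complex
admittivity (or any contrast coefficient) of a sphere of radius 1 centred in
a host medium.  The interior field factor <E_z>/E0 is measured over cells
well inside the sphere (r < 0.6) and the O(h) staircase-boundary error is
removed by Richardson extrapolation over two grids.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def _interior_field_factor_single(k1: complex, k2: complex, n: int,
                                  box_half_width: float = 3.0) -> complex:
    a = 1.0
    L = box_half_width * a
    h = 2.0 * L / n
    x = -L + h * (np.arange(n) + 0.5)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    R2 = X**2 + Y**2 + Z**2
    k = np.where(R2 <= a * a, k1, k2).astype(complex)

    N = n**3
    idx = np.arange(N).reshape(n, n, n)
    rows, cols, vals = [], [], []
    b = np.zeros(N, dtype=complex)
    for axis in range(3):
        for side in (-1, 1):
            kn = np.roll(k, -side, axis=axis)
            kf = 2.0 * k * kn / (k + kn)  # harmonic mean on faces
            sl = [slice(None)] * 3
            sl[axis] = slice(-1, None) if side == 1 else slice(0, 1)
            interior = np.ones((n, n, n), dtype=bool)
            interior[tuple(sl)] = False
            i_self = idx[interior]
            i_nb = np.roll(idx, -side, axis=axis)[interior]
            c = kf[interior] / h**2
            rows += [i_self, i_self]
            cols += [i_self, i_nb]
            vals += [c, -c]
            # domain boundary: Dirichlet phi = -z at the face, half-cell away
            bm = ~interior
            cb = 2.0 * k[bm] / h**2
            rows.append(idx[bm])
            cols.append(idx[bm])
            vals.append(cb)
            b[idx[bm]] += cb * (-(L * side)) if axis == 2 else cb * (-Z[bm])
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    M = sp.diags(1.0 / A.diagonal())
    phi, info = spla.bicgstab(A, b, rtol=1e-10, maxiter=8000, M=M)
    if info != 0:
        raise RuntimeError(f"FD solver did not converge (info={info})")
    phi = phi.reshape(n, n, n)
    ez = -(np.roll(phi, -1, axis=2) - np.roll(phi, 1, axis=2)) / (2.0 * h)
    return complex(ez[R2 < (0.6 * a) ** 2].mean())


def fd_interior_field_factor(k1: complex, k2: complex,
                             grids: tuple[int, int] = (40, 56)) -> complex:
    """Richardson-extrapolated interior field factor for a coated sphere.

    The staircase boundary gives an O(h) error; extrapolating two grid
    resolutions in 1/n removes the leading term (f* = (n2 f2 - n1 f1)/(n2 - n1)).
    """
    n1, n2 = grids
    f1 = _interior_field_factor_single(k1, k2, n1)
    f2 = _interior_field_factor_single(k1, k2, n2)
    return (n2 * f2 - n1 * f1) / (n2 - n1)
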
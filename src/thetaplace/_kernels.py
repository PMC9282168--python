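"""Jitted inner loops: grid-field evaluation and LCA/learning dynamics.

These kernels are strictly sequential in simulated time (the membrane state
and the dictionary both carry over between trajectory steps), so they are
written as explicit loops and compiled with numba; the linear algebra inside
each step goes through BLAS via ``np.dot``.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_LN5 = np.log(5.0)
_DEG = np.pi / 180.0


@njit(cache=True, parallel=True)
def grid_rates_kernel(pos, times, headings,
                      off, basis, inv_basis, r2, kphi, phi0, dphi, freq,
                      i0, j0, ni, nj, amp_start, amps, out):
    """Evaluate a population of spatiotemporal grid cells along a path.

    pos (N,2), times (N), headings (N); per-cell packed lattice arrays;
    out (N, C).  A query outside every field (or nearer than the field
    radius to no retained vertex) yields 0.
    """
    n = pos.shape[0]
    n_cells = off.shape[0]
    for c in prange(n_cells):
        b00 = basis[c, 0]
        b01 = basis[c, 1]
        b10 = basis[c, 2]
        b11 = basis[c, 3]
        q00 = inv_basis[c, 0]
        q01 = inv_basis[c, 1]
        q10 = inv_basis[c, 2]
        q11 = inv_basis[c, 3]
        rr = r2[c]
        for k in range(n):
            x = pos[k, 0] - off[c, 0]
            y = pos[k, 1] - off[c, 1]
            a = q00 * x + q01 * y
            b = q10 * x + q11 * y
            ia = int(np.floor(a))
            jb = int(np.floor(b))
            # nearest lattice vertex among the 4 corners of the cell
            best = 1.0e30
            bi = ia
            bj = jb
            bdx = 0.0
            bdy = 0.0
            for di in range(2):
                for dj in range(2):
                    vx = b00 * (ia + di) + b01 * (jb + dj)
                    vy = b10 * (ia + di) + b11 * (jb + dj)
                    dx = x - vx
                    dy = y - vy
                    d2 = dx * dx + dy * dy
                    if d2 < best:
                        best = d2
                        bi = ia + di
                        bj = jb + dj
                        bdx = dx
                        bdy = dy
            if best >= rr:
                out[k, c] = 0.0
                continue
            ii = bi - i0[c]
            jj = bj - j0[c]
            if ii < 0 or ii >= ni[c] or jj < 0 or jj >= nj[c]:
                out[k, c] = 0.0
                continue
            amp = amps[amp_start[c] + ii * nj[c] + jj]
            if amp <= 0.0:
                out[k, c] = 0.0
                continue
            fs = amp * np.exp(-_LN5 * best / rr)
            # firing phase from the chord along the running direction
            ux = np.cos(headings[k])
            uy = np.sin(headings[k])
            d = bdx * ux + bdy * uy
            cperp = -bdx * uy + bdy * ux
            rp = np.sqrt(rr - cperp * cperp)
            phi = (phi0[c] - dphi[c] * (d + rp) / (2.0 * rp)) * _DEG
            out[k, c] = fs * np.exp(
                kphi[c] * (np.cos(2.0 * np.pi * freq[c] * times[k] - phi)
                           - 1.0))


@njit(cache=True)
def lca_steps(A, b, u, s, n_iter, dt_over_tau, beta):
    """Forward-Euler LCA iterations, in place on (u, s).

    tau u' = -u + b - (A^T A - I) s,  s = max(u - beta, 0), with b = A^T I
    precomputed; the lateral term is formed implicitly as A^T(A s) - s.
    """
    n = u.shape[0]
    for _ in range(n_iter):
        As = np.dot(A, s)
        inh = np.dot(As, A)   # = A^T (A s)
        for j in range(n):
            u[j] += dt_over_tau * (b[j] - u[j] - inh[j] + s[j])
            s[j] = max(u[j] - beta, 0.0)


@njit(cache=True)
def run_session(A, I, u, s, n_iter, dt_over_tau, beta, eta, learn,
                S_out, err_out):
    """Run LCA inference (and optionally dictionary learning) over a block
    of trajectory steps with inputs ``I`` (steps, n_inputs).

    After the ``n_iter`` inner iterations of each step the dictionary is
    updated with dA = eta (I - A s) s^T, clipped at 0, and the touched
    columns are renormalised to unit length.  S_out (steps, n_cells)
    records the settled rates; err_out (steps,) the squared reconstruction
    error ||I - A s||^2.
    """
    n_steps = I.shape[0]
    m = A.shape[0]
    n = A.shape[1]
    for t in range(n_steps):
        row = I[t]
        b = np.dot(row, A)
        lca_steps(A, b, u, s, n_iter, dt_over_tau, beta)
        resid = row - np.dot(A, s)
        err = 0.0
        for i in range(m):
            err += resid[i] * resid[i]
        err_out[t] = err
        for j in range(n):
            S_out[t, j] = s[j]
        if learn:
            for j in range(n):
                if s[j] <= 0.0:
                    continue
                coef = eta * s[j]
                norm = 0.0
                for i in range(m):
                    v = A[i, j] + coef * resid[i]
                    if v < 0.0:
                        v = 0.0
                    A[i, j] = v
                    norm += v * v
                if norm > 0.0:
                    norm = np.sqrt(norm)
                    for i in range(m):
                        A[i, j] /= norm
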
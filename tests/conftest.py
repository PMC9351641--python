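"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent brute-force coherence oracle: definition-level DFT sums,
# no shared code with the package estimator.
# ---------------------------------------------------------------------------

def dft_matrix(n: int) -> np.ndarray:
    k = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(k, k) / n)


def brute_force_coherence(x_trials, y_trials, fs, freq_grid):
    """Coherence from first principles: per-trial Hanning-tapered DFT sums,
    trial-averaged auto/cross spectra, magnitude ratio."""
    x = np.asarray(x_trials, float)
    y = np.asarray(y_trials, float)
    n_tr, n = x.shape
    w = np.hanning(n)
    W = dft_matrix(n)
    sxx = np.zeros(n)
    syy = np.zeros(n)
    sxy = np.zeros(n, dtype=complex)
    for t in range(n_tr):
        X = W @ (w * x[t])
        Y = W @ (w * y[t])
        sxx += np.abs(X) ** 2
        syy += np.abs(Y) ** 2
        sxy += X * np.conj(Y)
    sxx, syy, sxy = sxx / n_tr, syy / n_tr, sxy / n_tr
    native = np.arange(n) * fs / n
    out = []
    for f in np.atleast_1d(freq_grid):
        b = int(round(f * n / fs))
        denom = np.sqrt(sxx[b] * syy[b])
        out.append(np.abs(sxy[b]) / denom if denom > 0 else 0.0)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Independent brute-force dip oracle: LP minimization over unimodal CDFs
# on a grid (convex-then-concave, jump allowed at the mode).
# ---------------------------------------------------------------------------

def brute_force_dip(sample, pad=1.0):
    from scipy.optimize import linprog

    x = np.sort(np.asarray(sample, float))
    n = x.size
    pts = np.unique(x)
    grid = np.concatenate([[pts[0] - pad], pts, [pts[-1] + pad]])
    mids = (grid[:-1] + grid[1:]) / 2
    grid = np.sort(np.concatenate([grid, mids]))
    m_ = grid.size
    Fr = np.searchsorted(x, grid, side="right") / n
    Fl = np.searchsorted(x, grid, side="left") / n
    best = np.inf
    for mode in range(m_):
        nv = m_ + 2          # g_0..g_{m-1}, gL (left limit at mode), d
        iL, iD = m_, m_ + 1
        A, b = [], []

        def con(row, rhs):
            A.append(row)
            b.append(rhs)

        def var_row():
            return [0.0] * nv

        for i in range(m_ - 1):
            r = var_row()
            if i == mode - 1:
                r[i] = 1
                r[iL] = -1
                con(r, 0)
                r = var_row()
                r[iL] = 1
                r[mode] = -1
                con(r, 0)
            else:
                r[i] = 1
                r[i + 1] = -1
                con(r, 0)

        def seg(i):
            r = var_row()
            r[i] = -1
            if i + 1 == mode:
                r[iL] = 1
            else:
                r[i + 1] = 1
            return r, grid[i + 1] - grid[i]

        for i in range(0, mode - 1):
            r1, dx1 = seg(i)
            r2, dx2 = seg(i + 1)
            con([r1[k] / dx1 - r2[k] / dx2 for k in range(nv)], 0)

        def rseg(i):
            r = var_row()
            r[mode if i == mode else i] = -1
            r[i + 1] = 1
            return r, grid[i + 1] - grid[i]

        for i in range(mode, m_ - 2):
            r1, dx1 = rseg(i)
            r2, dx2 = rseg(i + 1)
            con([r2[k] / dx2 - r1[k] / dx1 for k in range(nv)], 0)

        for i in range(m_):
            r = var_row(); r[i] = 1; r[iD] = -1; con(r, Fr[i])
            r = var_row(); r[i] = -1; r[iD] = -1; con(r, -Fr[i])
            gl = iL if i == mode else i
            r = var_row(); r[gl] = 1; r[iD] = -1; con(r, Fl[i])
            r = var_row(); r[gl] = -1; r[iD] = -1; con(r, -Fl[i])

        bounds = [(0, 1)] * (m_ + 1) + [(0, None)]
        c = [0.0] * nv
        c[iD] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                      method="highs")
        if res.success:
            best = min(best, res.fun)
    return best
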
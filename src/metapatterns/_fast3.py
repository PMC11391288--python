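"""Vectorized three-species pair classification for robustness grids.

Classifying a full Monte-Carlo grid means testing, for every (P, C)
pair and every kappa on the scan grid, whether the spectral abscissa of
J = P - kappa * C exceeds the tolerance.  For 3x3 matrices this reduces
to a Routh--Hurwitz test on the characteristic polynomial of J shifted
by the tolerance (lambda -> mu + tol): the abscissa exceeds tol exactly
when the shifted polynomial fails the Hurwitz conditions

    b1 > 0,  b3 > 0,  b1*b2 > b3.

This avoids millions of dense eigenvalue calls; the generic eigenvalue
path in :mod:`metapatterns.stability` serves as its cross-check in the
test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _classify_pairs_numba(P_stack, C_stack, kappas, unstable_row, asym_col, tol):
    n_P = P_stack.shape[0]
    n_C = C_stack.shape[0]
    K = kappas.shape[0]
    out = np.zeros((n_P, n_C), dtype=np.uint8)
    for i in range(n_P):
        if unstable_row[i]:
            for j in range(n_C):
                out[i, j] = 1
            continue
        P = P_stack[i]
        for j in range(n_C):
            if asym_col[j]:
                out[i, j] = 2
                continue
            C = C_stack[j]
            crossed = False
            for k in range(K):
                kp = kappas[k]
                j00 = P[0, 0] - kp * C[0, 0]
                j01 = P[0, 1] - kp * C[0, 1]
                j02 = P[0, 2] - kp * C[0, 2]
                j10 = P[1, 0] - kp * C[1, 0]
                j11 = P[1, 1] - kp * C[1, 1]
                j12 = P[1, 2] - kp * C[1, 2]
                j20 = P[2, 0] - kp * C[2, 0]
                j21 = P[2, 1] - kp * C[2, 1]
                j22 = P[2, 2] - kp * C[2, 2]
                a1 = -(j00 + j11 + j22)
                a2 = (
                    (j00 * j11 - j01 * j10)
                    + (j00 * j22 - j02 * j20)
                    + (j11 * j22 - j12 * j21)
                )
                det = (
                    j00 * (j11 * j22 - j12 * j21)
                    - j01 * (j10 * j22 - j12 * j20)
                    + j02 * (j10 * j21 - j11 * j20)
                )
                a3 = -det
                b1 = a1 + 3.0 * tol
                b2 = a2 + 2.0 * tol * a1 + 3.0 * tol * tol
                b3 = tol * (tol * (tol + a1) + a2) + a3
                if not (b1 > 0.0 and b3 > 0.0 and b1 * b2 > b3):
                    crossed = True
                    break
            if crossed:
                out[i, j] = 2
    return out


def _classify_pairs_numpy(P_stack, C_stack, kappas, unstable_row, asym_col, tol):
    """Pure-numpy fallback: Routh--Hurwitz vectorized over kappa per pair."""
    n_P, n_C = P_stack.shape[0], C_stack.shape[0]
    out = np.zeros((n_P, n_C), dtype=np.uint8)
    kp = kappas[:, None, None]
    for i in range(n_P):
        if unstable_row[i]:
            out[i, :] = 1
            continue
        for j in range(n_C):
            if asym_col[j]:
                out[i, j] = 2
                continue
            J = P_stack[i][None, :, :] - kp * C_stack[j][None, :, :]
            a1 = -np.trace(J, axis1=1, axis2=2)
            a2 = (
                (J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0])
                + (J[:, 0, 0] * J[:, 2, 2] - J[:, 0, 2] * J[:, 2, 0])
                + (J[:, 1, 1] * J[:, 2, 2] - J[:, 1, 2] * J[:, 2, 1])
            )
            a3 = -np.linalg.det(J)
            b1 = a1 + 3.0 * tol
            b2 = a2 + 2.0 * tol * a1 + 3.0 * tol * tol
            b3 = tol * (tol * (tol + a1) + a2) + a3
            unstable = ~((b1 > 0.0) & (b3 > 0.0) & (b1 * b2 > b3))
            if unstable.any():
                out[i, j] = 2
    return out


def classify_pairs_3x3(P_stack, C_stack, kappas, unstable_row, asym_col, tol):
    """Label codes (0 stable, 1 unstable, 2 pattern-forming) per (P, C) pair.

    ``unstable_row`` marks P draws with positive spectral abscissa (the
    unstable label depends only on P); ``asym_col`` marks C draws with an
    eigenvalue of negative real part (unstable at large kappa).
    ``kappas`` must exclude kappa = 0.
    """
    P_stack = np.ascontiguousarray(P_stack, dtype=np.float64)
    C_stack = np.ascontiguousarray(C_stack, dtype=np.float64)
    kappas = np.ascontiguousarray(kappas, dtype=np.float64)
    unstable_row = np.ascontiguousarray(unstable_row, dtype=np.bool_)
    asym_col = np.ascontiguousarray(asym_col, dtype=np.bool_)
    impl = _classify_pairs_numba if _HAVE_NUMBA else _classify_pairs_numpy
    return impl(P_stack, C_stack, kappas, unstable_row, asym_col, float(tol))
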
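"""Master stability functions and the three-way dynamical classification.

On a patch network, perturbations of the homogeneous equilibrium
decompose over Laplacian eigenmodes; the mode with Laplacian eigenvalue
``kappa`` grows at the spectral abscissa of

    J(kappa) = P - kappa * C,

the master stability function (dispersion relation) lambda(kappa).
Treating kappa as a free non-negative parameter covers every possible
patch network at once.  Outcomes fall into three classes:

* ``unstable``        — lambda(0) > 0: coexistence fails even in isolation.
* ``pattern_forming`` — lambda(0) < 0 but lambda(kappa) > 0 for some
  kappa > 0: dispersal destabilizes the homogeneous state on suitable
  networks (a Turing-type instability).
* ``stable``          — lambda(kappa) < 0 for all kappa >= 0.

Because kappa is unbounded, a finite scan is augmented by an asymptotic
test: if C has an eigenvalue with negative real part, J(kappa) is
unstable for all sufficiently large kappa, so the pair is
pattern-forming regardless of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STABLE",
    "UNSTABLE",
    "PATTERN_FORMING",
    "LABEL_CODES",
    "CODE_LABELS",
    "StabilityConfig",
    "MasterStabilityFunction",
    "DynamicalClass",
    "mode_jacobian",
    "spectral_abscissa",
    "msf",
    "classify",
]

STABLE = "stable"
UNSTABLE = "unstable"
PATTERN_FORMING = "pattern_forming"

LABEL_CODES = {STABLE: 0, UNSTABLE: 1, PATTERN_FORMING: 2}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


def _default_grid() -> np.ndarray:
    return np.concatenate(([0.0], np.logspace(-3.0, 3.0, 400)))


@dataclass(frozen=True)
class StabilityConfig:
    """kappa grid and tolerances for the classification.

    The grid starts at kappa = 0 and covers six decades; instabilities
    beyond the last grid point are caught by the asymptotic eigenvalue
    test on C, which makes the classification insensitive to the grid's
    upper bound.
    """

    kappa_grid: np.ndarray = field(default_factory=_default_grid)
    zero_tol: float = 1e-9
    asymptotic_tol: float = 1e-9

    def __post_init__(self) -> None:
        grid = np.asarray(self.kappa_grid, dtype=float)
        if grid[0] != 0.0 or np.any(np.diff(grid) <= 0) or np.any(grid < 0):
            raise ValueError("kappa_grid must start at 0 and increase strictly")
        if not self.zero_tol > 0:
            raise ValueError("zero_tol must be positive")
        object.__setattr__(self, "kappa_grid", grid)


@dataclass(frozen=True)
class MasterStabilityFunction:
    """lambda(kappa) samples plus the large-kappa instability flag."""

    kappa: np.ndarray
    lam: np.ndarray
    asymptotically_unstable: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"kappa": self.kappa, "lambda": self.lam})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DynamicalClass:
    """Three-way outcome label with marginality/oscillation metadata.

    ``marginal`` flags |lambda(0)| below tolerance (classified by sign
    but numerically ambiguous).  ``oscillatory`` records whether the
    leading eigenvalue at the decisive point is complex — oscillatory
    versus static patterns — without splitting the three-way taxonomy.
    """

    label: str
    marginal: bool = False
    oscillatory: bool | None = None


def mode_jacobian(P: np.ndarray, C: np.ndarray, kappa: float) -> np.ndarray:
    """The mode Jacobian J = P - kappa * C."""
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    if P.shape != C.shape or P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P and C must be square matrices of equal size")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return P - kappa * C


def spectral_abscissa(M: np.ndarray) -> float:
    """Maximum real part of the eigenvalues of M."""
    return float(np.linalg.eigvals(M).real.max())


def _asymptotically_unstable(C: np.ndarray, tol: float) -> tuple[bool, bool]:
    """Large-kappa test: does C have an eigenvalue with Re < -tol?

    Returns (flag, oscillatory) where oscillatory reflects whether the
    most destabilizing eigenvalue of C is complex.
    """
    ev = np.linalg.eigvals(C)
    k = int(np.argmin(ev.real))
    return bool(ev.real[k] < -tol), bool(abs(ev.imag[k]) > tol)


def _scan_first_positive(
    P: np.ndarray,
    C: np.ndarray,
    kappas: np.ndarray,
    tol: float,
    chunk: int = 64,
) -> tuple[int, bool]:
    """First index of the kappa grid with lambda(kappa) > tol, else -1.

    Eigenvalues are computed in batched chunks so the scan can stop at
    the first unstable mode.
    """
    for lo in range(0, len(kappas), chunk):
        ks = kappas[lo : lo + chunk]
        J = P[None, :, :] - ks[:, None, None] * C[None, :, :]
        ev = np.linalg.eigvals(J)
        re_max = ev.real.max(axis=1)
        hits = np.nonzero(re_max > tol)[0]
        if hits.size:
            k = lo + int(hits[0])
            lead = np.argmax(ev[hits[0]].real)
            osc = bool(abs(ev[hits[0], lead].imag) > tol)
            return k, osc
    return -1, False


def msf(P: np.ndarray, C: np.ndarray, config: StabilityConfig | None = None) -> MasterStabilityFunction:
    """Evaluate lambda(kappa) over the configured grid."""
    cfg = config or StabilityConfig()
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    if P.shape != C.shape:
        raise ValueError("P and C must have the same shape")
    kappas = cfg.kappa_grid
    lam = np.empty(len(kappas))
    chunk = 64
    for lo in range(0, len(kappas), chunk):
        ks = kappas[lo : lo + chunk]
        J = P[None, :, :] - ks[:, None, None] * C[None, :, :]
        lam[lo : lo + len(ks)] = np.linalg.eigvals(J).real.max(axis=1)
    asym, _ = _asymptotically_unstable(C, cfg.asymptotic_tol)
    return MasterStabilityFunction(kappa=kappas, lam=lam, asymptotically_unstable=asym)


def classify(
    P: np.ndarray, C: np.ndarray, config: StabilityConfig | None = None
) -> DynamicalClass:
    """Classify a (P, C) pair as stable, unstable or pattern-forming."""
    cfg = config or StabilityConfig()
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    if P.shape != C.shape:
        raise ValueError("P and C must have the same shape")
    ev0 = np.linalg.eigvals(P)
    lead0 = int(np.argmax(ev0.real))
    lam0 = float(ev0.real[lead0])
    marginal = abs(lam0) <= cfg.zero_tol
    if lam0 > cfg.zero_tol:
        return DynamicalClass(
            UNSTABLE,
            marginal=marginal,
            oscillatory=bool(abs(ev0.imag[lead0]) > cfg.zero_tol),
        )
    idx, osc = _scan_first_positive(P, C, cfg.kappa_grid[1:], cfg.zero_tol)
    if idx >= 0:
        return DynamicalClass(PATTERN_FORMING, marginal=marginal, oscillatory=osc)
    asym, asym_osc = _asymptotically_unstable(C, cfg.asymptotic_tol)
    if asym:
        return DynamicalClass(PATTERN_FORMING, marginal=marginal, oscillatory=asym_osc)
    return DynamicalClass(STABLE, marginal=marginal)
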
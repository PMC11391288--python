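"""Connectivity (linearized dispersal-response) matrices.

The connectivity matrix C collects the derivatives of each species'
emigration rate with respect to local densities, evaluated at the
homogeneous equilibrium.  Diagonal entries are strictly positive
(mass-action diffusion); an off-diagonal entry C[i, j] — species i's
dispersal response to species j — is only permitted where i and j share
a feeding link.  Under the adaptive sign constraint

    sgn(C[i, j]) = -sgn(P[i, j]),   i != j,

responses encode prey tracking (a consumer leaves patches where its prey
is scarce) and predator avoidance (prey leave patches where predators
are dense).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .motifs import MotifTopology

__all__ = [
    "CrossPositionSet",
    "ConnectivityMatrix",
    "DispersalConfig",
    "cross_positions",
    "enumerate_subsets",
    "sign_pattern",
    "sample_connectivity",
    "connectivity_to_row",
]


@dataclass(frozen=True)
class CrossPositionSet:
    """Off-diagonal (i, j) slots where a dispersal response is allowed."""

    positions: tuple[tuple[int, int], ...]

    @property
    def n_cross(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One sampled connectivity matrix with its active cross positions."""

    C: np.ndarray
    constrained: bool
    active_positions: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class DispersalConfig:
    """Scales of the uniform magnitude distributions for C entries.

    Diagonals are drawn from U(0, diag_scale] (strictly positive),
    off-diagonal magnitudes from U(0, off_scale), matching the
    Bern(q) * U(-1, 1) convention used for large random webs.
    """

    diag_scale: float = 1.0
    off_scale: float = 1.0


def cross_positions(motif: MotifTopology) -> CrossPositionSet:
    """Both orientations of every feeding link, sorted by (i, j)."""
    pos = set()
    for p, c in motif.links:
        pos.add((p, c))
        pos.add((c, p))
    return CrossPositionSet(positions=tuple(sorted(pos)))


def enumerate_subsets(
    positions: CrossPositionSet, n_cross: int
) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All size-``n_cross`` combinations of positions, deterministic order."""
    if not 0 <= n_cross <= positions.n_cross:
        raise ValueError(
            f"n_cross={n_cross} out of range [0, {positions.n_cross}]"
        )
    return tuple(itertools.combinations(positions.positions, n_cross))


def sign_pattern(motif: MotifTopology) -> np.ndarray:
    """Off-diagonal sign pattern of the local Jacobian implied by the motif.

    For every feeding link (prey p, predator c) the type-II interaction
    terms force P[c, p] > 0 and P[p, c] < 0 at any feasible equilibrium.
    """
    n = motif.n_species
    S = np.zeros((n, n), dtype=np.int8)
    for p, c in motif.links:
        S[c, p] = 1
        S[p, c] = -1
    return S


def sample_connectivity(
    P_signs: np.ndarray,
    subset: tuple[tuple[int, int], ...],
    constrained: bool,
    rng: np.random.Generator,
    config: DispersalConfig | None = None,
) -> ConnectivityMatrix:
    """Draw one connectivity matrix on the given active positions.

    Magnitudes are drawn before signs, and the sign draw is consumed from
    the stream whether or not the constraint applies; with a matched
    generator state, constrained and unconstrained draws therefore share
    all magnitudes and differ only in off-diagonal signs.
    """
    cfg = config or DispersalConfig()
    P_signs = np.asarray(P_signs)
    n = P_signs.shape[0]
    for i, j in subset:
        if i == j or P_signs[i, j] == 0:
            raise ValueError(
                f"position ({i}, {j}) does not correspond to a feeding link"
            )
    C = np.zeros((n, n))
    C[np.diag_indices(n)] = cfg.diag_scale * (1.0 - rng.random(n))  # (0, scale]
    mags = cfg.off_scale * rng.random(len(subset))
    sign_u = rng.random(len(subset))
    for k, (i, j) in enumerate(subset):
        if constrained:
            sign = -float(P_signs[i, j])
        else:
            sign = 1.0 if sign_u[k] < 0.5 else -1.0
        C[i, j] = sign * mags[k]
    return ConnectivityMatrix(C=C, constrained=constrained, active_positions=tuple(subset))


def connectivity_to_row(cm: ConnectivityMatrix, **meta) -> dict:
    """Flatten a connectivity draw (plus metadata) to a CSV row."""
    row: dict[str, object] = dict(meta)
    n = cm.C.shape[0]
    for i in range(n):
        for j in range(n):
            row[f"C_{i}_{j}"] = cm.C[i, j]
    row["constrained"] = cm.constrained
    row["active_positions"] = ";".join(f"{i},{j}" for i, j in cm.active_positions)
    return row
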
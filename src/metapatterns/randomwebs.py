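"""Niche-model random food webs and Jacobian-level metacommunity scans.

For communities larger than three species the local dynamics are
represented directly at the Jacobian level: a niche-model topology
(Williams--Martinez construction) determines which entries of P are
nonzero, consumer-side entries are drawn from a folded normal |N(0,
sigma)|, resource-side entries from its negative, and the diagonal is
fixed at -1 (self-regulation).  Connectivity matrices get an
interspecific response at each trophic link independently with
probability q, with magnitude U(-1, 1) and the sign optionally
constrained to oppose the corresponding Jacobian entry (prey tracking /
predator avoidance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .stability import PATTERN_FORMING, StabilityConfig, classify

__all__ = [
    "NicheWeb",
    "RandomJacobian",
    "RandomConnectivity",
    "niche_topology",
    "random_web_jacobian",
    "random_web_connectivity",
    "scan_Nq",
    "web_to_edgelist",
]


@dataclass(frozen=True)
class NicheWeb:
    """A connected niche-model topology.

    ``links`` are (consumer, resource) pairs.  ``attempts`` counts how
    many topologies were drawn before a connected one appeared.
    """

    N: int
    niche: np.ndarray
    range_: np.ndarray
    centre: np.ndarray
    links: tuple[tuple[int, int], ...]
    target_connectance: float
    attempts: int = 1


@dataclass(frozen=True)
class RandomJacobian:
    P: np.ndarray
    sigma: float


@dataclass(frozen=True)
class RandomConnectivity:
    C: np.ndarray
    q: float
    constrained: bool


def _raw_niche_draw(
    N: int, target_connectance: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, set[tuple[int, int]]]:
    """One unconditioned niche-model draw (may be disconnected).

    Niche values are U(0, 1); feeding-range widths are n_i * x with
    x ~ Beta(1, beta) and beta = 1/(2 C0) - 1, which tunes the expected
    connectance (links / N^2) to C0; range centres are U(r_i/2, n_i).
    The species with the smallest niche value gets range 0, guaranteeing
    a basal species.  Potential cannibalistic self-links are ignored.
    """
    niche = rng.uniform(0.0, 1.0, size=N)
    beta = 1.0 / (2.0 * target_connectance) - 1.0
    width = niche * rng.beta(1.0, beta, size=N)
    width[np.argmin(niche)] = 0.0
    centre = rng.uniform(width / 2.0, niche)
    links: set[tuple[int, int]] = set()
    for i in range(N):
        if width[i] <= 0:
            continue
        lo, hi = centre[i] - width[i] / 2.0, centre[i] + width[i] / 2.0
        for j in range(N):
            if j != i and lo <= niche[j] <= hi:
                links.add((i, j))
    # Mutual designations would collide on the Jacobian sign pattern;
    # keep the direction whose consumer sits higher on the niche axis.
    for (i, j) in [l for l in links]:
        if (j, i) in links and (i, j) in links and niche[i] < niche[j]:
            links.discard((i, j))
    return niche, width, centre, links


def _is_connected(N: int, links: set[tuple[int, int]]) -> bool:
    if not links:
        return N == 1
    rows = [i for i, j in links] + [j for i, j in links]
    cols = [j for i, j in links] + [i for i, j in links]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(N, N))
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def niche_topology(
    N: int,
    target_connectance: float,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> NicheWeb:
    """Draw a connected niche-model web, regenerating until connected."""
    if N < 2:
        raise ValueError("a food web needs at least 2 species")
    if not 0.0 < target_connectance < 0.5:
        raise ValueError("target_connectance must lie in (0, 0.5)")
    for attempt in range(1, max_attempts + 1):
        niche, width, centre, links = _raw_niche_draw(N, target_connectance, rng)
        if _is_connected(N, links):
            return NicheWeb(
                N=N,
                niche=niche,
                range_=width,
                centre=centre,
                links=tuple(sorted(links)),
                target_connectance=target_connectance,
                attempts=attempt,
            )
    raise RuntimeError(
        f"no connected web in {max_attempts} attempts "
        f"(N={N}, connectance={target_connectance})"
    )


def random_web_jacobian(
    web: NicheWeb, sigma: float, rng: np.random.Generator
) -> RandomJacobian:
    """Random Jacobian on the web's sign structure; diagonal fixed at -1."""
    P = -np.eye(web.N)
    for consumer, resource in web.links:
        P[consumer, resource] = abs(rng.normal(0.0, sigma))
        P[resource, consumer] = -abs(rng.normal(0.0, sigma))
    return RandomJacobian(P=P, sigma=sigma)


def _offdiag_positions(P: np.ndarray) -> list[tuple[int, int]]:
    pos = np.argwhere(P != 0)
    return sorted((int(i), int(j)) for i, j in pos if i != j)


def _connectivity_from_draws(
    P: np.ndarray,
    positions: Sequence[tuple[int, int]],
    diag: np.ndarray,
    active: np.ndarray,
    values: np.ndarray,
    constrained: bool,
) -> np.ndarray:
    """Assemble C from pre-drawn diagonal, Bernoulli mask and U(-1,1) values."""
    C = np.diag(diag)
    for k, (i, j) in enumerate(positions):
        if not active[k]:
            continue
        if constrained:
            C[i, j] = -np.sign(P[i, j]) * abs(values[k])
        else:
            C[i, j] = values[k]
    return C


def random_web_connectivity(
    web: NicheWeb,
    P: np.ndarray,
    q: float,
    constrained: bool,
    rng: np.random.Generator,
) -> RandomConnectivity:
    """Connectivity draw: diagonal U(0,1], off-diagonals Bern(q)*U(-1,1).

    Signs are applied after all magnitudes and Bernoulli outcomes are
    drawn, so matched generator states give constrained and
    unconstrained draws that differ only in signs.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    positions = _offdiag_positions(P)
    diag = 1.0 - rng.random(web.N)  # (0, 1]
    active = rng.random(len(positions)) < q
    values = rng.uniform(-1.0, 1.0, size=len(positions))
    C = _connectivity_from_draws(P, positions, diag, active, values, constrained)
    return RandomConnectivity(C=C, q=q, constrained=constrained)


def scan_Nq(
    N_values: Sequence[int],
    q_values: Sequence[float],
    reps: int = 200,
    constrained: bool = False,
    *,
    sigma: float = 0.5,
    target_connectance: float = 0.15,
    seed: int = 0,
    stability_config: StabilityConfig | None = None,
) -> pd.DataFrame:
    """Pattern-forming robustness over web size N and response prevalence q.

    Per replicate one web and Jacobian are drawn; locally unstable draws
    are excluded (so omega_pf may reach 1 among kept draws).  The same
    replicate's Bernoulli variates and magnitudes are reused across all
    q values (a response active at q stays active at q' > q) and across
    the constraint flag, giving paired comparisons in both q and the
    constraint.  Cells with no locally stable draw report NaN.

    Returns a DataFrame with columns (N, q, constrained, reps_kept,
    reps_total, omega_pf, seed).
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    cfg = stability_config or StabilityConfig()
    q_values = [float(q) for q in q_values]
    rows = []
    for iN, N in enumerate(N_values):
        kept = 0
        pf_counts = np.zeros(len(q_values), dtype=int)
        for rep in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 2, iN, rep]))
            web = niche_topology(N, target_connectance, rng)
            P = random_web_jacobian(web, sigma, rng).P
            positions = _offdiag_positions(P)
            diag = 1.0 - rng.random(N)
            u_bern = rng.random(len(positions))
            values = rng.uniform(-1.0, 1.0, size=len(positions))
            if np.linalg.eigvals(P).real.max() > cfg.zero_tol:
                continue  # locally unstable; draws above keep streams matched
            kept += 1
            for iq, q in enumerate(q_values):
                C = _connectivity_from_draws(
                    P, positions, diag, u_bern < q, values, constrained
                )
                if classify(P, C, cfg).label == PATTERN_FORMING:
                    pf_counts[iq] += 1
        for iq, q in enumerate(q_values):
            rows.append(
                {
                    "N": N,
                    "q": q,
                    "constrained": constrained,
                    "reps_kept": kept,
                    "reps_total": reps,
                    "omega_pf": pf_counts[iq] / kept if kept else np.nan,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def web_to_edgelist(web: NicheWeb) -> str:
    """Two-column consumer,resource text representation of a web."""
    return "\n".join(f"{c},{r}" for c, r in web.links) + "\n"
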
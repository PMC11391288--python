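"""Food-web motifs: topology, local dynamics, equilibria and Jacobians.

The within-patch community model is a generalized Rosenzweig--MacArthur
system: primary producers grow logistically, consumers feed through
saturating (type-II) functional responses and suffer density-dependent
mortality.  For species ``i`` with density ``x_i``,

    f_i(x) = x_i * [ r_i (1 - x_i / K_i)
                     - sum over links (i prey of c)  A x_c / (B + x_i)
                     + sum over links (p prey of i)  e A x_p / (B + x_p)
                     - d_i x_i ],

where each feeding link (prey ``p``, consumer ``c``) carries an attack
rate ``A``, a half-saturation constant ``B`` and a conversion efficiency
``e``.  Producers have ``d = 0``; consumers have ``r = 0`` and no
carrying capacity.

The four canonical three-species motifs (food chain, apparent
competition, resource competition, intraguild predation) are built by
:func:`build_motif`; arbitrary topologies (e.g. a two-species chain) can
be constructed directly through :class:`MotifTopology`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "PRODUCER",
    "INTERMEDIATE_CONSUMER",
    "TOP_CONSUMER",
    "MOTIF_NAMES",
    "MotifTopology",
    "LocalParameters",
    "Equilibrium",
    "LocalJacobian",
    "EquilibriumConfig",
    "DEFAULT_SAMPLING_RANGES",
    "build_motif",
    "local_rhs",
    "dynamics_jacobian",
    "find_equilibrium",
    "local_jacobian",
    "sample_local_parameters",
    "sample_feasible_parameters",
    "permute_parameters",
]

PRODUCER = "producer"
INTERMEDIATE_CONSUMER = "intermediate_consumer"
TOP_CONSUMER = "top_consumer"

MOTIF_NAMES = (
    "food_chain",
    "apparent_competition",
    "resource_competition",
    "intraguild_predation",
)

# Canonical link sets, 0-based (prey, predator).  Species 0 is always a
# producer; species are ordered producers first, then ascending trophic
# position.
_MOTIF_LINKS: dict[str, tuple[tuple[int, int], ...]] = {
    "food_chain": ((0, 1), (1, 2)),
    "apparent_competition": ((0, 2), (1, 2)),
    "resource_competition": ((0, 1), (0, 2)),
    "intraguild_predation": ((0, 1), (0, 2), (1, 2)),
}


@dataclass(frozen=True)
class MotifTopology:
    """A directed feeding structure on a small community.

    ``links`` are (prey, predator) pairs with 0-based species indices;
    ``roles`` label each species as producer, intermediate consumer
    (a consumer that is itself preyed upon) or top consumer.
    """

    name: str
    links: tuple[tuple[int, int], ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.roles)
        preds = {c for _, c in self.links}
        prey = {p for p, _ in self.links}
        for p, c in self.links:
            if not (0 <= p < n and 0 <= c < n) or p == c:
                raise ValueError(f"invalid link ({p}, {c}) for {n} species")
        if prey | preds != set(range(n)):
            raise ValueError("every species must appear in at least one link")
        if not self._weakly_connected():
            raise ValueError("feeding graph must be weakly connected")
        for i, role in enumerate(self.roles):
            if role == PRODUCER and i in preds:
                raise ValueError(f"producer {i} cannot be a predator")
            if role != PRODUCER and i not in preds:
                raise ValueError(f"consumer {i} must have at least one prey")

    def _weakly_connected(self) -> bool:
        n = len(self.roles)
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for p, c in self.links:
            adj[p].add(c)
            adj[c].add(p)
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    @property
    def n_species(self) -> int:
        return len(self.roles)

    @property
    def producers(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.roles) if r == PRODUCER)

    @property
    def consumers(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.roles) if r != PRODUCER)

    def predators_of(self, i: int) -> tuple[int, ...]:
        return tuple(c for p, c in self.links if p == i)

    def prey_of(self, i: int) -> tuple[int, ...]:
        return tuple(p for p, c in self.links if c == i)


def build_motif(name: str) -> MotifTopology:
    """Return one of the four canonical three-species motifs by name."""
    if name not in _MOTIF_LINKS:
        raise ValueError(
            f"unknown motif {name!r}; valid names are: " + ", ".join(MOTIF_NAMES)
        )
    links = _MOTIF_LINKS[name]
    preds = {c for _, c in links}
    prey = {p for p, _ in links}
    roles = []
    for i in range(3):
        if i not in preds:
            roles.append(PRODUCER)
        elif i in prey:
            roles.append(INTERMEDIATE_CONSUMER)
        else:
            roles.append(TOP_CONSUMER)
    return MotifTopology(name=name, links=links, roles=tuple(roles))


@dataclass(frozen=True)
class LocalParameters:
    """One concrete parameterization of the local dynamics.

    Arrays are indexed by species; ``r`` and ``K`` are zero / NaN for
    consumers, ``d`` is zero for producers.  ``A``, ``B`` and ``e`` are
    keyed by feeding link (prey, predator).
    """

    motif: MotifTopology
    r: np.ndarray
    K: np.ndarray
    d: np.ndarray
    A: Mapping[tuple[int, int], float]
    B: Mapping[tuple[int, int], float]
    e: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        n = self.motif.n_species
        for arr_name in ("r", "K", "d"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{arr_name} must have shape ({n},)")
            object.__setattr__(self, arr_name, arr)
        links = set(self.motif.links)
        for tbl_name in ("A", "B", "e"):
            tbl = getattr(self, tbl_name)
            if set(tbl) != links:
                raise ValueError(f"{tbl_name} must be keyed by the motif links")
        for i in self.motif.producers:
            if not (self.r[i] > 0 and self.K[i] > 0):
                raise ValueError("producers need r > 0 and K > 0")
            if self.d[i] != 0:
                raise ValueError("producers have no mortality coefficient")
        for i in self.motif.consumers:
            if self.r[i] != 0 or np.isfinite(self.K[i]):
                raise ValueError("consumers have r = 0 and undefined K")
            if not self.d[i] > 0:
                raise ValueError("consumers need d > 0")
        for link in links:
            if not (self.A[link] > 0 and self.B[link] > 0):
                raise ValueError("A and B must be strictly positive")
            if not (0 < self.e[link] <= 1):
                raise ValueError("conversion efficiency e must lie in (0, 1]")


@dataclass(frozen=True)
class Equilibrium:
    """A candidate spatially homogeneous steady state."""

    x_star: np.ndarray
    feasible: bool
    residual: float
    multiplicity: int = 1


@dataclass(frozen=True)
class LocalJacobian:
    """Linearization P of the local dynamics at the equilibrium."""

    P: np.ndarray


@dataclass(frozen=True)
class EquilibriumConfig:
    """Multi-start root-search settings for the coexistence state."""

    n_starts: int = 8
    seed: int = 0
    start_low: float = 1e-3
    x_floor: float = 1e-6
    residual_tol: float = 1e-9
    distinct_tol: float = 1e-4


#: Default uniform sampling ranges (low, high) per parameter class.  They
#: span standard Rosenzweig--MacArthur regimes, covering both locally
#: stable and oscillatory communities.
DEFAULT_SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "r": (0.5, 2.0),
    "K": (1.0, 10.0),
    "A": (0.5, 5.0),
    "B": (0.5, 5.0),
    "e": (0.1, 1.0),
    "d": (0.05, 1.0),
}


def _per_capita(params: LocalParameters, x: np.ndarray) -> np.ndarray:
    """Per-capita growth rates g with f(x) = x * g(x)."""
    m = params.motif
    g = np.zeros(m.n_species)
    for i in m.producers:
        g[i] = params.r[i] * (1.0 - x[i] / params.K[i])
    for link in m.links:
        p, c = link
        a, b, e = params.A[link], params.B[link], params.e[link]
        g[p] -= a * x[c] / (b + x[p])
        g[c] += e * a * x[p] / (b + x[p])
    g -= params.d * x
    return g


def local_rhs(params: LocalParameters, x: Sequence[float]) -> np.ndarray:
    """Evaluate the local growth rates f(x).

    Raises if any density is negative: the model is undefined there.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.motif.n_species,):
        raise ValueError("density vector has wrong length")
    if np.any(x < 0):
        raise ValueError("densities must be non-negative")
    return x * _per_capita(params, x)


def _per_capita_jacobian(params: LocalParameters, x: np.ndarray) -> np.ndarray:
    """dg_i/dx_j for the per-capita rates."""
    m = params.motif
    n = m.n_species
    G = np.zeros((n, n))
    for i in m.producers:
        G[i, i] -= params.r[i] / params.K[i]
    for i in range(n):
        G[i, i] -= params.d[i]
    for link in m.links:
        p, c = link
        a, b, e = params.A[link], params.B[link], params.e[link]
        G[p, p] += a * x[c] / (b + x[p]) ** 2
        G[p, c] -= a / (b + x[p])
        G[c, p] += e * a * b / (b + x[p]) ** 2
    return G


def dynamics_jacobian(params: LocalParameters, x: Sequence[float]) -> np.ndarray:
    """Analytic Jacobian df_i/dx_j of the local dynamics at any state."""
    x = np.asarray(x, dtype=float)
    g = _per_capita(params, x)
    G = _per_capita_jacobian(params, x)
    return np.diag(g) + x[:, None] * G


def find_equilibrium(
    params: LocalParameters, config: EquilibriumConfig | None = None
) -> Equilibrium:
    """Search for a coexistence steady state with all densities positive.

    Interior equilibria are roots of the per-capita rates g(x); the search
    runs a damped-hybrid root finder from several log-uniform random
    starting points.  Non-convergence is not an error: it yields
    ``feasible=False``.  If several distinct feasible roots are found the
    first is kept and the count recorded in ``multiplicity``.
    """
    cfg = config or EquilibriumConfig()
    m = params.motif
    n = m.n_species
    high = float(np.nanmax(params.K))
    rng = np.random.default_rng(cfg.seed)
    log_lo, log_hi = math.log10(cfg.start_low), math.log10(high)
    feasible_roots: list[np.ndarray] = []
    best_x: np.ndarray | None = None
    best_res = math.inf
    for _ in range(cfg.n_starts):
        x0 = 10.0 ** rng.uniform(log_lo, log_hi, size=n)
        sol = optimize.root(
            lambda x: _per_capita(params, x),
            x0,
            jac=lambda x: _per_capita_jacobian(params, x),
            method="hybr",
            options={"xtol": 1e-12},
        )
        if not sol.success:
            continue
        x = np.asarray(sol.x)
        with np.errstate(all="ignore"):
            res = float(np.max(np.abs(x * _per_capita(params, x))))
        if not math.isfinite(res):
            continue
        if np.all(x > cfg.x_floor) and res < cfg.residual_tol:
            if not any(
                np.max(np.abs(x - r)) <= cfg.distinct_tol for r in feasible_roots
            ):
                feasible_roots.append(x)
        if res < best_res:
            best_res, best_x = res, x
    if feasible_roots:
        x = feasible_roots[0]
        res = float(np.max(np.abs(local_rhs(params, x))))
        return Equilibrium(x, True, res, multiplicity=len(feasible_roots))
    if best_x is None:
        return Equilibrium(np.full(n, np.nan), False, math.inf)
    return Equilibrium(best_x, False, best_res)


def local_jacobian(params: LocalParameters, eq: Equilibrium) -> LocalJacobian:
    """Analytic Jacobian P at a feasible equilibrium."""
    if not eq.feasible:
        raise ValueError("local Jacobian requires a feasible equilibrium")
    return LocalJacobian(dynamics_jacobian(params, eq.x_star))


def _check_ranges(ranges: Mapping[str, tuple[float, float]]) -> None:
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"range for {name!r} has lower >= upper: ({lo}, {hi})")


def sample_local_parameters(
    motif: MotifTopology,
    rng: np.random.Generator,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> LocalParameters:
    """Draw one parameterization with each class uniform on its range.

    The draw order (producers, then links, then consumers, each in index
    order) is fixed, so a given generator state yields a reproducible set.
    """
    rr = dict(DEFAULT_SAMPLING_RANGES)
    if ranges:
        rr.update(ranges)
    _check_ranges(rr)
    n = motif.n_species
    r = np.zeros(n)
    K = np.full(n, np.nan)
    d = np.zeros(n)
    for i in motif.producers:
        r[i] = rng.uniform(*rr["r"])
        K[i] = rng.uniform(*rr["K"])
    A, B, e = {}, {}, {}
    for link in motif.links:
        A[link] = rng.uniform(*rr["A"])
        B[link] = rng.uniform(*rr["B"])
        e[link] = rng.uniform(*rr["e"])
    for i in motif.consumers:
        d[i] = rng.uniform(*rr["d"])
    return LocalParameters(motif=motif, r=r, K=K, d=d, A=A, B=B, e=e)


def sample_feasible_parameters(
    motif: MotifTopology,
    rng: np.random.Generator,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    eq_config: EquilibriumConfig | None = None,
    max_tries: int = 100,
) -> tuple[LocalParameters, Equilibrium, int]:
    """Redraw parameters until a feasible coexistence equilibrium is found.

    Returns (parameters, equilibrium, number of discarded draws).  Raises
    if ``max_tries`` draws in a row are infeasible, which flags a
    degenerate sampling configuration.
    """
    for tries in range(max_tries):
        params = sample_local_parameters(motif, rng, ranges)
        eq = find_equilibrium(params, eq_config)
        if eq.feasible:
            return params, eq, tries
    raise RuntimeError(
        f"no feasible equilibrium in {max_tries} draws for motif {motif.name!r}"
    )


def permute_parameters(params: LocalParameters, perm: Sequence[int]) -> LocalParameters:
    """Relabel species by ``perm`` (new index of old species i is perm[i])."""
    perm = list(perm)
    m = params.motif
    n = m.n_species
    inv = np.argsort(perm)
    links = tuple(sorted((perm[p], perm[c]) for p, c in m.links))
    roles = tuple(m.roles[inv[i]] for i in range(n))
    motif = MotifTopology(name=m.name + "_permuted", links=links, roles=roles)
    remap = lambda tbl: {(perm[p], perm[c]): v for (p, c), v in tbl.items()}
    return LocalParameters(
        motif=motif,
        r=params.r[inv],
        K=params.K[inv],
        d=params.d[inv],
        A=remap(params.A),
        B=remap(params.B),
        e=remap(params.e),
    )


def parameters_to_row(params: LocalParameters, eq: Equilibrium | None = None) -> dict:
    """Flatten a parameter draw (and optional equilibrium) to a CSV row."""
    row: dict[str, object] = {"motif": params.motif.name}
    for i in range(params.motif.n_species):
        row[f"r_{i}"] = params.r[i]
        row[f"K_{i}"] = params.K[i]
        row[f"d_{i}"] = params.d[i]
    for (p, c) in params.motif.links:
        for tbl_name in ("A", "B", "e"):
            row[f"{tbl_name}_{p}_{c}"] = getattr(params, tbl_name)[(p, c)]
    if eq is not None:
        for i, v in enumerate(eq.x_star):
            row[f"x_star_{i}"] = v
        row["feasible"] = eq.feasible
        row["residual"] = eq.residual
        row["multiplicity"] = eq.multiplicity
    return row
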
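"""Monte-Carlo robustness of the three dynamical classes.

Robustness measures the fraction of parameter space yielding a given
outcome.  A grid crosses n_P feasible local parameterizations (rows)
with n_C connectivity draws (columns) and classifies every pair:

* total robustness omega(P, C) — fraction of all cells with a label;
* local robustness omega(P)    — per connectivity draw, the fraction of
  local parameterizations with the label (one value per column);
* spatial robustness omega(C)  — per local parameterization, the
  fraction of connectivity draws with the label (one value per row).

On a full grid the means of the local and spatial distributions both
equal the total robustness exactly, so variance and skewness of either
distribution are taken about this shared mean.  Following the
figure-level conventions of the analysis, moment summaries condition on
local stability (locally unstable rows excluded).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _fast3
from .dispersal import (
    DispersalConfig,
    cross_positions,
    enumerate_subsets,
    sample_connectivity,
    sign_pattern,
)
from .motifs import (
    EquilibriumConfig,
    MotifTopology,
    build_motif,
    local_jacobian,
    sample_feasible_parameters,
)
from .stability import (
    CODE_LABELS,
    LABEL_CODES,
    PATTERN_FORMING,
    STABLE,
    UNSTABLE,
    StabilityConfig,
    _asymptotically_unstable,
    _scan_first_positive,
)

__all__ = [
    "RobustnessGrid",
    "RobustnessSummary",
    "MomentSummary",
    "LocalEnsemble",
    "draw_local_ensemble",
    "build_grid",
    "total_robustness",
    "local_robustness_distribution",
    "spatial_robustness_distribution",
    "moments",
    "exclude_unstable",
    "scan_motif",
    "average_over_subsets",
]


@dataclass(frozen=True)
class RobustnessGrid:
    """Classification outcomes over one P-draw x C-draw grid."""

    labels: np.ndarray  # uint8 codes, shape (n_P, n_C)
    motif: MotifTopology
    subset: tuple[tuple[int, int], ...]
    constrained: bool
    n_discarded: int = 0
    n_marginal: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_P(self) -> int:
        return self.labels.shape[0]

    @property
    def n_C(self) -> int:
        return self.labels.shape[1]


@dataclass(frozen=True)
class RobustnessSummary:
    """Total robustness of each class; the three fractions sum to one."""

    omega_st: float
    omega_us: float
    omega_pf: float


@dataclass(frozen=True)
class MomentSummary:
    """Variance and skewness of the robustness distributions.

    Both distributions come from the same grid and share their mean (the
    total robustness); central moments are taken about it.  Skewness is
    the third central moment standardized by variance**1.5, reported as
    zero for (near-)constant distributions.
    """

    shared_mean: float
    variance_local: float
    variance_spatial: float
    skew_local: float
    skew_spatial: float


@dataclass(frozen=True)
class LocalEnsemble:
    """Feasible local parameterizations with Jacobians, reusable across grids."""

    motif: MotifTopology
    params: tuple
    equilibria: tuple
    P_stack: np.ndarray  # (n_P, N, N)
    lam0: np.ndarray  # spectral abscissa of each P
    n_discarded: int


def draw_local_ensemble(
    motif: MotifTopology | str,
    n_P: int,
    rng: np.random.Generator,
    *,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    eq_config: EquilibriumConfig | None = None,
    max_discard_frac: float = 0.99,
) -> LocalEnsemble:
    """Draw ``n_P`` feasible local systems, conditioning on coexistence.

    Infeasible draws are discarded and redrawn; exhausting the per-draw
    retry budget implied by ``max_discard_frac`` raises, flagging a
    degenerate sampling configuration.
    """
    if isinstance(motif, str):
        motif = build_motif(motif)
    max_tries = max(2, int(round(1.0 / max(1e-12, 1.0 - max_discard_frac))))
    params_list, eq_list, P_list = [], [], []
    discarded = 0
    for _ in range(n_P):
        params, eq, n_disc = sample_feasible_parameters(
            motif, rng, ranges, eq_config, max_tries=max_tries
        )
        discarded += n_disc
        params_list.append(params)
        eq_list.append(eq)
        P_list.append(local_jacobian(params, eq).P)
    P_stack = np.stack(P_list)
    lam0 = np.array([np.linalg.eigvals(P).real.max() for P in P_list])
    return LocalEnsemble(
        motif=motif,
        params=tuple(params_list),
        equilibria=tuple(eq_list),
        P_stack=P_stack,
        lam0=lam0,
        n_discarded=discarded,
    )


def _classify_grid(
    P_stack: np.ndarray,
    lam0: np.ndarray,
    C_stack: np.ndarray,
    config: StabilityConfig,
) -> np.ndarray:
    """uint8 label codes for all (P, C) pairs under one stability config."""
    tol = config.zero_tol
    unstable_row = lam0 > tol
    asym_col = np.array(
        [_asymptotically_unstable(C, config.asymptotic_tol)[0] for C in C_stack]
    )
    kappas = config.kappa_grid[1:]
    if P_stack.shape[1] == 3:
        return _fast3.classify_pairs_3x3(
            P_stack, C_stack, kappas, unstable_row, asym_col, tol
        )
    labels = np.zeros((P_stack.shape[0], C_stack.shape[0]), dtype=np.uint8)
    for i in range(P_stack.shape[0]):
        if unstable_row[i]:
            labels[i, :] = LABEL_CODES[UNSTABLE]
            continue
        for j in range(C_stack.shape[0]):
            if asym_col[j]:
                labels[i, j] = LABEL_CODES[PATTERN_FORMING]
                continue
            idx, _ = _scan_first_positive(P_stack[i], C_stack[j], kappas, tol)
            if idx >= 0:
                labels[i, j] = LABEL_CODES[PATTERN_FORMING]
    return labels


def build_grid(
    motif: MotifTopology | str,
    subset: tuple[tuple[int, int], ...],
    constrained: bool,
    n_P: int,
    n_C: int,
    rng: np.random.Generator,
    *,
    local_ensemble: LocalEnsemble | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    dispersal_config: DispersalConfig | None = None,
    stability_config: StabilityConfig | None = None,
    eq_config: EquilibriumConfig | None = None,
    max_discard_frac: float = 0.99,
) -> RobustnessGrid:
    """Classify all pairs of n_P local draws x n_C connectivity draws.

    A precomputed :class:`LocalEnsemble` may be supplied to share local
    draws across subsets and constraint flags (which also makes the
    unstable fraction identical across those runs); otherwise the local
    draws are taken from ``rng`` before the connectivity draws.
    """
    if isinstance(motif, str):
        motif = build_motif(motif)
    if n_P < 1 or n_C < 1:
        raise ValueError("n_P and n_C must be at least 1")
    cfg = stability_config or StabilityConfig()
    if local_ensemble is None:
        local_ensemble = draw_local_ensemble(
            motif,
            n_P,
            rng,
            ranges=ranges,
            eq_config=eq_config,
            max_discard_frac=max_discard_frac,
        )
    elif local_ensemble.P_stack.shape[0] != n_P:
        raise ValueError("local ensemble size does not match n_P")
    S = sign_pattern(motif)
    C_stack = np.stack(
        [
            sample_connectivity(S, subset, constrained, rng, dispersal_config).C
            for _ in range(n_C)
        ]
    )
    labels = _classify_grid(local_ensemble.P_stack, local_ensemble.lam0, C_stack, cfg)
    n_marginal = int(np.sum(np.abs(local_ensemble.lam0) <= cfg.zero_tol))
    return RobustnessGrid(
        labels=labels,
        motif=motif,
        subset=tuple(subset),
        constrained=constrained,
        n_discarded=local_ensemble.n_discarded,
        n_marginal=n_marginal,
    )


def total_robustness(grid: RobustnessGrid) -> RobustnessSummary:
    """Fractions of the grid in each class (they partition the grid)."""
    size = grid.labels.size
    counts = np.bincount(grid.labels.ravel(), minlength=3)
    return RobustnessSummary(
        omega_st=counts[LABEL_CODES[STABLE]] / size,
        omega_us=counts[LABEL_CODES[UNSTABLE]] / size,
        omega_pf=counts[LABEL_CODES[PATTERN_FORMING]] / size,
    )


def _code(label: str) -> int:
    if label not in LABEL_CODES:
        raise ValueError(f"unknown class label {label!r}")
    return LABEL_CODES[label]


def local_robustness_distribution(grid: RobustnessGrid, label: str) -> np.ndarray:
    """omega(P) per connectivity draw: column means of the class indicator."""
    return (grid.labels == _code(label)).mean(axis=0)


def spatial_robustness_distribution(grid: RobustnessGrid, label: str) -> np.ndarray:
    """omega(C) per local draw: row means of the class indicator."""
    return (grid.labels == _code(label)).mean(axis=1)


def moments(
    local_dist: np.ndarray,
    spatial_dist: np.ndarray,
    variance_floor: float = 1e-12,
) -> MomentSummary:
    """Second and third central moments about the shared (grand) mean."""
    local_dist = np.asarray(local_dist, dtype=float)
    spatial_dist = np.asarray(spatial_dist, dtype=float)
    mean = local_dist.mean()
    if abs(mean - spatial_dist.mean()) > 1e-9:
        raise ValueError("distributions do not share a mean; not from one grid?")

    def _vs(dist: np.ndarray) -> tuple[float, float]:
        dev = dist - mean
        var = float(np.mean(dev**2))
        if var < variance_floor:
            return var, 0.0
        return var, float(np.mean(dev**3) / var**1.5)

    var_l, skew_l = _vs(local_dist)
    var_s, skew_s = _vs(spatial_dist)
    return MomentSummary(
        shared_mean=float(mean),
        variance_local=var_l,
        variance_spatial=var_s,
        skew_local=skew_l,
        skew_spatial=skew_s,
    )


def exclude_unstable(grid: RobustnessGrid) -> RobustnessGrid:
    """Drop locally unstable rows so omega_pf can reach one."""
    keep = ~np.any(grid.labels == LABEL_CODES[UNSTABLE], axis=1)
    if not keep.any():
        raise ValueError("all local parameterizations are unstable; empty grid")
    return replace(grid, labels=grid.labels[keep])


def _grid_row(grid: RobustnessGrid, n_cross: int, subset_id: int, seed: int) -> dict:
    summary = total_robustness(grid)
    row = {
        "motif": grid.motif.name,
        "n_cross": n_cross,
        "subset_id": subset_id,
        "constrained": grid.constrained,
        "omega_st": summary.omega_st,
        "omega_us": summary.omega_us,
        "omega_pf": summary.omega_pf,
        "n_P": grid.n_P,
        "n_C": grid.n_C,
        "seed": seed,
    }
    try:
        sub = exclude_unstable(grid)
        mom = moments(
            local_robustness_distribution(sub, PATTERN_FORMING),
            spatial_robustness_distribution(sub, PATTERN_FORMING),
        )
        row.update(
            n_P_kept=sub.n_P,
            variance_local=mom.variance_local,
            variance_spatial=mom.variance_spatial,
            skew_local=mom.skew_local,
            skew_spatial=mom.skew_spatial,
        )
    except ValueError:
        row.update(
            n_P_kept=0,
            variance_local=np.nan,
            variance_spatial=np.nan,
            skew_local=np.nan,
            skew_spatial=np.nan,
        )
    return row


def scan_motif(
    motif: MotifTopology | str,
    constrained: bool,
    n_P: int = 300,
    n_C: int = 300,
    seed: int = 0,
    *,
    n_cross_values: Sequence[int] | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    dispersal_config: DispersalConfig | None = None,
    stability_config: StabilityConfig | None = None,
    eq_config: EquilibriumConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Robustness scan over cross-diffusion prevalence for one motif.

    For each value of n_cross (default: 0 up to the motif maximum) every
    placement of that many interspecific dispersal responses is scanned
    with its own grid.  The local ensemble is drawn once per motif and
    shared by all grids; connectivity seeds depend on (seed, n_cross,
    subset) but not on the constraint flag, so constrained and
    unconstrained runs at the same seed have matched magnitudes.

    Returns a per-subset long-format DataFrame plus a run-info dict
    (discard counts, marginal counts, runtime).
    """
    if isinstance(motif, str):
        motif = build_motif(motif)
    t0 = time.perf_counter()
    rng_P = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    ensemble = draw_local_ensemble(
        motif, n_P, rng_P, ranges=ranges, eq_config=eq_config
    )
    cps = cross_positions(motif)
    if n_cross_values is None:
        n_cross_values = range(cps.n_cross + 1)
    rows = []
    for k in n_cross_values:
        for si, subset in enumerate(enumerate_subsets(cps, k)):
            rng_C = np.random.default_rng(np.random.SeedSequence([seed, 1, k, si]))
            grid = build_grid(
                motif,
                subset,
                constrained,
                n_P,
                n_C,
                rng_C,
                local_ensemble=ensemble,
                dispersal_config=dispersal_config,
                stability_config=stability_config,
            )
            rows.append(_grid_row(grid, k, si, seed))
    df = pd.DataFrame(rows)
    info = {
        "motif": motif.name,
        "constrained": constrained,
        "n_discarded": ensemble.n_discarded,
        "n_marginal": int(
            np.sum(np.abs(ensemble.lam0) <= (stability_config or StabilityConfig()).zero_tol)
        ),
        "runtime_s": time.perf_counter() - t0,
    }
    return df, info


def average_over_subsets(df: pd.DataFrame) -> pd.DataFrame:
    """Equal-weight average of subset rows per (motif, n_cross, constrained)."""
    value_cols = [
        c
        for c in (
            "omega_st",
            "omega_us",
            "omega_pf",
            "variance_local",
            "variance_spatial",
            "skew_local",
            "skew_spatial",
        )
        if c in df.columns
    ]
    out = (
        df.groupby(["motif", "n_cross", "constrained"], as_index=False)[value_cols]
        .mean()
        .sort_values(["motif", "n_cross"])
        .reset_index(drop=True)
    )
    return out
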
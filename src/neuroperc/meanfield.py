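"""Mean-field map of the activation density and the critical probability.

Annealed mean-field closure of the threshold dynamics: each vertex has its
4 short neighbors plus a Poisson(lambda) number of long neighbors, every
neighbor independently active with the current global density rho, so

    rho_{t+1} = F(rho) = E_{J ~ Poisson(lambda)} P(Binomial(4 + J, rho) >= k).

The critical probability p_c(lambda, k) is the interior unstable fixed
point of F — the basin boundary between extinction (rho -> 0) and full
activation (rho -> 1) — with sentinels 0 / 1 when no interior unstable
point exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MeanFieldModel",
    "MeanFieldSolution",
    "MonteCarloCritical",
    "mean_field_map",
    "fixed_points",
    "critical_probability",
    "phase_diagram",
    "monte_carlo_critical",
]

from .percolation import (
    LongEdgeModel,
    UpdateRule,
    build_graph,
    run_dynamics,
)


@dataclass(frozen=True)
class MeanFieldModel:
    """Mean-field parameters: expected long degree and activation threshold.

    The Poisson long-degree distribution is truncated at ``j_max`` chosen so
    the discarded tail mass is below ``tail_tol``; the kept weights are
    renormalized.
    """

    lam: float
    k: int
    tail_tol: float = 1e-12
    j_max: int = field(init=False)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.k < 1:
            raise ValueError(f"threshold k must be >= 1, got {self.k}")
        if self.lam == 0:
            j_max = 0
        else:
            j_max = int(stats.poisson.isf(self.tail_tol, self.lam))
            while stats.poisson.sf(j_max, self.lam) >= self.tail_tol:
                j_max += 1
        object.__setattr__(self, "j_max", j_max)

    def degree_weights(self) -> np.ndarray:
        """Renormalized truncated Poisson pmf over j = 0..j_max."""
        j = np.arange(self.j_max + 1)
        w = stats.poisson.pmf(j, self.lam) if self.lam > 0 else np.ones(1)
        return w / w.sum()


@dataclass(frozen=True)
class MeanFieldSolution:
    """Fixed points of F with stability labels, and the critical probability.

    ``fixed_points`` is sorted ascending in rho; ``p_c`` is the smallest
    interior unstable fixed point, or 0 (activation spreads from any
    positive density) / 1 (activation always dies) when none exists.
    ``multiple_interior_unstable`` flags the k > 4 regime where several
    basin boundaries can coexist.
    """

    fixed_points: tuple[tuple[float, str], ...]
    p_c: float
    multiple_interior_unstable: bool = False


def mean_field_map(rho, model: MeanFieldModel):
    """One mean-field iteration F(rho); accepts scalars or arrays."""
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any((rho_arr < 0) | (rho_arr > 1)):
        raise ValueError("rho must lie in [0, 1]")
    w = model.degree_weights()
    out = np.zeros_like(rho_arr)
    for j, wj in enumerate(w):
        # P(Binomial(4 + j, rho) >= k)
        out += wj * stats.binom.sf(model.k - 1, 4 + j, rho_arr)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(rho) else float(out[0])


def _slope(model: MeanFieldModel, rho: float, h: float = 1e-6) -> float:
    lo = max(0.0, rho - h)
    hi = min(1.0, rho + h)
    return (mean_field_map(hi, model) - mean_field_map(lo, model)) / (hi - lo)


def fixed_points(
    model: MeanFieldModel, tol: float = 1e-6, grid_size: int = 4001
) -> MeanFieldSolution:
    """Locate all fixed points of F on [0, 1] and classify their stability.

    Roots of g(rho) = F(rho) - rho are bracketed by a sign-change scan on a
    dense grid and polished by Brent's method to ``tol``; stability follows
    from the local slope of F (stable iff F'(rho*) < 1).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    grid = np.linspace(0.0, 1.0, grid_size)
    g = mean_field_map(grid, model) - grid

    roots = [0.0]  # F(0) = 0 always
    if abs(g[-1]) < 1e-13:
        roots.append(1.0)
    sign = np.sign(g)
    for i in range(1, grid_size - 1):
        a, b = grid[i], grid[i + 1]
        if sign[i] == 0.0 and grid[i] not in (0.0, 1.0):
            roots.append(float(grid[i]))
        elif sign[i] * sign[i + 1] < 0:
            r = optimize.brentq(
                lambda x: mean_field_map(x, model) - x, a, b, xtol=tol
            )
            roots.append(float(r))

    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or r - dedup[-1] > 10 * tol:
            dedup.append(r)

    labeled = tuple(
        (r, "stable" if _slope(model, r) < 1.0 else "unstable") for r in dedup
    )
    interior_unstable = [
        r for r, s in labeled if s == "unstable" and tol < r < 1.0 - tol
    ]
    if interior_unstable:
        p_c = interior_unstable[0]
    else:
        # no basin boundary: activation either always spreads or always dies,
        # decided by the stability of the extinct state rho = 0
        zero_stable = labeled[0][1] == "stable"
        p_c = 1.0 if zero_stable else 0.0
    return MeanFieldSolution(
        fixed_points=labeled,
        p_c=p_c,
        multiple_interior_unstable=len(interior_unstable) > 1,
    )


def critical_probability(model: MeanFieldModel, tol: float = 1e-6) -> float:
    """Critical initial density p_c(lambda, k) of the mean-field map."""
    return fixed_points(model, tol=tol).p_c


def phase_diagram(
    lam_grid, k_values, tol: float = 1e-6
) -> pd.DataFrame:
    """Tabulate p_c over a lambda grid for each threshold k.

    Returns a DataFrame with columns (lambda, k, p_c, n_fixed_points, flag);
    ``flag`` marks cells with multiple interior unstable fixed points.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size > 1 and np.any(np.diff(lam_grid) < 0):
        raise ValueError("lam_grid must be ascending")
    rows = []
    for k in k_values:
        for lam in lam_grid:
            sol = fixed_points(MeanFieldModel(lam=float(lam), k=int(k)), tol=tol)
            rows.append(
                {
                    "lambda": float(lam),
                    "k": int(k),
                    "p_c": sol.p_c,
                    "n_fixed_points": len(sol.fixed_points),
                    "flag": int(sol.multiple_interior_unstable),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MonteCarloCritical:
    """Finite-size Monte-Carlo estimate of the critical initial density."""

    estimate: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray
    n: int
    reps: int
    converged: bool


def monte_carlo_critical(
    n: int,
    model: LongEdgeModel,
    k: int,
    reps: int = 20,
    max_steps: int = 500,
    tol: float = 0.01,
    seed: int = 0,
    success_rho: float = 0.5,
) -> MonteCarloCritical:
    """Estimate the critical initial density on finite N x N lattices.

    A run counts as "activation spread" when its final density reaches
    ``success_rho``.  The default 0.5 classifies the basin (growth toward
    the active branch vs. extinction): on finite lattices the grown phase
    freezes with a few stubborn inactive holes, so demanding full coverage
    would estimate the hole-free coverage threshold instead of the basin
    boundary that the mean-field p_c describes.

    Each replicate gets one quenched graph and one fixed vector of
    per-vertex uniforms u; the initial state at probe density p0 is
    ``u < p0``, so initial sets are nested in p0 and — the threshold rule
    being monotone — the run outcome is monotone in p0.  Each replicate's
    critical density is then a deterministic threshold found by bisection;
    the estimate is the median across replicates with an order-statistic
    95% confidence interval.
    """
    if reps < 10:
        raise ValueError(f"reps must be >= 10, got {reps}")
    rule = UpdateRule(k=k)
    ss = np.random.SeedSequence(seed)
    thresholds = np.empty(reps)
    converged = True
    for r, child in enumerate(ss.spawn(reps)):
        graph_seed, init_seed = child.generate_state(2) >> np.uint32(1)
        graph = build_graph(n, model, seed=int(graph_seed))
        u = np.random.default_rng(int(init_seed)).random((n, n))

        def success(p0: float) -> bool:
            traj = run_dynamics(
                p0,
                graph,
                rule,
                max_steps=max_steps,
                initial_state=(u < p0).astype(np.uint8),
            )
            return traj.final_rho >= success_rho

        if not success(1.0):
            # full initial activation does not spread (e.g. k above the
            # minimum degree): flag rather than raise
            thresholds[r] = 1.0
            converged = False
            continue
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if success(mid):
                hi = mid
            else:
                lo = mid
        thresholds[r] = 0.5 * (lo + hi)

    order = np.sort(thresholds)
    estimate = float(np.median(order))
    lo_idx = int(stats.binom.ppf(0.025, reps, 0.5))
    hi_idx = min(reps - 1, reps - lo_idx)
    return MonteCarloCritical(
        estimate=estimate,
        ci_low=float(order[lo_idx]),
        ci_high=float(order[hi_idx - 1]),
        thresholds=thresholds,
        n=n,
        reps=reps,
        converged=converged,
    )
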
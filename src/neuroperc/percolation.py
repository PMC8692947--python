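"""Threshold activation dynamics on a torus lattice with random long-range edges.

The substrate is the N x N torus (periodic boundaries, 4-neighbor short
edges) augmented with random "axonal" long edges: a pair of vertices at
torus L1 distance d >= 2 is connected independently with probability

    p_d = min(1, c / (N * d**alpha)).

On this graph a synchronous bootstrap-percolation style update runs: a
vertex is active at t+1 iff at least ``k`` of its graph neighbors are
active at t.  An optional noise parameter flips each computed state
independently with probability ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TorusLattice",
    "LongEdgeModel",
    "PercolationGraph",
    "UpdateRule",
    "ActivationState",
    "ActivationTrajectory",
    "torus_l1_distance",
    "long_edge_probability",
    "distance_shell_sizes",
    "expected_long_degree",
    "solve_c_for_lambda",
    "build_graph",
    "activation_step",
    "run_dynamics",
]

#: long edges are only sampled between vertices at least this far apart;
#: distance-1 pairs are already short-edge neighbors.
MIN_LONG_EDGE_DISTANCE = 2


@dataclass(frozen=True)
class TorusLattice:
    """N x N square lattice with periodic boundaries (a discrete torus)."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"torus side length must be >= 3, got {self.n}")

    @property
    def n_vertices(self) -> int:
        return self.n * self.n

    def flat_index(self, i: int, j: int) -> int:
        return (i % self.n) * self.n + (j % self.n)

    def coords(self, idx: int) -> tuple[int, int]:
        return divmod(int(idx), self.n)


@dataclass(frozen=True)
class LongEdgeModel:
    """Distance-dependent long-edge probability p_d = min(1, c / (N d^alpha))."""

    c: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"scale constant c must be >= 0, got {self.c}")


def torus_l1_distance(x: tuple[int, int], y: tuple[int, int], n: int) -> int:
    """L1 (graph) distance between two vertices on the N x N torus.

    Per axis the distance is ``min(|dx|, N - |dx|)``; the total is the sum
    over the two axes, which is the geodesic distance of the 4-neighbor
    lattice.
    """
    for p in (x, y):
        if not (0 <= p[0] < n and 0 <= p[1] < n):
            raise ValueError(f"coordinate {p} out of range for N={n}")
    d = 0
    for a, b in zip(x, y):
        delta = abs(a - b)
        d += min(delta, n - delta)
    return d


def long_edge_probability(d: int, n: int, model: LongEdgeModel) -> float:
    """Probability of a long edge between vertices at distance d (clamped to 1)."""
    if d < 1:
        raise ValueError("long-edge distance must be >= 1 (no self-loops)")
    return min(1.0, model.c / (n * float(d) ** model.alpha))


def distance_shell_sizes(n: int) -> np.ndarray:
    """Exact count of vertices at each torus L1 distance from a fixed vertex.

    Returns an array ``S`` with ``S[d]`` the number of vertices at distance
    ``d``, computed by enumerating all N^2 - 1 offsets (no 4d approximation,
    which over-counts once wraparound sets in).
    """
    a = np.arange(n)
    ax = np.minimum(a, n - a)
    dist = ax[:, None] + ax[None, :]
    counts = np.bincount(dist.ravel())
    counts[0] -= 1  # drop the zero offset
    return counts


def expected_long_degree(
    n: int, model: LongEdgeModel, d_min: int = MIN_LONG_EDGE_DISTANCE
) -> float:
    """Expected number of long edges per vertex, lambda = sum_d S(d) p_d."""
    if n < 3:
        raise ValueError("N must be >= 3")
    shells = distance_shell_sizes(n)
    lam = 0.0
    for d in range(max(d_min, 1), len(shells)):
        if shells[d]:
            lam += shells[d] * long_edge_probability(d, n, model)
    return lam


def solve_c_for_lambda(
    n: int, lam: float, alpha: float = 1.0, d_min: int = MIN_LONG_EDGE_DISTANCE
) -> float:
    """Invert expected_long_degree: find c such that the mean long degree is lam.

    lambda is linear in c until the probability clamp engages, so the linear
    solution is tried first and refined by bisection if clamping matters.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 0.0
    base = expected_long_degree(n, LongEdgeModel(c=1.0, alpha=alpha), d_min)
    if base <= 0:
        raise ValueError("no eligible pairs: cannot realize a positive lambda")
    c = lam / base
    if abs(expected_long_degree(n, LongEdgeModel(c, alpha), d_min) - lam) < 1e-9 * max(lam, 1):
        return c
    lo, hi = 0.0, c
    while expected_long_degree(n, LongEdgeModel(hi, alpha), d_min) < lam:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"lambda={lam} not attainable on an N={n} torus")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_long_degree(n, LongEdgeModel(mid, alpha), d_min) < lam:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PercolationGraph:
    """Torus lattice plus sampled long edges, with a CSR adjacency matrix.

    ``long_edges`` holds each sampled long edge once, as a pair of flat
    vertex indices ``(i, j)`` with ``i < j``.
    """

    lattice: TorusLattice
    model: LongEdgeModel
    seed: int
    long_edges: frozenset[tuple[int, int]]
    adjacency: sp.csr_matrix = field(repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.lattice.n

    @property
    def n_vertices(self) -> int:
        return self.lattice.n_vertices

    @property
    def n_short_edges(self) -> int:
        return 2 * self.lattice.n_vertices

    def long_edge_coords(self) -> set[tuple[tuple[int, int], tuple[int, int]]]:
        """Long edges as unordered coordinate pairs ((i1, j1), (i2, j2))."""
        return {
            (self.lattice.coords(a), self.lattice.coords(b))
            for a, b in self.long_edges
        }

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


def _canonical_offsets(n: int):
    """Enumerate torus offsets so each unordered vertex pair appears once.

    Yields ``(da, db, dist, self_inverse)``.  An offset and its negation
    generate the same pair set, so only the lexicographically smaller of the
    two is kept; offsets equal to their own negation (possible for even N)
    are flagged so the caller can halve the base-vertex set instead.
    """
    for da in range(n):
        for db in range(n):
            if da == 0 and db == 0:
                continue
            neg = ((n - da) % n, (n - db) % n)
            if (da, db) > neg:
                continue
            dist = min(da, n - da) + min(db, n - db)
            yield da, db, dist, (da, db) == neg


def build_graph(n: int, model: LongEdgeModel, seed: int = 0) -> PercolationGraph:
    """Sample the random graph: torus short edges plus distance-decaying long edges.

    Every unordered pair at torus L1 distance >= 2 is included independently
    with probability ``min(1, c / (N d^alpha))``.  Sampling is deterministic
    under ``seed``.
    """
    lattice = TorusLattice(n)
    nv = lattice.n_vertices
    rng = np.random.default_rng(seed)

    base = np.arange(nv)
    rows_i = base // n
    rows_j = base % n

    long_a: list[np.ndarray] = []
    long_b: list[np.ndarray] = []
    for da, db, dist, self_inv in _canonical_offsets(n):
        if dist < MIN_LONG_EDGE_DISTANCE:
            continue
        p = long_edge_probability(dist, n, model)
        if p <= 0.0:
            continue
        partner = ((rows_i + da) % n) * n + (rows_j + db) % n
        draws = rng.random(nv) < p
        if self_inv:
            draws &= base < partner  # each pair appears for two base vertices
        if draws.any():
            long_a.append(base[draws])
            long_b.append(partner[draws])

    if long_a:
        ea = np.concatenate(long_a)
        eb = np.concatenate(long_b)
    else:
        ea = eb = np.empty(0, dtype=int)
    lo = np.minimum(ea, eb)
    hi = np.maximum(ea, eb)
    long_edges = frozenset(zip(lo.tolist(), hi.tolist()))

    # short edges: 4-neighbor torus offsets, each pair once via (+1, 0)/(0, +1)
    short_a = np.concatenate([base, base])
    short_b = np.concatenate(
        [((rows_i + 1) % n) * n + rows_j, rows_i * n + (rows_j + 1) % n]
    )
    src = np.concatenate([short_a, lo])
    dst = np.concatenate([short_b, hi])
    rows = np.concatenate([src, dst])
    cols = np.concatenate([dst, src])
    adjacency = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int32), (rows, cols)), shape=(nv, nv)
    )
    return PercolationGraph(
        lattice=lattice,
        model=model,
        seed=seed,
        long_edges=long_edges,
        adjacency=adjacency,
    )


@dataclass(frozen=True)
class UpdateRule:
    """Threshold update: active iff >= k neighbors active, with optional noise.

    ``eps`` is the probability of independently flipping each vertex's
    computed state after the deterministic update; ``eps = 0`` recovers the
    deterministic threshold rule exactly.
    """

    k: int
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"activation threshold k must be >= 1, got {self.k}")
        if not (0.0 <= self.eps <= 0.5):
            raise ValueError(f"noise eps must lie in [0, 0.5], got {self.eps}")


@dataclass(frozen=True)
class ActivationState:
    """Binary lattice configuration at one time step."""

    chi: np.ndarray  # (n, n) uint8
    t: int = 0

    @property
    def rho(self) -> float:
        return float(self.chi.mean())

    @property
    def n_active(self) -> int:
        return int(self.chi.sum())


@dataclass(frozen=True)
class ActivationTrajectory:
    """Recorded run of the activation dynamics.

    ``outcome`` is one of ``all_active``, ``all_inactive``, ``cycle``
    (a state repeated with period <= 2, including non-uniform fixed points)
    or ``timeout``.
    """

    rho: np.ndarray
    outcome: str
    steps_taken: int
    p0: float
    seed: int | None = None
    states: list[np.ndarray] | None = None

    @property
    def final_rho(self) -> float:
        return float(self.rho[-1])


def activation_step(
    state: ActivationState,
    graph: PercolationGraph,
    rule: UpdateRule,
    rng: np.random.Generator | None = None,
) -> ActivationState:
    """One synchronous update of every vertex.

    chi_v(t+1) = 1 iff the sum of chi_u(t) over graph neighbors u of v is
    >= k; v's own state is excluded from the sum.  With ``eps > 0`` each
    computed value is then flipped independently with probability ``eps``
    (an ``rng`` must be supplied in that case).
    """
    n = graph.n
    if state.chi.shape != (n, n):
        raise ValueError(
            f"state shape {state.chi.shape} does not match graph side {n}"
        )
    counts = graph.adjacency @ state.chi.ravel().astype(np.int32)
    new = (counts >= rule.k).astype(np.uint8)
    if rule.eps > 0.0:
        if rng is None:
            raise ValueError("eps > 0 requires an rng")
        new ^= (rng.random(new.size) < rule.eps).astype(np.uint8)
    return ActivationState(chi=new.reshape(n, n), t=state.t + 1)


def run_dynamics(
    p0: float,
    graph: PercolationGraph,
    rule: UpdateRule,
    max_steps: int = 1000,
    seed: int = 0,
    record_states: bool = False,
    initial_state: np.ndarray | None = None,
) -> ActivationTrajectory:
    """Run the activation process from an i.i.d. Bernoulli(p0) initial state.

    Iterates :func:`activation_step` until an absorbing uniform state, a
    repeat of one of the previous two states (outcome ``cycle``), or
    ``max_steps``.  ``initial_state`` overrides the random initialization
    (used for coupled Monte-Carlo estimates).
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    n = graph.n
    rng = np.random.default_rng(seed)
    if initial_state is not None:
        chi0 = np.asarray(initial_state, dtype=np.uint8).reshape(n, n)
    else:
        chi0 = (rng.random((n, n)) < p0).astype(np.uint8)
    state = ActivationState(chi=chi0, t=0)

    rhos = [state.rho]
    states = [chi0.copy()] if record_states else None
    prev = [chi0.tobytes()]
    min_degree = int(graph.degrees().min())

    def _uniform_outcome(s: ActivationState) -> str | None:
        na = s.n_active
        if na == 0:
            return "all_inactive"
        # the full lattice is absorbing only if every vertex keeps >= k
        # active neighbors, i.e. k does not exceed the minimum degree
        if na == s.chi.size and rule.k <= min_degree:
            return "all_active"
        return None

    outcome = _uniform_outcome(state)
    steps = 0
    while outcome is None and steps < max_steps:
        state = activation_step(state, graph, rule, rng=rng)
        steps += 1
        rhos.append(state.rho)
        if record_states:
            states.append(state.chi.copy())
        raw = state.chi.tobytes()
        outcome = _uniform_outcome(state)
        if outcome is None and rule.eps == 0.0 and raw in prev:
            outcome = "cycle"
        prev.append(raw)
        if len(prev) > 2:
            prev.pop(0)
    if outcome is None:
        outcome = "timeout"
    return ActivationTrajectory(
        rho=np.asarray(rhos),
        outcome=outcome,
        steps_taken=steps,
        p0=p0,
        seed=seed,
        states=states,
    )
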
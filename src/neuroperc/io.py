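"""Run configuration, experiment orchestration, output writers, fixture generators.

Every experiment is described by a JSON document with a ``kind`` field and
flat, fully-explicit parameters (defaults are materialized on load, unknown
keys rejected).  ``run_experiment`` dispatches to the simulator modules and
writes CSV outputs plus a ``manifest.json`` recording the exact config,
seed and file list, so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import datetime as _dt
import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from . import can, meanfield, percolation, synchrony

__all__ = [
    "ConfigError",
    "RunRecord",
    "load_config",
    "save_config",
    "run_experiment",
    "make_fixtures",
    "trajectory_frame",
    "graph_edge_frame",
]


class ConfigError(ValueError):
    """Raised for malformed or contradictory run configurations."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0


class PercolationRunConfig(_Base):
    kind: Literal["percolation_run"] = "percolation_run"
    N: int
    c: float
    k: int
    alpha: float = 1.0
    eps: float = 0.0
    p0: float = 0.5
    max_steps: int = 1000
    record_states: bool = False


class PhaseDiagramConfig(_Base):
    kind: Literal["percolation_phase_diagram"] = "percolation_phase_diagram"
    lambdas: list[float]
    ks: list[int]
    tol: float = 1e-6


class McCriticalConfig(_Base):
    kind: Literal["mc_critical"] = "mc_critical"
    N: int
    k: int
    c: float | None = None
    lam: float | None = None
    alpha: float = 1.0
    reps: int = 20
    max_steps: int = 500
    tol: float = 0.01


class _CanBase(_Base):
    T: float = 2000.0
    dt: float = 0.1
    a: float = 0.02
    b: float = 0.2
    c_reset: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0
    omega: float = 1.0
    beta: float = 0.0
    kappa: float = 5e-4
    tau: float = 20.0
    k_g: float = 0.01
    k_m: float = 0.005
    g_max: float = 1.0
    m_max: float = 1.0
    drive_mode: str = "rectified"
    i_dc: float = 10.0

    def izh_params(self) -> can.IzhikevichParams:
        return can.IzhikevichParams(
            a=self.a, b=self.b, c_reset=self.c_reset, d=self.d,
            v_peak=self.v_peak, omega=self.omega, beta=self.beta,
        )

    def met_params(self) -> can.MetabolicParams:
        return can.MetabolicParams(
            kappa=self.kappa, tau=self.tau, k_g=self.k_g, k_m=self.k_m,
            g_max=self.g_max, m_max=self.m_max, drive_mode=self.drive_mode,
        )


class CanUnitConfig(_CanBase):
    kind: Literal["can_unit"] = "can_unit"


class _CanPopBase(_CanBase):
    n: int = 50
    coupling: str = "all_to_all"
    p_conn: float = 0.2
    w: float = 5.0
    syn_tau: float = 5.0
    sigma_noise: float = 1.0
    shared_glycogen: bool = True
    i_dc: float = 2.0

    def pop_config(self) -> can.PopulationConfig:
        return can.PopulationConfig(
            n=self.n, coupling=self.coupling, p_conn=self.p_conn, w=self.w,
            syn_tau=self.syn_tau, i_dc=self.i_dc,
            sigma_noise=self.sigma_noise, shared_glycogen=self.shared_glycogen,
        )


class CanPopulationConfig(_CanPopBase):
    kind: Literal["can_population"] = "can_population"


class HysteresisConfig(_CanPopBase):
    kind: Literal["hysteresis"] = "hysteresis"
    param_name: str = "i_dc"
    values: list[float] = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    dwell: float = 1000.0
    delta_min: float = 0.2


class CuspScanConfig(_CanPopBase):
    kind: Literal["cusp_scan"] = "cusp_scan"
    kappa_grid: list[float] = [0.0, 5e-4, 1e-3]
    beta_grid: list[float] = [0.0, 0.25, 0.5]
    delta_min: float = 0.2


class ConeFitConfig(_Base):
    kind: Literal["cone_fit"] = "cone_fit"
    grid_size: int = 16
    n_cones: int = 10
    gamma: float = 0.2
    noise_sd: float = 0.2


RunConfig = Union[
    PercolationRunConfig,
    PhaseDiagramConfig,
    McCriticalConfig,
    CanUnitConfig,
    CanPopulationConfig,
    HysteresisConfig,
    CuspScanConfig,
    ConeFitConfig,
]

_KIND_MAP: dict[str, type[_Base]] = {
    "percolation_run": PercolationRunConfig,
    "percolation_phase_diagram": PhaseDiagramConfig,
    "mc_critical": McCriticalConfig,
    "can_unit": CanUnitConfig,
    "can_population": CanPopulationConfig,
    "hysteresis": HysteresisConfig,
    "cusp_scan": CuspScanConfig,
    "cone_fit": ConeFitConfig,
}


def config_from_dict(data: dict) -> RunConfig:
    """Validate a raw dict into the kind-specific config model."""
    if not isinstance(data, dict):
        raise ConfigError("config must be a JSON object")
    kind = data.get("kind")
    if kind not in _KIND_MAP:
        raise ConfigError(
            f"unknown experiment kind {kind!r}; expected one of {sorted(_KIND_MAP)}"
        )
    try:
        return _KIND_MAP[kind].model_validate(data)
    except ValidationError as exc:
        keys = sorted({str(e["loc"][0]) for e in exc.errors() if e["loc"]})
        raise ConfigError(f"invalid config fields: {', '.join(keys)}\n{exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration (defaults materialized)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config.model_dump(), indent=2, sort_keys=True))


class RunRecord(BaseModel):
    """Provenance of one experiment run."""

    config: dict
    package_version: str
    seed: int
    started: str
    finished: str
    outputs: list[str]


def trajectory_frame(traj: percolation.ActivationTrajectory) -> pd.DataFrame:
    """Trajectory as (step, rho, outcome_flag) rows; flag set on the final row."""
    steps = np.arange(traj.rho.size)
    flag = np.array([""] * traj.rho.size, dtype=object)
    flag[-1] = traj.outcome
    return pd.DataFrame({"step": steps, "rho": traj.rho, "outcome_flag": flag})


def graph_edge_frame(graph: percolation.PercolationGraph) -> pd.DataFrame:
    """Edge list as (x1, y1, x2, y2, type in {short, long}) rows."""
    n = graph.n
    rows = []
    for i in range(n):
        for j in range(n):
            rows.append((i, j, (i + 1) % n, j, "short"))
            rows.append((i, j, i, (j + 1) % n, "short"))
    for a, b in sorted(graph.long_edges):
        (x1, y1), (x2, y2) = graph.lattice.coords(a), graph.lattice.coords(b)
        rows.append((x1, y1, x2, y2, "long"))
    return pd.DataFrame(rows, columns=["x1", "y1", "x2", "y2", "type"])


def states_to_text(states: list[np.ndarray]) -> str:
    """Dense 0/1 grids, one block per step, blank-line separated."""
    blocks = []
    for s in states:
        blocks.append("\n".join("".join(str(int(x)) for x in row) for row in s))
    return "\n\n".join(blocks) + "\n"


def _package_version() -> str:
    try:
        return _pkg_version("neuroperc")
    except PackageNotFoundError:  # editable/dev tree
        return "0.0.0+dev"


def run_experiment(config: RunConfig, out_dir) -> RunRecord:
    """Execute the configured experiment and write its outputs + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    outputs: list[str] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs.append(name)

    if isinstance(config, PercolationRunConfig):
        model = percolation.LongEdgeModel(c=config.c, alpha=config.alpha)
        graph = percolation.build_graph(config.N, model, seed=config.seed)
        rule = percolation.UpdateRule(k=config.k, eps=config.eps)
        traj = percolation.run_dynamics(
            config.p0, graph, rule, max_steps=config.max_steps,
            seed=config.seed, record_states=config.record_states,
        )
        _write(trajectory_frame(traj), "trajectory.csv")
        _write(graph_edge_frame(graph), "edges.csv")
        if config.record_states:
            (out / "states.txt").write_text(states_to_text(traj.states))
            outputs.append("states.txt")
    elif isinstance(config, PhaseDiagramConfig):
        table = meanfield.phase_diagram(config.lambdas, config.ks, tol=config.tol)
        _write(table, "phase_diagram.csv")
    elif isinstance(config, McCriticalConfig):
        if (config.c is None) == (config.lam is None):
            raise ConfigError("mc_critical needs exactly one of 'c' or 'lam'")
        c = (
            config.c
            if config.c is not None
            else percolation.solve_c_for_lambda(config.N, config.lam, config.alpha)
        )
        model = percolation.LongEdgeModel(c=c, alpha=config.alpha)
        est = meanfield.monte_carlo_critical(
            config.N, model, config.k, reps=config.reps,
            max_steps=config.max_steps, tol=config.tol, seed=config.seed,
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "N": config.N, "c": c, "k": config.k,
                        "estimate": est.estimate, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "converged": est.converged,
                    }
                ]
            ),
            "mc_critical.csv",
        )
    elif isinstance(config, CanUnitConfig):
        trace = can.simulate_unit(
            config.izh_params(), config.met_params(), T=config.T,
            dt=config.dt, i_fn=config.i_dc, seed=config.seed,
        )
        _write(
            pd.DataFrame(
                {"t": trace.t, "v": trace.v, "u": trace.u,
                 "g": trace.g, "m": trace.m}
            ),
            "unit_trace.csv",
        )
        _write(pd.DataFrame({"spike_time_ms": trace.spike_times}), "spikes.csv")
    elif isinstance(config, CanPopulationConfig):
        res = can.simulate_population(
            config.pop_config(), config.izh_params(), config.met_params(),
            T=config.T, dt=config.dt, seed=config.seed,
        )
        _write(
            pd.DataFrame(
                {"neuron_id": res.raster.neuron_ids,
                 "spike_time_ms": res.raster.times}
            ),
            "raster.csv",
        )
        traces, _ = synchrony.smoothed_activity(res.raster, kernel_width=3.0)
        if traces.shape[0] >= 2:
            r = synchrony.order_parameter(traces, res.dt).r
        else:
            r = np.zeros(res.t.size - 1)
        n_r = r.size
        _write(
            pd.DataFrame(
                {"t": res.t[:n_r], "v_mean": res.v_mean[:n_r],
                 "g_mean": res.g_mean[:n_r], "m_mean": res.m_mean[:n_r], "R": r}
            ),
            "traces.csv",
        )
    elif isinstance(config, HysteresisConfig):
        curve = synchrony.can_hysteresis_sweep(
            config.param_name, config.values, config.pop_config(),
            config.izh_params(), config.met_params(), dwell=config.dwell,
            dt=config.dt, seed=config.seed, delta_min=config.delta_min,
        )
        frames = []
        for branch, r, sd in (("up", curve.r_up, curve.sd_up),
                              ("down", curve.r_down, curve.sd_down)):
            frames.append(
                pd.DataFrame(
                    {"param_value": curve.values, "branch": branch,
                     "mean_R": r, "sd_R": sd}
                )
            )
        _write(pd.concat(frames, ignore_index=True), "hysteresis.csv")
    elif isinstance(config, CuspScanConfig):
        table = synchrony.cusp_scan(
            config.kappa_grid, config.beta_grid, config.pop_config(),
            config.izh_params(), config.met_params(), T=config.T,
            dt=config.dt, seed=config.seed, delta_min=config.delta_min,
        )
        _write(table, "cusp_map.csv")
    elif isinstance(config, ConeFitConfig):
        cones = make_fixtures("synthetic_cones", seed=config.seed,
                              n_cones=config.n_cones,
                              grid_size=config.grid_size,
                              gamma=config.gamma, noise_sd=config.noise_sd)
        rows = []
        for i, cone in enumerate(cones):
            fit = synchrony.fit_phase_cone(cone["field"])
            rows.append(
                {"t": i, "apex_x": fit.apex[0], "apex_y": fit.apex[1],
                 "gamma": fit.gamma, "phi0": fit.phi0, "quality": fit.quality}
            )
        _write(pd.DataFrame(rows), "cone_fits.csv")
    else:  # pragma: no cover - the union is exhaustive
        raise ConfigError(f"unhandled config type {type(config).__name__}")

    record = RunRecord(
        config=config.model_dump(),
        package_version=_package_version(),
        seed=config.seed,
        started=started,
        finished=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        outputs=outputs,
    )
    (out / "manifest.json").write_text(record.model_dump_json(indent=2))
    return record


# ---------------------------------------------------------------------------
# fixture generators: deterministic small inputs with known ground truth
# ---------------------------------------------------------------------------


def _brute_force_step(chi: np.ndarray, k: int, n: int) -> np.ndarray:
    """Reference threshold update on the pure torus: explicit per-vertex loops."""
    out = np.zeros_like(chi)
    for i in range(n):
        for j in range(n):
            total = (
                chi[(i - 1) % n, j]
                + chi[(i + 1) % n, j]
                + chi[i, (j - 1) % n]
                + chi[i, (j + 1) % n]
            )
            out[i, j] = 1 if total >= k else 0
    return out


def make_fixtures(kind: str, seed: int = 0, **kw):
    """Deterministic ground-truth inputs for the test suites.

    Kinds: ``tiny_torus_states`` (random small-torus states with brute-force
    next states per k), ``telegraph_labels`` (two-state Markov series with
    known switching rates), ``synthetic_cones`` (noisy conical phase fields
    with known apex/slope), ``bistable_surrogate`` (a cusp normal-form map
    with a known bistable interval, for injection into hysteresis sweeps).
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny_torus_states":
        n = kw.get("n", 4)
        count = kw.get("count", 200)
        states = (rng.random((count, n, n)) < rng.random((count, 1, 1))).astype(np.uint8)
        nxt = {
            k: np.stack([_brute_force_step(s, k, n) for s in states])
            for k in range(1, 5)
        }
        return {"states": states, "next": nxt, "n": n}
    if kind == "telegraph_labels":
        n_samples = kw.get("n_samples", 200_000)
        p_hl = kw.get("p_hl", 0.01)  # P(high -> low) per sample
        p_lh = kw.get("p_lh", 0.02)
        labels = np.empty(n_samples, dtype=np.uint8)
        state = 1
        flips = rng.random(n_samples)
        for i in range(n_samples):
            if state == 1 and flips[i] < p_hl:
                state = 0
            elif state == 0 and flips[i] < p_lh:
                state = 1
            labels[i] = state
        return {
            "labels": labels,
            "true_mean_dwell_high": 1.0 / p_hl,
            "true_mean_dwell_low": 1.0 / p_lh,
        }
    if kind == "synthetic_cones":
        n_cones = kw.get("n_cones", 100)
        size = kw.get("grid_size", 16)
        gamma = kw.get("gamma", 0.2)
        noise_sd = kw.get("noise_sd", 0.2)
        ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        cones = []
        for _ in range(n_cones):
            apex = (int(rng.integers(2, size - 2)), int(rng.integers(2, size - 2)))
            g = gamma * float(rng.choice([-1.0, 1.0]))
            phi0 = float(rng.uniform(-np.pi, np.pi))
            field = phi0 + g * np.hypot(ii - apex[0], jj - apex[1])
            field = np.angle(np.exp(1j * (field + noise_sd * rng.standard_normal(field.shape))))
            cones.append({"field": field, "apex": apex, "gamma": g, "phi0": phi0})
        return cones
    if kind == "bistable_surrogate":
        # cusp normal form x' = p + x - x^3: folds at p = +/- 2/(3 sqrt 3)
        fold = 2.0 / (3.0 * np.sqrt(3.0))

        def step_fn(p, state, rng_unused, n_relax=2000, h=0.01):
            x = -1.0 if state is None else state
            for _ in range(n_relax):
                x = x + h * (p + x - x**3)
            r = float(np.clip((x + 1.5) / 3.0, 0.0, 1.0))
            return r, 0.0, x

        return {"step_fn": step_fn, "bistable_interval": (-fold, fold)}
    raise ValueError(f"unknown fixture kind {kind!r}")
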
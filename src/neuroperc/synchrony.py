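"""Synchrony metrics, metastable-state statistics, hysteresis/cusp sweeps, phase cones.

Synchrony is quantified with a Kuramoto-style order parameter: spike
trains are smoothed into continuous rates, each neuron's instantaneous
phase is taken from the analytic signal of its mean-subtracted trace, and

    R(t) = | (1/n) sum_j exp(i phi_j(t)) |

so R = 1 is perfect coherence and R ~ 1/sqrt(n) is asynchrony.  On top of
this sit a two-threshold (Schmitt) high/low state classifier with dwell
statistics, generic up/down hysteresis sweeps with loop-area and
bistable-interval readouts, a (kappa, beta) cusp scan for bistability, and
a phase-cone fitter for lattice phase fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from .can import (
    IzhikevichParams,
    MetabolicParams,
    PopulationConfig,
    SpikeRaster,
    simulate_population,
)

__all__ = [
    "SynchronyTrace",
    "StateLabels",
    "DwellSummary",
    "HysteresisCurve",
    "PhaseConeFit",
    "smoothed_activity",
    "order_parameter",
    "spike_train_correlations",
    "classify_states",
    "dwell_times",
    "hysteresis_sweep",
    "can_hysteresis_sweep",
    "cusp_scan",
    "fit_phase_cone",
]


@dataclass(frozen=True)
class SynchronyTrace:
    """Order-parameter time series; ``degenerate`` flags all-constant input."""

    t: np.ndarray
    r: np.ndarray
    method: str = "hilbert_kuramoto"
    degenerate: bool = False


@dataclass(frozen=True)
class StateLabels:
    """Per-sample high(1)/low(0) labels from Schmitt-trigger thresholding."""

    labels: np.ndarray
    theta_hi: float
    theta_lo: float


@dataclass(frozen=True)
class DwellSummary:
    """Contiguous-run statistics of a two-state label series.

    Runs truncated by the trace ends are censored: counted separately and
    excluded from the mean/median dwell estimates.
    """

    mean_dwell_high: float
    mean_dwell_low: float
    median_dwell_high: float
    median_dwell_low: float
    n_transitions: int
    n_censored: int


@dataclass(frozen=True)
class HysteresisCurve:
    """Up/down branch synchrony along a swept parameter.

    ``bistable_interval`` is the sub-range where the branches separate by
    more than ``delta_min``; ``loop_area`` is the integral of the absolute
    branch difference over the sweep.
    """

    values: np.ndarray
    r_up: np.ndarray
    r_down: np.ndarray
    sd_up: np.ndarray
    sd_down: np.ndarray
    bistable_interval: tuple[float, float] | None
    loop_area: float
    delta_min: float


@dataclass(frozen=True)
class PhaseConeFit:
    """Conical phase-gradient fit: phi ~ phi0 + gamma * dist(apex)."""

    apex: tuple[int, int] | None
    gamma: float
    phi0: float
    quality: float
    degenerate: bool = False


def smoothed_activity(
    raster: SpikeRaster, kernel_width: float, dt: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve each spike train with a unit-mass Gaussian kernel.

    Returns ``(traces, t)`` with ``traces`` of shape (n_neurons, n_bins);
    a single spike integrates to ~1 (sum * dt = 1 away from the edges).
    An empty raster yields all-zero traces.
    """
    if kernel_width <= 0:
        raise ValueError("kernel_width must be > 0")
    dt = raster.dt if dt is None else dt
    n_bins = max(1, int(round(raster.duration / dt)))
    counts = np.zeros((raster.n_neurons, n_bins))
    if raster.n_spikes:
        idx = np.minimum((raster.times / dt).astype(int), n_bins - 1)
        np.add.at(counts, (raster.neuron_ids, idx), 1.0)
    traces = ndimage.gaussian_filter1d(
        counts / dt, sigma=kernel_width / dt, axis=1, mode="constant"
    )
    return traces, np.arange(n_bins) * dt


def order_parameter(traces: np.ndarray, dt: float) -> SynchronyTrace:
    """Kuramoto order parameter R(t) from analytic-signal phases.

    Traces with no temporal variation carry no phase; if fewer than two
    traces vary, R is reported as 0 with the ``degenerate`` flag set.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need a (n_neurons, n_samples) array with >= 2 traces")
    t = np.arange(traces.shape[1]) * dt
    centered = traces - traces.mean(axis=1, keepdims=True)
    varying = centered.std(axis=1) > 1e-12
    if varying.sum() < 2:
        return SynchronyTrace(t=t, r=np.zeros(traces.shape[1]), degenerate=True)
    analytic = signal.hilbert(centered[varying], axis=1)
    phases = np.angle(analytic)
    r = np.abs(np.exp(1j * phases).mean(axis=0))
    return SynchronyTrace(t=t, r=r)


def spike_train_correlations(raster: SpikeRaster, bin_width: float = 5.0) -> np.ndarray:
    """Pairwise Pearson correlations of binned spike counts (cross-check metric).

    Pairs involving a silent (zero-variance) train get correlation 0.
    """
    n_bins = max(1, int(round(raster.duration / bin_width)))
    counts = np.zeros((raster.n_neurons, n_bins))
    if raster.n_spikes:
        idx = np.minimum((raster.times / bin_width).astype(int), n_bins - 1)
        np.add.at(counts, (raster.neuron_ids, idx), 1.0)
    sd = counts.std(axis=1)
    ok = sd > 0
    corr = np.zeros((raster.n_neurons, raster.n_neurons))
    if ok.sum() >= 2:
        sub = np.corrcoef(counts[ok])
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return corr


def classify_states(
    r_trace: SynchronyTrace | np.ndarray, theta_hi: float = 0.6, theta_lo: float = 0.3
) -> StateLabels:
    """Schmitt-trigger labeling of a synchrony trace into high/low states.

    The label flips to high only when R exceeds ``theta_hi`` and back to low
    only below ``theta_lo``, so oscillation inside the deadband causes no
    transitions.  The initial label compares the first sample with the
    midpoint of the two thresholds.
    """
    if not (0.0 <= theta_lo < theta_hi <= 1.0):
        raise ValueError(
            f"need 0 <= theta_lo < theta_hi <= 1, got ({theta_lo}, {theta_hi})"
        )
    r = r_trace.r if isinstance(r_trace, SynchronyTrace) else np.asarray(r_trace)
    labels = np.empty(r.size, dtype=np.uint8)
    current = 1 if r[0] >= 0.5 * (theta_hi + theta_lo) else 0
    for i, x in enumerate(r):
        if current == 0 and x > theta_hi:
            current = 1
        elif current == 1 and x < theta_lo:
            current = 0
        labels[i] = current
    return StateLabels(labels=labels, theta_hi=theta_hi, theta_lo=theta_lo)


def dwell_times(labels: StateLabels | np.ndarray, dt: float) -> DwellSummary:
    """Mean/median dwell time per state and the transition count.

    The first and last runs touch the trace boundaries and are censored
    (excluded from the dwell statistics, counted in ``n_censored``).
    """
    lab = labels.labels if isinstance(labels, StateLabels) else np.asarray(labels)
    if lab.size == 0:
        raise ValueError("label series is empty")
    change = np.flatnonzero(np.diff(lab.astype(int)) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [lab.size]])
    run_lab = lab[starts]
    run_len = (ends - starts) * dt
    n_transitions = change.size
    interior = np.ones(run_lab.size, dtype=bool)
    interior[0] = False
    interior[-1] = False
    n_censored = int((~interior).sum()) if run_lab.size > 1 else 1

    def _stats(state):
        sel = run_len[interior & (run_lab == state)]
        if sel.size == 0:
            return np.nan, np.nan
        return float(sel.mean()), float(np.median(sel))

    mh, medh = _stats(1)
    ml, medl = _stats(0)
    return DwellSummary(
        mean_dwell_high=mh,
        mean_dwell_low=ml,
        median_dwell_high=medh,
        median_dwell_low=medl,
        n_transitions=n_transitions,
        n_censored=n_censored,
    )


def hysteresis_sweep(
    step_fn,
    values,
    seed: int = 0,
    delta_min: float = 0.2,
) -> HysteresisCurve:
    """Sweep a parameter up then down with state carried between steps.

    ``step_fn(value, state, rng) -> (mean_r, sd_r, state)`` runs the system
    at one parameter value starting from the carried ``state`` (None at the
    start of each branch... the up-branch's final state seeds the down
    branch, which is what makes the loop path-dependent).  ``values`` must
    be ascending; the down branch revisits the same grid in reverse.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.any(np.diff(values) <= 0):
        raise ValueError("values must be a strictly ascending grid")
    rng = np.random.default_rng(seed)
    r_up = np.empty(values.size)
    sd_up = np.empty(values.size)
    r_down = np.empty(values.size)
    sd_down = np.empty(values.size)
    state = None
    for i, val in enumerate(values):
        r_up[i], sd_up[i], state = step_fn(float(val), state, rng)
    for i in range(values.size - 1, -1, -1):
        r_down[i], sd_down[i], state = step_fn(float(values[i]), state, rng)
    diff = np.abs(r_up - r_down)
    mask = diff > delta_min
    interval = (
        (float(values[mask].min()), float(values[mask].max())) if mask.any() else None
    )
    loop_area = float(np.trapezoid(diff, values))
    return HysteresisCurve(
        values=values,
        r_up=r_up,
        r_down=r_down,
        sd_up=sd_up,
        sd_down=sd_down,
        bistable_interval=interval,
        loop_area=loop_area,
        delta_min=delta_min,
    )


def _set_param(config, params, met, name: str, value: float):
    """Place a swept parameter on whichever CAN dataclass owns it."""
    for obj in (params, met, config):
        if name in {f.name for f in dataclasses.fields(obj)}:
            repl = dataclasses.replace(obj, **{name: value})
            if obj is params:
                return config, repl, met
            if obj is met:
                return config, params, repl
            return repl, params, met
    raise ValueError(f"unknown CAN parameter {name!r}")


def mean_synchrony(
    result, kernel_width: float = 3.0, settle_frac: float = 0.5
) -> tuple[float, float]:
    """Windowed mean and SD of R over the post-transient part of a run.

    Phases are extracted on the post-transient segment only, so a
    population that fell silent after a transient volley reads as
    asynchronous (R = 0), not as trivially phase-locked.
    """
    traces, _ = smoothed_activity(result.raster, kernel_width)
    if traces.shape[0] < 2:
        return 0.0, 0.0
    tail = traces[:, int(settle_frac * traces.shape[1]):]
    sync = order_parameter(tail, result.dt)
    if sync.degenerate:
        return 0.0, 0.0
    return float(sync.r.mean()), float(sync.r.std())


def can_hysteresis_sweep(
    param_name: str,
    values,
    config: PopulationConfig,
    params: IzhikevichParams,
    met: MetabolicParams,
    dwell: float = 1000.0,
    dt: float = 0.1,
    seed: int = 0,
    delta_min: float = 0.2,
    kernel_width: float = 3.0,
) -> HysteresisCurve:
    """Hysteresis sweep of a CAN population parameter (e.g. "beta", "kappa").

    At each grid value the population is simulated for ``dwell`` ms
    continuing from the previous endpoint state; the windowed mean R over
    the second half of each dwell forms the branch curves.
    """

    def step(value, state, rng):
        cfg, prm, mp = _set_param(config, params, met, param_name, value)
        res = simulate_population(
            cfg, prm, mp, T=dwell, dt=dt,
            seed=int(rng.integers(2**31)), init=state,
        )
        mean_r, sd_r = mean_synchrony(res, kernel_width)
        return mean_r, sd_r, res.final_state

    return hysteresis_sweep(step, values, seed=seed, delta_min=delta_min)


#: initial conditions used by the cusp scan: a coherent, metabolically
#: charged state vs. a quiescent, depleted one.
HIGH_SYNC_INIT = {"v": -50.0, "u": -12.0, "g": 0.9, "m": 0.8}
LOW_SYNC_INIT = {"v": -70.0, "g": 0.0, "m": 0.0}


def cusp_scan(
    kappa_grid,
    beta_grid,
    config: PopulationConfig,
    params: IzhikevichParams,
    met: MetabolicParams,
    T: float = 3000.0,
    dt: float = 0.1,
    seed: int = 0,
    delta_min: float = 0.2,
    kernel_width: float = 3.0,
) -> pd.DataFrame:
    """Classify each (kappa, beta) cell as monostable or bistable.

    Each cell is simulated from a high-synchrony and a low-synchrony
    initial condition; if the long-run mean R differs by more than
    ``delta_min`` the forward-gain/feedback-gain cell is bistable — the
    coexistence region of the cusp.
    """
    rows = []
    for ik, kappa in enumerate(np.asarray(kappa_grid, dtype=float)):
        for ib, beta in enumerate(np.asarray(beta_grid, dtype=float)):
            prm = dataclasses.replace(params, beta=float(beta))
            mp = dataclasses.replace(met, kappa=float(kappa))
            r_vals = {}
            for tag, init in (("high", HIGH_SYNC_INIT), ("low", LOW_SYNC_INIT)):
                res = simulate_population(
                    config, prm, mp, T=T, dt=dt,
                    seed=seed + 104729 * ik + 1299709 * ib, init=dict(init),
                )
                r_vals[tag], _ = mean_synchrony(res, kernel_width)
            bistable = abs(r_vals["high"] - r_vals["low"]) > delta_min
            rows.append(
                {
                    "kappa": float(kappa),
                    "beta": float(beta),
                    "r_high_ic": r_vals["high"],
                    "r_low_ic": r_vals["low"],
                    "class": "bistable" if bistable else "monostable",
                }
            )
    return pd.DataFrame(rows)


def _cone_objective(z: np.ndarray, r: np.ndarray, gammas: np.ndarray) -> np.ndarray:
    """|mean exp(i(phi - gamma r))| for each candidate slope."""
    return np.abs(np.mean(z[None, :] * np.exp(-1j * gammas[:, None] * r[None, :]), axis=1))


def fit_phase_cone(
    phase_grid: np.ndarray,
    candidate_apexes=None,
    gamma_max: float = np.pi,
    n_gamma: int = 121,
) -> PhaseConeFit:
    """Fit a conical phase field phi ~ phi0 + gamma * ||x - apex||.

    Grid search over apex candidates (all lattice points by default); for
    each apex the slope maximizing the mean resultant length of the
    slope-corrected phases is found on a coarse grid and refined.  The
    sign of gamma distinguishes expanding from contracting cones.  Fit
    quality is the squared mean resultant length R1^2 in [0, 1]; a
    near-constant field is reported as degenerate with zero slope.
    """
    phi = np.asarray(phase_grid, dtype=float)
    if phi.ndim != 2 or min(phi.shape) < 8:
        raise ValueError("phase grid must be 2-D with both sides >= 8")
    z = np.exp(1j * phi).ravel()
    r0 = np.abs(z.mean())
    if r0 > 0.999:
        return PhaseConeFit(
            apex=None,
            gamma=0.0,
            phi0=float(np.angle(z.mean())),
            quality=1.0,
            degenerate=True,
        )
    h, w = phi.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    if candidate_apexes is None:
        candidate_apexes = [(i, j) for i in range(h) for j in range(w)]
    gammas = np.linspace(-gamma_max, gamma_max, n_gamma)

    best = (-1.0, None, 0.0)  # (R1, apex, gamma)
    for apex in candidate_apexes:
        dist = np.hypot(ii - apex[0], jj - apex[1]).ravel()
        obj = _cone_objective(z, dist, gammas)
        i_best = int(np.argmax(obj))
        if obj[i_best] > best[0]:
            best = (float(obj[i_best]), tuple(apex), float(gammas[i_best]))

    r1_coarse, apex, gamma = best
    dist = np.hypot(ii - apex[0], jj - apex[1]).ravel()
    dg = gammas[1] - gammas[0]
    res = optimize.minimize_scalar(
        lambda g: -_cone_objective(z, dist, np.array([g]))[0],
        bounds=(gamma - dg, gamma + dg),
        method="bounded",
    )
    gamma = float(res.x)
    r1 = float(-res.fun)
    phi0 = float(np.angle(np.mean(z * np.exp(-1j * gamma * dist))))
    return PhaseConeFit(
        apex=(int(apex[0]), int(apex[1])),
        gamma=gamma,
        phi0=phi0,
        quality=r1 * r1,
        degenerate=False,
    )
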
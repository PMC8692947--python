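"""Capillary-astrocyte-neuron (CAN) model: Izhikevich spiking with metabolic feedback.

Each unit couples the two-variable Izhikevich neuron

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I(t)
    du/dt = a (b+ v - u),        spike: v >= v_peak  ->  v <- c_reset, u <- u + d

to two metabolic pools: astrocyte glycogen ``g`` and mitochondrial ATP ``m``,

    dg/dt = -Psi1(g, m) + kappa * D(t)
    dm/dt = -Psi2(g, m) + Psi1(g, m)

where ``D(t)`` is a sliding-window functional of recent membrane activity
(the glutamate drive of spiking on the astrocyte), Psi1 = k_g g (1 - m/m_max)
converts glycogen to ATP with saturation, and Psi2 = k_m m is ATP
consumption.  The loop closes through the effective sensitivity

    b+(m) = omega * b + beta * m,

so available ATP raises excitability; ``beta = 0`` decouples metabolism
from spiking exactly.

Time is in milliseconds, voltages in the dimensionless-mV convention of the
Izhikevich model; the metabolic pools are dimensionless in [0, capacity].
All integration is explicit Euler at ``dt`` (default 0.1 ms); the per-step
order is fixed: drive -> metabolic update -> b+ from the new m -> membrane
update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IzhikevichParams",
    "MetabolicParams",
    "PopulationConfig",
    "CANUnitState",
    "SpikeRaster",
    "UnitTrace",
    "PopulationResult",
    "sensitivity_modulation",
    "izhikevich_step",
    "sliding_window_drive",
    "metabolic_step",
    "simulate_unit",
    "simulate_population",
]

DRIVE_MODES = ("raw", "rectified", "spike_count")


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich neuron constants plus the metabolic-feedback gains.

    Defaults are the regular-spiking set (a=0.02, b=0.2, c=-65, d=8);
    ``omega`` scales the nominal sensitivity (range [0.75, 1.25]) and
    ``beta`` (range [0, 0.5]) sets how strongly ATP feeds back into it.
    """

    a: float = 0.02
    b: float = 0.2
    c_reset: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0
    omega: float = 1.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"sensitivity b must be > 0, got {self.b}")
        if not (0.75 <= self.omega <= 1.25):
            raise ValueError(f"omega must lie in [0.75, 1.25], got {self.omega}")
        if not (0.0 <= self.beta <= 0.5):
            raise ValueError(f"beta must lie in [0, 0.5], got {self.beta}")


@dataclass(frozen=True)
class MetabolicParams:
    """Rates and capacities of the glycogen/ATP subsystem.

    ``kappa`` scales the spiking-to-glycogen drive, accumulated over a
    sliding window of length ``tau`` (ms).  ``drive_mode`` selects the
    window functional: integral of v ("raw"), integral of (v - v_ref)_+
    ("rectified", default — subthreshold rest produces no drive), or the
    spike count ("spike_count").
    """

    kappa: float = 5e-4
    tau: float = 20.0
    k_g: float = 0.01
    k_m: float = 0.005
    g_max: float = 1.0
    m_max: float = 1.0
    drive_mode: str = "rectified"
    v_ref: float = -65.0

    def __post_init__(self) -> None:
        for name in ("kappa", "k_g", "k_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.g_max <= 0 or self.m_max <= 0:
            raise ValueError("pool capacities must be > 0")
        if self.drive_mode not in DRIVE_MODES:
            raise ValueError(
                f"unknown drive_mode {self.drive_mode!r}; choose from {DRIVE_MODES}"
            )


@dataclass(frozen=True)
class PopulationConfig:
    """Coupled-population layout: synapses, baseline drive, noise, pooling.

    ``w`` is the total synaptic weight a neuron receives when every
    presynaptic partner is maximally active (individual weights are w/n for
    all-to-all, w/(p n) for Erdos-Renyi).  ``sigma_noise`` is the white
    current-noise amplitude (Euler-Maruyama scaling).  With
    ``shared_glycogen`` one astrocyte pool services the whole population
    (ATP stays per-neuron), reflecting the mini-column reading of the model.
    """

    n: int = 50
    coupling: str = "all_to_all"
    p_conn: float = 0.2
    w: float = 5.0
    syn_tau: float = 5.0
    i_dc: float = 2.0
    sigma_noise: float = 0.2
    shared_glycogen: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population size must be >= 1, got {self.n}")
        if self.coupling not in ("all_to_all", "erdos_renyi"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "erdos_renyi" and not (0.0 < self.p_conn <= 1.0):
            raise ValueError("p_conn must lie in (0, 1] for erdos_renyi coupling")
        if not np.isfinite(self.w):
            raise ValueError("synaptic weight must be finite")
        if self.syn_tau <= 0:
            raise ValueError("syn_tau must be > 0")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


@dataclass
class CANUnitState:
    """Instantaneous state of one CAN unit (used as an initial condition)."""

    v: float = -70.0
    u: float | None = None  # default: b+ (at m) * v
    g: float = 0.0
    m: float = 0.0


@dataclass(frozen=True)
class SpikeRaster:
    """Spike events (neuron_id, time) sorted by time."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float
    dt: float

    def __post_init__(self) -> None:
        if self.times.size and (
            self.times.min() < 0 or self.times.max() > self.duration + 1e-9
        ):
            raise ValueError("spike times must lie in [0, duration]")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def spike_trains(self) -> list[np.ndarray]:
        return [self.times[self.neuron_ids == i] for i in range(self.n_neurons)]


@dataclass(frozen=True)
class UnitTrace:
    """Full single-unit trajectory: membrane, recovery, metabolic pools, spikes."""

    t: np.ndarray
    v: np.ndarray
    u: np.ndarray
    g: np.ndarray
    m: np.ndarray
    spike_times: np.ndarray
    dt: float

    def firing_rate(self, t_min: float = 0.0) -> float:
        """Mean firing rate in spikes/s over [t_min, end] (times in ms)."""
        span_ms = self.t[-1] - t_min
        if span_ms <= 0:
            return 0.0
        return 1000.0 * np.sum(self.spike_times >= t_min) / span_ms

    def isi_cv(self, t_min: float = 0.0) -> float:
        """Coefficient of variation of inter-spike intervals after t_min."""
        st = self.spike_times[self.spike_times >= t_min]
        if st.size < 3:
            return np.nan
        isi = np.diff(st)
        return float(np.std(isi) / np.mean(isi))


@dataclass(frozen=True)
class PopulationResult:
    """Population run: raster plus population-mean traces and the final state."""

    raster: SpikeRaster
    t: np.ndarray
    v_mean: np.ndarray
    g_mean: np.ndarray
    m_mean: np.ndarray
    final_state: dict
    dt: float


def sensitivity_modulation(params: IzhikevichParams, m):
    """Effective sensitivity b+(m) = omega * b + beta * m."""
    m = np.asarray(m, dtype=float) if np.ndim(m) else m
    if np.any(np.asarray(m) < 0):
        raise ValueError("ATP level m must be >= 0")
    return params.omega * params.b + params.beta * m


def izhikevich_step(v, u, i_input, b_plus, dt: float, params: IzhikevichParams):
    """One explicit-Euler step of the membrane/recovery pair; vectorized.

    Returns ``(v', u', spiked)``.  The reset (v -> c_reset, u -> u + d) is
    applied at most once per step, whenever the updated v reaches v_peak.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    with np.errstate(over="raise", invalid="raise"):
        try:
            v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_input)
            u_new = u + dt * params.a * (b_plus * v - u)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"neuron state overflow (v range [{v.min()}, {v.max()}], dt={dt}); "
                "reduce dt or the input current"
            ) from exc
    spiked = v_new >= params.v_peak
    v_new = np.where(spiked, params.c_reset, v_new)
    u_new = np.where(spiked, u_new + params.d, u_new)
    return v_new, u_new, spiked


def sliding_window_drive(
    history, tau: float, dt: float, mode: str = "rectified", v_ref: float = -65.0
) -> float:
    """Windowed activity drive over the last tau ms of a history series.

    ``history`` holds per-step membrane values (modes "raw"/"rectified") or
    spike flags (mode "spike_count"), most recent last; shorter histories
    are treated as zero-padded at the start.
    """
    if mode not in DRIVE_MODES:
        raise ValueError(f"unknown drive mode {mode!r}; choose from {DRIVE_MODES}")
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be > 0")
    window = max(1, int(round(tau / dt)))
    h = np.asarray(history, dtype=float)[-window:]
    if mode == "raw":
        return float(np.sum(h) * dt)
    if mode == "rectified":
        return float(np.sum(np.maximum(h - v_ref, 0.0)) * dt)
    return float(np.sum(h))  # spike_count


def metabolic_step(g, m, drive, dt: float, params: MetabolicParams):
    """One Euler step of the glycogen/ATP pair; vectorized, clamped to capacity.

    Psi1 = k_g g (1 - m/m_max) transfers glycogen to ATP (saturating as m
    fills); Psi2 = k_m m consumes ATP; ``kappa * drive`` replenishes g.
    """
    psi1 = params.k_g * np.asarray(g, dtype=float) * (1.0 - np.asarray(m) / params.m_max)
    psi2 = params.k_m * np.asarray(m, dtype=float)
    g_new = np.clip(g + dt * (-psi1 + params.kappa * np.asarray(drive)), 0.0, params.g_max)
    m_new = np.clip(m + dt * (-psi2 + psi1), 0.0, params.m_max)
    return g_new, m_new


def _drive_contribution(v, spiked, dt: float, met: MetabolicParams):
    """Per-step increment of the sliding-window drive sum."""
    if met.drive_mode == "raw":
        return v * dt
    if met.drive_mode == "rectified":
        return np.maximum(v - met.v_ref, 0.0) * dt
    return spiked.astype(float)


def _integrate(
    n: int,
    params: IzhikevichParams,
    met: MetabolicParams,
    T: float,
    dt: float,
    i_ext,
    seed: int,
    w_total: float = 0.0,
    syn_tau: float = 5.0,
    syn_weights=None,
    sigma_noise: float = 0.0,
    shared_glycogen: bool = False,
    init: dict | None = None,
    record_full: bool = False,
):
    """Shared Euler integrator for single units (n=1) and populations.

    ``i_ext`` is a constant or a callable t -> current (scalar or length-n).
    ``syn_weights`` overrides the homogeneous all-to-all coupling with an
    (n, n) weight matrix.  Randomness (current noise only) flows from
    ``seed``; with ``sigma_noise = 0`` the run is fully deterministic.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be > 0")
    n_steps = int(round(T / dt))
    rng = np.random.default_rng(seed)

    init = init or {}
    m = np.atleast_1d(np.asarray(init.get("m", 0.0), dtype=float)) * np.ones(n)
    g0 = init.get("g", 0.0)
    if shared_glycogen:
        g = float(np.mean(g0))
    else:
        g = np.atleast_1d(np.asarray(g0, dtype=float)) * np.ones(n)
    v = np.atleast_1d(np.asarray(init.get("v", -70.0), dtype=float)) * np.ones(n)
    u0 = init.get("u")
    if u0 is None:
        u = sensitivity_modulation(params, m) * v
    else:
        u = np.atleast_1d(np.asarray(u0, dtype=float)) * np.ones(n)
    s = np.atleast_1d(np.asarray(init.get("s", 0.0), dtype=float)) * np.ones(n)

    window = max(1, int(round(met.tau / dt)))
    buf = np.zeros((window, n))
    win_sum = np.zeros(n)
    ptr = 0
    last_spiked = np.zeros(n, dtype=bool)
    syn_decay = float(np.exp(-dt / syn_tau))

    spike_t: list[float] = []
    spike_id: list[int] = []
    rec_t = np.arange(n_steps + 1) * dt
    if record_full:
        rec_v = np.empty((n_steps + 1, n))
        rec_u = np.empty((n_steps + 1, n))
        rec_m = np.empty((n_steps + 1, n))
        rec_g = np.empty(n_steps + 1) if shared_glycogen else np.empty((n_steps + 1, n))
        rec_v[0], rec_u[0], rec_m[0], rec_g[0] = v, u, m, g
    rec_vmean = np.empty(n_steps + 1)
    rec_gmean = np.empty(n_steps + 1)
    rec_mmean = np.empty(n_steps + 1)
    rec_vmean[0], rec_gmean[0], rec_mmean[0] = v.mean(), np.mean(g), m.mean()

    for i in range(n_steps):
        t = i * dt
        # 1. sliding-window drive from activity up to and including time t
        contrib = _drive_contribution(v, last_spiked, dt, met)
        win_sum += contrib - buf[ptr]
        buf[ptr] = contrib
        ptr = (ptr + 1) % window
        drive = win_sum

        # 2. metabolic update (shared astrocyte pool averages the drive)
        if shared_glycogen:
            psi1 = met.k_g * g * (1.0 - m / met.m_max)
            g = float(
                np.clip(
                    g + dt * (-np.mean(psi1) + met.kappa * np.mean(drive)),
                    0.0,
                    met.g_max,
                )
            )
            m = np.clip(m + dt * (-met.k_m * m + psi1), 0.0, met.m_max)
        else:
            g, m = metabolic_step(g, m, drive, dt, met)

        # 3. effective sensitivity from the updated ATP level
        b_plus = sensitivity_modulation(params, m)

        # 4. input current: external + synaptic + noise
        i_now = i_ext(t) if callable(i_ext) else i_ext
        i_total = np.broadcast_to(np.asarray(i_now, dtype=float), (n,)).copy()
        if w_total != 0.0 or syn_weights is not None:
            if syn_weights is not None:
                i_total += syn_weights @ s
            else:
                i_total += (w_total / n) * s.sum()
        if sigma_noise > 0.0:
            i_total += sigma_noise / np.sqrt(dt) * rng.standard_normal(n)

        v, u, spiked = izhikevich_step(v, u, i_total, b_plus, dt, params)
        if spiked.any():
            t_spk = (i + 1) * dt
            for j in np.flatnonzero(spiked):
                spike_t.append(t_spk)
                spike_id.append(int(j))
        s = s * syn_decay + spiked
        last_spiked = spiked

        if record_full:
            rec_v[i + 1], rec_u[i + 1], rec_m[i + 1], rec_g[i + 1] = v, u, m, g
        rec_vmean[i + 1], rec_gmean[i + 1], rec_mmean[i + 1] = (
            v.mean(),
            np.mean(g),
            m.mean(),
        )

    raster = SpikeRaster(
        neuron_ids=np.asarray(spike_id, dtype=int),
        times=np.asarray(spike_t, dtype=float),
        n_neurons=n,
        duration=n_steps * dt,
        dt=dt,
    )
    final_state = {"v": v, "u": u, "g": g, "m": m, "s": s}
    full = (
        dict(v=rec_v, u=rec_u, m=rec_m, g=rec_g) if record_full else None
    )
    return raster, rec_t, rec_vmean, rec_gmean, rec_mmean, final_state, full


def simulate_unit(
    params: IzhikevichParams,
    met: MetabolicParams,
    T: float,
    dt: float = 0.1,
    i_fn=10.0,
    seed: int = 0,
    init: CANUnitState | None = None,
) -> UnitTrace:
    """Integrate one CAN unit for T ms and return its full trace.

    ``i_fn`` is a constant current or a callable t -> current.  The same
    integrator as :func:`simulate_population` is used with n = 1, no
    synapses and no noise, so a one-neuron population run reduces to this
    exactly.
    """
    init_d = None
    if init is not None:
        init_d = {"v": init.v, "g": init.g, "m": init.m}
        if init.u is not None:
            init_d["u"] = init.u
    raster, t, _, _, _, _, full = _integrate(
        1,
        params,
        met,
        T,
        dt,
        i_fn,
        seed,
        w_total=0.0,
        sigma_noise=0.0,
        shared_glycogen=False,
        init=init_d,
        record_full=True,
    )
    return UnitTrace(
        t=t,
        v=full["v"][:, 0],
        u=full["u"][:, 0],
        g=full["g"][:, 0],
        m=full["m"][:, 0],
        spike_times=raster.times,
        dt=dt,
    )


def simulate_population(
    config: PopulationConfig,
    params: IzhikevichParams,
    met: MetabolicParams,
    T: float,
    dt: float = 0.1,
    seed: int = 0,
    init: dict | None = None,
) -> PopulationResult:
    """Integrate a coupled CAN population and return raster + mean traces.

    Synaptic input to neuron i is ``I_dc + noise + sum_j w_ij s_j`` with a
    current-based exponential kernel; metabolic pools are shared (one
    glycogen pool, per-neuron ATP) or fully per-neuron per the config.
    The final state dict can seed a continuation run (hysteresis sweeps).
    """
    syn_weights = None
    w_total = config.w
    if config.coupling == "erdos_renyi":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        adj = rng.random((config.n, config.n)) < config.p_conn
        np.fill_diagonal(adj, False)
        syn_weights = adj * (config.w / (config.p_conn * config.n))
        w_total = 0.0
    raster, t, v_mean, g_mean, m_mean, final_state, _ = _integrate(
        config.n,
        params,
        met,
        T,
        dt,
        config.i_dc,
        seed,
        w_total=w_total,
        syn_tau=config.syn_tau,
        syn_weights=syn_weights,
        sigma_noise=config.sigma_noise,
        shared_glycogen=config.shared_glycogen,
        init=init,
        record_full=False,
    )
    return PopulationResult(
        raster=raster,
        t=t,
        v_mean=v_mean,
        g_mean=g_mean,
        m_mean=m_mean,
        final_state=final_state,
        dt=dt,
    )
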
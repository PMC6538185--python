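"""Three-compartment inferior-olive neuron model.

Each cell has a soma, a dendrite and an axon hillock carrying 12
Hodgkin-Huxley conductances.  The subthreshold oscillation (STO) emerges
from the interplay of the somatic low-threshold (T-type, Ca_v3.1) calcium
current, the dendritic high-threshold (P/Q-type, Ca_v2.1) calcium current,
the calcium-gated SK potassium current and the somatic HCN (h) current.
The T-type conductance is the main determinant of whether a cell
oscillates at rest, and is the parameter randomized across the population.

Units: potentials mV, time ms, conductances mS/cm^2, currents uA/cm^2,
capacitance uF/cm^2.  The dendritic calcium variable is in the model's own
concentration-like unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

__all__ = [
    "CellParameters",
    "CellState",
    "STOMetrics",
    "DEFAULT_RANDOM_RANGES",
    "randomize_population",
    "cell_derivatives",
    "simulate_single_cell",
    "characterize_sto",
    "rebound_sweep",
    "despike_trace",
    "initial_state",
    "params_table",
    "params_from_table",
]

C_M = 1.0  # membrane capacitance, uF/cm^2


@dataclass
class CellParameters:
    """Conductance set and passive constants of one model neuron.

    The wild-type leak is 0.010 mS/cm^2; networks without gap junctions use
    0.013 mS/cm^2 to compensate for the missing junctional leak.
    """

    # somatic conductances
    g_CaT: float = 1.0        # low-threshold Ca (Ca_v3.1); randomized 0.5-1.1
    g_Na_s: float = 150.0     # fast sodium
    g_Kdr_s: float = 9.0      # delayed-rectifier potassium (fast gate)
    g_K_s: float = 5.0        # slow potassium
    g_h: float = 0.12         # HCN
    g_ls: float = 0.010       # somatic leak
    # dendritic conductances
    g_CaPQ: float = 4.5       # high-threshold Ca (Ca_v2.1)
    g_KCa: float = 65.0       # Ca-activated K (SK)
    g_ld: float = 0.025       # dendritic leak
    # axonal conductances
    g_Na_a: float = 240.0     # axonal sodium
    g_K_a: float = 20.0       # axonal potassium
    g_la: float = 0.010       # axonal leak
    # intercompartment coupling
    g_int: float = 0.13       # internal coupling conductance
    p_soma_dend: float = 0.25  # somatic fraction of soma-dendrite surface
    p_soma_axon: float = 0.15  # axonal fraction of soma-axon surface
    # dendritic calcium kinetics
    ca_decay: float = 0.10         # 1/ms
    ca_influx_scale: float = 3.0   # concentration units per (uA/cm^2 * ms)
    sk_off_rate: float = 0.025     # SK channel closing rate, 1/ms
    sk_act_cap: float = 0.01       # ceiling of the Ca->SK opening rate, 1/ms
    # reversal potentials, mV
    E_Na: float = 55.0
    E_K: float = -75.0
    E_Ca: float = 120.0
    E_h: float = -43.0
    E_leak: float = 10.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("g_") and getattr(self, f.name) < 0:
                raise ValueError(f"conductance {f.name} must be >= 0")

    def with_extra_leak(self, dg: float) -> "CellParameters":
        """Copy with every compartment's leak raised by ``dg`` (gap-junction
        leak compensation for uncoupled networks)."""
        return replace(self, g_ls=self.g_ls + dg, g_ld=self.g_ld + dg,
                       g_la=self.g_la + dg)


PARAM_NAMES = [f.name for f in fields(CellParameters)]

#: Default randomization ranges: only the T-type conductance varies, over
#: the 0.5-1.1 mS/cm^2 band that yields a mixed population of oscillating
#: and non-oscillating cells.
DEFAULT_RANDOM_RANGES: dict[str, tuple[float, float]] = {"g_CaT": (0.5, 1.1)}


@dataclass
class CellState:
    """Dynamical state of one neuron (potentials, gates, dendritic Ca)."""

    V_soma: float = -60.0
    V_dend: float = -60.0
    V_axon: float = -60.0
    # somatic gates
    k_CaT: float = 0.5       # T-type activation
    l_CaT: float = 0.5       # T-type inactivation
    h_Na_s: float = 0.5      # Na inactivation (activation instantaneous)
    x_Kdr_s: float = 0.1     # delayed-rectifier gate
    n_K_s: float = 0.1       # slow K gate
    q_h: float = 0.1         # HCN gate
    # dendritic gates
    r_CaPQ: float = 0.01     # P/Q-type activation
    s_KCa: float = 0.01      # SK gate
    Ca_dend: float = 5.0     # dendritic calcium
    # axonal gates
    h_Na_a: float = 0.5
    x_K_a: float = 0.1

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "CellState":
        return cls(**{f.name: float(v) for f, v in zip(fields(cls), a)})


STATE_NAMES = [f.name for f in fields(CellState)]
N_STATE = len(STATE_NAMES)

GATE_NAMES = [n for n in STATE_NAMES if n not in
              ("V_soma", "V_dend", "V_axon", "Ca_dend")]


@dataclass
class STOMetrics:
    """Summary of a cell's subthreshold oscillation."""

    amplitude: float          # median peak-to-trough excursion, mV
    frequency: float          # dominant subthreshold frequency, Hz
    is_oscillator: bool

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.frequency < 0:
            raise ValueError("amplitude and frequency must be >= 0")


#: Peak-to-trough amplitude (mV) above which a cell counts as oscillating.
OSCILLATOR_AMPLITUDE_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# population randomization
# ---------------------------------------------------------------------------

def randomize_population(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.SeedSequence = 0,
    base: CellParameters | None = None,
) -> list[CellParameters]:
    """Draw ``n`` parameter sets with uniform randomization of ``ranges``.

    Parameters not named in ``ranges`` are copied from ``base`` (default
    :class:`CellParameters`).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = DEFAULT_RANDOM_RANGES
    base = base if base is not None else CellParameters()
    for name, (lo, hi) in ranges.items():
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        if lo > hi:
            raise ValueError(f"invalid range for {name}: low {lo} > high {hi}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        kw = {name: float(rng.uniform(lo, hi))
              for name, (lo, hi) in ranges.items()}
        out.append(replace(base, **kw))
    return out


def params_table(cells: list[CellParameters]) -> pd.DataFrame:
    """One row per cell, one column per parameter."""
    return pd.DataFrame([{n: getattr(c, n) for n in PARAM_NAMES}
                         for c in cells])


def params_from_table(df: pd.DataFrame) -> list[CellParameters]:
    return [CellParameters(**{n: float(row[n]) for n in PARAM_NAMES})
            for _, row in df.iterrows()]


def pack_params(cells: list[CellParameters]) -> np.ndarray:
    """(n_cells, n_params) float array in ``PARAM_NAMES`` order."""
    return np.array([[getattr(c, n) for n in PARAM_NAMES] for c in cells],
                    dtype=np.float64)


# ---------------------------------------------------------------------------
# gating kinetics (shared by the reference RHS and the compiled kernel)
# ---------------------------------------------------------------------------

def _kinetics_soma(v: float) -> tuple[float, ...]:
    """Steady states and time constants of the somatic gates at potential v."""
    k_inf = 1.0 / (1.0 + math.exp(-(v + 61.0) / 4.2))
    l_inf = 1.0 / (1.0 + math.exp((v + 85.5) / 8.5))
    tau_l = 20.0 * math.exp((v + 160.0) / 30.0) / (
        1.0 + math.exp((v + 84.0) / 7.3)) + 35.0
    h_inf = 1.0 / (1.0 + math.exp((v + 70.0) / 5.8))
    tau_h = 3.0 * math.exp(-(v + 40.0) / 33.0)
    n_inf = 1.0 / (1.0 + math.exp(-(v + 3.0) / 10.0))
    tau_n = 5.0 + 47.0 * math.exp(-(v + 50.0) / 900.0)
    dv = v + 25.0
    if abs(dv) < 1e-9:
        alpha_x = 1.3
    else:
        alpha_x = 0.13 * dv / (1.0 - math.exp(-dv / 10.0))
    beta_x = 1.69 * math.exp(-0.0125 * (v + 35.0))
    q_inf = 1.0 / (1.0 + math.exp((v + 80.0) / 4.0))
    tau_q = 1.0 / (math.exp(-0.086 * v - 14.6) + math.exp(0.070 * v - 1.87))
    return k_inf, l_inf, tau_l, h_inf, tau_h, n_inf, tau_n, alpha_x, beta_x, \
        q_inf, tau_q


def _kinetics_dend(v: float, ca: float,
                   sk_off: float = 0.025,
                   sk_cap: float = 0.01) -> tuple[float, ...]:
    alpha_r = 1.7 / (1.0 + math.exp(-(v - 5.0) / 13.9))
    dv = v + 8.5
    if abs(dv) < 1e-9:
        beta_r = 0.1
    else:
        beta_r = 0.02 * dv / (math.exp(dv / 5.0) - 1.0)
    alpha_s = min(2.0e-5 * ca, sk_cap)
    return alpha_r, beta_r, alpha_s, sk_off


def _kinetics_axon(v: float) -> tuple[float, ...]:
    h_inf = 1.0 / (1.0 + math.exp((v + 60.0) / 5.8))
    tau_h = 1.5 * math.exp(-(v + 40.0) / 33.0)
    dv = v + 25.0
    if abs(dv) < 1e-9:
        alpha_x = 1.3
    else:
        alpha_x = 0.13 * dv / (1.0 - math.exp(-dv / 10.0))
    beta_x = 1.69 * math.exp(-0.0125 * (v + 35.0))
    return h_inf, tau_h, alpha_x, beta_x


def cell_derivatives(
    state: CellState,
    params: CellParameters,
    I_soma_ext: float = 0.0,
    I_dend_ext: float = 0.0,
    I_dend_gap: float = 0.0,
) -> CellState:
    """Time derivative of every state field (reference implementation).

    External currents are depolarizing-positive current densities entering
    the stated compartment only; gap-junction current enters the dendrite.
    """
    arr = state.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite cell state")
    p = params
    vs, vd, va = state.V_soma, state.V_dend, state.V_axon

    # --- soma ---------------------------------------------------------
    (k_inf, l_inf, tau_l, h_inf, tau_h, n_inf, tau_n,
     alpha_x, beta_x, q_inf, tau_q) = _kinetics_soma(vs)
    m_inf = 1.0 / (1.0 + math.exp(-(vs + 30.0) / 5.5))
    I_CaT = p.g_CaT * state.k_CaT ** 3 * state.l_CaT * (vs - p.E_Ca)
    I_Na_s = p.g_Na_s * m_inf ** 3 * state.h_Na_s * (vs - p.E_Na)
    I_Kdr_s = p.g_Kdr_s * state.x_Kdr_s ** 4 * (vs - p.E_K)
    I_K_s = p.g_K_s * state.n_K_s ** 4 * (vs - p.E_K)
    I_h = p.g_h * state.q_h * (vs - p.E_h)
    I_ls = p.g_ls * (vs - p.E_leak)
    I_ds = (p.g_int / p.p_soma_dend) * (vs - vd)
    I_as = (p.g_int / (1.0 - p.p_soma_axon)) * (vs - va)
    dvs = (-(I_CaT + I_Na_s + I_Kdr_s + I_K_s + I_h + I_ls + I_ds + I_as)
           + I_soma_ext) / C_M

    # --- dendrite -----------------------------------------------------
    alpha_r, beta_r, alpha_s, beta_s = _kinetics_dend(vd, state.Ca_dend, p.sk_off_rate, p.sk_act_cap)
    I_CaPQ = p.g_CaPQ * state.r_CaPQ ** 2 * (vd - p.E_Ca)
    I_KCa = p.g_KCa * state.s_KCa * (vd - p.E_K)
    I_ld = p.g_ld * (vd - p.E_leak)
    I_sd = (p.g_int / (1.0 - p.p_soma_dend)) * (vd - vs)
    dvd = (-(I_CaPQ + I_KCa + I_ld + I_sd) + I_dend_ext + I_dend_gap) / C_M

    # --- axon ---------------------------------------------------------
    h_inf_a, tau_h_a, alpha_xa, beta_xa = _kinetics_axon(va)
    m_inf_a = 1.0 / (1.0 + math.exp(-(va + 30.0) / 5.5))
    I_Na_a = p.g_Na_a * m_inf_a ** 3 * state.h_Na_a * (va - p.E_Na)
    I_K_a = p.g_K_a * state.x_K_a ** 4 * (va - p.E_K)
    I_la = p.g_la * (va - p.E_leak)
    I_sa = (p.g_int / p.p_soma_axon) * (va - vs)
    dva = (-(I_Na_a + I_K_a + I_la + I_sa)) / C_M

    return CellState(
        V_soma=dvs,
        V_dend=dvd,
        V_axon=dva,
        k_CaT=(k_inf - state.k_CaT) / 1.0,
        l_CaT=(l_inf - state.l_CaT) / tau_l,
        h_Na_s=(h_inf - state.h_Na_s) / tau_h,
        x_Kdr_s=alpha_x * (1.0 - state.x_Kdr_s) - beta_x * state.x_Kdr_s,
        n_K_s=(n_inf - state.n_K_s) / tau_n,
        q_h=(q_inf - state.q_h) / tau_q,
        r_CaPQ=alpha_r * (1.0 - state.r_CaPQ) - beta_r * state.r_CaPQ,
        s_KCa=alpha_s * (1.0 - state.s_KCa) - beta_s * state.s_KCa,
        Ca_dend=-p.ca_influx_scale * I_CaPQ - p.ca_decay * state.Ca_dend,
        h_Na_a=(h_inf_a - state.h_Na_a) / tau_h_a,
        x_K_a=alpha_xa * (1.0 - state.x_K_a) - beta_xa * state.x_K_a,
    )


def initial_state(params: CellParameters, v0: float = -60.0) -> CellState:
    """Gates at their steady states for a uniform resting potential v0."""
    (k_inf, l_inf, _, h_inf, _, n_inf, _, ax, bx, q_inf, _) = \
        _kinetics_soma(v0)
    alpha_r, beta_r, _, _ = _kinetics_dend(v0, 0.0, params.sk_off_rate, params.sk_act_cap)
    r0 = alpha_r / (alpha_r + beta_r)
    p = params
    i_capq = p.g_CaPQ * r0 ** 2 * (v0 - p.E_Ca)
    ca0 = max(-p.ca_influx_scale * i_capq / p.ca_decay, 0.0)
    alpha_s = min(2.0e-5 * ca0, 0.01)
    h_inf_a, _, axa, bxa = _kinetics_axon(v0)
    sk0 = alpha_s / (alpha_s + params.sk_off_rate)
    return CellState(
        V_soma=v0, V_dend=v0, V_axon=v0,
        k_CaT=k_inf, l_CaT=l_inf, h_Na_s=h_inf,
        x_Kdr_s=ax / (ax + bx), n_K_s=n_inf, q_h=q_inf,
        r_CaPQ=r0, s_KCa=sk0, Ca_dend=ca0,
        h_Na_a=h_inf_a, x_K_a=axa / (axa + bxa),
    )


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------

def simulate_single_cell(
    params: CellParameters,
    input_current: np.ndarray | float | None = None,
    dt: float = 0.025,
    T: float = 1000.0,
    state0: CellState | None = None,
    input_compartment: str = "soma",
) -> dict[str, np.ndarray]:
    """Forward-Euler integration of one isolated cell.

    ``input_current`` may be a scalar, ``None`` (no input) or a time series
    sampled at ``dt`` (length >= floor(T/dt)+1).  Returns full-resolution
    traces ``t``, ``V_soma``, ``V_dend``, ``V_axon``, ``Ca_dend`` of length
    floor(T/dt)+1.  Raises :class:`FloatingPointError` naming the step on
    numerical blow-up (|V| > 200 mV or non-finite).
    """
    from . import _kernels

    if dt <= 0:
        raise ValueError("dt must be > 0")
    if T < dt:
        raise ValueError("T must be >= dt")
    n_steps = int(math.floor(T / dt))
    n_samp = n_steps + 1
    if input_current is None:
        i_ext = np.zeros(n_samp)
    elif np.isscalar(input_current):
        i_ext = np.full(n_samp, float(input_current))
    else:
        i_ext = np.asarray(input_current, dtype=np.float64)
        if i_ext.size < n_samp:
            raise ValueError("input_current shorter than floor(T/dt)+1")
        i_ext = i_ext[:n_samp]
    if input_compartment not in ("soma", "dend"):
        raise ValueError("input_compartment must be 'soma' or 'dend'")
    soma_in = input_compartment == "soma"

    P = pack_params([params])
    state = (state0 or initial_state(params)).as_array()[None, :].copy()
    i_soma = i_ext[:, None] if soma_in else np.zeros((n_samp, 1))
    i_dend = np.zeros((n_samp, 1)) if soma_in else i_ext[:, None]

    rec_vs, rec_vd, rec_va, rec_ca, bad = _kernels.integrate_uncoupled(
        state, P, dt, n_steps, i_soma, i_dend)
    if bad >= 0:
        raise FloatingPointError(
            f"numerical blow-up at step {bad} (t = {bad * dt:.3f} ms)")
    t = np.arange(n_samp) * dt
    return {"t": t, "V_soma": rec_vs[:, 0], "V_dend": rec_vd[:, 0],
            "V_axon": rec_va[:, 0], "Ca_dend": rec_ca[:, 0]}


# ---------------------------------------------------------------------------
# STO characterization
# ---------------------------------------------------------------------------

def despike_trace(trace: np.ndarray, dt: float, threshold: float = -30.0,
                  clip_ms: float = 20.0) -> np.ndarray:
    """Clip +-clip_ms around threshold crossings and linearly interpolate."""
    v = np.asarray(trace, dtype=np.float64).copy()
    above = v >= threshold
    if not above.any():
        return v
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    half = max(int(round(clip_ms / dt)), 1)
    mask = np.zeros(v.size, dtype=bool)
    for c in crossings:
        mask[max(c - half, 0):min(c + half + 1, v.size)] = True
    good = np.flatnonzero(~mask)
    if good.size < 2:
        return np.full_like(v, np.median(v))
    v[mask] = np.interp(np.flatnonzero(mask), good, v[good])
    return v


def characterize_sto(trace: np.ndarray, dt: float,
                     max_freq: float = 20.0) -> STOMetrics:
    """Amplitude / frequency / oscillator classification of a voltage trace.

    Amplitude is the median peak-to-trough excursion between successive
    extrema of the lightly smoothed trace; frequency is the dominant
    spectral peak below ``max_freq`` Hz.  ``trace`` must cover >= 1 s and
    should have spikes removed (see :func:`despike_trace`).
    """
    from scipy import signal

    v = np.asarray(trace, dtype=np.float64)
    fs = 1000.0 / dt  # Hz
    if v.size < fs:  # 1 s worth of samples
        raise ValueError("trace shorter than 1 s")
    v = v - v.mean()
    # light low-pass to suppress integration jitter before peak picking
    sos = signal.butter(2, min(max_freq * 2, 0.45 * fs), "low", fs=fs,
                        output="sos")
    vf = signal.sosfiltfilt(sos, v)

    peaks, _ = signal.find_peaks(vf)
    troughs, _ = signal.find_peaks(-vf)
    if peaks.size == 0 or troughs.size == 0:
        return STOMetrics(0.0, 0.0, False)
    ext = np.sort(np.concatenate([peaks, troughs]))
    excurs = np.abs(np.diff(vf[ext]))
    amplitude = float(np.median(excurs)) if excurs.size else 0.0

    freqs, pxx = signal.welch(vf, fs=fs, nperseg=min(v.size, int(4 * fs)))
    band = (freqs > 0.5) & (freqs <= max_freq)
    if band.any() and pxx[band].max() > 0:
        frequency = float(freqs[band][np.argmax(pxx[band])])
    else:
        frequency = 0.0
    osc = amplitude >= OSCILLATOR_AMPLITUDE_THRESHOLD
    if not osc:
        frequency = 0.0  # non-oscillating cells report zero frequency
    return STOMetrics(amplitude, frequency, osc)


# ---------------------------------------------------------------------------
# rebound sweep
# ---------------------------------------------------------------------------

def _classify_post_pulse(t: np.ndarray, vs: np.ndarray, pulse_end: float,
                         dt: float) -> str:
    """Label post-pulse behavior of a somatic trace."""
    post = vs[t > pulse_end]
    if post.size == 0:
        return "no_rebound"
    # saturated depolarization: mean V_soma > -30 mV over > 500 ms
    n500 = int(500.0 / dt)
    if post.size >= n500 and post[-n500:].mean() > -30.0:
        return "saturated_depolarization"
    # rebound: a spike 50-250 ms after pulse offset without sustained input
    w = (t > pulse_end + 50.0) & (t <= pulse_end + 250.0)
    seg = vs[w]
    if seg.size and (seg >= -30.0).any():
        return "rebound"
    return "no_rebound"


def rebound_sweep(
    g_CaT_grid: np.ndarray,
    g_CaPQ_grid: np.ndarray,
    pulse_amplitude: float = 15.0,
    pulse_duration: float = 20.0,
    pulse_onset: float = 100.0,
    T: float = 1200.0,
    dt: float = 0.025,
    base: CellParameters | None = None,
) -> np.ndarray:
    """Post-spike behavior labels over a (g_CaT, g_CaPQ) grid.

    A depolarizing pulse is applied at ``pulse_onset``; the trace after the
    pulse is classified as ``rebound``, ``no_rebound`` or
    ``saturated_depolarization``.  Blow-ups yield ``invalid`` for that grid
    point and the sweep continues.  Returns an object array of shape
    (len(g_CaT_grid), len(g_CaPQ_grid)).
    """
    g_CaT_grid = np.atleast_1d(np.asarray(g_CaT_grid, dtype=float))
    g_CaPQ_grid = np.atleast_1d(np.asarray(g_CaPQ_grid, dtype=float))
    if g_CaT_grid.size == 0 or g_CaPQ_grid.size == 0:
        raise ValueError("grids must be non-empty")
    base = base if base is not None else CellParameters()
    n_samp = int(math.floor(T / dt)) + 1
    t = np.arange(n_samp) * dt
    i_ext = np.where((t >= pulse_onset) & (t < pulse_onset + pulse_duration),
                     pulse_amplitude, 0.0)
    labels = np.empty((g_CaT_grid.size, g_CaPQ_grid.size), dtype=object)
    for i, gt in enumerate(g_CaT_grid):
        for j, gq in enumerate(g_CaPQ_grid):
            p = replace(base, g_CaT=float(gt), g_CaPQ=float(gq))
            try:
                out = simulate_single_cell(p, i_ext, dt=dt, T=T)
            except FloatingPointError:
                labels[i, j] = "invalid"
                continue
            labels[i, j] = _classify_post_pulse(
                out["t"], out["V_soma"], pulse_onset + pulse_duration, dt)
    return labels
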
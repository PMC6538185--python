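"""Phase extraction, Kuramoto synchrony and the tandem-pulse PRC.

Membrane phase is obtained in two stages: a protophase from the analytic
signal of the band-passed (1-15 Hz), despiked trace, and a protophase-to-
phase transformation that removes the waveform-shape dependence so the
phase advances uniformly on average over a cycle (Fourier-series
correction of the empirical protophase density).  This compensates for the
different rates of membrane-potential change that the ionic mechanisms
impose at different parts of the subthreshold-oscillation cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cell import despike_trace

__all__ = [
    "PhaseSeries",
    "SynchronyTrace",
    "PhaseResponseCurve",
    "compute_phase",
    "instantaneous_frequency",
    "kuramoto_order",
    "phase_distribution_map",
    "run_prc_protocol",
]


@dataclass
class PhaseSeries:
    """Unwrapped per-cell phase on the recording grid."""

    phase: np.ndarray            # (n_samples, n_cells) or (n_samples,)
    dt: float                    # ms
    confident: np.ndarray | bool = True   # per-cell oscillatory-power flag


@dataclass
class SynchronyTrace:
    """Kuramoto order parameter K(t) in [0, 1] and mean phase Psi(t)."""

    K: np.ndarray
    Psi: np.ndarray
    dt: float


@dataclass
class PhaseResponseCurve:
    """Probe phases with per-probe phase shift and spike probability."""

    probe_phases: np.ndarray          # radians
    phase_shift: np.ndarray           # radians (advance > 0)
    spike_probability: np.ndarray     # fraction of masked cells spiking
    sto_period_ms: float

    def __post_init__(self) -> None:
        p = np.asarray(self.spike_probability, float)
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValueError("spike probabilities must lie in [0, 1]")


def _protophase_to_phase(theta: np.ndarray, order: int = 10) -> np.ndarray:
    """Fourier-series transformation making phase growth uniform.

    theta: unwrapped protophase.  Returns the corrected unwrapped phase
    phi(theta) = theta + sum_n 2 Re[ S_n/(i n) (e^{i n theta} - 1) ] with
    S_n the empirical Fourier coefficients <e^{-i n theta}>.
    """
    phi = theta.astype(float).copy()
    for n in range(1, order + 1):
        sn = np.mean(np.exp(-1j * n * theta))
        phi += 2.0 * np.real(sn / (1j * n) * (np.exp(1j * n * theta) - 1.0))
    return phi


def compute_phase(
    trace: np.ndarray,
    dt: float,
    band: tuple[float, float] = (1.0, 15.0),
    order: int = 10,
    min_power_ratio: float = 0.1,
) -> PhaseSeries:
    """Instantaneous phase of one or more membrane-potential traces.

    ``trace``: (n_samples,) or (n_samples, n_cells) at ``dt`` ms; must
    cover >= 2 s.  Spikes are clipped first.  Cells whose band power is
    below ``min_power_ratio`` of total power are flagged low-confidence
    (their phase is still returned).
    """
    v = np.asarray(trace, dtype=float)
    one_d = v.ndim == 1
    if one_d:
        v = v[:, None]
    fs = 1000.0 / dt
    if v.shape[0] < 2 * fs:
        raise ValueError("trace must cover at least 2 s")
    lo, hi = band
    sos = signal.butter(2, (lo, min(hi, 0.45 * fs)), "bandpass", fs=fs,
                        output="sos")
    phases = np.empty_like(v)
    confident = np.empty(v.shape[1], dtype=bool)
    for c in range(v.shape[1]):
        x = despike_trace(v[:, c], dt)
        xf = signal.sosfiltfilt(sos, x - x.mean())
        total = np.var(x - x.mean())
        confident[c] = total > 0 and np.var(xf) / total >= min_power_ratio
        theta = np.unwrap(np.angle(signal.hilbert(xf)))
        phases[:, c] = _protophase_to_phase(theta, order=order)
    return PhaseSeries(phase=phases[:, 0] if one_d else phases, dt=dt,
                       confident=bool(confident[0]) if one_d else confident)


def instantaneous_frequency(phase: PhaseSeries) -> np.ndarray:
    """f(t) = dphi/dt / 2pi via first-order finite difference, in Hz."""
    p = np.atleast_2d(phase.phase.T).T
    f = np.diff(p, axis=0) / (2.0 * np.pi * phase.dt) * 1000.0
    return f[:, 0] if phase.phase.ndim == 1 else f


def kuramoto_order(phases: np.ndarray,
                   subset: np.ndarray | None = None,
                   dt: float = 1.0) -> SynchronyTrace:
    """Kuramoto order parameter K(t) = |<e^{i phi_n(t)}>_n| over cells.

    ``phases``: (n_samples, n_cells); ``subset``: optional index/boolean
    mask choosing the cell group (e.g. stimulated cells only).
    """
    p = np.asarray(phases, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("need phases of at least 2 cells")
    if subset is not None:
        p = p[:, subset]
        if p.shape[1] < 2:
            raise ValueError("subset must keep at least 2 cells")
    z = np.exp(1j * p).mean(axis=1)
    return SynchronyTrace(K=np.abs(z), Psi=np.angle(z), dt=dt)


def phase_distribution_map(
    phases: np.ndarray,
    n_phase_bins: int = 100,
    time_stride: int = 1,
) -> np.ndarray:
    """Time x phase occupancy histogram (rows normalized to 1).

    Phase bin size 2pi/n_phase_bins; one row per (strided) time sample.
    """
    p = np.mod(np.asarray(phases, dtype=float), 2.0 * np.pi)
    p = np.atleast_2d(p.T).T[::time_stride]
    edges = np.linspace(0.0, 2.0 * np.pi, n_phase_bins + 1)
    out = np.empty((p.shape[0], n_phase_bins))
    for i, row in enumerate(p):
        h, _ = np.histogram(row, bins=edges)
        out[i] = h / row.size
    return out


# ---------------------------------------------------------------------------
# tandem-pulse phase-response experiment
# ---------------------------------------------------------------------------

def _mean_masked_peaks(res, mask_idx, after_ms: float):
    """Peak times (ms) of the mean masked somatic potential after a time."""
    vm = res.V_soma[:, mask_idx].mean(axis=1)
    vm = despike_trace(vm, float(res.time[1] - res.time[0]))
    pk, _ = signal.find_peaks(vm, prominence=0.25)
    t = res.time[pk]
    return t[t > after_ms]


def run_prc_protocol(
    cells,
    network,
    mask,
    reset_at_ms: float = 1000.0,
    n_probe: int = 13,
    n_cycles: float = 2.0,
    g_peak: float = 0.15,
    spike_window_ms: float = 40.0,
    T_post_ms: float = 800.0,
    dt: float = 0.025,
    seed: int = 0,
) -> PhaseResponseCurve:
    """Tandem-stimulation phase-response experiment on the noiseless network.

    A reset pulse is delivered to the masked cells at ``reset_at_ms``; the
    interval to the next peak of their mean membrane potential defines the
    post-reset cycle.  ``n_probe`` probe pulses at offsets spanning
    ``n_cycles`` subthreshold cycles are then delivered in separate
    simulations.  For each probe the fraction of masked cells spiking
    within ``spike_window_ms`` after the probe, and the shift of the next
    subthreshold peak relative to the unprobed reference run (radians,
    advance positive), are recorded.
    """
    from .engine import run_network
    from .inputs import build_protocol

    if n_probe < 2:
        raise ValueError("need at least 2 probe offsets")
    mask_idx = mask.indices
    T = reset_at_ms + T_post_ms

    # align the reset pulse with a peak of the ongoing subthreshold
    # oscillation (a phase known to trigger spiking and resetting)
    free = run_network(cells, network, ou=None, protocol=None, mask=None,
                       T=reset_at_ms + 400.0, dt=dt, seed=seed, rec_dt=1.0)
    free_peaks = _mean_masked_peaks(free, mask_idx, reset_at_ms * 0.5)
    if free_peaks.size:
        reset_at_ms = float(free_peaks[np.argmin(
            np.abs(free_peaks - reset_at_ms))])
        T = reset_at_ms + T_post_ms

    prot0 = build_protocol("single", t0=reset_at_ms)
    ref = run_network(cells, network, ou=None, protocol=prot0, mask=mask,
                      T=T, dt=dt, seed=seed, g_peak=g_peak, rec_dt=1.0)
    peaks = _mean_masked_peaks(ref, mask_idx, reset_at_ms + 20.0)
    if peaks.size < 3:
        raise ValueError("no post-reset subthreshold oscillation detected")
    period = float(np.median(np.diff(peaks)))

    offsets = np.linspace(0.0, n_cycles * period, n_probe)[1:]
    # label each probe by the actual phase of the post-reset oscillation:
    # peaks of the reference run mark multiples of 2 pi
    ref_marks = np.concatenate([[reset_at_ms], peaks])
    ref_phase = 2.0 * np.pi * np.arange(ref_marks.size)
    probe_phases = np.interp(reset_at_ms + offsets, ref_marks, ref_phase,
                             right=np.nan)
    spike_prob = np.empty(offsets.size)
    shifts = np.empty(offsets.size)
    for k, off in enumerate(offsets):
        prot = build_protocol("tandem", t0=reset_at_ms, offset=float(off))
        res = run_network(cells, network, ou=None, protocol=prot, mask=mask,
                          T=T, dt=dt, seed=seed, g_peak=g_peak, rec_dt=1.0)
        t_probe = reset_at_ms + off
        n_spk = sum(
            1 for i in mask_idx
            if np.any((res.spike_times[i] > t_probe)
                      & (res.spike_times[i] <= t_probe + spike_window_ms)))
        spike_prob[k] = n_spk / mask_idx.size
        # next subthreshold peak after the probe settles (skip the evoked
        # transient itself by looking 1/4 cycle past the probe)
        after = t_probe + 0.25 * period
        p_probe = _mean_masked_peaks(res, mask_idx, after)
        p_ref = peaks[peaks > after]
        if p_probe.size and p_ref.size:
            raw = 2.0 * np.pi * (p_ref[0] - p_probe[0]) / period
            # fold into (-pi, pi]: peak matching is cycle-ambiguous
            shifts[k] = (raw + np.pi) % (2.0 * np.pi) - np.pi
        else:
            shifts[k] = np.nan
    return PhaseResponseCurve(probe_phases=probe_phases,
                              phase_shift=shifts,
                              spike_probability=spike_prob,
                              sto_period_ms=period)
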
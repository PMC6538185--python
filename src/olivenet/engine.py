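"""Coupled-network integration, spike detection and run management.

All cells advance together under forward Euler; gap-junction currents are
recomputed every step from the instantaneous dendritic potentials.  One
master seed spawns named substreams (cell randomization, connectivity,
OU independent, OU shared, mask) so changing one component leaves the
others' draws unchanged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cell import (CellParameters, PARAM_NAMES, initial_state, pack_params,
                   params_from_table, params_table, randomize_population)
from .inputs import (OUGenerator, OUParams, ProtocolSchedule, StimulusMask,
                     synaptic_waveform)
from .network import GapJunctionNetwork, LatticeGeometry, build_connectivity

__all__ = [
    "SimResult",
    "SpikeTrainSet",
    "run_network",
    "detect_spikes",
    "spike_triggered_average",
    "calibrate_ou_sigma",
    "substreams",
    "wild_type_network",
    "gapless_network",
    "SPIKE_THRESHOLD_MV",
    "SPIKE_MIN_ISI_MS",
]

log = logging.getLogger("olivenet")

SPIKE_THRESHOLD_MV = -30.0
SPIKE_MIN_ISI_MS = 10.0
E_AMPA_MV = 0.0

#: fixed substream order hanging off the master seed
_SUBSTREAMS = ("cells", "connectivity", "ou_independent", "ou_shared",
               "mask")


def substreams(seed: int) -> dict[str, np.random.SeedSequence]:
    """Named child seeds of one master seed (stable assignment)."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return dict(zip(_SUBSTREAMS, children))


@dataclass
class SimResult:
    """Recorded traces, spikes and provenance of one network run."""

    time: np.ndarray                  # recording grid, ms
    V_soma: np.ndarray                # (n_rec, n_cells)
    V_dend: np.ndarray                # (n_rec, n_cells)
    spike_times: list[np.ndarray]     # per cell, ms, full resolution
    stimulus_times: np.ndarray        # ms
    config: dict                      # resolved run configuration
    seed: int

    @property
    def n_cells(self) -> int:
        return self.V_soma.shape[1]

    @property
    def duration_ms(self) -> float:
        return float(self.config["T"])

    def firing_rates(self) -> np.ndarray:
        """Per-cell mean rate over the run, Hz."""
        return np.array([1000.0 * s.size / self.duration_ms
                         for s in self.spike_times])

    def to_spike_trains(self, group: str = "model") -> "SpikeTrainSet":
        return SpikeTrainSet(trains=[s.copy() for s in self.spike_times],
                             stimulus_times=self.stimulus_times.copy(),
                             duration_ms=self.duration_ms, group=group)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(self.config)
            f.attrs["seed"] = self.seed
            f.create_dataset("time", data=self.time)
            f.create_dataset("V_soma", data=self.V_soma)
            f.create_dataset("V_dend", data=self.V_dend)
            f.create_dataset("stimulus_times", data=self.stimulus_times)
            g = f.create_group("spikes")
            for i, s in enumerate(self.spike_times):
                g.create_dataset(str(i), data=s)

    @classmethod
    def from_hdf5(cls, path) -> "SimResult":
        import h5py

        with h5py.File(path, "r") as f:
            spikes = [f["spikes"][str(i)][()]
                      for i in range(len(f["spikes"]))]
            return cls(time=f["time"][()], V_soma=f["V_soma"][()],
                       V_dend=f["V_dend"][()],
                       spike_times=spikes,
                       stimulus_times=f["stimulus_times"][()],
                       config=json.loads(f.attrs["config"]),
                       seed=int(f.attrs["seed"]))


@dataclass
class SpikeTrainSet:
    """Spike and stimulus times per cell; the simulator/statistics
    interchange object."""

    trains: list[np.ndarray]
    stimulus_times: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    duration_ms: float = 0.0
    group: str = ""
    cell_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for i, t in enumerate(self.trains):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"spike times of cell {i} must be "
                                 "strictly increasing")
            if t.size and (t.min() < 0 or t.max() > self.duration_ms):
                raise ValueError(f"spike times of cell {i} outside "
                                 "recording duration")
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.cell_ids is None:
            self.cell_ids = list(range(len(self.trains)))

    @property
    def n_cells(self) -> int:
        return len(self.trains)

    def to_table(self, path, stimulus_path=None) -> None:
        """Delimited text: columns cell_id, spike_time_ms; stimuli in a
        companion file (one onset per line)."""
        with open(path, "w") as fh:
            fh.write(f"# duration_ms={self.duration_ms!r} "
                     f"group={self.group}\n")
            fh.write("cell_id\tspike_time_ms\n")
            for cid, train in zip(self.cell_ids, self.trains):
                for t in train:
                    fh.write(f"{cid}\t{float(t)!r}\n")
        if stimulus_path is not None:
            with open(stimulus_path, "w") as fh:
                fh.write("stimulus_time_ms\n")
                for t in self.stimulus_times:
                    fh.write(f"{float(t)!r}\n")

    @classmethod
    def from_table(cls, path, stimulus_path=None) -> "SpikeTrainSet":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=", 1) for kv in header)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        ids = sorted(df.cell_id.unique().tolist()) if len(df) else []
        trains = [np.sort(df.loc[df.cell_id == cid,
                                 "spike_time_ms"].to_numpy())
                  for cid in ids]
        stim = np.empty(0)
        if stimulus_path is not None:
            sdf = pd.read_csv(stimulus_path, float_precision="round_trip")
            stim = sdf["stimulus_time_ms"].to_numpy()
        return cls(trains=trains, stimulus_times=stim,
                   duration_ms=float(meta["duration_ms"]),
                   group=meta.get("group", ""), cell_ids=ids)


# ---------------------------------------------------------------------------
# network presets
# ---------------------------------------------------------------------------

def wild_type_network(seed: int, geometry: LatticeGeometry | None = None,
                      gc_mean: float = 0.04):
    """Randomized cells + default gap-junction connectivity (leak 0.010)."""
    geometry = geometry or LatticeGeometry()
    ss = substreams(seed)
    cells = randomize_population(geometry.n_cells, seed=ss["cells"])
    net = build_connectivity(geometry, gc_mean=gc_mean,
                             seed=ss["connectivity"])
    return cells, net


def gapless_network(seed: int, geometry: LatticeGeometry | None = None,
                    extra_leak: float = 0.003):
    """Zero adjacency with each leak raised by 0.003 mS/cm^2 (somatic leak
    0.010 -> 0.013) to compensate the missing junctional load."""
    geometry = geometry or LatticeGeometry()
    ss = substreams(seed)
    base = CellParameters().with_extra_leak(extra_leak)
    cells = randomize_population(geometry.n_cells, seed=ss["cells"],
                                 base=base)
    net = GapJunctionNetwork(np.zeros((geometry.n_cells,
                                       geometry.n_cells)), gc_mean=0.0)
    return cells, net


# ---------------------------------------------------------------------------
# main runner
# ---------------------------------------------------------------------------

def run_network(
    cells: list[CellParameters],
    network: GapJunctionNetwork,
    ou: OUParams | None = None,
    protocol: ProtocolSchedule | None = None,
    mask: StimulusMask | None = None,
    T: float = 10000.0,
    dt: float = 0.025,
    seed: int = 0,
    rec_dt: float = 1.0,
    g_peak: float = 0.15,
    ou_compartment: str = "soma",
    dc_soma: np.ndarray | None = None,
    dc_dend: np.ndarray | None = None,
    dc_soma_step: np.ndarray | None = None,
    dc_onset_ms: float = 0.0,
    chunk_ms: float = 500.0,
) -> SimResult:
    """Integrate the coupled network and record traces and spikes.

    OU currents are injected into every cell (``ou_compartment``); the
    AMPA-like sensory conductance acts on the soma of masked cells at each
    protocol onset.  Optional DC current vectors switch on at
    ``dc_onset_ms`` (used for coupling-coefficient measurements).  Traces
    are stored every ``rec_dt`` ms; spike detection runs at full
    resolution inside the integrator (threshold -30 mV, minimum
    inter-spike interval 10 ms).  Deterministic per (config, seed).
    """
    n = len(cells)
    if network.n_cells != n:
        raise ValueError("cells / network size mismatch")
    if mask is not None and mask.size and mask.indices.max() >= n:
        raise ValueError("mask indices outside the network")
    if T < dt:
        raise ValueError("T must be >= dt")
    if rec_dt < dt:
        raise ValueError("rec_dt must be >= dt")

    P = pack_params(cells)
    S = np.stack([initial_state(c).as_array() for c in cells])
    indptr, indices, weights = network.to_csr()
    n_steps = int(math.floor(T / dt))
    rec_stride = max(int(round(rec_dt / dt)), 1)
    n_rec = n_steps // rec_stride
    rec_vs = np.empty((n_rec, n))
    rec_vd = np.empty((n_rec, n))

    stim_mask = np.zeros(n)
    onsets = np.empty(0)
    if protocol is not None and mask is not None and mask.size:
        stim_mask[mask.indices] = 1.0
        onsets = protocol.onsets_ms

    # full-resolution stimulus conductance waveform (sum of kernels)
    stim_g = np.zeros(n_steps)
    if onsets.size:
        kern = synaptic_waveform(g_peak=g_peak, dt=dt)
        for t0 in onsets:
            i0 = int(round(t0 / dt))
            if i0 >= n_steps:
                continue
            sl = min(kern.size, n_steps - i0)
            stim_g[i0:i0 + sl] += kern[:sl]

    dc_s = np.zeros(n) if dc_soma is None else np.asarray(dc_soma, float)
    dc_d = np.zeros(n) if dc_dend is None else np.asarray(dc_dend, float)
    dc_step = dc_s if dc_soma_step is None else np.asarray(dc_soma_step,
                                                           float)
    dc_onset_step = int(round(dc_onset_ms / dt))

    ss = substreams(seed)
    ou_gen = None
    ou_hold = 1
    if ou is not None:
        ratio = ou.delta / dt
        ou_hold = int(round(ratio))
        if ou_hold < 1 or abs(ratio - ou_hold) > 1e-9:
            raise ValueError("OU delta must be an integer multiple of dt")
        ou_gen = OUGenerator(n, ou, ss["ou_independent"], ss["ou_shared"])

    cap = max(int(n * T / 1000.0 * 50), 1000)  # spike buffer (50 Hz/cell)
    spike_cell = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)
    spike_count = np.zeros(1, dtype=np.int64)
    last_spike = np.full(n, -10 ** 9, dtype=np.int64)
    min_isi_steps = int(round(SPIKE_MIN_ISI_MS / dt))

    chunk_steps = max(int(round(chunk_ms / dt)), 1)
    chunk_steps = max(chunk_steps // ou_hold, 1) * ou_hold
    step0 = 0
    rec_offset = 0
    zeros_dc = np.zeros(n)
    while step0 < n_steps:
        m = min(chunk_steps, n_steps - step0)
        if step0 < dc_onset_step < step0 + m:
            m = dc_onset_step - step0  # align chunk edge with DC onset
        if ou_gen is not None:
            # noise values updated every ou_hold integration steps
            # (zero-order hold between OU updates)
            n_draw = -(-m // ou_hold)
            coarse = ou_gen.chunk(n_draw)
            ou_chunk = np.repeat(coarse, ou_hold, axis=0)[:m]
        else:
            ou_chunk = np.zeros((m, n))
        cdc_s = dc_step if dc_onset_step <= step0 else dc_s
        cdc_d = dc_d
        bad = _kernels.integrate_network_chunk(
            S, P, dt, ou_chunk, ou_compartment == "soma",
            stim_g[step0:step0 + m], stim_mask, E_AMPA_MV,
            cdc_s, cdc_d, indptr, indices, weights,
            rec_stride, rec_vs, rec_vd, rec_offset, step0,
            SPIKE_THRESHOLD_MV, min_isi_steps,
            last_spike, spike_cell, spike_step, spike_count)
        if bad >= 0:
            i_bad = int(np.argmax(~np.isfinite(S[:, 0]) |
                                  (np.abs(S[:, 0]) >= 200)))
            raise FloatingPointError(
                f"numerical blow-up at t = {bad * dt:.3f} ms "
                f"(cell {i_bad})")
        step0 += m
        rec_offset = (step0 // rec_stride)

    k = int(spike_count[0])
    spikes: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    order = np.argsort(spike_step[:k], kind="stable")
    sc, st = spike_cell[:k][order], spike_step[:k][order]
    for i in range(n):
        spikes[i] = st[sc == i] * dt

    config = {
        "T": T, "dt": dt, "rec_dt": rec_dt, "n_cells": n,
        "g_peak": g_peak, "ou_compartment": ou_compartment,
        "ou": None if ou is None else vars(ou).copy(),
        "protocol": None if protocol is None else
        {"kind": protocol.kind,
         "onsets_ms": protocol.onsets_ms.tolist()},
        "mask": None if mask is None else mask.indices.tolist(),
        "gc_mean": network.gc_mean,
        "cell_params": params_table(cells).to_dict("list"),
        "edges": network.edges().tolist(),
    }
    log.info("run_network: n=%d T=%.0f ms dt=%g seed=%d spikes=%d",
             n, T, dt, seed, k)
    time = (np.arange(n_rec) + 1) * rec_stride * dt
    return SimResult(time=time, V_soma=rec_vs, V_dend=rec_vd,
                     spike_times=spikes, stimulus_times=onsets,
                     config=config, seed=seed)


# ---------------------------------------------------------------------------
# spike utilities
# ---------------------------------------------------------------------------

def detect_spikes(trace: np.ndarray, dt: float,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  min_isi: float = SPIKE_MIN_ISI_MS) -> np.ndarray:
    """Upward threshold-crossing times (ms) with a refractory rule.

    Crossings within ``min_isi`` ms of an accepted spike are suppressed
    (spikelets riding the dendritic plateau).
    """
    v = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite trace")
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    out = []
    last = -np.inf
    for i in up:
        t = i * dt
        if t - last >= min_isi:
            out.append(t)
            last = t
    return np.array(out)


def spike_triggered_average(
    traces: np.ndarray,
    spike_times: list[np.ndarray],
    dt: float,
    window_ms: tuple[float, float] = (200.0, 100.0),
    stimulus_times: np.ndarray | None = None,
    evoked_window_ms: tuple[float, float] = (0.0, 100.0),
) -> dict:
    """Mean and 10/90% band of spike-aligned voltage segments.

    ``traces``: (n_samples, n_cells); spikes without a full window inside
    the recording are skipped.  When ``stimulus_times`` is given, spikes
    are split into stimulus-evoked (latency within ``evoked_window_ms`` of
    an onset) and spontaneous groups; otherwise one group 'all' returns.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    if traces.shape[0] < traces.shape[1]:
        raise ValueError("traces must be (n_samples, n_cells)")
    pre, post = window_ms
    npre, npost = int(round(pre / dt)), int(round(post / dt))
    lag = np.arange(-npre, npost + 1) * dt
    groups: dict[str, list[np.ndarray]] = {}

    def classify(t: float) -> str:
        if stimulus_times is None or stimulus_times.size == 0:
            return "all"
        lat = t - stimulus_times
        lat = lat[(lat >= evoked_window_ms[0]) & (lat <= evoked_window_ms[1])]
        return "evoked" if lat.size else "spontaneous"

    for ci in range(traces.shape[1]):
        for t in spike_times[ci]:
            i = int(round(t / dt))
            if i - npre < 0 or i + npost >= traces.shape[0]:
                continue
            groups.setdefault(classify(t), []).append(
                traces[i - npre:i + npost + 1, ci])
    if not groups:
        raise ValueError("no spike with a full window inside the recording")
    out = {"lag_ms": lag}
    for name, segs in groups.items():
        a = np.stack(segs)
        out[name] = {"mean": a.mean(axis=0),
                     "p10": np.percentile(a, 10, axis=0),
                     "p90": np.percentile(a, 90, axis=0),
                     "n": a.shape[0]}
    return out


# ---------------------------------------------------------------------------
# firing-rate calibration
# ---------------------------------------------------------------------------

def calibrate_ou_sigma(
    cells,
    network,
    target_rate_hz: float = 1.0,
    sigma_grid: np.ndarray | None = None,
    T: float = 5000.0,
    seed: int = 0,
    ou_kwargs: dict | None = None,
    dt: float = 0.025,
    refine_T: float | None = 10000.0,
) -> tuple[float, dict]:
    """Tune the OU noise scale so the network fires at ``target_rate_hz``.

    Simulates the network over a coarse sigma grid, interpolates the
    (monotone) rate-vs-sigma relation at the target, and optionally
    refines with one run of length ``refine_T`` (the short grid runs
    overweight the onset transient) using the local power-law slope of
    the rate-sigma curve.  Returns the calibrated sigma and the measured
    grid.  This mirrors the way the contextual-input amplitude is set
    against the ~1 Hz olivary rate.
    """
    ou_kwargs = dict(ou_kwargs or {})
    ou_kwargs.setdefault("delta", 1.0)
    if sigma_grid is None:
        sigma_grid = np.array([0.4, 0.55, 0.7, 0.85, 1.0])
    rates = []
    for s in sigma_grid:
        ou = OUParams(sigma=float(s), **ou_kwargs)
        res = run_network(cells, network, ou=ou, T=T, dt=dt, seed=seed,
                          rec_dt=5.0)
        rates.append(float(res.firing_rates().mean()))
    rates_a = np.array(rates)
    info = {"sigma_grid": np.asarray(sigma_grid, float), "rates": rates_a}
    if target_rate_hz <= rates_a[0]:
        sigma = float(sigma_grid[0])
    elif target_rate_hz >= rates_a[-1]:
        sigma = float(sigma_grid[-1])
    else:
        sigma = float(np.interp(target_rate_hz, rates_a,
                                np.asarray(sigma_grid, float)))
    if refine_T is not None:
        pos = np.flatnonzero(rates_a > 0)
        if pos.size >= 2:
            g = (np.log(rates_a[pos[-1]] / rates_a[pos[-2]])
                 / np.log(sigma_grid[pos[-1]] / sigma_grid[pos[-2]]))
        else:
            g = 3.0
        res = run_network(cells, network,
                          ou=OUParams(sigma=sigma, **ou_kwargs),
                          T=refine_T, dt=dt, seed=seed, rec_dt=5.0)
        rate = float(res.firing_rates().mean())
        info["refine_rate"] = rate
        if rate > 0:
            sigma = float(sigma * (target_rate_hz / rate) ** (1.0 / g))
    log.info("calibrated OU sigma=%.3f for %.2f Hz (grid rates %s)",
             sigma, target_rate_hz, np.round(rates_a, 3))
    return sigma, info
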
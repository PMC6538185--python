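"""Network inputs: correlated Ornstein-Uhlenbeck drive, sensory-pulse
conductance waveforms, stimulus masks and stimulation schedules.

The contextual input is an OU-type recursion applied per integration step:

    eta(t+1) = eta(t) * exp(-delta/tau) + (1/tau) * (mu - eta(t))
               + sigma * sqrt(delta) * xi(t)

with xi standard normal.  Note the drift term is applied per *step*, so for
small ``delta`` the recursion relaxes much faster than ``tau`` ms and its
stationary spread is well below ``sigma``; the fixed point for sigma = 0 is
mu / (tau * (1 - exp(-delta/tau)) + 1).  Calibration of sigma against the
target network firing rate therefore accompanies this recursion (see
``engine.calibrate_ou_sigma``).

Correlation across cells ("noise correlation" alpha) is introduced by
mixing a shared standard-normal innovation into every cell's innovation
with weight sqrt(alpha), which leaves the marginal law untouched and makes
the pairwise correlation between cells' inputs equal alpha.  Two stream-
mixture variants are retained for comparison (``mixing='shared'`` and the
printed-form ``mixing='literal'``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OUParams",
    "OUGenerator",
    "generate_ou",
    "ou_fixed_point",
    "StimulusMask",
    "build_stimulus_mask",
    "synaptic_waveform",
    "ProtocolSchedule",
    "build_protocol",
]


@dataclass
class OUParams:
    """Parameters of the contextual-input noise process.

    mu / sigma are in the simulator's current-density unit (uA/cm^2);
    tau and delta in ms; alpha in [0, 1] is the shared ("noise
    correlation") fraction.
    """

    mu: float = -0.6
    sigma: float = 0.6
    tau: float = 20.0
    alpha: float = 0.10
    delta: float = 0.025
    mixing: str = "innovation"   # 'innovation' | 'shared' | 'literal'

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.mixing not in ("innovation", "shared", "literal"):
            raise ValueError("mixing must be innovation|shared|literal")


def ou_fixed_point(params: OUParams) -> float:
    """Closed-form fixed point of the recursion for sigma = 0."""
    return params.mu / (params.tau * (1.0 - math.exp(-params.delta
                                                     / params.tau)) + 1.0)


class OUGenerator:
    """Chunked generator of per-cell OU current series.

    Draws one independent innovation stream per cell plus one shared
    stream from two named substream RNGs, so that consecutive chunks
    concatenate into exactly the series a single full-length call yields.
    """

    def __init__(self, n_cells: int, params: OUParams,
                 seed_independent, seed_shared):
        self.n = int(n_cells)
        if self.n < 1:
            raise ValueError("n_cells must be >= 1")
        self.p = params
        self._rng_ind = np.random.default_rng(seed_independent)
        self._rng_sh = np.random.default_rng(seed_shared)
        fp = ou_fixed_point(params)
        self._eta = np.full(self.n, fp)
        self._eta_sh = fp
        self._decay = math.exp(-params.delta / params.tau)
        self._sq = params.sigma * math.sqrt(params.delta)

    def chunk(self, n_steps: int) -> np.ndarray:
        """(n_steps, n_cells) current densities for the next n_steps."""
        p = self.p
        xi_ind = self._rng_ind.standard_normal((n_steps, self.n))
        xi_sh = self._rng_sh.standard_normal(n_steps)
        out = np.empty((n_steps, self.n))
        e, inv_tau, sq = self._decay, 1.0 / p.tau, self._sq
        if p.mixing == "innovation":
            w_ind = math.sqrt(1.0 - p.alpha)
            w_sh = math.sqrt(p.alpha)
            eta = self._eta
            for t in range(n_steps):
                xi = w_ind * xi_ind[t] + w_sh * xi_sh[t]
                eta = eta * e + inv_tau * (p.mu - eta) + sq * xi
                out[t] = eta
            self._eta = eta
        else:
            # stream-mixture variants: run an independent recursion per cell
            # and one shared recursion, then combine the streams
            eta = self._eta
            eta_sh = self._eta_sh
            for t in range(n_steps):
                eta = eta * e + inv_tau * (p.mu - eta) + sq * xi_ind[t]
                eta_sh = eta_sh * e + inv_tau * (p.mu - eta_sh) \
                    + sq * xi_sh[t]
                if p.mixing == "shared":
                    out[t] = (1.0 - p.alpha) * eta + p.alpha * eta_sh
                else:  # 'literal' printed form
                    out[t] = p.alpha * eta + (1.0 - p.alpha) * eta_sh
            self._eta = eta
            self._eta_sh = eta_sh
        return out


def generate_ou(
    n_cells: int,
    T: float,
    params: OUParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Full (n_steps, n_cells) OU series over T ms at step ``params.delta``.

    Deterministic per seed; the same seed split drives the network engine,
    so an engine run and this function see identical currents.
    """
    params = params or OUParams()
    if T < params.delta:
        raise ValueError("T must be >= delta")
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    s_ind, s_sh = ss.spawn(2)
    gen = OUGenerator(n_cells, params, s_ind, s_sh)
    n_steps = int(math.floor(T / params.delta))
    return gen.chunk(n_steps)


# ---------------------------------------------------------------------------
# sensory input
# ---------------------------------------------------------------------------

@dataclass
class StimulusMask:
    """Cells receiving the direct sensory input."""

    indices: np.ndarray
    center: tuple[float, float, float] | None = None
    radius: float = 3.0
    fraction: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size != np.unique(idx).size:
            raise ValueError("mask indices must be unique")
        self.indices = np.sort(idx)

    @property
    def size(self) -> int:
        return int(self.indices.size)

    def as_bool(self, n_cells: int) -> np.ndarray:
        m = np.zeros(n_cells, dtype=bool)
        m[self.indices] = True
        return m


def build_stimulus_mask(
    geometry,
    center: tuple[float, float, float] | None = None,
    radius: float = 3.0,
    fraction: float = 0.4,
    seed: int | np.random.SeedSequence = 0,
) -> StimulusMask:
    """Random subset (``fraction``) of the cells within ``radius`` nodes of
    ``center`` (default: lattice centroid).  Deterministic per seed."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    c = np.asarray(center if center is not None else geometry.center(),
                   dtype=float)
    pos = geometry.positions.astype(float)
    d = np.linalg.norm(pos - c[None, :], axis=1)
    candidates = np.flatnonzero(d <= radius)
    if candidates.size == 0:
        raise ValueError("no cells within radius of the mask center")
    k = int(round(fraction * candidates.size))
    k = max(k, 1)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=k, replace=False)
    return StimulusMask(np.sort(chosen), center=tuple(c), radius=radius,
                        fraction=fraction,
                        seed=None if isinstance(seed, np.random.SeedSequence)
                        else int(seed))


def synaptic_waveform(
    g_peak: float = 0.15,
    onset: float = 0.0,
    rise_ms: float = 0.5,
    decay_ms: float = 5.0,
    dt: float = 0.025,
    duration: float | None = None,
) -> np.ndarray:
    """Double-exponential AMPA conductance transient peaking at ``g_peak``.

    g(t) = A * (exp(-t/decay) - exp(-t/rise)) for t >= onset, normalized so
    the maximum equals g_peak (mS/cm^2).  Returns samples at ``dt`` over
    ``duration`` ms (default: onset + 8 decay constants).
    """
    if g_peak < 0:
        raise ValueError("g_peak must be >= 0")
    if duration is None:
        duration = onset + 8.0 * decay_ms
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt - onset
    g = np.where(t >= 0,
                 np.exp(-np.maximum(t, 0) / decay_ms)
                 - np.exp(-np.maximum(t, 0) / rise_ms), 0.0)
    peak = g.max()
    if peak > 0 and g_peak > 0:
        g = g * (g_peak / peak)
    else:
        g = np.zeros_like(g)
    return g


# ---------------------------------------------------------------------------
# stimulation protocols
# ---------------------------------------------------------------------------

@dataclass
class ProtocolSchedule:
    """Ordered stimulus onsets with the generating protocol parameters."""

    onsets_ms: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        o = np.asarray(self.onsets_ms, dtype=float)
        if o.size > 1 and not np.all(np.diff(o) > 0):
            raise ValueError("onsets must be strictly increasing")
        self.onsets_ms = o

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("onset_ms\tkind\n")
            for t in self.onsets_ms:
                fh.write(f"{float(t)!r}\t{self.kind}\n")


def build_protocol(kind: str, **params) -> ProtocolSchedule:
    """Construct a stimulation schedule.

    kinds:
      single   -- one onset at ``t0`` (default 0)
      periodic -- ``n`` onsets spaced ``period`` ms from ``t0``
      tandem   -- reset pulse at ``t0`` plus one probe at ``t0 + offset``;
                  ``offsets`` (explicit) or ``sto_period`` with ``n_steps``
                  equally spaced offsets spanning two cycles; returns the
                  list of probe offsets in ``params['offsets']``
      gallop   -- onsets alternating ``short`` / ``long`` intervals
                  (e.g. 250/400 ms), ``n`` stimuli from ``t0``
    """
    t0 = float(params.get("t0", 0.0))
    if kind == "single":
        return ProtocolSchedule(np.array([t0]), "single", {"t0": t0})
    if kind == "periodic":
        period = float(params["period"])
        n = int(params["n"])
        if period <= 0 or n < 1:
            raise ValueError("periodic protocol needs period > 0, n >= 1")
        return ProtocolSchedule(t0 + period * np.arange(n), "periodic",
                                {"t0": t0, "period": period, "n": n})
    if kind == "tandem":
        if "offsets" in params:
            offsets = np.asarray(params["offsets"], dtype=float)
        elif "sto_period" not in params:
            offsets = np.array([float(params.get("offset", 0.0))])
        else:
            sto_period = float(params["sto_period"])
            n_steps = int(params.get("n_steps", 13))
            if sto_period <= 0 or n_steps < 2:
                raise ValueError("tandem needs sto_period > 0, n_steps >= 2")
            # n_steps offsets covering two whole cycles
            offsets = np.linspace(0.0, 2.0 * sto_period, n_steps)
        off = float(params.get("offset", offsets[0]))
        onsets = np.array([t0, t0 + off]) if off > 0 else np.array([t0])
        return ProtocolSchedule(onsets, "tandem",
                                {"t0": t0, "offset": off,
                                 "offsets": offsets})
    if kind == "gallop":
        short = float(params["short"])
        long_ = float(params["long"])
        n = int(params["n"])
        if short <= 0 or long_ <= 0:
            raise ValueError("gallop intervals must be > 0")
        if short == long_:
            raise ValueError("gallop needs two distinct alternating "
                             "intervals")
        intervals = np.empty(n - 1)
        intervals[0::2] = short
        intervals[1::2] = long_
        onsets = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
        return ProtocolSchedule(onsets, "gallop",
                                {"t0": t0, "short": short, "long": long_,
                                 "n": n})
    raise ValueError(f"unknown protocol kind {kind!r}")
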
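"""Cell-model unit tests: randomization, dynamics, STO metrics, rebound."""

import math
from dataclasses import fields, replace

import numpy as np
import pytest

from olivenet import (CellParameters, CellState, cell_derivatives,
                      characterize_sto, despike_trace,
                      randomize_population, rebound_sweep,
                      simulate_single_cell)
from olivenet.cell import GATE_NAMES, STATE_NAMES, initial_state


class TestRandomizePopulation:
    def test_default_range_and_determinism(self):
        pop = randomize_population(200, seed=1)
        g = np.array([c.g_CaT for c in pop])
        assert len(pop) == 200
        assert g.min() >= 0.5 and g.max() <= 1.1
        pop2 = randomize_population(200, seed=1)
        assert all(a == b for a, b in zip(pop, pop2))
        pop3 = randomize_population(200, seed=2)
        assert any(a != b for a, b in zip(pop, pop3))

    def test_degenerate_range(self):
        pop = randomize_population(3, ranges={"g_CaT": (0.8, 0.8)}, seed=0)
        assert all(c.g_CaT == 0.8 for c in pop)

    def test_invalid_range_names_parameter(self):
        with pytest.raises(ValueError, match="g_CaT"):
            randomize_population(2, ranges={"g_CaT": (1.0, 0.5)})
        with pytest.raises(ValueError, match="bogus"):
            randomize_population(2, ranges={"bogus": (0, 1)})


def _zero_conductance_params():
    kw = {f.name: 0.0 for f in fields(CellParameters)
          if f.name.startswith("g_")}
    return replace(CellParameters(), **kw)


class TestCellDerivatives:
    def test_no_currents_no_drift(self):
        p = _zero_conductance_params()
        s = CellState(V_soma=-55.0, V_dend=-55.0, V_axon=-55.0)
        d = cell_derivatives(s, p)
        assert d.V_soma == d.V_dend == d.V_axon == 0.0

    def test_leak_sign(self):
        p = replace(_zero_conductance_params(), g_ls=0.1)
        s = CellState(V_soma=p.E_leak + 10.0, V_dend=p.E_leak + 10.0,
                      V_axon=p.E_leak + 10.0)
        assert cell_derivatives(s, p).V_soma < 0.0
        s2 = CellState(V_soma=p.E_leak - 10.0, V_dend=p.E_leak - 10.0,
                       V_axon=p.E_leak - 10.0)
        assert cell_derivatives(s2, p).V_soma > 0.0

    def test_external_currents_enter_stated_compartments(self):
        p = CellParameters()
        s = initial_state(p)
        d0 = cell_derivatives(s, p)
        d1 = cell_derivatives(s, p, I_soma_ext=2.0)
        assert d1.V_soma == pytest.approx(d0.V_soma + 2.0)
        assert d1.V_dend == d0.V_dend and d1.V_axon == d0.V_axon
        d2 = cell_derivatives(s, p, I_dend_ext=1.0, I_dend_gap=0.5)
        assert d2.V_dend == pytest.approx(d0.V_dend + 1.5)
        assert d2.V_soma == d0.V_soma

    def test_rejects_nonfinite_state(self):
        s = CellState()
        s.V_soma = float("nan")
        with pytest.raises(ValueError):
            cell_derivatives(s, CellParameters())

    def test_matches_independent_rhs_oracle(self, rng):
        """Hand-coded second implementation of the full right-hand side,
        evaluated on random state points."""
        p = CellParameters(g_CaT=0.9)

        def oracle(sv):
            (vs, vd, va, k, l, hs, xs, ns, q, r, sk, ca, ha, xa) = sv
            e = math.exp
            # soma
            i_cat = p.g_CaT * k**3 * l * (vs - p.E_Ca)
            minf = 1 / (1 + e(-(vs + 30) / 5.5))
            i_na = p.g_Na_s * minf**3 * hs * (vs - p.E_Na)
            i_kdr = p.g_Kdr_s * xs**4 * (vs - p.E_K)
            i_ks = p.g_K_s * ns**4 * (vs - p.E_K)
            i_h = p.g_h * q * (vs - p.E_h)
            i_ls = p.g_ls * (vs - p.E_leak)
            i_ds = p.g_int / p.p_soma_dend * (vs - vd)
            i_as = p.g_int / (1 - p.p_soma_axon) * (vs - va)
            dvs = -(i_cat + i_na + i_kdr + i_ks + i_h + i_ls + i_ds + i_as)
            # dendrite
            i_capq = p.g_CaPQ * r**2 * (vd - p.E_Ca)
            i_kca = p.g_KCa * sk * (vd - p.E_K)
            i_ld = p.g_ld * (vd - p.E_leak)
            i_sd = p.g_int / (1 - p.p_soma_dend) * (vd - vs)
            dvd = -(i_capq + i_kca + i_ld + i_sd)
            # axon
            minfa = 1 / (1 + e(-(va + 30) / 5.5))
            i_naa = p.g_Na_a * minfa**3 * ha * (va - p.E_Na)
            i_ka = p.g_K_a * xa**4 * (va - p.E_K)
            i_la = p.g_la * (va - p.E_leak)
            i_sa = p.g_int / p.p_soma_axon * (va - vs)
            dva = -(i_naa + i_ka + i_la + i_sa)
            # gates
            dk = (1 / (1 + e(-(vs + 61) / 4.2)) - k) / 1.0
            tl = 20 * e((vs + 160) / 30) / (1 + e((vs + 84) / 7.3)) + 35
            dl = (1 / (1 + e((vs + 85.5) / 8.5)) - l) / tl
            dh = (1 / (1 + e((vs + 70) / 5.8)) - hs) / (3 * e(-(vs + 40)
                                                              / 33))
            ax = 0.13 * (vs + 25) / (1 - e(-(vs + 25) / 10))
            bx = 1.69 * e(-0.0125 * (vs + 35))
            dxs = ax * (1 - xs) - bx * xs
            dns = (1 / (1 + e(-(vs + 3) / 10)) - ns) / (
                5 + 47 * e(-(vs + 50) / 900))
            tq = 1 / (e(-0.086 * vs - 14.6) + e(0.070 * vs - 1.87))
            dq = (1 / (1 + e((vs + 80) / 4)) - q) / tq
            ar = 1.7 / (1 + e(-(vd - 5) / 13.9))
            br = 0.02 * (vd + 8.5) / (e((vd + 8.5) / 5) - 1)
            dr = ar * (1 - r) - br * r
            as_ = min(2e-5 * ca, p.sk_act_cap)
            dsk = as_ * (1 - sk) - p.sk_off_rate * sk
            dca = -p.ca_influx_scale * i_capq - p.ca_decay * ca
            dha = (1 / (1 + e((va + 60) / 5.8)) - ha) / (
                1.5 * e(-(va + 40) / 33))
            axa = 0.13 * (va + 25) / (1 - e(-(va + 25) / 10))
            bxa = 1.69 * e(-0.0125 * (va + 35))
            dxa = axa * (1 - xa) - bxa * xa
            return np.array([dvs, dvd, dva, dk, dl, dh, dxs, dns, dq,
                             dr, dsk, dca, dha, dxa])

        for _ in range(100):
            sv = np.concatenate([
                rng.uniform(-80, -20, 3),          # potentials
                rng.uniform(0.01, 0.99, 6),        # somatic gates
                rng.uniform(0.01, 0.99, 2),        # dendritic gates
                rng.uniform(0.1, 100.0, 1),        # Ca
                rng.uniform(0.01, 0.99, 2),        # axonal gates
            ])
            got = cell_derivatives(CellState.from_array(sv), p).as_array()
            np.testing.assert_allclose(got, oracle(sv), rtol=1e-12,
                                       atol=1e-12)


class TestSimulateSingleCell:
    def test_trace_length_and_finiteness(self):
        out = simulate_single_cell(CellParameters(), None, dt=0.05,
                                   T=100.0)
        assert out["V_soma"].size == int(100.0 / 0.05) + 1
        assert np.isfinite(out["V_soma"]).all()

    def test_oscillator_period_in_olivary_band(self):
        """Subthreshold oscillation period lies in the 40-160 ms band."""
        out = simulate_single_cell(CellParameters(g_CaT=0.9), None,
                                   dt=0.025, T=3000.0)
        v = despike_trace(out["V_soma"][40000:], 0.025)
        m = characterize_sto(v, 0.025)
        assert m.is_oscillator
        assert 1000.0 / 160.0 <= m.frequency <= 1000.0 / 40.0

    def test_non_oscillator_flat(self):
        out = simulate_single_cell(CellParameters(g_CaT=0.5), None,
                                   dt=0.025, T=3000.0)
        m = characterize_sto(out["V_soma"][40000:], 0.025)
        assert not m.is_oscillator
        assert m.amplitude < 0.5 and m.frequency == 0.0

    def test_euler_step_convergence(self):
        """Halving dt changes the trace by less than the dt -> dt/2 gap."""
        p = CellParameters(g_CaT=0.7)
        s0 = initial_state(p)
        a = simulate_single_cell(p, None, dt=0.05, T=1000.0, state0=s0)
        b = simulate_single_cell(p, None, dt=0.025, T=1000.0, state0=s0)
        va = a["V_soma"]
        vb = b["V_soma"][::2]
        # compare over the first 300 ms (phase drift accumulates later)
        n = int(300.0 / 0.05)
        assert np.max(np.abs(va[:n] - vb[:n])) < 1.0

    def test_gates_bounded_and_ca_nonneg_along_trajectory(self):
        p = CellParameters(g_CaT=1.1)
        s = initial_state(p)
        dt = 0.025
        for _ in range(8000):  # 200 ms with a strong input
            d = cell_derivatives(s, p, I_soma_ext=5.0)
            s = CellState.from_array(s.as_array() + dt * d.as_array())
        arr = s.as_array()
        assert np.all(np.isfinite(arr))
        gates = [getattr(s, g) for g in GATE_NAMES]
        assert all(0.0 <= g <= 1.0 for g in gates)
        assert s.Ca_dend >= 0.0

    def test_fixed_point_balance(self):
        """With no input, total membrane current at the settled state is
        ~zero for a non-oscillating cell."""
        p = CellParameters(g_CaT=0.5)
        out = simulate_single_cell(p, None, dt=0.025, T=4000.0)
        s = CellState(
            V_soma=out["V_soma"][-1], V_dend=out["V_dend"][-1],
            V_axon=out["V_axon"][-1], Ca_dend=out["Ca_dend"][-1])
        # settle the gates at the final potentials, then check dV/dt ~ 0
        st = initial_state(p, v0=out["V_soma"][-1])
        st.V_dend, st.V_axon = out["V_dend"][-1], out["V_axon"][-1]
        st.Ca_dend = out["Ca_dend"][-1]
        d = cell_derivatives(st, p)
        assert abs(d.V_soma) < 0.5  # mV/ms; integrator tolerance

    def test_blow_up_reported_with_step(self):
        with pytest.raises(FloatingPointError, match="step"):
            simulate_single_cell(CellParameters(), 1e6, dt=0.05, T=10.0)

    def test_invalid_timestep(self):
        with pytest.raises(ValueError):
            simulate_single_cell(CellParameters(), None, dt=0.0, T=10.0)
        with pytest.raises(ValueError):
            simulate_single_cell(CellParameters(), None, dt=1.0, T=0.5)


class TestCharacterizeSto:
    def test_pure_sinusoid(self):
        dt = 1.0
        t = np.arange(4000) * dt
        v = 2.0 * np.sin(2 * np.pi * 9.0 * t / 1000.0)  # 4 mV p2p, 9 Hz
        m = characterize_sto(v, dt)
        assert m.is_oscillator
        assert m.frequency == pytest.approx(9.0, abs=0.5)
        assert m.amplitude == pytest.approx(4.0, rel=0.15)

    def test_constant_trace(self):
        m = characterize_sto(np.full(3000, -61.0), 1.0)
        assert m.amplitude == pytest.approx(0.0, abs=1e-6)
        assert not m.is_oscillator and m.frequency == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            characterize_sto(np.zeros(100), 1.0)


class TestDespike:
    def test_spike_clipped_and_interpolated(self):
        dt = 1.0
        v = np.full(1000, -60.0)
        v[500:503] = 20.0  # spike
        out = despike_trace(v, dt)
        assert out.max() < -30.0
        assert np.allclose(out[:470], -60.0)


@pytest.fixture(scope="module")
def rebound_labels():
    return rebound_sweep(np.array([0.5, 0.8, 1.1]),
                         np.array([3.0, 4.5]), T=900.0)


class TestReboundSweep:

    def test_labels_valid(self, rebound_labels):
        valid = {"rebound", "no_rebound", "saturated_depolarization",
                 "invalid"}
        assert set(rebound_labels.ravel()) <= valid

    def test_rebound_region_narrow(self, rebound_labels):
        assert (rebound_labels == "rebound").sum() \
            <= rebound_labels.size // 2

    def test_deterministic(self, rebound_labels):
        again = rebound_sweep(np.array([0.5, 0.8, 1.1]),
                              np.array([3.0, 4.5]), T=900.0)
        assert (again == rebound_labels).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            rebound_sweep(np.array([]), np.array([4.5]))
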
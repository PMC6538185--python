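# olivenet

A tissue-scale model of the inferior olive and the statistics pipeline
used to analyze complex-spike rhythmicity.

The inferior olive paces cerebellar learning through rare (~1 Hz)
complex spikes whose timing rides on subthreshold membrane oscillations
(STOs, ~4-12 Hz) and on electrical coupling between neurons.  `olivenet`
is for computational neuroscientists who want to probe how intrinsic
oscillators, gap junctions and synaptic context interact to produce the
quasiperiodic spike patterns seen in awake animals.  It provides:

- a 200-neuron network of three-compartment conductance-based olivary
  cells (somatic T-type Ca, dendritic P/Q Ca + SK, somatic HCN, Na/K
  spiking machinery) on a 10 x 10 x 2 lattice;
- gap-junction coupling with the saturating conductance normalization
  `g_eff = g_c (0.8 e^{-dV^2/100} + 0.2)`, ~8 neighbors within a
  120 um radius, +-10% conductance jitter;
- a correlated Ornstein-Uhlenbeck "contextual input" (10% shared noise)
  and pulsed AMPA "sensory input" to a central cell mask, with single,
  periodic, tandem (phase-response) and gallop (alternating-interval)
  protocols;
- phase analysis: protophase-to-phase transformation of membrane traces,
  instantaneous frequency, and the Kuramoto order parameter
  `K(t) = |N^{-1} sum_n e^{i phi_n(t)}|`;
- spike statistics: inter-complex-spike-interval densities
  (Epanechnikov kernel, Z > 3 rhythmicity rule), auto/cross-correlograms
  with center/side peaks, PSTHs with interval-shuffle bootstrap
  significance, gallop conditional-response tests, and an
  oscillatory-vs-uniform mixture model for cross-stimulus intervals;
- a gated point-process generator of synthetic complex-spike trains for
  estimator recovery tests.

## Worked example

```python
import numpy as np
from olivenet import (OUParams, wild_type_network, run_network,
                      compute_phase, instantaneous_frequency,
                      kuramoto_order, icsi_density, rhythmicity_score)

cells, net = wild_type_network(seed=1)      # 200 cells, ~8 neighbors
res = run_network(cells, net, ou=OUParams(sigma=0.703, delta=1.0),
                  T=10_000.0, seed=1)       # 10 s, calibrated noise

print(f"mean rate     {res.firing_rates().mean():.2f} Hz")
phase = compute_phase(res.V_soma, 1.0)
freq = instantaneous_frequency(phase).mean(axis=0)
print(f"mean STO freq {freq.mean():.2f} Hz")
print(f"synchrony     {kuramoto_order(phase.phase).K.mean():.2f}")

scores = [rhythmicity_score(icsi_density(tr))
          for tr in res.spike_times if tr.size >= 12]
n_rhythmic = sum(r.significant for r in scores)
print(f"rhythmic cells {n_rhythmic}/{len(scores)}; best ICSI peak "
      f"{max(scores, key=lambda r: r.z_score).peak_latency_ms:.0f} ms")
```

prints

```
mean rate     1.01 Hz
mean STO freq 8.67 Hz
synchrony     0.38
rhythmic cells 68/71; best ICSI peak 91 ms
```

so the coupled network fires near the 1 Hz olivary rate while its cells
oscillate near 9 Hz with moderate phase coherence (K well above the
~1/sqrt(N) floor of independent phases but far from lock-step), and most
cells with enough spikes keep a preferred inter-spike interval near the
STO period - rhythmic, but quasiperiodic rather than clock-like.

A command-line interface wraps the same machinery
(`olivenet simulate | spikes | sweep | prc | analyze | fixtures`);
simulations are configured through a TOML file with `[geometry]`,
`[cells]`, `[coupling]`, `[ou]`, `[protocol]` and `[run]` sections.

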
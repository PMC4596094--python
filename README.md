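# prebotc — a two-compartment model of eupnea and sigh rhythm generation

The pre-Bötzinger complex (preBötC) of the brainstem generates two
concurrent inspiratory rhythms: frequent, small **eupneic** bursts
(normal breathing, ~14/min in embryonic slices) and sparse, large,
biphasic **sigh** bursts (~1/min), each followed by a prolonged pause
(post-sigh apnea).  This package implements a conductance-based model in
which the two rhythms arise from two lumped neural subpopulations with
distinct burst-generating mechanisms, coupled by asymmetric synapses:

- the **eupnea compartment** bursts on the activation/inactivation
  kinetics of a persistent sodium current (I_NaP);
- the **sigh compartment** bursts on slow intracellular Ca²⁺
  oscillations — IP₃-receptor release from the endoplasmic reticulum,
  SERCA reuptake, PMCA extrusion and a voltage-gated Ca²⁺ influx —
  paced by a hyperpolarization-activated current (I_h) with a
  depolarized half-activation;
- eupnea **inhibits** sigh (3 nS, reversal −70 mV) while sigh
  **excites** eupnea (9 nS, reversal 0 mV), a 1:3 inhibition:excitation
  ratio.

Each compartment carries six state variables (V, h, s, [Ca]ᵢ, [Ca]_ER,
l), giving a 12-dimensional stiff ODE system

```
Cm dV/dt = −I_NaP − I_leak − I_Ca − I_CaN − I_h − I_syn
I_NaP = g_NaP m∞(V) h (V − V_NaP),   m∞, h∞, n∞, H: sigmoids
d[Ca]ᵢ/dt = f_i [ (J_PM_in − J_PM_out)/λ + (J_ER_in − J_ER_out) ]
d[Ca]_ER/dt = −(f_i/σ) (J_ER_in − J_ER_out)
```

integrated with LSODA.  The analysis layer detects bursts on the
population-average voltage, splits them into sigh/eupnea classes by
amplitude, and reports per-class frequencies, post-sigh apnea and
monophasic/biphasic shape calls.  An experiment registry reproduces the
model manipulations studied with this network: synaptic-inhibition
block, Ca²⁺-conductance and SERCA knockdowns, g_NaP reduction, an
excitability (V_K ∝ [K⁺]ₒ) sweep, and I_h distribution/half-activation
scenarios.

Intended users: computational neuroscientists studying coupled
heterogeneous oscillators and respiratory rhythm generation.

## Worked example

```python
from prebotc import default_network, simulate, SolverSettings, MINUTE
from prebotc.experiments import measure_rhythm

trace = simulate(default_network(), SolverSettings(duration=20 * MINUTE))
bursts, summary, profiles = measure_rhythm(trace)
print(f"sigh   {summary.freq_sigh:.2f} bursts/min  (n={summary.n_sigh})")
print(f"eupnea {summary.freq_eupnea:.1f} bursts/min (n={summary.n_eupnea})")
print(f"post-sigh eupneic period {summary.period_post_sigh:.2f} s "
      f"vs ordinary {summary.period_post_eupnea:.2f} s")
print(f"biphasic sighs: {summary.sigh_biphasic_fraction:.0%}")
```

prints, after ~10 s of integration:

```
sigh   0.91 bursts/min  (n=16)
eupnea 13.5 bursts/min (n=237)
post-sigh eupneic period 6.36 s vs ordinary 4.01 s
biphasic sighs: 100%
```

i.e. the coupled network concurrently produces a slow large-amplitude
sigh rhythm and a fast eupneic rhythm, every sigh rides on a eupnea-like
first phase (biphasic shape), and the eupneic cycle immediately after a
sigh is stretched — the post-sigh apnea.

The same protocols are available from a shell:

```sh
prebotc list-experiments
prebotc experiment vk_sweep --out results/vk       # excitability sweep
prebotc simulate --duration 20 --override both.VK=-62 --out results/run
prebotc analyze results/run/trace.csv --summary results/run/summary.json
```

## Layout

- `src/prebotc/params.py` — Parameter tables for both subpopulations,
  dotted-path perturbations, YAML/JSON configs
- `src/prebotc/model.py` — currents, calcium fluxes and the 12-dim RHS
- `src/prebotc/simulate.py` — LSODA integration, transient handling,
  trace CSV I/O
- `src/prebotc/analysis.py` — burst detection/classification, rhythm
  statistics, burst profiles, synthetic fixtures
- `src/prebotc/experiments.py` — the named protocol registry
- `src/prebotc/cli.py`, `src/prebotc/plotting.py` — shell interface and
  figure-style plots

See `docs/methods.md` for the model equations, parameter provenance,
measurement conventions and known limitations.
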
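# Methods

## Model

Two single-compartment conductance-based units represent the eupnea and
sigh subpopulations of the embryonic preBötC.  Spiking is deliberately
absent: each compartment tracks the slow envelope of its population's
bursting.  The membrane balance of each compartment is

    Cm dV/dt = −I_NaP − I_leak − I_Ca − I_CaN − I_h − I_syn

with

    I_NaP  = g_NaP · m∞(V) · h · (V − V_NaP)      persistent Na⁺
    I_leak = g_K · (V − V_K)                      K⁺-dominated leak
    I_Ca   = g_Ca · m∞(V) · (V − V_Ca)            voltage-gated Ca²⁺
    I_CaN  = g_CaN · [Ca]ᵢ/([Ca]ᵢ+K_CaN) · (V − V_NaP)
    I_h    = g_h · n∞(V) · (V − E_h)              hyperpolarization-activated
    I_syn  = g_syn · s_pre · (V − V_syn)          coupling synapse

I_Ca reuses the I_NaP activation m∞ (one fewer gate to parameterize; the
current only needs to track depolarization-driven Ca²⁺ entry).  I_CaN
reverses at V_NaP.  The I_h gate is algebraic (instantaneous n∞); its
driving force reverses at E_h = +30 mV, while its half-activation V_n is
the parameter that differs between compartments (−90 mV eupnea, −70 mV
sigh) and is the lever behind the sigh rhythm's excitability
insensitivity.

Steady-state gates are sigmoids x∞ = 1/(1+exp((V−V_x)/s_x)); the h gate
relaxes with τ(V) = τ̄_h / cosh((V−V_h)/(2 s_h)), τ̄_h = 10 s.

### Synaptic activation

Each compartment's synaptic output s obeys

    ds/dt = (1 − s) · H(V) − k_syn · s / τ_s

with H the synaptic sigmoid (V_ss = −10 mV, s = −5 mV) and τ_s = 5 ms.
The activation term is a mass-action binding rate (per ms) and only the
decay is scaled by τ_s.  This grouping is a deliberate design choice:
scaling *both* terms by τ_s caps s at H/(H+k_syn) ≈ 0.07 during bursts
(the burst plateau sits near −22 mV, far below V_ss), which makes both
synapses functionally negligible — the sigh never phase-locks to the
eupneic rhythm and the entire inhibition-dependent phenomenology
(biphasic sighs, their loss under inhibition block) disappears.  With
the adopted grouping s reaches ≈0.29 and the coupled behavior matches
the studied regime.  A `syn_tau_vdep` switch restores a cosh-shaped
voltage dependence of τ_s if wanted; it is off by default.

### Calcium handling

A two-pool model with physical sign conventions — IP₃R release raises
cytosolic Ca²⁺ and drains the ER, SERCA does the opposite:

    J_ER_in  = (L_IP3R + P_IP3R · p³) (Ca_ER − Ca_i),
               p = IP3·Ca_i·l / ((IP3+K_I)(Ca_i+K_a))
    J_ER_out = V_SERCA Ca_i² / (K_SERCA² + Ca_i²)
    J_PM_in  = −α · I_Ca
    J_PM_out = V_PMCA Ca_i² / (K_PMCA² + Ca_i²)

    dCa_i/dt  = f_i [ (J_PM_in − J_PM_out)/λ + (J_ER_in − J_ER_out) ]
    dCa_ER/dt = −(f_i/σ) (J_ER_in − J_ER_out)
    dl/dt     = A (K_d − l (Ca_i + K_d))

λ (ER-to-plasma-membrane area ratio) is the key difference between the
compartments: 10⁻⁴ in eupnea (an ER too small to matter) versus 0.1 in
sigh (periodic ER release dominates).  With plasma-membrane fluxes
disabled, Ca_i + σ·Ca_ER is exactly conserved; the test suite asserts
drift < 10⁻⁶ µM over a minute of model time.  Alternative placements of
λ and the opposite ER signs were checked: none of them oscillates at
all, so this convention is the only self-consistent reading.

Units: mV, ms, nS, pF, µM; flux rate constants (V_SERCA = 400,
P_IP3R = 31000, L_IP3R = 0.37, V_PMCA = 2) are used as dimensionless
rates in the µM/ms balance exactly as tabulated.

### Coupling and population average

The eupnea compartment receives the excitatory synapse (9 nS, 0 mV)
driven by the sigh compartment's s; the sigh compartment receives the
inhibitory synapse (3 nS, −70 mV) driven by eupnea's s.  The reported
"population" voltage is the unweighted mean of the two compartment
voltages (weights configurable via `avg_weights`).

### How the two rhythms interact

Between sighs, the ER refills; as Ca_i creeps up, the sigh compartment
slowly depolarizes and, via its strong excitatory synapse, advances the
eupneic cycle.  Each eupneic burst transiently inhibits the sigh
compartment, postponing the regenerative IP₃R release; the release
therefore fires phase-locked ~0.5 s after a eupneic burst onset.  On the
average voltage this produces the biphasic sigh: a eupnea-like first
phase followed by the large sigh peak.  Removing the inhibition unlocks
the release, which then fires mid-cycle and drags the eupnea compartment
up simultaneously — a monophasic sigh.  The deep afterhyperpolarization
while SERCA re-sequesters the released Ca²⁺ delays the next eupneic
burst: the post-sigh apnea.

## Numerics

- LSODA (stiff-capable, adaptive) with rtol = atol = 10⁻⁸ by default;
  halving tolerances changes measured frequencies by <1% (tested).
- The first 6 s of every run are discarded.  Because one sigh cycle is
  ~1 min, rhythm statistics additionally start the measurement window at
  the second detected sigh (half-open window, the boundary sigh itself
  excluded) — this makes all reported statistics insensitive to initial
  conditions (tested with disparate initial states).
- Default initial conditions: V = −60 mV, h = h∞(V), s = 0,
  Ca_i = 0.05 µM, Ca_ER = 2.5 µM, l = K_d/(Ca_i+K_d); overridable.
- Output sampling 1 ms; 20 min of model time integrates in ~10 s on one
  CPU.  Frequency measurements use 20 min per condition (≥15 baseline
  sigh cycles), 30 min at V_K = −64 mV where the sigh period exceeds
  2 min.

## Burst analytics

- Detection: baseline = 0.2-quantile of the series; threshold =
  baseline + 0.15·(max − baseline); supra-threshold runs closer than
  100 ms are merged.  Invariant to offsets, equivariant to time shifts,
  exact on noiseless synthetic fixtures, recall ≥ 0.99 at 5% noise
  (all tested).
- Classification: deterministic 1-D largest-gap split on peak
  amplitude; if the largest gap in sorted amplitudes is below half the
  median amplitude the train is unimodal and labeled eupnea.  The
  experiment layer reassigns a unimodal train to the sigh class when its
  mean inter-burst interval exceeds 30 s: minute-scale cycles can only
  come from the ER oscillator (the V_K = −64 mV regime, or the residual
  slow events after complete I_NaP removal, whose amplitudes are no
  longer separable from eupneic ones).
- Post-sigh apnea: the onset-to-onset interval from each sigh to the
  first following eupneic burst (an `offset_to_onset` convention is
  available); the ordinary eupneic period averages eupnea-to-eupnea
  intervals not adjacent to a sigh.
- Shape calls: phases are local maxima whose prominence exceeds a
  fraction of the burst amplitude.  The generic default is 0.2 (robust
  for noisy waveforms; a 5%-prominence side bump does not count).  On
  noise-free simulated traces the pipeline uses 0.02, because the notch
  between the eupnea-like first phase and the sigh peak is shallow
  (~4% of burst amplitude) but perfectly reproducible; at 0.02 the
  baseline/inhibition-block contrast is clean (biphasic fraction 1.0 vs
  0.0).

## Synthetic fixtures

`make_fixture` builds voltage traces from exactly specified event times,
amplitudes, widths and phase counts (compact-support pulses, optional
Gaussian noise, seeded).  It emulates the *timing and amplitude*
structure of model output, not its biophysics: passing detector tests on
fixtures validates the analytics, not the ODE model — the model itself
is validated by the property tests (conservation, block-diagonality,
finite-difference consistency) and the reproduction of the reference
in-silico statistics.

## Known limitations

- The intrinsic sigh calcium cycle runs ~15% fast against the reference
  values the model targets (uncoupled period ≈60 s vs 1.2 min; coupled
  sigh rate 0.91/min vs 0.85), and the post-sigh apnea is
  correspondingly deeper (6.4 s vs 5.34 s).  This is
  tolerance-independent and robust to every alternative equation reading
  we tested; the remaining gap presumably reflects small differences
  between the tabulated parameters and the code that produced the
  reference values.
- With I_h restricted to the sigh compartment the model keeps its
  phase-locked biphasic sighs, whereas the reference behavior for that
  scenario is monophasic; in this implementation eupnea's I_h
  (V_n = −90 mV) carries only ~1 pA at rest, too little for its removal
  to break the lock.
- No spiking currents, no stochastic channel noise, no within-population
  connectivity: compartments are population envelopes.  Wet-lab-only
  phenomena (drug kinetics, slice variability) are outside the model's
  scope.
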
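"""Right-hand side of the coupled two-compartment ODE system.

Each compartment carries six state variables

    V      membrane potential (mV)
    h      I_NaP inactivation gate, in [0, 1]
    s      synaptic output activation, in [0, 1]
    Ca_i   cytosolic Ca2+ (µM)
    Ca_ER  endoplasmic-reticulum Ca2+ (µM)
    l      IP3-receptor inactivation gate, in [0, 1]

The network state is the 12-vector [eupnea; sigh] in that field order.

Sign conventions.  Inward membrane currents are negative, so
Cm dV/dt = −ΣI.  The ER fluxes follow the physical convention: J_ER_in
(IP3R release + leak, directed ER → cytosol) raises Ca_i and lowers
Ca_ER, J_ER_out (SERCA reuptake) does the opposite:

    dCa_i/dt  = f_i · ( (J_PM_in − J_PM_out)/λ + (J_ER_in − J_ER_out) )
    dCa_ER/dt = −(f_i/σ) · (J_ER_in − J_ER_out)

(A literal transcription with the opposite ER-term signs — release
lowering Ca_i and filling the ER — would make the store dynamics
unphysical; with plasma-membrane fluxes disabled the convention above
conserves Ca_i + σ·Ca_ER exactly.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import GatingParams, NetworkConfig, ParameterSet

__all__ = [
    "CompartmentState",
    "steady_state",
    "time_constant",
    "membrane_currents",
    "calcium_fluxes",
    "compartment_rhs",
    "network_rhs",
    "default_initial_state",
    "STATE_FIELDS",
]

STATE_FIELDS = ("V", "h", "s", "Ca_i", "Ca_ER", "l")


@dataclass
class CompartmentState:
    """Dynamic variables of one compartment."""

    V: float
    h: float
    s: float
    Ca_i: float
    Ca_ER: float
    l: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.s, self.Ca_i, self.Ca_ER, self.l])

    @classmethod
    def from_array(cls, a) -> "CompartmentState":
        return cls(*(float(x) for x in a))


def steady_state(V: float, gate: GatingParams) -> float:
    """Sigmoidal steady-state activation/inactivation x∞(V).

    x∞ = 1/(1 + exp((V − V_half)/slope)); strictly in (0, 1), equal to
    0.5 at V_half, increasing in V for negative slope and decreasing for
    positive slope.
    """
    return 1.0 / (1.0 + math.exp((V - gate.V_half) / gate.slope))


def time_constant(V: float, gate: GatingParams) -> float:
    """Voltage-dependent time constant τ(V) = τ̄ / cosh((V − V_half)/(2·slope)).

    Peaks at τ̄ for V = V_half and is even-symmetric about V_half.
    """
    if gate.tau_bar is None:
        raise ValueError("gate has no tau_bar; its time constant is undefined")
    return gate.tau_bar / math.cosh((V - gate.V_half) / (2.0 * gate.slope))


def membrane_currents(
    state: CompartmentState,
    pre_s: float,
    params: ParameterSet,
    pre_gsyn: float | None = None,
    pre_Vsyn: float | None = None,
) -> dict[str, float]:
    """All membrane currents (pA) of one compartment.

    ``pre_s`` is the synaptic activation of the *presynaptic* compartment;
    the synapse's conductance/reversal default to the postsynaptic
    compartment's incoming-synapse parameters.  I_Ca shares the I_NaP
    activation function m∞, and I_CaN reverses at VNaP.
    """
    V = state.V
    gsyn = params.gsyn if pre_gsyn is None else pre_gsyn
    Vsyn = params.Vsyn if pre_Vsyn is None else pre_Vsyn
    m_inf = steady_state(V, params.m_gate)
    n_inf = steady_state(V, params.n_gate)
    return {
        "I_NaP": params.gNaP * m_inf * state.h * (V - params.VNaP),
        "I_leak": params.gK * (V - params.VK),
        "I_Ca": params.gCa * m_inf * (V - params.VCa),
        "I_CaN": params.gCaN * (state.Ca_i / (state.Ca_i + params.KCaN)) * (V - params.VNaP),
        "I_h": params.gh * n_inf * (V - params.Eh),
        "I_syn": gsyn * pre_s * (V - Vsyn),
    }


def calcium_fluxes(
    state: CompartmentState, I_Ca: float, params: ParameterSet
) -> dict[str, float]:
    """Ca2+ fluxes across the ER and plasma membranes (µM/ms scale).

    J_ER_in:  IP3R release plus ER leak, ∝ (Ca_ER − Ca_i) with the cubed
              Li–Rinzel-type open probability IP3·Ca_i·l/((IP3+K_I)(Ca_i+K_a)).
    J_ER_out: SERCA reuptake, Hill coefficient 2.
    J_PM_in:  −α·I_Ca (voltage-gated influx; I_Ca < 0 when inward).
    J_PM_out: PMCA extrusion, Hill coefficient 2.
    """
    ca, ca_er = state.Ca_i, state.Ca_ER
    gate = (params.IP3 * ca * state.l) / ((params.IP3 + params.KI) * (ca + params.Ka))
    return {
        "J_ER_in": (params.LIP3R + params.PIP3R * gate**3) * (ca_er - ca),
        "J_ER_out": params.VSERCA * ca**2 / (params.KSERCA**2 + ca**2),
        "J_PM_in": -params.alpha * I_Ca,
        "J_PM_out": params.VPMCA * ca**2 / (params.KPMCA**2 + ca**2),
    }


def compartment_rhs(
    state: CompartmentState,
    pre_s: float,
    own: ParameterSet,
    syn_gsyn: float | None = None,
    syn_Vsyn: float | None = None,
) -> np.ndarray:
    """Time-derivative of one compartment's six state variables."""
    I = membrane_currents(state, pre_s, own, syn_gsyn, syn_Vsyn)
    J = calcium_fluxes(state, I["I_Ca"], own)
    V = state.V
    dV = -(I["I_NaP"] + I["I_leak"] + I["I_Ca"] + I["I_CaN"] + I["I_h"] + I["I_syn"]) / own.Cm
    dh = (steady_state(V, own.h_gate) - state.h) / time_constant(V, own.h_gate)
    # Synaptic activation: mass-action binding at rate H(V) per ms with
    # first-order unbinding at ksyn/τ_s.  Only this grouping yields
    # synapses strong enough to phase-lock the sigh onto the eupneic
    # rhythm (the biphasic sigh); dividing both terms by τ_s caps the
    # effective coupling ~4x lower and the lock is lost.
    tau_s = time_constant(V, own.s_gate) if own.syn_tau_vdep else own.s_gate.tau_bar
    H = steady_state(V, own.s_gate)
    ds = (1.0 - state.s) * H - own.ksyn * state.s / tau_s
    j_er = J["J_ER_in"] - J["J_ER_out"]
    j_pm = J["J_PM_in"] - J["J_PM_out"]
    dCa_i = own.f_i * (j_pm / own.lam + j_er)
    dCa_ER = -(own.f_i / own.sigma) * j_er
    dl = own.A_ip3 * (own.Kd - state.l * (state.Ca_i + own.Kd))
    return np.array([dV, dh, ds, dCa_i, dCa_ER, dl])


def network_rhs(t: float, y: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """RHS of the 12-dimensional coupled system.

    ``y`` stacks [eupnea; sigh], each in STATE_FIELDS order.  With
    coupling off, both cross-synaptic conductances are zero and the two
    compartments evolve independently.
    """
    if len(y) != 12:
        raise ValueError(f"expected a 12-vector, got length {len(y)}")
    eup = CompartmentState.from_array(y[:6])
    sig = CompartmentState.from_array(y[6:])
    if config.coupling_on:
        d_eup = compartment_rhs(eup, sig.s, config.eupnea)
        d_sig = compartment_rhs(sig, eup.s, config.sigh)
    else:
        d_eup = compartment_rhs(eup, 0.0, config.eupnea, 0.0)
        d_sig = compartment_rhs(sig, 0.0, config.sigh, 0.0)
    return np.concatenate([d_eup, d_sig])


def default_initial_state(
    params: ParameterSet,
    V: float = -60.0,
    Ca_i: float = 0.05,
    Ca_ER: float = 2.5,
) -> CompartmentState:
    """Documented default initial condition: gates start at their fixed
    points for the given voltage/calcium, the synapse silent.  All
    reported statistics are computed after transient discard and are
    insensitive to this choice."""
    return CompartmentState(
        V=V,
        h=steady_state(V, params.h_gate),
        s=0.0,
        Ca_i=Ca_i,
        Ca_ER=Ca_ER,
        l=params.Kd / (Ca_i + params.Kd),
    )


# ---------------------------------------------------------------------------
# fast flat-parameter RHS used by the integrator


def _flatten(p: ParameterSet) -> tuple:
    return (
        p.Cm, p.gNaP, p.gK, p.gCaN, p.gCa, p.gh, p.gsyn,
        p.VNaP, p.VK, p.VCa, p.Vsyn, p.Eh, p.KCaN,
        p.m_gate.V_half, p.m_gate.slope,
        p.h_gate.V_half, p.h_gate.slope, p.h_gate.tau_bar,
        p.n_gate.V_half, p.n_gate.slope,
        p.s_gate.V_half, p.s_gate.slope, p.s_gate.tau_bar,
        p.ksyn, 1.0 if p.syn_tau_vdep else 0.0,
        p.alpha, p.VPMCA, p.KPMCA,
        p.lam, p.f_i, p.sigma, p.IP3, p.A_ip3, p.Kd, p.KI, p.Ka,
        p.VSERCA, p.KSERCA, p.LIP3R, p.PIP3R,
    )


def _comp_deriv(y, off, pre_s, gsyn, Vsyn, q, out):
    (Cm, gNaP, gK, gCaN, gCa, gh, _gsyn_own,
     VNaP, VK, VCa, _Vsyn_own, Eh, KCaN,
     mV, ms_, hV, hs, htau, nV, ns_, sV, ss_, stau,
     ksyn, svdep, alpha, VPMCA, KPMCA,
     lam, f_i, sigma, IP3, A, Kd, KI, Ka,
     VSERCA, KSERCA, LIP3R, PIP3R) = q
    V, h, s, ca, ca_er, l = y[off:off + 6]
    m_inf = 1.0 / (1.0 + math.exp((V - mV) / ms_))
    n_inf = 1.0 / (1.0 + math.exp((V - nV) / ns_))
    I_NaP = gNaP * m_inf * h * (V - VNaP)
    I_leak = gK * (V - VK)
    I_Ca = gCa * m_inf * (V - VCa)
    I_CaN = gCaN * (ca / (ca + KCaN)) * (V - VNaP)
    I_h = gh * n_inf * (V - Eh)
    I_syn = gsyn * pre_s * (V - Vsyn)
    out[off] = -(I_NaP + I_leak + I_Ca + I_CaN + I_h + I_syn) / Cm
    h_inf = 1.0 / (1.0 + math.exp((V - hV) / hs))
    out[off + 1] = (h_inf - h) * math.cosh((V - hV) / (2.0 * hs)) / htau
    H = 1.0 / (1.0 + math.exp((V - sV) / ss_))
    tau_s = stau / math.cosh((V - sV) / (2.0 * ss_)) if svdep else stau
    out[off + 2] = (1.0 - s) * H - ksyn * s / tau_s
    gate = (IP3 * ca * l) / ((IP3 + KI) * (ca + Ka))
    j_er = (LIP3R + PIP3R * gate**3) * (ca_er - ca) - VSERCA * ca * ca / (KSERCA * KSERCA + ca * ca)
    j_pm = -alpha * I_Ca - VPMCA * ca * ca / (KPMCA * KPMCA + ca * ca)
    out[off + 3] = f_i * (j_pm / lam + j_er)
    out[off + 4] = -(f_i / sigma) * j_er
    out[off + 5] = A * (Kd - l * (ca + Kd))


def make_flat_rhs(config: NetworkConfig):
    """Build a fast f(t, y) closure over pre-flattened parameters.

    Agrees with :func:`network_rhs` to machine precision; used by the
    integrator to avoid per-call dataclass attribute lookups.
    """
    q_e = _flatten(config.eupnea)
    q_s = _flatten(config.sigh)
    if config.coupling_on:
        g_e, v_e = config.eupnea.gsyn, config.eupnea.Vsyn
        g_s, v_s = config.sigh.gsyn, config.sigh.Vsyn
    else:
        g_e = g_s = 0.0
        v_e, v_s = config.eupnea.Vsyn, config.sigh.Vsyn

    def rhs(t, y):
        out = np.empty(12)
        _comp_deriv(y, 0, y[8], g_e, v_e, q_e, out)   # eupnea driven by sigh's s
        _comp_deriv(y, 6, y[2], g_s, v_s, q_s, out)   # sigh driven by eupnea's s
        return out

    return rhs
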
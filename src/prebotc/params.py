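"""Parameter sets for the eupnea and sigh subpopulation models.

Each compartment lumps one subpopulation of pre-Bötzinger complex (preBötC)
neurons into a single conductance-based unit whose currents are the essential
burst-generating ones: a persistent sodium current (I_NaP), a K+-dominated
leak, a voltage-gated Ca2+ current (I_Ca), a Ca2+-activated nonspecific
cation current (I_CaN), a hyperpolarization-activated current (I_h) and a
synaptic current.  Intracellular Ca2+ is handled by a two-pool model
(cytosol + endoplasmic reticulum) with IP3-receptor release, SERCA reuptake,
PMCA extrusion and voltage-gated influx.

Units: voltages in mV, time in ms, conductances in nS, capacitance in pF
(currents then come out in pA and dV/dt in mV/ms), Ca2+ concentrations in
µM.  The calcium flux constants (VSERCA, VPMCA, LIP3R, PIP3R) are treated
as rate parameters in the µM/ms balance exactly as tabulated.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "GatingParams",
    "ParameterSet",
    "NetworkConfig",
    "default_parameters",
    "default_network",
    "perturb",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class GatingParams:
    """Sigmoidal steady-state gate x∞(V) = 1/(1+exp((V−V_half)/slope)).

    ``slope`` is signed: negative for activation gates that open with
    depolarization (m, s), positive for gates that close with
    depolarization (h, n).  ``tau_bar`` (ms) is the peak of the
    voltage-dependent time constant and is only meaningful for gates
    integrated as ODEs (h, and optionally s).
    """

    V_half: float
    slope: float
    tau_bar: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("gate slope must be nonzero")
        if self.tau_bar is not None and self.tau_bar <= 0:
            raise ValueError("tau_bar must be positive")


@dataclass
class ParameterSet:
    """All parameters of one compartment plus its *incoming* synapse.

    The synaptic fields (gsyn, Vsyn) describe the synapse terminating on
    this compartment: the eupnea compartment receives the excitatory
    synapse from sigh (9 nS, reversal 0 mV) and the sigh compartment
    receives the inhibitory synapse from eupnea (3 nS, reversal −70 mV),
    a 1:3 inhibition:excitation ratio.
    """

    # membrane
    Cm: float = 21.0            # pF
    gNaP: float = 2.5           # nS
    gK: float = 2.7             # nS (leak, K+-dominated)
    gCaN: float = 1.5           # nS
    gCa: float = 0.02           # nS
    gh: float = 2.0             # nS
    gsyn: float = 9.0           # nS, incoming synapse
    VNaP: float = 50.0          # mV (also reversal used for I_CaN)
    VK: float = -60.0           # mV, proxy for extracellular [K+]
    VCa: float = 150.0          # mV
    Vsyn: float = 0.0           # mV, incoming synapse reversal
    Eh: float = 30.0            # mV, I_h reversal
    KCaN: float = 0.74          # µM, half-activation of I_CaN by Ca_i
    # gates
    m_gate: GatingParams = field(default_factory=lambda: GatingParams(-40.0, -6.0))
    h_gate: GatingParams = field(default_factory=lambda: GatingParams(-48.0, 5.0, 10000.0))
    n_gate: GatingParams = field(default_factory=lambda: GatingParams(-90.0, 8.0))
    s_gate: GatingParams = field(default_factory=lambda: GatingParams(-10.0, -5.0, 5.0))
    ksyn: float = 1.0           # synaptic dissociation constant
    syn_tau_vdep: bool = False  # if True, τ_s follows the cosh law instead of τ̄_s
    # plasma-membrane calcium
    alpha: float = 0.055        # µM·pA⁻¹·ms⁻¹ influx proportionality
    VPMCA: float = 2.0          # max PMCA pump rate
    KPMCA: float = 0.3          # µM
    # ER calcium
    lam: float = 0.0001         # λ, ER-to-plasma-membrane area ratio
    f_i: float = 0.000025       # bound-to-free Ca fraction
    sigma: float = 0.185        # σ, cytosol-to-ER volume ratio
    IP3: float = 1.0            # µM
    A_ip3: float = 0.0005       # IP3R gate rate constant (ms⁻¹·µM⁻¹)
    Kd: float = 0.4             # µM, IP3R inactivation by Ca
    KI: float = 1.0             # µM, IP3R activation by IP3
    Ka: float = 0.4             # µM, IP3R activation by Ca
    VSERCA: float = 400.0       # max SERCA pump rate
    KSERCA: float = 0.2         # µM
    LIP3R: float = 0.37         # ER leak permeability
    PIP3R: float = 31000.0      # max IP3R permeability

    def __post_init__(self) -> None:
        for name in ("gNaP", "gK", "gCaN", "gCa", "gh", "gsyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("KCaN", "KPMCA", "Kd", "KI", "Ka", "KSERCA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lam <= 0 or self.sigma <= 0:
            raise ValueError("lam and sigma must be > 0")
        if not (0 < self.f_i <= 1):
            raise ValueError("f_i must be in (0, 1]")


#: Fields in which the sigh subpopulation departs from the eupnea one.
SIGH_OVERRIDES: dict[str, Any] = {
    "gNaP": 1.3,
    "n_gate": GatingParams(-70.0, 8.0),
    "lam": 0.1,
    "gsyn": 3.0,
    "Vsyn": -70.0,
}


def default_parameters(population: str) -> ParameterSet:
    """Baseline parameter set for ``"eupnea"`` or ``"sigh"``.

    The two subpopulations are identical except for the persistent-sodium
    conductance, the I_h half-activation voltage, the ER capacity λ and
    the incoming synapse.
    """
    if population == "eupnea":
        return ParameterSet()
    if population == "sigh":
        return replace(ParameterSet(), **SIGH_OVERRIDES)
    raise ValueError(f"unknown population {population!r}; expected 'eupnea' or 'sigh'")


@dataclass
class NetworkConfig:
    """The coupled two-compartment network.

    Eupnea inhibits sigh and sigh excites eupnea; each compartment's
    incoming synapse parameters live in its own :class:`ParameterSet`.
    ``avg_weights`` are the (eupnea, sigh) weights of the population-average
    voltage, normalized to sum to 1.
    """

    eupnea: ParameterSet = field(default_factory=lambda: default_parameters("eupnea"))
    sigh: ParameterSet = field(default_factory=lambda: default_parameters("sigh"))
    coupling_on: bool = True
    avg_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        w = self.avg_weights
        if len(w) != 2 or min(w) < 0:
            raise ValueError("avg_weights must be two non-negative numbers")
        total = w[0] + w[1]
        if total <= 0:
            raise ValueError("avg_weights must not both be zero")
        if abs(total - 1.0) > 1e-12:
            self.avg_weights = (w[0] / total, w[1] / total)

    def copy(self) -> "NetworkConfig":
        return copy.deepcopy(self)


def default_network(coupling_on: bool = True) -> NetworkConfig:
    return NetworkConfig(coupling_on=coupling_on)


# ---------------------------------------------------------------------------
# perturbation / config-file machinery


def _resolve(obj: Any, parts: list[str]) -> tuple[Any, str]:
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise KeyError(f"unknown parameter path segment {p!r}")
        obj = getattr(obj, p)
    leaf = parts[-1]
    if not hasattr(obj, leaf):
        raise KeyError(f"unknown parameter {leaf!r}")
    return obj, leaf


def _apply_edit(config: NetworkConfig, path: str, action: Any) -> None:
    parts = path.split(".")
    if parts[0] == "both":
        for comp in ("eupnea", "sigh"):
            _apply_edit(config, ".".join([comp] + parts[1:]), action)
        return
    if parts[0] not in ("eupnea", "sigh", "coupling_on", "avg_weights"):
        raise KeyError(
            f"edit path must start with 'eupnea', 'sigh' or 'both': {path!r}"
        )
    if parts[0] in ("coupling_on", "avg_weights"):
        setattr(config, parts[0], action)
        return
    owner, leaf = _resolve(config, parts)
    current = getattr(owner, leaf)
    if isinstance(action, Mapping):
        if set(action) == {"scale"}:
            scale = float(action["scale"])
            if scale < 0:
                raise ValueError("scale must be non-negative")
            new = current * scale
        elif set(action) == {"set"}:
            new = action["set"]
        else:
            raise ValueError(f"edit action must be {{'scale': f}} or {{'set': v}}: {action!r}")
    else:
        new = action
    if isinstance(current, (int, float)) and not isinstance(current, bool):
        new = float(new)
    elif isinstance(current, GatingParams) and isinstance(new, Mapping):
        new = replace(current, **new)
    if isinstance(owner, GatingParams):
        # frozen dataclass: rebuild the gate on its parent ParameterSet
        parent, gate_name = _resolve(config, parts[:-1])
        setattr(parent, gate_name, replace(owner, **{leaf: new}))
        return
    setattr(owner, leaf, new)


def perturb(config: NetworkConfig, edits: Mapping[str, Any]) -> NetworkConfig:
    """Return a new config with dotted-path edits applied; input untouched.

    Paths look like ``"sigh.gsyn"``, ``"both.VK"`` or
    ``"sigh.n_gate.V_half"``.  Values are either plain numbers (set), or
    one-key mappings ``{"scale": f}`` / ``{"set": v}``.
    """
    out = config.copy()
    for path, action in edits.items():
        _apply_edit(out, path, action)
    # revalidate
    out.eupnea.__post_init__()
    out.sigh.__post_init__()
    return out


def _gate_to_dict(g: GatingParams) -> dict[str, Any]:
    d = {"V_half": g.V_half, "slope": g.slope}
    if g.tau_bar is not None:
        d["tau_bar"] = g.tau_bar
    return d


def params_to_dict(p: ParameterSet) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in fields(p):
        v = getattr(p, f.name)
        out[f.name] = _gate_to_dict(v) if isinstance(v, GatingParams) else v
    return out


def config_to_dict(config: NetworkConfig) -> dict[str, Any]:
    return {
        "eupnea": params_to_dict(config.eupnea),
        "sigh": params_to_dict(config.sigh),
        "coupling_on": config.coupling_on,
        "avg_weights": list(config.avg_weights),
    }


def _params_from_dict(base: ParameterSet, d: Mapping[str, Any]) -> ParameterSet:
    kw: dict[str, Any] = {}
    for name, v in d.items():
        current = getattr(base, name)  # KeyError -> AttributeError on bad names
        if isinstance(current, GatingParams):
            kw[name] = replace(current, **v)
        else:
            kw[name] = v
    return replace(base, **kw)


def load_config(path: str | Path) -> NetworkConfig:
    """Load a network config from YAML or JSON; any subset overrides defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    cfg = default_network()
    for comp in ("eupnea", "sigh"):
        if comp in data:
            setattr(cfg, comp, _params_from_dict(getattr(cfg, comp), data[comp]))
    if "coupling_on" in data:
        cfg.coupling_on = bool(data["coupling_on"])
    if "avg_weights" in data:
        cfg.avg_weights = tuple(data["avg_weights"])
        cfg.__post_init__()
    return cfg


def dump_config(config: NetworkConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
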
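"""Registry of named in-silico protocols.

Every model manipulation studied with the two-compartment network is a
named experiment: a list of conditions (dotted-path parameter edits),
solver settings per condition, and a driver that simulates, analyzes and
tabulates each condition.  All experiments run end-to-end from shipped
defaults with no external inputs.

Durations: frequency measurements use 20 min of model time per condition
(≥15 sigh cycles at baseline); conditions at V_K = −64 mV use 30 min
because the sigh period stretches beyond 2 min there.  Bath-style
manipulations (V_K, calcium-channel and SERCA block) apply to both
compartments; synapse- and compartment-specific edits name their target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .analysis import Burst, RhythmSummary, SIGH, analyze_trace, rhythm_summary
from .params import NetworkConfig, default_network, perturb
from .simulate import MINUTE, SolverSettings, Trace, simulate, write_trace

__all__ = [
    "ExperimentSpec",
    "SweepResult",
    "run_experiment",
    "get_experiment",
    "list_experiments",
    "measure_rhythm",
    "vk_sweep",
    "gnap_sweep",
    "ih_distribution",
    "ih_halfact_grid",
]

#: A unimodal burst train slower than this mean inter-burst interval (ms) is
#: the sigh rhythm: only the ER-calcium oscillator produces minute-scale
#: cycles, while single-class fast trains (e.g. after calcium-channel block)
#: are eupnea.  Used only to resolve class labels in single-rhythm regimes.
SLOW_CLASS_CUTOFF = 30_000.0

VK_CONDITIONS = (-64.0, -62.0, -60.0, -58.0)


def _settings(duration_min: float, **kw) -> SolverSettings:
    return SolverSettings(duration=duration_min * MINUTE, **kw)


@dataclass
class ExperimentSpec:
    """A named protocol: one edit-map per condition, in presentation
    order."""

    name: str
    description: str
    conditions: list[str]
    edits: list[Mapping[str, Any]]
    settings: list[SolverSettings]

    def __post_init__(self) -> None:
        if not (len(self.conditions) == len(self.edits) == len(self.settings)):
            raise ValueError("conditions, edits and settings must align")


@dataclass
class SweepResult:
    """Per-condition rhythm summaries and qualitative flags."""

    name: str
    conditions: list[str]
    summaries: list[RhythmSummary | None]
    flags: list[dict]
    errors: dict[str, str] = field(default_factory=dict)
    traces: dict[str, Trace] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for cond, summ, flag in zip(self.conditions, self.summaries, self.flags):
            row = {"condition": cond}
            if summ is not None:
                row.update(summ.as_dict())
            row.update(flag)
            rows.append(row)
        return pd.DataFrame(rows)


def measure_rhythm(trace: Trace, **analysis_kw) -> tuple[list[Burst], RhythmSummary, dict]:
    """Analyze a trace and resolve class labels in single-rhythm regimes.

    The amplitude classifier labels a unimodal train "eupnea"; here a
    unimodal train with mean inter-burst interval above
    ``SLOW_CLASS_CUTOFF`` is reassigned to the sigh class (minute-scale
    cycles can only come from the ER oscillator — the V_K = −64 mV
    regime, or the residual slow events after I_NaP removal).
    """
    bursts, summary, profiles = analyze_trace(trace, **analysis_kw)
    if summary.n_sigh == 0 and summary.n_eupnea >= 2:
        onsets = np.array([b.onset for b in bursts])
        if np.diff(onsets).mean() > SLOW_CLASS_CUTOFF:
            for b in bursts:
                b.label = SIGH
            window = trace.t[-1] - trace.t[0]
            summary = rhythm_summary(bursts, window)
            profiles = {SIGH: profiles["eupnea"]} if "eupnea" in profiles else profiles
    return bursts, summary, profiles


def _sigh_shape(bursts: Sequence[Burst], summary: RhythmSummary) -> str | None:
    if not summary.n_sigh:
        return None
    frac = summary.sigh_biphasic_fraction or 0.0
    return "biphasic" if frac >= 0.5 else "monophasic"


def _phase_lag(trace: Trace, coarse_dt: float = 10.0) -> float:
    """Lag (ms) of the peak cross-correlation between the two
    compartments' mean-subtracted voltages (FFT correlation on a
    ``coarse_dt``-resampled trace)."""
    step = max(1, int(round(coarse_dt / trace.dt)))
    x = trace.eupnea[::step, 0]
    y = trace.sigh[::step, 0]
    x = x - x.mean()
    y = y - y.mean()
    cc = signal.correlate(x, y, mode="full", method="fft")
    lag = int(np.argmax(cc)) - (len(x) - 1)
    return float(lag * step * trace.dt)


def run_experiment(
    spec: ExperimentSpec,
    base: NetworkConfig | None = None,
    out_dir: str | Path | None = None,
    keep_traces: bool = False,
    analysis_kw: Mapping[str, Any] | None = None,
) -> SweepResult:
    """Drive one experiment: perturb → simulate → analyze per condition.

    A failing condition is recorded in ``result.errors`` without aborting
    the remaining conditions.  With ``out_dir``, each condition's trace is
    written as CSV (plus JSON config sidecar) and the summary table as
    CSV and JSON.
    """
    base = base or default_network()
    analysis_kw = dict(analysis_kw or {})
    out = SweepResult(name=spec.name, conditions=list(spec.conditions),
                      summaries=[], flags=[])
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for cond, edits, settings in zip(spec.conditions, spec.edits, spec.settings):
        try:
            cfg = perturb(base, edits)
            trace = simulate(cfg, settings)
            bursts, summary, _profiles = measure_rhythm(trace, **analysis_kw)
            flags = {
                "sigh_present": summary.n_sigh > 0,
                "eupnea_present": summary.n_eupnea > 0,
                "sigh_shape": _sigh_shape(bursts, summary),
                "phase_lag_ms": _phase_lag(trace),
            }
            out.summaries.append(summary)
            out.flags.append(flags)
            if keep_traces or out_dir is not None:
                out.traces[cond] = trace
            if out_dir is not None:
                write_trace(trace, out_dir / f"{spec.name}_{cond}.csv")
        except Exception as exc:  # keep sweeping; report per-condition
            out.summaries.append(None)
            out.flags.append({"sigh_present": None, "eupnea_present": None,
                              "sigh_shape": None, "phase_lag_ms": None})
            out.errors[cond] = f"{type(exc).__name__}: {exc}"
    if out_dir is not None:
        table = out.table()
        table.to_csv(out_dir / f"{spec.name}_summary.csv", index=False)
        (out_dir / f"{spec.name}_summary.json").write_text(
            json.dumps(table.to_dict(orient="records"), indent=2, default=str)
        )
    return out


# ---------------------------------------------------------------------------
# registry


def _baseline_spec(duration: float = 20.0) -> ExperimentSpec:
    return ExperimentSpec(
        "baseline",
        "Coupled two-compartment model with shipped defaults; both rhythms, "
        "biphasic sighs, post-sigh apnea.",
        ["control"], [{}], [_settings(duration)],
    )


def _uncoupled_spec(duration: float = 20.0) -> ExperimentSpec:
    return ExperimentSpec(
        "uncoupled",
        "Both cross-synaptic conductances zero; each compartment free-runs "
        "(fast eupnea, slow calcium-driven sigh).",
        ["uncoupled"], [{"coupling_on": False}], [_settings(duration)],
    )


def _inhibition_block_spec(duration: float = 20.0) -> ExperimentSpec:
    return ExperimentSpec(
        "inhibition_block",
        "Inhibitory synapse onto the sigh compartment removed "
        "(glycinergic-block analogue): sighs persist but turn monophasic.",
        ["control", "gsynINH=0"],
        [{}, {"sigh.gsyn": 0.0}],
        [_settings(duration), _settings(duration)],
    )


def _gca_reduction_spec(duration: float = 20.0) -> ExperimentSpec:
    return ExperimentSpec(
        "gca_reduction",
        "Voltage-gated calcium conductance halved in both compartments "
        "(low-dose cadmium analogue): sighs abolished, eupnea persists.",
        ["control", "gCa_50pct"],
        [{}, {"both.gCa": {"scale": 0.5}}],
        [_settings(duration), _settings(duration)],
    )


def _serca_reduction_spec(duration: float = 20.0) -> ExperimentSpec:
    return ExperimentSpec(
        "serca_reduction",
        "SERCA pump rate reduced to 10% in both compartments (thapsigargin/"
        "CPA analogue): sighs abolished, eupnea persists.",
        ["control", "VSERCA_10pct"],
        [{}, {"both.VSERCA": {"scale": 0.1}}],
        [_settings(duration), _settings(duration)],
    )


#: The g_NaP sweep uses 2.5 nS (eupnea) / 1.0 nS (sigh) as its 100% reference,
#: departing from the 1.3 nS sigh baseline used everywhere else.
GNAP_SWEEP_REFERENCE = {"eupnea": 2.5, "sigh": 1.0}


def _gnap_sweep_spec(duration: float = 20.0) -> ExperimentSpec:
    conditions, edits = [], []
    for pct in (100, 80, 0):
        conditions.append(f"gNaP_{pct}pct")
        f = pct / 100.0
        edits.append({
            "eupnea.gNaP": GNAP_SWEEP_REFERENCE["eupnea"] * f,
            "sigh.gNaP": GNAP_SWEEP_REFERENCE["sigh"] * f,
        })
    return ExperimentSpec(
        "gnap_sweep",
        "Persistent-sodium conductance at 100/80/0% of (2.5, 1.0) nS "
        "(riluzole analogue): eupnea slows then stops; slow events persist "
        "but lose their amplitude separation.",
        conditions, edits, [_settings(duration)] * 3,
    )


def _vk_sweep_spec(durations: Mapping[float, float] | None = None) -> ExperimentSpec:
    durations = durations or {}
    conditions, edits, settings = [], [], []
    for vk in VK_CONDITIONS:
        conditions.append(f"VK_{int(vk)}mV")
        edits.append({"both.VK": vk})
        settings.append(_settings(durations.get(vk, 30.0 if vk == -64.0 else 20.0)))
    return ExperimentSpec(
        "vk_sweep",
        "Leak reversal V_K (the [K+]o proxy) stepped over −64…−58 mV in both "
        "compartments: eupnea frequency rises steeply, sigh frequency barely.",
        conditions, edits, settings,
    )


def _low_vk_spec(duration: float = 30.0) -> ExperimentSpec:
    return ExperimentSpec(
        "low_vk_compartments",
        "V_K = −64 mV: eupnea is below oscillatory threshold yet both "
        "compartments deflect in phase during each sigh (excitatory synapse "
        "from sigh recruits eupnea).",
        ["VK_-64mV"], [{"both.VK": -64.0}], [_settings(duration)],
    )


def _ih_distribution_spec(duration: float = 20.0) -> ExperimentSpec:
    return ExperimentSpec(
        "ih_distribution",
        "I_h restricted to the eupnea compartment, the sigh compartment, "
        "both, or neither: sighs need I_h in the sigh compartment and turn "
        "biphasic only with I_h in both.",
        ["eupnea_only", "sigh_only", "both", "neither"],
        [{"sigh.gh": 0.0}, {"eupnea.gh": 0.0}, {}, {"both.gh": 0.0}],
        [_settings(duration)] * 4,
    )


def _ih_halfact_grid_spec(
    durations: Mapping[float, float] | None = None,
) -> ExperimentSpec:
    durations = durations or {}
    conditions, edits, settings = [], [], []
    for vn in (-90.0, -80.0, -70.0):
        for vk in VK_CONDITIONS:
            conditions.append(f"Vn_{int(vn)}mV_VK_{int(vk)}mV")
            edits.append({"sigh.n_gate.V_half": vn, "both.VK": vk})
            settings.append(_settings(durations.get(vk, 30.0 if vk == -64.0 else 20.0)))
    return ExperimentSpec(
        "ih_halfact_grid",
        "Sigh-compartment I_h half-activation (−90/−80/−70 mV) crossed with "
        "V_K: a right-shifted activation curve makes the sigh period "
        "insensitive to excitability while eupnea is unaffected.",
        conditions, edits, settings,
    )


_REGISTRY: dict[str, Callable[..., ExperimentSpec]] = {
    "baseline": _baseline_spec,
    "uncoupled": _uncoupled_spec,
    "inhibition_block": _inhibition_block_spec,
    "gca_reduction": _gca_reduction_spec,
    "serca_reduction": _serca_reduction_spec,
    "gnap_sweep": _gnap_sweep_spec,
    "vk_sweep": _vk_sweep_spec,
    "low_vk_compartments": _low_vk_spec,
    "ih_distribution": _ih_distribution_spec,
    "ih_halfact_grid": _ih_halfact_grid_spec,
}


def list_experiments() -> list[str]:
    return sorted(_REGISTRY)


def get_experiment(name: str, **kw) -> ExperimentSpec:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown experiment {name!r}; available: {', '.join(list_experiments())}"
        ) from None
    return factory(**kw)


# convenience wrappers for the headline sweep protocols


def vk_sweep(**kw) -> SweepResult:
    return run_experiment(get_experiment("vk_sweep"), **kw)


def gnap_sweep(**kw) -> SweepResult:
    return run_experiment(get_experiment("gnap_sweep"), **kw)


def ih_distribution(**kw) -> SweepResult:
    return run_experiment(get_experiment("ih_distribution"), **kw)


def ih_halfact_grid(**kw) -> SweepResult:
    """Sigh/eupnea cycle periods over the I_h half-activation × V_K grid."""
    res = run_experiment(get_experiment("ih_halfact_grid"), **kw)
    for summ, flag in zip(res.summaries, res.flags):
        if summ is None:
            continue
        flag["sigh_period_s"] = 60.0 / summ.freq_sigh if summ.freq_sigh else None
        flag["eupnea_period_s"] = 60.0 / summ.freq_eupnea if summ.freq_eupnea else None
    return res
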
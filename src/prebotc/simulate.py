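"""Numerical integration of the coupled network and trace I/O.

The system is stiff on two widely separated timescales (ms-scale synaptic
activation against the ~10 s I_NaP inactivation and the minute-scale ER
calcium cycle), so integration uses SciPy's LSODA with an adaptive step.
The first ``transient`` milliseconds (default 6 s) are discarded before
any trace is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import CompartmentState, default_initial_state, make_flat_rhs, STATE_FIELDS
from .params import NetworkConfig, ParameterSet, config_to_dict

__all__ = [
    "SolverSettings",
    "Trace",
    "simulate",
    "single_compartment",
    "write_trace",
    "read_trace",
    "MINUTE",
]

MINUTE = 60_000.0  # ms


@dataclass
class SolverSettings:
    """Integration controls.

    duration/transient in ms of model time; ``output_dt`` is the uniform
    sampling interval of the returned trace.  ``seed`` is reserved for
    forward compatibility — the dynamics are deterministic.
    """

    duration: float = 20 * MINUTE
    transient: float = 6000.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-8
    max_step: float = np.inf
    output_dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transient < 0 or self.duration <= self.transient:
            raise ValueError("require duration > transient >= 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.output_dt <= 0:
            raise ValueError("tolerances and output_dt must be positive")


_COLUMNS = (
    ["t"]
    + [f"{f}_eup" for f in ("V", "h", "s", "Cai", "CaER", "l")]
    + [f"{f}_sigh" for f in ("V", "h", "s", "Cai", "CaER", "l")]
    + ["v_avg"]
)


@dataclass
class Trace:
    """Uniformly sampled post-transient trajectory of both compartments."""

    t: np.ndarray                 # ms, absolute model time
    eupnea: np.ndarray            # (n, 6) in STATE_FIELDS order
    sigh: np.ndarray              # (n, 6)
    v_avg: np.ndarray             # population-average voltage (mV)
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Length of the sampled window (ms)."""
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        data = np.column_stack([self.t, self.eupnea, self.sigh, self.v_avg])
        return pd.DataFrame(data, columns=_COLUMNS)


class IntegrationError(RuntimeError):
    pass


def _initial_vector(config: NetworkConfig, initial: dict | None) -> np.ndarray:
    states = []
    for name in ("eupnea", "sigh"):
        params: ParameterSet = getattr(config, name)
        if initial and name in initial:
            st = initial[name]
            if isinstance(st, CompartmentState):
                states.append(st.as_array())
            else:
                states.append(np.asarray(st, dtype=float))
        else:
            states.append(default_initial_state(params).as_array())
    return np.concatenate(states)


def simulate(
    config: NetworkConfig,
    settings: SolverSettings | None = None,
    initial: dict | None = None,
) -> Trace:
    """Integrate the coupled 12-dimensional system and return the
    post-transient trace sampled at ``output_dt``.

    ``initial`` may map compartment names to CompartmentState (or
    6-vectors) to override the documented default initial conditions.
    """
    settings = settings or SolverSettings()
    y0 = _initial_vector(config, initial)
    t_eval = np.arange(settings.transient, settings.duration + 0.5 * settings.output_dt,
                       settings.output_dt)
    rhs = make_flat_rhs(config)
    sol = solve_ivp(
        rhs,
        (0.0, float(settings.duration)),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        max_step=settings.max_step,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed at t={sol.t[-1]:.3f} ms: {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))[0]
        raise IntegrationError(f"non-finite state at t={sol.t[bad[0]]:.3f} ms")
    w_e, w_s = config.avg_weights
    trace = Trace(
        t=sol.t,
        eupnea=y[:, :6],
        sigh=y[:, 6:],
        v_avg=w_e * y[:, 0] + w_s * y[:, 6],
        metadata={"config": config_to_dict(config), "settings": asdict(settings)},
    )
    return trace


def single_compartment(
    params: ParameterSet,
    settings: SolverSettings | None = None,
    initial: CompartmentState | None = None,
) -> Trace:
    """Integrate one compartment in isolation (zero synaptic input).

    Returned as a Trace whose two compartment blocks are identical, so
    the analysis layer applies unchanged.
    """
    cfg = NetworkConfig(eupnea=params, sigh=params, coupling_on=False)
    init = {"eupnea": initial, "sigh": initial} if initial is not None else None
    tr = simulate(cfg, settings, init)
    tr.metadata["single_compartment"] = True
    return tr


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as CSV plus a JSON sidecar with the resolved config."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(trace.metadata, indent=2, default=float))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trace(
        t=df["t"].to_numpy(),
        eupnea=df[_COLUMNS[1:7]].to_numpy(),
        sigh=df[_COLUMNS[7:13]].to_numpy(),
        v_avg=df["v_avg"].to_numpy(),
        metadata=meta,
    )
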
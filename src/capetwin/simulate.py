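"""Time integration of block sets, dose scans and fold-change summaries.

Two coupling modes are supported:

* ``modular`` (default) — each figure-style block set is integrated on its
  own, mirroring the per-block simulations the model was reported with.
  The matrix (``ecm``) block consumes CAF and tumour trajectories from a
  stroma run and the M2 trajectory from an immunoregulation run,
  interpolated on the solver's time axis; the hypoxia block evolves its
  own tumour compartment; modular immunoregulation runs use a constant
  lactate proxy.
* ``coupled`` — all selected blocks share one joint state; the lactate
  proxy is the tumour-burden fraction ``T/KT`` and the tumour equation
  combines the effector-killing/delta terms with the CAF growth boost and
  the direct CAPE kill when the owning blocks are selected.

Integration uses adaptive solvers from :func:`scipy.integrate.solve_ivp`
(LSODA by default, rtol 1e-6 / atol 1e-9).  Trajectories are reported on a
uniform output grid; values that undershoot zero by more than the absolute
tolerance are clamped to zero and logged as clamp events (undershoots
within the tolerance are treated as solver round-off and clamped
silently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .blocks import BLOCKS, ConfigurationError, rhs_immunoreg
from .params import ParameterBundle, STATE_COMPONENTS, TMEState, validate_state

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "FoldChangeSummary",
    "resolve_coupling",
    "integrate",
    "run_dose_scan",
    "fold_change",
    "SolverError",
    "UndefinedRatioError",
]

#: Modular stages run in this order so that prerequisite trajectories exist.
_MODULAR_ORDER = ("tumour_immune", "immunoreg", "stroma", "hypoxia_angio", "ecm")

#: Clamp events are only logged for undershoots beyond this multiple of the
#: solver's absolute tolerance; smaller ones are round-off.
_CLAMP_TOL_FACTOR = 10.0


class SolverError(RuntimeError):
    """Adaptive integration failed; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class UndefinedRatioError(ZeroDivisionError):
    """Fold change requested against a zero-valued control."""


@dataclass
class SimulationConfig:
    """What to simulate: block set, coupling mode, time span and solver."""

    blocks: tuple[str, ...] = ("tumour_immune",)
    coupling: str = "modular"
    t_end: float = 200.0
    dt_out: float = 1.0
    initial_state: TMEState | None = None
    method: str = "LSODA"
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    dose_list: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0, 100.0)
    lactate: float | str = "default"
    immunoreg_variant: str = "table"

    def __post_init__(self) -> None:
        self.blocks = tuple(self.blocks)
        unknown = [b for b in self.blocks if b not in BLOCKS]
        if unknown:
            raise ConfigurationError(f"unknown block(s): {', '.join(unknown)}")
        if not self.blocks:
            raise ConfigurationError("at least one block must be selected")
        if self.coupling not in ("modular", "coupled"):
            raise ConfigurationError(
                f"coupling must be 'modular' or 'coupled', got {self.coupling!r}"
            )
        if self.t_end < 0:
            raise ConfigurationError("t_end must be >= 0")


@dataclass
class Trajectory:
    """A simulated time course on a uniform grid.

    ``states`` has one row per grid time and one column per entry of
    ``components``; components that were not simulated are absent from
    ``components`` (and written as empty fields in CSV output).
    """

    times: np.ndarray
    states: np.ndarray
    components: tuple[str, ...]
    dose: float
    block_set: tuple[str, ...]
    solver_meta: dict = field(default_factory=dict)
    clamp_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)

    def column(self, component: str) -> np.ndarray:
        try:
            idx = self.components.index(component)
        except ValueError:
            raise KeyError(
                f"component {component!r} was not simulated "
                f"(available: {self.components})"
            ) from None
        return self.states[:, idx]

    def value(self, component: str, time: float) -> float:
        """State value at a grid time (exact match required)."""
        hit = np.nonzero(np.isclose(self.times, time))[0]
        if not hit.size:
            raise KeyError(f"time {time} h is not on the output grid")
        return float(self.column(component)[hit[0]])

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times}
        for name in STATE_COMPONENTS:
            if name in self.components:
                data[name] = self.column(name)
            else:
                data[name] = np.full(self.times.shape, np.nan)
        return pd.DataFrame(data)


@dataclass
class FoldChangeSummary:
    """Treated-vs-control ratio of one variable at one time."""

    variable: str
    time: float
    dose: float
    ratio: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.ratio - 1.0)


# ---------------------------------------------------------------------------
# coupling resolution
# ---------------------------------------------------------------------------

def resolve_coupling(config: SimulationConfig) -> list[dict]:
    """Build the input-supply plan: an ordered list of integration stages.

    Each stage is ``{"blocks": (...), "inputs": {component: source}}``
    where *source* is ``"stage:<name>"`` for an interpolated prerequisite
    trajectory, ``"proxy"``/``"const"`` for the lactate closure, or
    ``"state"`` for a shared joint state.  Raises
    :class:`~capetwin.blocks.ConfigurationError` naming any missing
    prerequisite.
    """
    if config.coupling == "coupled":
        inputs = {"L": "proxy" if "immunoreg" in config.blocks else "none"}
        return [{"blocks": config.blocks, "inputs": inputs}]

    plan: list[dict] = []
    for name in _MODULAR_ORDER:
        if name not in config.blocks:
            continue
        inputs: dict[str, str] = {}
        if name == "immunoreg":
            inputs["L"] = "const"
        if name == "ecm":
            missing = []
            if "stroma" not in config.blocks:
                missing.append("stroma (supplies F and T)")
            if "immunoreg" not in config.blocks:
                missing.append("immunoreg (supplies M2)")
            if missing:
                raise ConfigurationError(
                    "modular ecm run is missing prerequisite block(s): "
                    + "; ".join(missing)
                )
            inputs.update(
                {"F": "stage:stroma", "T": "stage:stroma",
                 "M2": "stage:immunoreg"}
            )
        plan.append({"blocks": (name,), "inputs": inputs})
    return plan


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _stage_rhs_factory(
    blocks: Sequence[str],
    params: ParameterBundle,
    dose: float,
    components: tuple[str, ...],
    feeds: Mapping[str, object],
    lactate_const: float,
    coupled: bool,
    variant: str,
):
    """Compile one stage's vector field y -> dy/dt."""
    index = {name: i for i, name in enumerate(components)}
    block_list = [BLOCKS[b] for b in blocks]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        state = {name: max(v, 0.0) for name, v in zip(components, y)}
        for name, feed in feeds.items():
            if callable(feed):
                state[name] = max(float(feed(t)), 0.0)
            else:
                state[name] = float(feed)
        if coupled:
            state["L"] = state.get("T", 0.0) / params.stroma.KT
        elif "L" not in state:
            state["L"] = lactate_const
        dy = np.zeros(len(components))
        dT_terms: list[float] = []
        for blk in block_list:
            if blk.name == "immunoreg":
                derivs = rhs_immunoreg(state, params, dose, variant)
            else:
                derivs = blk.fn(state, params, dose)
            for name, val in derivs.items():
                if name == "T" and coupled:
                    dT_terms.append(val)
                    continue
                dy[index[name]] += val
        if coupled and dT_terms:
            dy[index["T"]] = _combine_coupled_dT(state, params, dose, blocks)
        return dy

    return rhs


def _combine_coupled_dT(
    state: Mapping[str, float],
    params: ParameterBundle,
    dose: float,
    blocks: Sequence[str],
) -> float:
    """Single joint tumour derivative for coupled mode.

    The tumour-immune block's equation (logistic + effector killing +
    delta suppression) is the backbone when selected, otherwise the stroma
    block's.  The CAF growth boost multiplies the proliferation term when
    the stroma block is present, and the hypoxia block contributes its
    direct CAPE kill term.
    """
    from .blocks import rhs_hypoxia_angio, rhs_stroma, rhs_tumour_immune
    from .pharmacodynamics import hill_fraction

    f = hill_fraction(dose, params.cape)
    boost = 1.0
    if "stroma" in blocks:
        p = params.stroma
        F = state.get("F", 0.0)
        boost = 1.0 + p.betaF * F / (p.KF + F)
    if "tumour_immune" in blocks:
        base = rhs_tumour_immune(state, params, dose)["T"]
        p = params.tumour_immune
        T = state.get("T", 0.0)
        logistic = p.r * T * (1.0 - T / p.K)
        dT = base + (boost - 1.0) * logistic
    elif "stroma" in blocks:
        dT = rhs_stroma(state, params, dose)["T"]
    else:
        return rhs_hypoxia_angio(state, params, dose)["T"]
    if "hypoxia_angio" in blocks:
        dT -= params.hypoxia_angio.kkill * f * state.get("T", 0.0)
    return dT


def integrate(
    config: SimulationConfig,
    params: ParameterBundle | None = None,
    dose: float = 0.0,
) -> Trajectory:
    """Integrate the configured block set at one CAPE dose.

    Returns the trajectory on the uniform output grid.  Components that
    undershoot zero beyond the tolerance are clamped and the events
    recorded in ``Trajectory.clamp_events``.
    """
    params = params if params is not None else _default_bundle()
    y0_state = config.initial_state or params.initial_state
    validate_state(y0_state)
    if dose < 0:
        raise ValueError("dose must be non-negative")

    plan = resolve_coupling(config)
    n_out = int(round(config.t_end / config.dt_out)) if config.t_end > 0 else 0
    times = np.linspace(0.0, config.t_end, n_out + 1)

    lactate_const = (
        params.simulation.lactate_const
        if config.lactate == "default"
        else float(config.lactate)
    )

    results: dict[str, dict[str, np.ndarray]] = {}
    columns: dict[str, np.ndarray] = {}
    clamp_events: list[tuple[str, float, float]] = []
    nfev = 0

    for stage in plan:
        blocks = stage["blocks"]
        components: tuple[str, ...] = tuple(
            dict.fromkeys(
                c for b in blocks for c in BLOCKS[b].outputs
            )
        )
        feeds: dict[str, object] = {}
        for comp, source in stage["inputs"].items():
            if source.startswith("stage:"):
                src = source.split(":", 1)[1]
                grid = results[src]
                feeds[comp] = _interp1(grid["t"], grid[comp])
            elif source == "const":
                feeds[comp] = lactate_const
        y0 = np.array([getattr(y0_state, c) for c in components], dtype=float)

        if config.t_end == 0:
            ygrid = y0[None, :]
            tgrid = np.array([0.0])
        else:
            rhs = _stage_rhs_factory(
                blocks, params, dose, components, feeds,
                lactate_const, config.coupling == "coupled",
                config.immunoreg_variant,
            )
            sol = solve_ivp(
                rhs, (0.0, config.t_end), y0,
                method=config.method, rtol=config.rtol, atol=config.atol,
                t_eval=times, dense_output=False,
            )
            if not sol.success:
                raise SolverError(
                    f"integration of stage {blocks} failed: {sol.message}",
                    last_time=float(sol.t[-1]) if sol.t.size else 0.0,
                )
            nfev += sol.nfev
            tgrid, ygrid = sol.t, sol.y.T.copy()
            ygrid[0] = y0  # the exact solution at t = 0 is the IC
            # clamp: log genuine crossings, silently zero round-off
            tol = _CLAMP_TOL_FACTOR * config.atol
            for j, comp in enumerate(components):
                col = ygrid[:, j]
                bad = col < -tol
                for i in np.nonzero(bad)[0]:
                    clamp_events.append((comp, float(tgrid[i]), float(col[i])))
                ygrid[:, j] = np.maximum(col, 0.0)

        stage_result = {"t": tgrid}
        for j, comp in enumerate(components):
            stage_result[comp] = ygrid[:, j]
            # first stage owning a component wins (e.g. T from stroma
            # rather than the hypoxia block's own tumour copy)
            if comp not in columns:
                columns[comp] = ygrid[:, j]
        for b in blocks:
            results[b] = stage_result

    ordered = tuple(c for c in STATE_COMPONENTS if c in columns)
    states = np.column_stack([columns[c] for c in ordered])
    tgrid = times if config.t_end > 0 else np.array([0.0])
    return Trajectory(
        times=tgrid,
        states=states,
        components=ordered,
        dose=dose,
        block_set=config.blocks,
        solver_meta={
            "method": config.method,
            "rtol": config.rtol,
            "atol": config.atol,
            "coupling": config.coupling,
            "nfev": nfev,
            "lactate_const": lactate_const,
        },
        clamp_events=clamp_events,
    )


def _interp1(t: np.ndarray, y: np.ndarray):
    def fn(x: float) -> float:
        return float(np.interp(x, t, y))

    return fn


def _default_bundle() -> ParameterBundle:
    from .params import load_parameters

    return load_parameters()


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_dose_scan(
    config: SimulationConfig,
    doses: Sequence[float] | None = None,
    params: ParameterBundle | None = None,
) -> dict[float, Trajectory]:
    """One trajectory per dose, identical initial state and grid."""
    doses = tuple(doses) if doses is not None else config.dose_list
    if not doses:
        raise ValueError("dose list must not be empty")
    return {
        float(d): integrate(config, params, dose=float(d)) for d in doses
    }


def fold_change(
    scan: Mapping[float, Trajectory],
    variable: str,
    time: float,
    dose: float,
) -> FoldChangeSummary:
    """Treated/control ratio of *variable* at *time* for *dose*.

    The dose-0 control must be present in the scan; a zero-valued control
    raises :class:`UndefinedRatioError`.
    """
    if 0.0 not in scan:
        raise KeyError("dose scan does not contain the dose-0 control")
    if dose not in scan:
        raise KeyError(f"dose {dose} uM is not in the scan")
    control = scan[0.0].value(variable, time)
    treated = scan[dose].value(variable, time)
    if control == 0.0:
        raise UndefinedRatioError(
            f"control value of {variable} at {time} h is zero"
        )
    ratio = treated / control
    if not math.isfinite(ratio):
        raise UndefinedRatioError(
            f"fold change of {variable} at {time} h is not finite"
        )
    return FoldChangeSummary(variable=variable, time=time, dose=dose,
                             ratio=ratio)
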
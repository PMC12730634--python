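"""Domain types and the parameter registry of the digital twin.

The model state collects tumour cells (``T``), CD8+ effectors (``E``),
regulatory T cells (``R``), M1/M2 macrophages, cancer-associated
fibroblasts (``F``), suppressive cytokines (``C``), ECM stiffness (``S``),
matrix proteases (``MMP``), HIF-1 alpha activity (``H``), VEGF (``V``) and
abnormal vessel density (``A``), plus the algebraic inputs oxygen (``O2``),
the lactate proxy (``L``) and the CAPE dose (``D``).

Parameters are grouped per model block.  Defaults ship in
``capetwin/data/defaults.yaml``; :func:`load_parameters` merges user
overrides (flat ``block.name`` keys or nested mappings) over them and
validates the result.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "STATE_COMPONENTS",
    "TMEState",
    "TumourImmuneParams",
    "ImmunoregParams",
    "StromaParams",
    "EcmParams",
    "HypoxiaAngioParams",
    "ExtendedParams",
    "CapePD",
    "ParameterBundle",
    "load_parameters",
    "save_parameters",
    "validate_state",
    "UnknownParameterError",
    "ParameterValidationError",
    "StateValidationError",
]

#: Dynamical components, in canonical order (trajectory column order).
STATE_COMPONENTS: tuple[str, ...] = (
    "T", "E", "R", "M1", "M2", "F", "C", "S", "MMP", "H", "V", "A",
)


class UnknownParameterError(KeyError):
    """A configuration key does not name any known parameter."""


class ParameterValidationError(ValueError):
    """A parameter value violates its invariant (e.g. a negative rate)."""


class StateValidationError(ValueError):
    """A state vector violates an invariant; names the offending fields."""


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class TMEState:
    """One point of the tumour-microenvironment state space.

    All dynamical components must be non-negative.  ``O2`` and ``L`` are
    algebraic inputs (not integrated); ``D`` is the CAPE dose in uM, held
    constant over a run.
    """

    T: float = 0.0
    E: float = 0.0
    R: float = 0.0
    M1: float = 0.0
    M2: float = 0.0
    F: float = 0.0
    C: float = 0.0
    S: float = 0.0
    MMP: float = 0.0
    H: float = 0.0
    V: float = 0.0
    A: float = 0.0
    O2: float = 10.0
    L: float = 0.0
    D: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def components(self) -> dict[str, float]:
        """The dynamical components only, in canonical order."""
        return {k: getattr(self, k) for k in STATE_COMPONENTS}


def validate_state(state: TMEState) -> TMEState:
    """Return *state* unchanged iff all invariants hold.

    Raises :class:`StateValidationError` naming every offending field.
    """
    bad = [k for k in STATE_COMPONENTS if getattr(state, k) < 0]
    if state.D < 0:
        bad.append("D")
    if not all(math.isfinite(getattr(state, k)) for k in STATE_COMPONENTS):
        bad.extend(k for k in STATE_COMPONENTS
                   if not math.isfinite(getattr(state, k)))
    if bad:
        raise StateValidationError(
            f"state invariant violated for component(s): {', '.join(bad)}"
        )
    return state


# ---------------------------------------------------------------------------
# per-block parameter groups
# ---------------------------------------------------------------------------

@dataclass
class TumourImmuneParams:
    """Coupled tumour / CD8+ effector block.

    CAPE enters twice: through the dose-response suppression coefficient
    delta(D) (an additive per-capita tumour loss) and through the Hill
    fraction f(D) scaling effector killing (``phi``) and antigen-driven
    stimulation (``eta``).
    """

    r: float = 0.05
    K: float = 1.0e6
    alpha_kill: float = 1.0e-7
    sE: float = 0.0
    pE: float = 100.0
    KE: float = 1.0e5
    dE: float = 0.05
    alphaTreg: float = 0.0
    phi: float = 1.0
    eta: float = 1.0

    _positive = ("r", "K", "dE", "KE")


@dataclass
class ImmunoregParams:
    """Treg / M1 / M2 block.

    The operational ("table") variant uses shared-niche logistic growth for
    both macrophage phenotypes plus the printed Treg interaction rates.  The
    literal text-form variant (pure source/linear terms) is retained behind
    the ``sM1 .. aE2 / alphaR / betaR`` coefficients, which have no
    published values and default to ``None``.
    """

    rM1: float = 0.02
    rM2: float = 0.02
    Kmac: float = 1.0e6
    aTregM1: float = 1.0e-3
    bTregM2: float = 1.0e-3
    gLacM2: float = 2.0e-3
    sR: float = 0.01
    aM2R: float = 1.0e-7
    dM1: float = 0.01
    dM2: float = 0.01
    dR: float = 0.005
    gM1: float = 0.0
    gM2: float = 0.0
    gR: float = 0.0
    sM1: float | None = None
    sM2: float | None = None
    aM1E: float | None = None
    bL1: float | None = None
    bL2: float | None = None
    gC2: float | None = None
    aE2: float | None = None
    alphaR: float | None = None
    betaR: float | None = None

    _positive = ("Kmac",)
    _unit_interval = ("gM2", "gR")


@dataclass
class StromaParams:
    """CAF / cytokine block with the CAF->tumour growth feedback."""

    sF: float = 5.0
    aF: float = 1.0e-4
    gF: float = 1.0e-3
    dF: float = 0.01
    kF_cape: float = 1.0e-3
    rT: float = 0.02
    KT: float = 1.0e6
    betaF: float = 1.0
    KF: float = 1.0e4
    aC: float = 1.0e-4
    dC: float = 0.01

    _positive = ("KT", "KF")


@dataclass
class EcmParams:
    """ECM stiffness / MMP block with CAPE modulation of MMP turnover."""

    rhoS: float = 1.0e-3
    lamS: float = 1.0e-3
    dS: float = 5.0e-3
    dS_mmp: float = 1.0e-4
    aMMP_T: float = 1.0e-4
    aMMP_F: float = 1.0e-4
    muMMP: float = 1.0e-2
    kMMPprod: float = 0.5
    kMMPdeg: float = 0.5

    _positive = ()
    _unit_interval = ("kMMPprod",)


@dataclass
class HypoxiaAngioParams:
    """Hypoxia-HIF-VEGF-vessel block with CAPE channels.

    ``kO2``, ``kAlpha`` and ``kDelta`` modify effective oxygenation and HIF
    turnover; ``krT`` and ``kkill`` act on this block's own tumour
    equation.
    """

    aH: float = 0.05
    KO2: float = 20.0
    KTH: float = 1.0e5
    dH: float = 0.01
    O2base: float = 10.0
    kO2: float = 0.60
    kAlpha: float = 0.40
    kDelta: float = 0.50
    krT: float = 0.35
    kkill: float = 0.015
    aV: float = 0.10
    dV: float = 0.02
    aA: float = 0.05
    KVA: float = 50.0
    Amax: float = 100.0
    dA: float = 0.01

    _positive = ("Amax", "KO2", "KTH", "KVA")
    _unit_interval = ("kAlpha", "krT")


# Coefficients of the structural (extended) tumour / effector equations.
# None of them has a published value; the extended right-hand side is only
# evaluable once every coefficient is supplied explicitly.
_EXTENDED_FIELDS = (
    "kE", "KEkill", "kM1", "KM1", "kM2", "khyp", "KH",          # tumour
    "sE", "kactE", "KAPC", "KIL2", "chiA", "KAE", "chiCX",      # effector
    "KCX", "muR", "muS", "kexh", "KCpx", "dE2",
    "rT", "KT",
)


@dataclass
class ExtendedParams:
    """User-supplied coefficients of the structural tumour/effector forms."""

    kE: float | None = None
    KEkill: float | None = None
    kM1: float | None = None
    KM1: float | None = None
    kM2: float | None = None
    khyp: float | None = None
    KH: float | None = None
    sE: float | None = None
    kactE: float | None = None
    KAPC: float | None = None
    KIL2: float | None = None
    chiA: float | None = None
    KAE: float | None = None
    chiCX: float | None = None
    KCX: float | None = None
    muR: float | None = None
    muS: float | None = None
    kexh: float | None = None
    KCpx: float | None = None
    dE2: float | None = None
    rT: float | None = None
    KT: float | None = None

    def missing(self, needed: tuple[str, ...] | None = None) -> list[str]:
        names = needed if needed is not None else _EXTENDED_FIELDS
        return [n for n in names if getattr(self, n) is None]


@dataclass
class CapePD:
    """CAPE dose-response settings.

    ``f(D) = D**nH / (D**nH + IC50**nH)`` is the fractional CAPE effect;
    ``delta_doses -> delta_values`` is the printed dose -> delta mapping
    used by the tumour-immune block (units 1/h).
    """

    IC50: float = 50.0
    nH: float = 2.0
    delta_doses: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0, 100.0)
    delta_values: tuple[float, ...] = (0.0, 0.02, 0.05, 0.08, 0.10)

    def __post_init__(self) -> None:
        self.delta_doses = tuple(float(d) for d in self.delta_doses)
        self.delta_values = tuple(float(v) for v in self.delta_values)
        if self.IC50 <= 0 or self.nH <= 0:
            raise ParameterValidationError("IC50 and nH must be positive")
        if len(self.delta_doses) != len(self.delta_values):
            raise ParameterValidationError("delta mapping length mismatch")
        if any(b < a for a, b in zip(self.delta_doses, self.delta_doses[1:])):
            raise ParameterValidationError("delta doses must be sorted")
        if any(b < a for a, b in zip(self.delta_values, self.delta_values[1:])):
            raise ParameterValidationError(
                "delta must be non-decreasing in dose"
            )


@dataclass
class SimulationDefaults:
    """Solver and experiment defaults shipped with the parameter file."""

    t_end: float = 200.0
    dt_out: float = 1.0
    method: str = "LSODA"
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    lactate_const: float = 0.5
    dose_list: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0, 100.0)

    def __post_init__(self) -> None:
        self.dose_list = tuple(float(d) for d in self.dose_list)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

_BLOCK_TYPES: dict[str, type] = {
    "tumour_immune": TumourImmuneParams,
    "immunoreg": ImmunoregParams,
    "stroma": StromaParams,
    "ecm": EcmParams,
    "hypoxia_angio": HypoxiaAngioParams,
    "extended": ExtendedParams,
}

# Config sections that are not per-block dataclasses of floats.
_SPECIAL_SECTIONS = ("cape", "initial_state", "simulation")


@dataclass
class ParameterBundle:
    """The full parameter set of the twin: one group per block plus the
    dose-response settings, shipped initial conditions and solver defaults."""

    tumour_immune: TumourImmuneParams = field(default_factory=TumourImmuneParams)
    immunoreg: ImmunoregParams = field(default_factory=ImmunoregParams)
    stroma: StromaParams = field(default_factory=StromaParams)
    ecm: EcmParams = field(default_factory=EcmParams)
    hypoxia_angio: HypoxiaAngioParams = field(default_factory=HypoxiaAngioParams)
    extended: ExtendedParams = field(default_factory=ExtendedParams)
    cape: CapePD = field(default_factory=CapePD)
    initial_state: TMEState = field(default_factory=TMEState)
    simulation: SimulationDefaults = field(default_factory=SimulationDefaults)

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)

    # -- flat access ------------------------------------------------------
    def get(self, key: str) -> Any:
        section, name = _split_key(key)
        return getattr(self._section(section), name)

    def set(self, key: str, value: float) -> None:
        section, name = _split_key(key)
        obj = self._section(section)
        if not hasattr(obj, name):
            raise UnknownParameterError(key)
        setattr(obj, name, value)

    def _section(self, section: str) -> Any:
        if not hasattr(self, section):
            raise UnknownParameterError(section)
        return getattr(self, section)

    def items(self) -> Iterator[tuple[str, Any]]:
        """Flat ``section.name -> value`` view over every parameter."""
        for section in (*_BLOCK_TYPES, *_SPECIAL_SECTIONS):
            obj = getattr(self, section)
            for f in fields(obj):
                yield f"{section}.{f.name}", getattr(obj, f.name)

    def to_dict(self) -> dict[str, dict[str, Any]]:
        out: dict[str, dict[str, Any]] = {}
        for key, value in self.items():
            section, name = key.split(".", 1)
            if isinstance(value, tuple):
                value = list(value)
            out.setdefault(section, {})[name] = value
        return out

    def validate(self) -> "ParameterBundle":
        errors: list[str] = []
        for key, value in self.items():
            if value is None or isinstance(value, (str, list, tuple)):
                continue
            section, name = key.split(".", 1)
            if value < 0:
                errors.append(f"{key} = {value} (negative rate/value)")
            obj = getattr(self, section)
            if name in getattr(obj, "_positive", ()) and value <= 0:
                errors.append(f"{key} = {value} (must be > 0)")
            if name in getattr(obj, "_unit_interval", ()) and value > 1:
                errors.append(f"{key} = {value} (reduction gain must be <= 1)")
        if self.hypoxia_angio.Amax > 0 and \
                self.initial_state.A > self.hypoxia_angio.Amax:
            errors.append("initial_state.A exceeds hypoxia_angio.Amax")
        if errors:
            raise ParameterValidationError("; ".join(errors))
        return self


def _split_key(key: str) -> tuple[str, str]:
    if "." not in key:
        raise UnknownParameterError(
            f"{key!r}: expected a namespaced key like 'stroma.kF_cape'"
        )
    section, name = key.split(".", 1)
    return section, name


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def _shipped_defaults() -> dict[str, dict[str, Any]]:
    ref = importlib.resources.files("capetwin.data") / "defaults.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _flatten(config: Mapping[str, Any]) -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in config.items():
        if isinstance(value, Mapping):
            for sub, v in value.items():
                flat[f"{key}.{sub}"] = v
        else:
            flat[key] = value
    return flat


def load_parameters(
    config: Mapping[str, Any] | str | Path | None = None,
) -> ParameterBundle:
    """Build a validated :class:`ParameterBundle`.

    *config* may be ``None`` (shipped defaults), a mapping with flat
    ``block.name`` keys or nested per-block mappings, or a path to a
    YAML/JSON document of the same shape.  Unknown keys raise
    :class:`UnknownParameterError`; invalid values raise
    :class:`ParameterValidationError`.
    """
    raw = _shipped_defaults()
    overrides: dict[str, Any] = {}
    if config is not None:
        if isinstance(config, (str, Path)):
            with open(config) as fh:
                config = yaml.safe_load(fh) or {}
        overrides = _flatten(config)

    flat = _flatten(raw)
    for key, value in overrides.items():
        if key not in flat and _is_unknown(key):
            raise UnknownParameterError(key)
        flat[key] = value

    bundle = _build_bundle(flat)
    return bundle.validate()


def _is_unknown(key: str) -> bool:
    try:
        section, name = _split_key(key)
    except UnknownParameterError:
        return True
    if section in _BLOCK_TYPES:
        return name not in {f.name for f in fields(_BLOCK_TYPES[section])}
    if section == "cape":
        return name not in {f.name for f in fields(CapePD)}
    if section == "initial_state":
        return name not in {f.name for f in fields(TMEState)}
    if section == "simulation":
        return name not in {f.name for f in fields(SimulationDefaults)}
    return True


def _build_bundle(flat: Mapping[str, Any]) -> ParameterBundle:
    grouped: dict[str, dict[str, Any]] = {}
    for key, value in flat.items():
        section, name = key.split(".", 1)
        grouped.setdefault(section, {})[name] = value
    kwargs: dict[str, Any] = {}
    for section, cls in _BLOCK_TYPES.items():
        kwargs[section] = cls(**grouped.get(section, {}))
    kwargs["cape"] = CapePD(**grouped.get("cape", {}))
    kwargs["initial_state"] = TMEState(**grouped.get("initial_state", {}))
    kwargs["simulation"] = SimulationDefaults(**grouped.get("simulation", {}))
    return ParameterBundle(**kwargs)


def save_parameters(bundle: ParameterBundle, path: str | Path) -> Path:
    """Serialise a bundle to YAML; :func:`load_parameters` on the result
    reproduces every value bit-exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(bundle.to_dict(), fh, sort_keys=False)
    return path
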
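"""Right-hand sides of the model blocks, as pure state -> derivative maps.

Each function takes a mapping of state components (missing components are
treated as absent couplings, i.e. zero), the parameter bundle and the CAPE
dose, and returns the time derivatives of the components it owns.  All
right-hand sides are finite and continuous on the non-negative orthant and
quasi-positive (a component at zero can never be pushed negative), which
makes the orthant forward-invariant for the exact flow.

Blocks
------
``tumour_immune``
    Logistic tumour growth, mass-action effector killing enhanced by CAPE,
    the tabulated delta(dose) suppression, and antigen-driven effector
    recruitment with Treg suppression.
``immunoreg``
    Tregs and M1/M2 macrophages sharing a niche.  The operational "table"
    variant matches the printed rate constants; the literal "text" variant
    (pure source/linear forms) requires user-supplied coefficients.
``stroma``
    CAFs sourced by tumour and cytokines, suppressed by CAPE through the
    Hill fraction; tumour growth boosted by CAFs through a saturating
    feedback.
``ecm``
    ECM stiffness raised by CAFs/M2 and degraded by MMPs; MMP production
    and decay modulated by CAPE.
``hypoxia_angio``
    Oxygen- and burden-driven HIF, HIF-driven VEGF, and saturating
    abnormal-vessel growth toward a capacity; CAPE improves oxygenation,
    destabilises HIF and directly kills tumour cells.
``extended``
    The full structural tumour/effector forms (saturating macrophage
    kill/support, hypoxic stress, APC/IL-2 priming, vessel/CXCL12
    trafficking, Treg/stiffness/exhaustion losses); every coefficient must
    be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .params import ExtendedParams, ParameterBundle
from .pharmacodynamics import delta_for_dose, hill_fraction

__all__ = [
    "BlockRHS",
    "BLOCKS",
    "rhs_tumour_immune",
    "rhs_immunoreg",
    "rhs_stroma",
    "rhs_ecm",
    "rhs_hypoxia_angio",
    "rhs_extended",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A block was asked to run without a required coefficient or input."""


def _get(state: Mapping[str, float], name: str, default: float = 0.0) -> float:
    v = state.get(name, default)
    return v if v is not None else default


def rhs_tumour_immune(
    state: Mapping[str, float],
    params: ParameterBundle,
    dose: float,
) -> dict[str, float]:
    """dT/dt and dE/dt of the coupled tumour / effector block.

    ``dT/dt = r T (1 - T/K) - alpha_kill E T (1 + phi f(D)) - delta(D) T``
    ``dE/dt = sE + pE T/(T+KE) (1 + eta f(D)) - dE E - alphaTreg R E``

    The Treg coupling defaults to zero (``alphaTreg = 0``) when the block
    runs uncoupled.
    """
    p = params.tumour_immune
    f = hill_fraction(dose, params.cape)
    delta = delta_for_dose(dose, params.cape, interpolate=True)
    T, E, R = _get(state, "T"), _get(state, "E"), _get(state, "R")
    dT = (
        p.r * T * (1.0 - T / p.K)
        - p.alpha_kill * E * T * (1.0 + p.phi * f)
        - delta * T
    )
    dE = (
        p.sE
        + p.pE * T / (T + p.KE) * (1.0 + p.eta * f)
        - p.dE * E
        - p.alphaTreg * R * E
    )
    return {"T": dT, "E": dE}


def rhs_immunoreg(
    state: Mapping[str, float],
    params: ParameterBundle,
    dose: float,
    variant: str = "table",
) -> dict[str, float]:
    """dR/dt, dM1/dt and dM2/dt of the immunoregulation block.

    "table" variant (operational default, parameterised by the printed
    rate constants)::

        dM1/dt = rM1 M1 (1 - (M1+M2)/Kmac) - aTregM1 R M1 - dM1 M1
                 + gM1 f(D) M1
        dM2/dt = rM2 M2 (1 - (M1+M2)/Kmac)
                 + (bTregM2 R + gLacM2 L) M2 (1 - gM2 f(D)) - dM2 M2
        dR/dt  = sR + aM2R M2 (1 - gR f(D)) - dR R

    CAPE boosts M1 expansion (``gM1``, 1/h scale) and attenuates both the
    immunosuppressive M2 polarisation drive (Treg promotion plus
    lactate-driven expansion, ``gM2``) and M2-mediated Treg induction
    (``gR``); the attenuation gains live in ``[0, 1]``.

    "text" variant (the literal source/linear forms)::

        dR/dt  = sR + alphaR C + betaR L - dR R
        dM1/dt = sM1 + aM1E E - bL1 L M1 - dM1 M1
        dM2/dt = sM2 + (bL2 L + gC2 C - aE2 E) M2 - dM2 M2

    whose coefficients have no published values and must be configured
    explicitly (:class:`ConfigurationError` otherwise).
    """
    p = params.immunoreg
    f = hill_fraction(dose, params.cape)
    R, M1, M2 = _get(state, "R"), _get(state, "M1"), _get(state, "M2")
    L = _get(state, "L")
    if variant == "table":
        crowd = (M1 + M2) / p.Kmac
        dM1 = (
            p.rM1 * M1 * (1.0 - crowd)
            - p.aTregM1 * R * M1
            - p.dM1 * M1
            + p.gM1 * f * M1
        )
        dM2 = (
            p.rM2 * M2 * (1.0 - crowd)
            + (p.bTregM2 * R + p.gLacM2 * L) * M2 * (1.0 - p.gM2 * f)
            - p.dM2 * M2
        )
        dR = p.sR + p.aM2R * M2 * (1.0 - p.gR * f) - p.dR * R
        return {"R": dR, "M1": dM1, "M2": dM2}
    if variant == "text":
        needed = ("sM1", "sM2", "aM1E", "bL1", "bL2", "gC2", "aE2",
                  "alphaR", "betaR")
        missing = [n for n in needed if getattr(p, n) is None]
        if missing:
            raise ConfigurationError(
                "text-variant immunoreg coefficients not configured: "
                + ", ".join(missing)
            )
        C = _get(state, "C")
        E = _get(state, "E")
        dR = p.sR + p.alphaR * C + p.betaR * L - p.dR * R
        dM1 = p.sM1 + p.aM1E * E - p.bL1 * L * M1 - p.dM1 * M1
        dM2 = p.sM2 + (p.bL2 * L + p.gC2 * C - p.aE2 * E) * M2 - p.dM2 * M2
        return {"R": dR, "M1": dM1, "M2": dM2}
    raise ConfigurationError(f"unknown immunoreg variant {variant!r}")


def rhs_stroma(
    state: Mapping[str, float],
    params: ParameterBundle,
    dose: float,
) -> dict[str, float]:
    """dF/dt, dC/dt and dT/dt of the CAF / cytokine block.

    ``dF/dt = sF + aF T + gF C - dF F - kF_cape f(D) F``
    ``dC/dt = aC T - dC C``
    ``dT/dt = rT_eff T (1 - T/KT)`` with
    ``rT_eff = rT (1 + betaF F/(KF+F)) (1 - krT f(D))``.
    """
    p = params.stroma
    f = hill_fraction(dose, params.cape)
    krT = params.hypoxia_angio.krT
    F, C, T = _get(state, "F"), _get(state, "C"), _get(state, "T")
    dF = p.sF + p.aF * T + p.gF * C - p.dF * F - p.kF_cape * f * F
    dC = p.aC * T - p.dC * C
    rT_eff = p.rT * (1.0 + p.betaF * F / (p.KF + F)) * (1.0 - krT * f)
    dT = rT_eff * T * (1.0 - T / p.KT)
    return {"F": dF, "C": dC, "T": dT}


def rhs_ecm(
    state: Mapping[str, float],
    params: ParameterBundle,
    dose: float,
) -> dict[str, float]:
    """dS/dt and dMMP/dt of the matrix block.

    ``dS/dt = rhoS F + lamS M2 - dS S - dS_mmp MMP S``
    ``dMMP/dt = aMMP_T T + aMMP_F (1 - kMMPprod f) F
                - muMMP (1 + kMMPdeg f) MMP``

    ``F``, ``M2`` and ``T`` are couplings supplied by the stroma and
    immunoregulation blocks (or interpolated from their runs in modular
    mode).
    """
    p = params.ecm
    f = hill_fraction(dose, params.cape)
    F, M2, T = _get(state, "F"), _get(state, "M2"), _get(state, "T")
    S, MMP = _get(state, "S"), _get(state, "MMP")
    dS = p.rhoS * F + p.lamS * M2 - p.dS * S - p.dS_mmp * MMP * S
    dMMP = (
        p.aMMP_T * T
        + p.aMMP_F * (1.0 - p.kMMPprod * f) * F
        - p.muMMP * (1.0 + p.kMMPdeg * f) * MMP
    )
    return {"S": dS, "MMP": dMMP}


def rhs_hypoxia_angio(
    state: Mapping[str, float],
    params: ParameterBundle,
    dose: float,
) -> dict[str, float]:
    """dH/dt, dV/dt, dA/dt and dT/dt of the hypoxia / angiogenesis block.

    With the CAPE-modified rates ``O2eff = O2base (1 + kO2 f)``,
    ``aHeff = aH (1 - kAlpha f)`` and ``dHeff = dH (1 + kDelta f)``::

        dH/dt = aHeff [1/(1 + O2eff/KO2)] [T/(KTH + T)] - dHeff H
        dV/dt = aV H - dV V
        dA/dt = aA V/(KVA + V) (1 - A/Amax) - dA A
        dT/dt = rT (1 - krT f) T (1 - T/KT) - kkill f T

    The tumour equation borrows ``rT``/``KT`` from the stroma block's
    logistic scale and adds this block's CAPE channels (proliferation
    brake ``krT`` and direct kill ``kkill``).
    """
    p = params.hypoxia_angio
    f = hill_fraction(dose, params.cape)
    rT, KT = params.stroma.rT, params.stroma.KT
    H, V, A, T = (_get(state, "H"), _get(state, "V"), _get(state, "A"),
                  _get(state, "T"))
    O2eff = p.O2base * (1.0 + p.kO2 * f)
    aHeff = p.aH * (1.0 - p.kAlpha * f)
    dHeff = p.dH * (1.0 + p.kDelta * f)
    dH = aHeff * (1.0 / (1.0 + O2eff / p.KO2)) * (T / (p.KTH + T)) - dHeff * H
    dV = p.aV * H - p.dV * V
    dA = p.aA * V / (p.KVA + V) * (1.0 - A / p.Amax) - p.dA * A
    dT = rT * (1.0 - p.krT * f) * T * (1.0 - T / KT) - p.kkill * f * T
    return {"H": dH, "V": dV, "A": dA, "T": dT}


def rhs_extended(
    state: Mapping[str, float],
    params: ExtendedParams | ParameterBundle,
    dose: float = 0.0,
    inputs: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """The literal structural tumour / effector forms.

    ``dT/dt = rT T (1 - T/KT) - kE E T/(T + KEkill)
              - kM1 M1 T/(T + KM1) + kM2 M2 T - khyp H/(KH + H) T``

    ``dE/dt = sE + kactE APC/(KAPC+APC) IL2/(KIL2+IL2)
              + chiA A/(KAE+A) + chiCX CX/(KCX+CX)
              - muR R E - muS S E - kexh Cpx/(KCpx+Cpx) E - dE2 E``

    *inputs* supplies the algebraic species (``APC``, ``IL2``, ``CX``,
    ``Cpx``) that have no dynamics of their own; missing entries default
    to 0.  Every coefficient must be set explicitly
    (:class:`ConfigurationError` names the missing ones).
    """
    p = params.extended if isinstance(params, ParameterBundle) else params
    missing = p.missing()
    if missing:
        raise ConfigurationError(
            "extended coefficients not configured: " + ", ".join(missing)
        )
    inputs = inputs or {}
    T, E = _get(state, "T"), _get(state, "E")
    M1, M2, H = _get(state, "M1"), _get(state, "M2"), _get(state, "H")
    R, S, A = _get(state, "R"), _get(state, "S"), _get(state, "A")
    APC = _get(inputs, "APC")
    IL2 = _get(inputs, "IL2")
    CX = _get(inputs, "CX")
    Cpx = _get(inputs, "Cpx")
    dT = (
        p.rT * T * (1.0 - T / p.KT)
        - p.kE * E * T / (T + p.KEkill)
        - p.kM1 * M1 * T / (T + p.KM1)
        + p.kM2 * M2 * T
        - p.khyp * H / (p.KH + H) * T
    )
    dE = (
        p.sE
        + p.kactE * APC / (p.KAPC + APC) * IL2 / (p.KIL2 + IL2)
        + p.chiA * A / (p.KAE + A)
        + p.chiCX * CX / (p.KCX + CX)
        - p.muR * R * E
        - p.muS * S * E
        - p.kexh * Cpx / (p.KCpx + Cpx) * E
        - p.dE2 * E
    )
    return {"T": dT, "E": dE}


@dataclass(frozen=True)
class BlockRHS:
    """Registry entry: which components a block owns and which it reads."""

    name: str
    outputs: tuple[str, ...]
    inputs: tuple[str, ...]
    fn: Callable[..., dict[str, float]]


BLOCKS: dict[str, BlockRHS] = {
    "tumour_immune": BlockRHS(
        "tumour_immune", ("T", "E"), ("R",), rhs_tumour_immune),
    "immunoreg": BlockRHS(
        "immunoreg", ("R", "M1", "M2"), ("L",), rhs_immunoreg),
    "stroma": BlockRHS(
        "stroma", ("F", "C", "T"), (), rhs_stroma),
    "ecm": BlockRHS(
        "ecm", ("S", "MMP"), ("F", "M2", "T"), rhs_ecm),
    "hypoxia_angio": BlockRHS(
        "hypoxia_angio", ("H", "V", "A", "T"), (), rhs_hypoxia_angio),
}
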
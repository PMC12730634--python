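"""CAPE dose-response layer.

Two dose-entry mechanisms coexist in the model and are never mixed within
one block:

* the tumour-immune block uses the tabulated ``delta(dose)`` suppression
  coefficient (an additive per-capita tumour loss, 1/h) together with the
  Hill-scaled effector gains ``phi`` and ``eta``;
* every other block sees the dose only through the Hill fraction
  ``f(D) = D**nH / (D**nH + IC50**nH)`` multiplied by a per-channel gain.

``apply_modifiers`` evaluates the standard modifier channels (effective
oxygenation, HIF induction/degradation, tumour proliferation, direct kill,
MMP production/degradation, CAF loss) at a given dose.
"""

from __future__ import annotations

import numpy as np

from .params import CapePD, HypoxiaAngioParams, ParameterValidationError

__all__ = ["hill_fraction", "delta_for_dose", "apply_modifiers", "CapePD"]

#: Names of the per-channel CAPE effect gains, with the parameter section
#: that owns each (used by the calibration routines to resolve free names).
CHANNEL_GAINS: dict[str, str] = {
    "phi": "tumour_immune",
    "eta": "tumour_immune",
    "kO2": "hypoxia_angio",
    "kAlpha": "hypoxia_angio",
    "kDelta": "hypoxia_angio",
    "krT": "hypoxia_angio",
    "kkill": "hypoxia_angio",
    "kMMPprod": "ecm",
    "kMMPdeg": "ecm",
    "kF_cape": "stroma",
    "gM1": "immunoreg",
    "gM2": "immunoreg",
    "gR": "immunoreg",
}

#: Highest dose the printed simulations use; beyond it the delta mapping is
#: extrapolation and must be requested explicitly.
MAX_MAPPED_DOSE = 100.0


def hill_fraction(dose: float, pd: CapePD) -> float:
    """Fractional CAPE effect ``D**n / (D**n + IC50**n)`` in ``[0, 1)``.

    Monotone non-decreasing in dose; exactly 0 at dose 0.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    if dose == 0:
        return 0.0
    dn = dose ** pd.nH
    return dn / (dn + pd.IC50 ** pd.nH)


def delta_for_dose(
    dose: float,
    pd: CapePD,
    *,
    interpolate: bool = False,
    allow_extrapolation: bool = False,
) -> float:
    """The tabulated CAPE tumour-suppression coefficient delta (1/h).

    Exact at the mapped doses; between them, piecewise-linear interpolation
    on the dose axis is returned only when ``interpolate=True``.  Doses
    beyond the mapped range require ``allow_extrapolation`` (the mapping is
    clamped at its last value) because the printed simulations stop at
    100 uM.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    doses = np.asarray(pd.delta_doses)
    values = np.asarray(pd.delta_values)
    if dose > doses[-1]:
        if not allow_extrapolation:
            raise ValueError(
                f"dose {dose} uM is beyond the mapped range "
                f"(max {doses[-1]} uM); pass allow_extrapolation=True "
                "to clamp at the last mapped value"
            )
        return float(values[-1])
    hit = np.nonzero(np.isclose(doses, dose))[0]
    if hit.size:
        return float(values[hit[0]])
    if not interpolate:
        raise ValueError(
            f"dose {dose} uM is not one of the mapped doses "
            f"{tuple(doses)}; pass interpolate=True for piecewise-linear "
            "interpolation"
        )
    return float(np.interp(dose, doses, values))


def apply_modifiers(
    base: HypoxiaAngioParams | None,
    dose: float,
    pd: CapePD,
    *,
    ecm_rates: tuple[float, float] | None = None,
    kMMPprod: float = 0.0,
    kMMPdeg: float = 0.0,
    kF_cape: float = 0.0,
    rT: float | None = None,
) -> dict[str, float]:
    """Effective rates for every CAPE modifier channel at *dose*.

    With ``f = hill_fraction(dose)``:

    ======================  =============================================
    ``O2eff``               ``O2base * (1 + kO2 * f)``
    ``aHeff``               ``aH * (1 - kAlpha * f)``
    ``dHeff``               ``dH * (1 + kDelta * f)``
    ``rTeff``               ``rT * (1 - krT * f)``
    ``extra_kill``          ``kkill * f``
    ``aMMP_F_eff``          ``aMMP_F * (1 - kMMPprod * f)``
    ``muMMP_eff``           ``muMMP * (1 + kMMPdeg * f)``
    ``caf_loss``            ``kF_cape * f``
    ======================  =============================================

    At dose 0 every effective rate equals its base rate.  Reduction gains
    above 1 would drive rates negative and are rejected.
    """
    f = hill_fraction(dose, pd)
    out: dict[str, float] = {"f": f}
    if base is not None:
        for gain in ("kAlpha", "krT"):
            if getattr(base, gain) > 1:
                raise ParameterValidationError(
                    f"reduction gain {gain} = {getattr(base, gain)} > 1 "
                    "would create a negative rate"
                )
        out["O2eff"] = base.O2base * (1.0 + base.kO2 * f)
        out["aHeff"] = base.aH * (1.0 - base.kAlpha * f)
        out["dHeff"] = base.dH * (1.0 + base.kDelta * f)
        out["extra_kill"] = base.kkill * f
        if rT is not None:
            out["rTeff"] = rT * (1.0 - base.krT * f)
    if ecm_rates is not None:
        if kMMPprod > 1:
            raise ParameterValidationError(
                f"reduction gain kMMPprod = {kMMPprod} > 1 "
                "would create a negative rate"
            )
        aMMP_F, muMMP = ecm_rates
        out["aMMP_F_eff"] = aMMP_F * (1.0 - kMMPprod * f)
        out["muMMP_eff"] = muMMP * (1.0 + kMMPdeg * f)
    out["caf_loss"] = kF_cape * f
    return out
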
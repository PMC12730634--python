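"""Right-hand sides: printed-form agreement, fixed points, quasi-positivity."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from capetwin.blocks import (
    BLOCKS,
    ConfigurationError,
    rhs_ecm,
    rhs_extended,
    rhs_hypoxia_angio,
    rhs_immunoreg,
    rhs_stroma,
    rhs_tumour_immune,
)
from capetwin.params import ExtendedParams, load_parameters


@pytest.fixture(scope="module")
def b():
    return load_parameters()


class TestTumourImmune:
    def test_extinction_is_a_fixed_point(self, b):
        bb = b.copy()
        bb.tumour_immune.sE = 0.0
        d = rhs_tumour_immune({"T": 0.0, "E": 0.0}, bb, 0.0)
        assert d == {"T": 0.0, "E": 0.0}

    def test_logistic_ceiling(self, b):
        bb = b.copy()
        bb.tumour_immune.sE = 0.0
        p = bb.tumour_immune
        d = rhs_tumour_immune({"T": p.K, "E": 0.0}, bb, 0.0)
        assert d["T"] == 0.0
        assert d["E"] == pytest.approx(p.pE * p.K / (p.K + p.KE))

    def test_early_logistic_growth_rate(self, b):
        # 0.05 * 1e5 * (1 - 0.1) = 4500 cells/h
        d = rhs_tumour_immune({"T": 1.0e5, "E": 0.0}, b, 0.0)
        assert d["T"] == pytest.approx(4500.0)

    def test_delta_suppression_is_additive_loss(self, b):
        d0 = rhs_tumour_immune({"T": 1.0e5, "E": 0.0}, b, 0.0)
        d100 = rhs_tumour_immune({"T": 1.0e5, "E": 0.0}, b, 100.0)
        assert d100["T"] == pytest.approx(d0["T"] - 0.10 * 1.0e5)


class TestImmunoreg:
    def test_source_only_growth(self, b):
        d = rhs_immunoreg({"R": 0.0, "M1": 0.0, "M2": 0.0, "L": 0.0}, b, 0.0)
        assert d["R"] == pytest.approx(b.immunoreg.sR)
        assert d["M1"] == 0.0 and d["M2"] == 0.0

    def test_dose_zero_matches_dose_free_expressions(self, b):
        p = b.immunoreg
        state = {"R": 50.0, "M1": 2e3, "M2": 3e3, "L": 0.5}
        d = rhs_immunoreg(state, b, 0.0)
        crowd = (2e3 + 3e3) / p.Kmac
        assert d["M1"] == pytest.approx(
            p.rM1 * 2e3 * (1 - crowd) - p.aTregM1 * 50 * 2e3 - p.dM1 * 2e3
        )
        assert d["M2"] == pytest.approx(
            p.rM2 * 3e3 * (1 - crowd)
            + (p.bTregM2 * 50 + p.gLacM2 * 0.5) * 3e3
            - p.dM2 * 3e3
        )
        assert d["R"] == pytest.approx(p.sR + p.aM2R * 3e3 - p.dR * 50)

    def test_shared_niche_ceiling_cancels_logistic_terms(self, b):
        p = b.immunoreg
        state = {"R": 0.0, "M1": p.Kmac / 2, "M2": p.Kmac / 2, "L": 0.0}
        d = rhs_immunoreg(state, b, 0.0)
        # logistic terms vanish at M1 + M2 = Kmac; only decay remains
        assert d["M1"] == pytest.approx(-p.dM1 * p.Kmac / 2)

    def test_text_variant_requires_coefficients(self, b):
        with pytest.raises(ConfigurationError, match="sM1"):
            rhs_immunoreg({"R": 0, "M1": 0, "M2": 0, "L": 0}, b, 0.0,
                          variant="text")

    def test_text_variant_literal_form(self, b):
        bb = b.copy()
        for name in ("sM1", "sM2", "aM1E", "bL1", "bL2", "gC2", "aE2",
                     "alphaR", "betaR"):
            bb.set(f"immunoreg.{name}", 0.01)
        state = {"R": 10.0, "M1": 5.0, "M2": 5.0, "L": 2.0, "C": 3.0,
                 "E": 1.0}
        d = rhs_immunoreg(state, bb, 0.0, variant="text")
        p = bb.immunoreg
        assert d["R"] == pytest.approx(
            p.sR + 0.01 * 3.0 + 0.01 * 2.0 - p.dR * 10.0
        )
        assert d["M1"] == pytest.approx(
            0.01 + 0.01 * 1.0 - 0.01 * 2.0 * 5.0 - p.dM1 * 5.0
        )


class TestStroma:
    def test_baseline_caf_source(self, b):
        d = rhs_stroma({"F": 0.0, "C": 0.0, "T": 0.0}, b, 0.0)
        assert d["F"] == 5.0  # the tabulated CAF source rate

    def test_caf_boost_saturates(self, b):
        p = b.stroma
        big_F = 1e12
        d = rhs_stroma({"F": big_F, "C": 0.0, "T": 1.0}, b, 0.0)
        # per-capita tumour growth approaches rT (1 + betaF)
        expected = p.rT * (1 + p.betaF * big_F / (p.KF + big_F))
        assert d["T"] / 1.0 == pytest.approx(expected * (1 - 1 / p.KT))
        assert expected == pytest.approx(p.rT * 2, rel=1e-6)

    def test_cytokine_production(self, b):
        d = rhs_stroma({"F": 0.0, "C": 0.0, "T": 1.0e5}, b, 0.0)
        assert d["C"] == pytest.approx(10.0)  # 1e-4 * 1e5


class TestEcm:
    def test_empty_stroma_fixed_point(self, b):
        d = rhs_ecm({"F": 0, "M2": 0, "T": 0, "S": 0, "MMP": 0}, b, 0.0)
        assert d == {"S": 0.0, "MMP": 0.0}

    def test_stiffness_quasi_steady_state(self, b):
        p = b.ecm
        F, M2, MMP = 100.0, 200.0, 5.0
        s_star = (p.rhoS * F + p.lamS * M2) / (p.dS + p.dS_mmp * MMP)
        d = rhs_ecm({"F": F, "M2": M2, "T": 0, "S": s_star, "MMP": MMP},
                    b, 0.0)
        assert d["S"] == pytest.approx(0.0, abs=1e-12)

    def test_cape_scales_mmp_production_and_decay(self, b):
        state = {"F": 10.0, "M2": 0, "T": 0, "S": 0, "MMP": 7.0}
        p = b.ecm
        d100 = rhs_ecm(state, b, 100.0)
        # production scaled by 1 - 0.5*0.8 = 0.6; decay by 1 + 0.5*0.8 = 1.4
        assert d100["MMP"] == pytest.approx(
            p.aMMP_F * 0.6 * 10.0 - p.muMMP * 1.4 * 7.0
        )


class TestHypoxiaAngio:
    def test_hif_fixed_point(self, b):
        p = b.hypoxia_angio
        T = 1e5
        h_star = (
            p.aH * (1 / (1 + p.O2base / p.KO2)) * (T / (p.KTH + T)) / p.dH
        )
        d = rhs_hypoxia_angio({"H": h_star, "V": 0, "A": 0, "T": T}, b, 0.0)
        assert d["H"] == pytest.approx(0.0, abs=1e-12)

    def test_vegf_relaxation_level(self, b):
        # V* = aV H / dV = 0.10/0.02 = 5 for H = 1
        d = rhs_hypoxia_angio({"H": 1.0, "V": 5.0, "A": 0, "T": 0}, b, 0.0)
        assert d["V"] == pytest.approx(0.0, abs=1e-12)

    def test_vessel_capacity_is_repelling_from_above(self, b):
        p = b.hypoxia_angio
        d = rhs_hypoxia_angio(
            {"H": 0, "V": 123.0, "A": p.Amax, "T": 0}, b, 0.0
        )
        assert d["A"] == pytest.approx(-p.dA * p.Amax)


class TestExtended:
    def _full(self, **overrides):
        values = {name: 0.0 for name in ExtendedParams().__dataclass_fields__}
        for k in ("KEkill", "KM1", "KH", "KAPC", "KIL2", "KAE", "KCX",
                  "KCpx", "KT"):
            values[k] = 1.0
        values.update(overrides)
        return ExtendedParams(**values)

    def test_missing_coefficient_is_named(self):
        with pytest.raises(ConfigurationError, match="khyp"):
            rhs_extended({"T": 1.0, "E": 1.0},
                         self._full(khyp=None))

    def test_reduces_to_logistic_ceiling(self):
        p = self._full(rT=0.05, KT=1e6)
        d = rhs_extended({"T": 1e6, "E": 0.0}, p)
        assert d["T"] == 0.0

    def test_pure_logistic_without_interactions(self):
        p = self._full(rT=0.05, KT=1e6)
        d = rhs_extended({"T": 1e5, "E": 0, "M1": 0, "M2": 0, "H": 0}, p)
        assert d["T"] == pytest.approx(4500.0)

    def test_exhaustion_saturates(self):
        p = self._full(kexh=0.3, dE2=0.0)
        d = rhs_extended({"T": 0, "E": 2.0}, p, inputs={"Cpx": 1e12})
        assert d["E"] == pytest.approx(-0.3 * 2.0, rel=1e-9)


# ---------------------------------------------------------------------------
# structural invariants shared by every block
# ---------------------------------------------------------------------------

_component = st.floats(min_value=0.0, max_value=1e7)


@given(data=st.data())
@settings(max_examples=150, deadline=None)
def test_quasi_positivity_of_every_block(data, ):
    """A component at zero can never be pushed negative (forward
    invariance of the non-negative orthant)."""
    b = load_parameters()
    block_name = data.draw(st.sampled_from(sorted(BLOCKS)))
    blk = BLOCKS[block_name]
    dose = data.draw(st.sampled_from([0.0, 10.0, 25.0, 50.0, 100.0]))
    state = {
        name: data.draw(_component, label=name)
        for name in set(blk.outputs) | set(blk.inputs) | {"T", "L"}
    }
    zeroed = data.draw(st.sampled_from(blk.outputs))
    state[zeroed] = 0.0
    derivs = blk.fn(state, b, dose)
    assert all(math.isfinite(v) for v in derivs.values())
    assert derivs[zeroed] >= 0.0


@pytest.mark.parametrize("block_name", sorted(BLOCKS))
def test_dose_zero_has_no_cape_terms(block_name, b):
    """At dose 0 every right-hand side equals its dose-free form exactly:
    raising all CAPE gains must not change the derivatives."""
    blk = BLOCKS[block_name]
    state = {name: 123.0 for name in
             set(blk.outputs) | set(blk.inputs) | {"T", "L"}}
    base = blk.fn(state, b, 0.0)
    bb = b.copy()
    for key in ("tumour_immune.phi", "tumour_immune.eta", "stroma.kF_cape",
                "ecm.kMMPprod", "ecm.kMMPdeg", "hypoxia_angio.kO2",
                "hypoxia_angio.kAlpha", "hypoxia_angio.kDelta",
                "hypoxia_angio.krT", "hypoxia_angio.kkill",
                "immunoreg.gM1", "immunoreg.gM2", "immunoreg.gR"):
        bb.set(key, min(1.0, bb.get(key) + 0.37) if "g" in key else 0.9)
    perturbed = blk.fn(state, bb, 0.0)
    for name in base:
        assert perturbed[name] == base[name]
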
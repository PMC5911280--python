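"""Ionization fractions and neutral-species availability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from solvadv import (
    Conditions,
    Protolyte,
    ionized_fraction_diprotic,
    ionized_fraction_monoprotic,
    neutral_availability,
)

pka = st.floats(min_value=-2.0, max_value=12.0)
ph = st.floats(min_value=0.0, max_value=14.0)


def dianion_fraction_mass_action(pka1, pka2, ph):
    """Independent oracle: numerically solve the coupled mass-action
    equations for [H2A], [HA-], [A2-] at fixed pH and return the A2-
    share of the total."""
    h = 10.0**-ph
    ka1, ka2 = 10.0**-pka1, 10.0**-pka2
    c_total = 1.0

    def residual(h2a):
        ha = ka1 * h2a / h
        a2 = ka2 * ha / h
        return h2a + ha + a2 - c_total

    h2a = brentq(residual, 0.0, c_total, xtol=1e-300, rtol=1e-15)
    ha = ka1 * h2a / h
    a2 = ka2 * ha / h
    return a2 / (h2a + ha + a2)


class TestMonoprotic:
    @pytest.mark.parametrize(
        "pka_, ph_, expected",
        [
            (4.18, 4.18, 0.5),  # half-ionized at pH == pKa
            (4.18, 6.5, 0.9952364986277893),
            (2.70, 6.5, 0.9998415357956377),
        ],
    )
    def test_known_values(self, pka_, ph_, expected):
        assert ionized_fraction_monoprotic(pka_, ph_) == pytest.approx(
            expected, rel=1e-12
        )

    def test_midpoint_is_exact(self):
        assert ionized_fraction_monoprotic(3.3, 3.3) == 0.5

    @pytest.mark.parametrize("bad", [math.nan, math.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            ionized_fraction_monoprotic(bad, 7.0)
        with pytest.raises(ValueError):
            ionized_fraction_monoprotic(4.0, bad)

    @settings(derandomize=True, max_examples=100)
    @given(pka_=pka, delta=st.floats(min_value=0.0, max_value=6.0))
    def test_reflection_symmetry_about_pka(self, pka_, delta):
        lo = ionized_fraction_monoprotic(pka_, pka_ - delta)
        hi = ionized_fraction_monoprotic(pka_, pka_ + delta)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)


class TestDiprotic:
    @pytest.mark.parametrize(
        "pka1, pka2, ph_, expected",
        [
            (4.20, 5.60, 6.5, 0.9943888331779343),
            (1.91, 6.33, 1.91, 3.801604897231427e-05),
        ],
    )
    def test_printed_formula_values(self, pka1, pka2, ph_, expected):
        assert ionized_fraction_diprotic(pka1, pka2, ph_) == pytest.approx(
            expected, rel=1e-12
        )

    def test_high_ph_limit(self):
        assert ionized_fraction_diprotic(3.0, 5.0, 14.0) == pytest.approx(1.0, abs=1e-8)

    def test_ordered_pka_required(self):
        with pytest.raises(ValueError):
            ionized_fraction_diprotic(5.0, 4.0, 7.0)
        with pytest.raises(ValueError):
            ionized_fraction_diprotic(5.0, 5.0, 7.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        pka1=st.floats(min_value=1.0, max_value=6.0),
        gap=st.floats(min_value=0.5, max_value=4.0),
        ph_=st.floats(min_value=1.0, max_value=13.0),
    )
    def test_textbook_mode_matches_mass_action_oracle(self, pka1, gap, ph_):
        """Textbook mode is exactly the dianion fraction of standard
        two-stage mass-action speciation."""
        pka2 = pka1 + gap
        ours = ionized_fraction_diprotic(pka1, pka2, ph_, mode="textbook")
        oracle = dianion_fraction_mass_action(pka1, pka2, ph_)
        assert ours == pytest.approx(oracle, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        pka1=st.floats(min_value=1.0, max_value=6.0),
        gap=st.floats(min_value=0.5, max_value=4.0),
        ph_=st.floats(min_value=1.0, max_value=13.0),
    )
    def test_printed_mode_bounded_below_by_dianion_fraction(self, pka1, gap, ph_):
        # pKa1 < pKa2 makes the printed denominator the smaller one,
        # so the printed alpha never falls below the true dianion share
        pka2 = pka1 + gap
        printed = ionized_fraction_diprotic(pka1, pka2, ph_, mode="printed")
        oracle = dianion_fraction_mass_action(pka1, pka2, ph_)
        assert printed >= oracle - 1e-12

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ionized_fraction_diprotic(3.0, 5.0, 7.0, mode="exact")


def test_monotonic_in_ph_on_random_grids():
    """Both ionized-fraction formulas are non-decreasing in pH
    (50 random parameter draws, 1000-point grids)."""
    rng = np.random.default_rng(7)
    grid = np.linspace(0.0, 14.0, 1000)
    for _ in range(50):
        pka1 = rng.uniform(0.0, 10.0)
        mono = np.array([ionized_fraction_monoprotic(pka1, p) for p in grid])
        assert np.all(np.diff(mono) >= 0)
        pka2 = pka1 + rng.uniform(0.3, 4.0)
        for mode in ("printed", "textbook"):
            di = np.array(
                [ionized_fraction_diprotic(pka1, pka2, p, mode=mode) for p in grid]
            )
            assert np.all(np.diff(di) >= 0)


class TestNeutralAvailability:
    def test_api_at_reference_conditions(self, body_conditions):
        melox = Protolyte(name="Meloxicam", proticity=1, pka1=4.18, c0=0.1)
        avail = neutral_availability(melox, body_conditions)
        assert avail.neutral_fraction == pytest.approx(4.76350137221071e-3, rel=1e-10)
        assert avail.alpha + avail.neutral_fraction == pytest.approx(1.0, abs=1e-15)
        assert avail.p_value == pytest.approx(3.3220737053401748, rel=1e-10)

    def test_midpoint_with_c0_two_gives_zero(self):
        sp = Protolyte(name="x", proticity=1, pka1=4.5, c0=2.0)
        avail = neutral_availability(sp, Conditions(ph=4.5))
        assert avail.p_value == pytest.approx(0.0, abs=1e-12)

    def test_saturation_clamps_c0(self, body_conditions):
        # nominal loading far above the aqueous solubility limit
        sp = Protolyte(
            name="1-Hydroxy-2-naphthoic acid",
            proticity=1,
            pka1=2.70,
            c0=0.5,
            solubility_limit=0.1,
        )
        avail = neutral_availability(sp, body_conditions)
        assert avail.effective_c0 == 0.1

    def test_limit_above_c0_does_not_clamp(self, body_conditions):
        sp = Protolyte(name="x", proticity=1, pka1=3.0, c0=0.5, solubility_limit=2.0)
        assert neutral_availability(sp, body_conditions).effective_c0 == 0.5

    @pytest.mark.parametrize("k", [2.0, 10.0, 0.25])
    def test_p_value_log_scaling_in_c0(self, k, body_conditions):
        base = Protolyte(name="x", proticity=1, pka1=3.5, c0=0.4)
        scaled = Protolyte(name="x", proticity=1, pka1=3.5, c0=0.4 * k)
        p0 = neutral_availability(base, body_conditions).p_value
        pk = neutral_availability(scaled, body_conditions).p_value
        assert pk == pytest.approx(p0 - math.log10(k), abs=1e-12)

    def test_fully_ionized_warns_and_returns_inf(self):
        sp = Protolyte(name="superacid", proticity=1, pka1=-300.0, c0=1.0)
        with pytest.warns(RuntimeWarning):
            avail = neutral_availability(sp, Conditions(ph=14.0))
        assert math.isinf(avail.p_value)

    def test_molar_mode_converts_by_molar_mass(self, body_conditions):
        sp = Protolyte(name="x", proticity=1, pka1=3.5, c0=0.5, molar_mass=138.12)
        mg = neutral_availability(sp, body_conditions)
        molar = neutral_availability(sp, body_conditions, concentration_unit="molar")
        assert molar.p_value == pytest.approx(
            mg.p_value + math.log10(138.12), abs=1e-12
        )

    def test_molar_mode_requires_molar_mass(self, body_conditions):
        sp = Protolyte(name="x", proticity=1, pka1=3.5, c0=0.5)
        with pytest.raises(ValueError):
            neutral_availability(sp, body_conditions, concentration_unit="molar")


class TestTypeInvariants:
    def test_diprotic_needs_ordered_pka2(self):
        with pytest.raises(ValueError):
            Protolyte(name="x", proticity=2, pka1=5.0, pka2=4.0, c0=0.5)
        with pytest.raises(ValueError):
            Protolyte(name="x", proticity=2, pka1=5.0, c0=0.5)
        with pytest.raises(ValueError):
            Protolyte(name="x", proticity=1, pka1=5.0, pka2=6.0, c0=0.5)

    def test_positive_concentrations(self):
        with pytest.raises(ValueError):
            Protolyte(name="x", proticity=1, pka1=5.0, c0=0.0)
        with pytest.raises(ValueError):
            Protolyte(name="x", proticity=1, pka1=5.0, c0=0.5, solubility_limit=-1.0)

    def test_conditions_ranges(self):
        with pytest.raises(ValueError):
            Conditions(ph=-0.5)
        with pytest.raises(ValueError):
            Conditions(ph=6.5, temperature=0.0)
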
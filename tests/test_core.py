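"""Rate laws, unit bridges, presets and scenario transformations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spatialflux as sf
from spatialflux.core import N_AVOGADRO, SCAFFOLD_PERMEABILITY, sphere_volume
from spatialflux.errors import InvalidParameterError, UnknownPresetError


class TestMichaelisMenten:
    @pytest.mark.parametrize(
        "S, V, K, expected",
        [
            (0.0, 123.4, 5.0, 0.0),
            (5.0, 10.0, 5.0, 5.0),            # half saturation
            (1.5e4, 2.0, 1.5e4, 1.0),         # PduP/Q K_M at half saturation
        ],
    )
    def test_examples(self, S, V, K, expected):
        assert sf.michaelis_menten_rate(S, V, K) == pytest.approx(expected, rel=1e-14)

    @given(
        S=st.floats(0, 1e9),
        V=st.floats(1e-6, 1e9),
        K=st.floats(1e-6, 1e9),
    )
    def test_bounded_below_vmax(self, S, V, K):
        rate = sf.michaelis_menten_rate(S, V, K)
        assert 0.0 <= rate < V

    @given(
        S=st.floats(1e-9, 1e8),
        V=st.floats(1e-6, 1e6),
        K=st.floats(1e-3, 1e6),
        factor=st.floats(1.0 + 1e-6, 10.0),
    )
    def test_strictly_increasing(self, S, V, K, factor):
        assert sf.michaelis_menten_rate(S * factor, V, K) > sf.michaelis_menten_rate(
            S, V, K
        )

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            sf.michaelis_menten_rate(-1.0, 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            sf.michaelis_menten_rate(1.0, 1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            sf.michaelis_menten_rate(1.0, -1.0, 1.0)

    def test_vectorized(self):
        S = np.array([0.0, 5.0, 50.0])
        out = sf.michaelis_menten_rate(S, 10.0, 5.0)
        assert out == pytest.approx([0.0, 5.0, 10.0 * 50 / 55])


class TestReversibleInterconversion:
    def test_irreversible_limit_is_exact(self):
        for s1 in (0.0, 3.7, 1e4):
            assert sf.reversible_interconversion_rate(
                s1, 99.0, (7.0, 11.0), (0.0, 1.0)
            ) == sf.michaelis_menten_rate(s1, 7.0, 11.0)

    def test_pure_back_reaction_is_negative(self):
        assert sf.reversible_interconversion_rate(0.0, 5.0, (7.0, 11.0), (3.0, 2.0)) < 0

    def test_detailed_balance_point(self):
        # forward term at half saturation = reverse term at half saturation
        net = sf.reversible_interconversion_rate(11.0, 2.0, (7.0, 11.0), (7.0, 2.0))
        assert net == pytest.approx(0.0, abs=1e-14)

    def test_zero_when_s2_zero_equals_mm(self):
        assert sf.reversible_interconversion_rate(
            4.0, 0.0, (7.0, 11.0), (3.0, 2.0)
        ) == sf.michaelis_menten_rate(4.0, 7.0, 11.0)


class TestVmaxFromCopies:
    def test_hand_arithmetic(self):
        # k_cat=300/s, 1500 copies in a 1e-5 cm sphere
        vol = sphere_volume(1e-5)
        expected = 300.0 * 1500.0 / (N_AVOGADRO * vol) * 1e9  # uM/s
        got = sf.vmax_from_copies(300.0, 1500.0, vol)
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(1.78e5, rel=5e-3)

    def test_zero_copies(self):
        assert sf.vmax_from_copies(300.0, 0.0, 1.0) == 0.0

    @given(
        k=st.floats(1e-3, 1e4),
        n=st.floats(1.0, 1e7),
        v=st.floats(1e-16, 1e-11),
        f=st.floats(0.1, 10.0),
    )
    def test_linearity_machine_precision(self, k, n, v, f):
        base = sf.vmax_from_copies(k, n, v)
        assert sf.vmax_from_copies(k * f, n, v) == pytest.approx(base * f, rel=1e-12)
        assert sf.vmax_from_copies(k, n * f, v) == pytest.approx(base * f, rel=1e-12)
        assert sf.vmax_from_copies(k, n, v * f) == pytest.approx(base / f, rel=1e-12)

    def test_bad_volume(self):
        with pytest.raises(InvalidParameterError):
            sf.vmax_from_copies(1.0, 1.0, 0.0)


class TestPresets:
    @pytest.mark.parametrize(
        "name, getter, expected",
        [
            ("pdu", lambda s: s.enzyme2.K_M, 1.5e4),
            ("pdu", lambda s: s.enzyme1.k_cat, 3.0e2),
            ("pdu", lambda s: s.enzyme1.copies, 1.5e3),
            ("pdu", lambda s: s.enzyme1.K_M, 5.0e2),
            ("pdu", lambda s: s.enzyme2.k_cat, 55.0),
            ("pdu", lambda s: s.enzyme2.copies, 2.5e3),
            ("pdu", lambda s: s.transport.k_c_S1, 1.0e-5),
            ("pdu", lambda s: s.transport.k_m_S1, 1.0e-2),
            ("pdu", lambda s: s.transport.D, 1.0e-5),
            ("pdu", lambda s: s.geometry.R_b, 5.0e-5),
            ("pdu", lambda s: s.geometry.R_c, 1.0e-5),
            ("pdu", lambda s: s.conditions.S1_out, 5.5e4),
            ("pdu", lambda s: s.conditions.S2_out, 0.0),
            ("mevalonate", lambda s: s.enzyme1.k_cat, 1.83),
            ("mevalonate", lambda s: s.enzyme1.K_M, 5.0),
            ("mevalonate", lambda s: s.enzyme1.copies, 5.0e5),
            ("mevalonate", lambda s: s.enzyme2.k_cat, 0.023),
            ("mevalonate", lambda s: s.enzyme2.K_M, 1.0e2),
            ("mevalonate", lambda s: s.enzyme2.copies, 5.0e5),
            ("mevalonate", lambda s: s.transport.k_m_S1, 1.0e-4),
            ("mevalonate", lambda s: s.transport.k_m_S2, 1.0e-4),
            ("mevalonate", lambda s: s.transport.k_c_S1, 1.0e-5),
        ],
    )
    def test_table_values(self, name, getter, expected):
        assert getter(sf.preset(name)) == expected

    def test_unknown_name(self):
        with pytest.raises(UnknownPresetError):
            sf.preset("nope")

    def test_capacity_arithmetic(self, pdu):
        # 55/s * 2500 copies / N_A in umol/cell/s
        assert pdu.enzyme2.capacity == pytest.approx(2.2833e-13, rel=1e-3, abs=0.0)

    def test_scaffold_pins_boundary_permeability(self, pdu):
        assert pdu.with_strategy("scaffold").kc_S1 == SCAFFOLD_PERMEABILITY
        assert pdu.with_strategy("organelle").kc_S1 == pdu.transport.k_c_S1

    def test_reaction_volume_follows_strategy(self, pdu):
        assert pdu.with_strategy("none").reaction_volume == pdu.cell_volume
        assert pdu.with_strategy("organelle").reaction_volume == pdu.compartment_volume


class TestDomainTypeValidation:
    def test_geometry_ordering(self):
        with pytest.raises(InvalidParameterError):
            sf.Geometry(R_b=1e-5, R_c=1e-5)

    def test_enzyme_invariants(self):
        with pytest.raises(InvalidParameterError):
            sf.EnzymeKinetics(k_cat=-1.0, K_M=1.0, copies=1.0)
        with pytest.raises(InvalidParameterError):
            sf.EnzymeKinetics(k_cat=1.0, K_M=0.0, copies=1.0)

    def test_transport_positive(self):
        with pytest.raises(InvalidParameterError):
            sf.TransportParams(D=0.0, k_m_S1=1.0, k_m_S2=1.0, k_c_S1=1.0, k_c_S2=1.0)

    def test_external_nonnegative(self):
        with pytest.raises(InvalidParameterError):
            sf.ExternalConditions(S1_out=-1.0)

    def test_reversible_requires_reverse_kinetics(self, pdu):
        from dataclasses import replace

        with pytest.raises(InvalidParameterError):
            replace(pdu, rate_law="reversible_mm")


class TestApplyFoldChange:
    def test_identity(self, pdu):
        out = sf.apply_fold_change(pdu, "k_cat_both", 1.0)
        assert out == pdu

    def test_km_improvement_divides(self, pdu):
        out = sf.apply_fold_change(pdu, "K_M_both", 100.0)
        assert out.enzyme1.K_M == pdu.enzyme1.K_M / 100.0
        assert out.enzyme2.K_M == pdu.enzyme2.K_M / 100.0
        # original untouched
        assert pdu.enzyme1.K_M == 5.0e2

    def test_kcat_improvement_multiplies(self, pdu):
        out = sf.apply_fold_change(pdu, "k_cat_both", 100.0)
        assert out.enzyme1.k_cat == pdu.enzyme1.k_cat * 100.0
        assert out.enzyme2.k_cat == pdu.enzyme2.k_cat * 100.0

    @given(f=st.floats(1e-3, 1e3))
    @pytest.mark.parametrize("target", ["k_cat_both", "K_M_both", "k_cat_E0_enzyme2"])
    def test_inverse_roundtrip(self, pdu, target, f):
        back = sf.apply_fold_change(sf.apply_fold_change(pdu, target, f), target, 1.0 / f)
        for enz_name in ("enzyme1", "enzyme2"):
            a, b = getattr(back, enz_name), getattr(pdu, enz_name)
            assert a.k_cat == pytest.approx(b.k_cat, rel=1e-12)
            assert a.K_M == pytest.approx(b.K_M, rel=1e-12)

    def test_unknown_target(self, pdu):
        with pytest.raises(InvalidParameterError):
            sf.apply_fold_change(pdu, "k_off", 2.0)
        with pytest.raises(InvalidParameterError):
            sf.apply_fold_change(pdu, "k_cat_both", 0.0)
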
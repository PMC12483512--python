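"""Configuration-sum equilibrium binding engine."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from idrsearch.equilibrium import (
    EnergyModel,
    BindingConfiguration,
    approximate_q,
    binding_probability,
    configuration_weight,
    count_configurations,
    enhancement_factor,
    enumerate_configurations,
    threshold_energy,
)
from idrsearch.layouts import make_layout
from idrsearch.units import TFArchitecture, gaussian_propagator

D = math.sqrt(50.0)
V_NUC = (1e3 / 0.34) ** 3


def _setup(n_b, n_t, l0=D, d=D, **energy_kw):
    kw = dict(E_B=10.0, E_DBD=15.0, V1=1.0, V=V_NUC)
    kw.update(energy_kw)
    return (
        TFArchitecture(n_b=n_b, l0=l0),
        make_layout("equal", n_t=n_t, d=d, side="one_sided"),
        EnergyModel(**kw),
    )


class TestThresholdEnergy:
    def test_reference_value(self):
        # phi^2 = 0.02 gives about 8.5 kBT
        assert threshold_energy(math.sqrt(0.02)) == pytest.approx(8.4769, abs=1e-3)
        assert round(threshold_energy(math.sqrt(0.02)), 1) == 8.5

    def test_phi_one(self):
        assert threshold_energy(1.0) == pytest.approx(
            1.5 * (math.log(2 * math.pi / 3) + 1), rel=1e-12
        )

    @given(phi=st.floats(0.01, 1.0))
    def test_breakeven_consistency(self, phi):
        # the enhancement factor at E_th with l0 = d equals one by definition
        d = 7.0
        v1 = (phi * d) ** 3
        assert enhancement_factor(threshold_energy(phi), d, d, v1) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_decreasing_in_phi(self):
        phis = np.linspace(0.05, 1.0, 40)
        es = [threshold_energy(p) for p in phis]
        assert np.all(np.diff(es) < 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            threshold_energy(0.0)


class TestEnhancementFactor:
    def test_typical_value(self):
        # e^10 * V1 * f(d, d) with d = sqrt(50) bp
        assert enhancement_factor(10.0, D, D, 1.0) == pytest.approx(4.586, rel=1e-3)

    def test_vanishes_at_large_distance(self):
        assert enhancement_factor(10.0, 1e3, D, 1.0) < 1e-300 or (
            enhancement_factor(10.0, 1e3, D, 1.0) < 1e-10
        )

    @given(e_b=st.floats(0, 25), ratio=st.floats(0.1, 5.0))
    def test_strictly_positive(self, e_b, ratio):
        assert enhancement_factor(e_b, D, ratio * D, 1.0) > 0


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_b,n_t,expected",
        [(1, 1, 4), (2, 2, 14), (0, 5, 2), (0, 0, 2), (3, 1, 8), (1, 3, 8)],
    )
    def test_configuration_counts(self, n_b, n_t, expected):
        assert count_configurations(n_b, n_t) == expected
        arch, lay, _ = _setup(n_b, n_t)
        assert sum(1 for _ in enumerate_configurations(arch, lay)) == expected

    def test_count_formula_matches_generator(self):
        for n_b in range(0, 4):
            for n_t in range(0, 4):
                arch, lay, _ = _setup(n_b, n_t)
                n_gen = sum(1 for _ in enumerate_configurations(arch, lay))
                assert n_gen == count_configurations(n_b, n_t)

    def test_cap_error(self):
        arch, lay, _ = _setup(8, 8)
        with pytest.raises(ValueError, match="cap"):
            list(enumerate_configurations(arch, lay, cap=100))

    def test_injectivity_enforced(self):
        with pytest.raises(ValueError):
            BindingConfiguration(matching={1: 1, 2: 1})
        with pytest.raises(ValueError):
            BindingConfiguration(matching={1: 0})  # IDR site on DBD target
        with pytest.raises(ValueError):
            BindingConfiguration(matching={0: 2})  # DBD site on IDR target


class TestWeights:
    def test_free_state_weight_is_volume(self):
        arch, lay, en = _setup(1, 1)
        cfg = BindingConfiguration(matching={})
        assert configuration_weight(cfg, arch, lay, en) == en.V

    def test_dbd_only_boltzmann_factor(self):
        arch, lay, en = _setup(1, 1)
        cfg = BindingConfiguration(matching={0: 0})
        assert configuration_weight(cfg, arch, lay, en) == pytest.approx(
            math.exp(15.0), rel=1e-12
        )

    def test_doubly_bound_weight(self):
        arch, lay, en = _setup(1, 1)
        cfg = BindingConfiguration(matching={0: 0, 1: 1})
        expected = math.exp(25.0) * gaussian_propagator(D, 1, D)
        assert configuration_weight(cfg, arch, lay, en) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("n_b,n_t", [(1, 2), (2, 1), (2, 2), (3, 2), (2, 3), (3, 3)])
    def test_vectorised_matches_explicit_enumeration(self, n_b, n_t):
        arch, lay, en = _setup(n_b, n_t, E_B=8.0, E_DBD=12.0)
        res = binding_probability(arch, lay, en)
        z = sum(
            configuration_weight(c, arch, lay, en)
            for c in enumerate_configurations(arch, lay)
        )
        p_tf = (
            sum(
                configuration_weight(c, arch, lay, en)
                for c in enumerate_configurations(arch, lay)
                if c.dbd_bound
            )
            / z
        )
        assert res.P_TF == pytest.approx(p_tf, rel=1e-10)


class TestBindingProbability:
    def test_single_site_reduces_to_one_plus_enhancement(self):
        # V-dominated regime: Q -> 1 + P
        arch, lay, en = _setup(1, 1, V=1e15)
        res = binding_probability(arch, lay, en)
        assert res.Q == pytest.approx(1.0 + enhancement_factor(10.0, D, D, 1.0),
                                      rel=1e-6)

    def test_typical_nucleus_value(self, fig2_energy):
        arch, lay, _ = _setup(1, 1)
        res = binding_probability(arch, lay, fig2_energy)
        assert res.Q == pytest.approx(5.586, rel=1e-3)

    def test_weak_binding_limit(self):
        arch, lay, en = _setup(1, 1, E_B=1e-9)
        res = binding_probability(arch, lay, en)
        assert res.Q == pytest.approx(1.0, abs=1e-3)

    @given(
        n_b=st.integers(0, 3),
        n_t=st.integers(0, 3),
        e_b=st.floats(0.0, 30.0),
        e_dbd=st.floats(0.0, 30.0),
        ratio=st.floats(0.2, 3.0),
    )
    def test_probability_closure(self, n_b, n_t, e_b, e_dbd, ratio):
        arch, lay, en = _setup(n_b, n_t, l0=ratio * D, E_B=e_b, E_DBD=e_dbd)
        res = binding_probability(arch, lay, en)
        assert res.P_free + res.P_IDR_only + res.P_TF == pytest.approx(1.0, abs=1e-12)
        for p in (res.P_free, res.P_IDR_only, res.P_TF):
            assert 0.0 <= p <= 1.0

    def test_idr_always_helps(self):
        # P > 0 means P_TF >= P_simple for the single-site TF
        arch, lay, en = _setup(1, 1)
        res = binding_probability(arch, lay, en)
        assert res.Q > 1.0

    def test_deep_wells_no_overflow(self):
        arch, lay, en = _setup(4, 4, E_B=300.0, E_DBD=300.0)
        res = binding_probability(arch, lay, en)
        assert math.isfinite(res.log_Z)
        assert res.P_TF <= 1.0

    def test_summary_mentions_key_quantities(self, fig2_energy):
        arch, lay, _ = _setup(2, 2)
        res = binding_probability(arch, lay, fig2_energy)
        text = res.summary()
        assert "P_TF" in text and "Q" in text

    def test_config_table_weights_sum_to_z(self, fig2_energy):
        arch, lay, _ = _setup(2, 2)
        res = binding_probability(arch, lay, fig2_energy)
        table = res.config_table()
        assert len(table) == count_configurations(2, 2)
        assert np.log(table["weight"].sum()) == pytest.approx(res.log_Z, rel=1e-10)


class TestApproximateQ:
    def test_exact_for_single_site(self):
        arch, lay, en = _setup(1, 1)
        q = approximate_q(arch, lay, en)
        assert q == pytest.approx(1.0 + enhancement_factor(10.0, D, D, 1.0), rel=1e-12)

    def test_lower_bound_one(self):
        arch, lay, en = _setup(3, 3, E_B=1e-6)
        assert approximate_q(arch, lay, en) >= 1.0

    @pytest.mark.parametrize("n", [2, 4])
    def test_agrees_with_full_sum_below_threshold(self, n):
        # in the weak-occupancy regime (E_B below E_th, Q << 1/P_simple) the
        # low-occupancy expansion tracks the full configuration sum
        for e_b in (2.0, 4.0, 6.0, 8.0):
            arch, lay, en = _setup(n, n, E_B=e_b)
            full = binding_probability(arch, lay, en).Q
            approx = approximate_q(arch, lay, en)
            assert abs(approx - full) / full < 0.10


class TestEnergyModelValidation:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            EnergyModel(E_B=-1.0, E_DBD=5.0)
        with pytest.raises(ValueError):
            EnergyModel(E_B=1.0, E_DBD=5.0, V1=0.0)
        with pytest.raises(ValueError):
            EnergyModel(E_B=1.0, E_DBD=5.0, V1=10.0, V=5.0)
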
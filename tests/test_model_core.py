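import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hairfield import (
    ArrayConfig,
    DimensionalParams,
    HairSpec,
    InvalidParameterError,
    allometric_morphology,
    compute_K,
    hair_charge_upper_bound,
    hair_spacing_from_density,
    make_row_array,
    nondimensionalize,
    redimensionalize,
    threshold_degrees,
)


class TestComputeK:
    def test_millimetre_hair_with_upper_charge_bound(self):
        # q = 1e-11 C on a 1 mm hair with the spider allometric spring
        # constant gives K just under 100
        S = allometric_morphology(1e-3, "spider_MeD1", "spring")
        K = compute_K(DimensionalParams(1e-3, S, 1e-11))
        assert K == pytest.approx(86.9, rel=1e-3)

    def test_zero_charge(self):
        assert compute_K(DimensionalParams(1e-3, 1e-11, 0.0)) == 0.0

    def test_functional_form(self):
        base = DimensionalParams(1e-3, 1e-11, 1e-12)
        K0 = compute_K(base)
        assert compute_K(DimensionalParams(1e-3, 1e-11, 2e-12)) == pytest.approx(4 * K0)
        assert compute_K(DimensionalParams(2e-3, 1e-11, 1e-12)) == pytest.approx(K0 / 2)
        assert compute_K(DimensionalParams(1e-3, 2e-11, 1e-12)) == pytest.approx(K0 / 2)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_quadratic_homogeneity_in_charge(self, c):
        K1 = compute_K(DimensionalParams(1e-3, 1e-11, 1e-12))
        Kc = compute_K(DimensionalParams(1e-3, 1e-11, c * 1e-12))
        assert Kc == pytest.approx(c**2 * K1, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            DimensionalParams(-1e-3, 1e-11, 1e-12)
        with pytest.raises(InvalidParameterError):
            DimensionalParams(1e-3, 0.0, 1e-12)


class TestAllometry:
    @pytest.mark.parametrize(
        "species,quantity,expected,rel",
        [
            ("spider_MeD1", "spring", 1.03e-11, 1e-2),
            ("cricket_cercal", "spring", 1.90e-11, 1e-2),
            ("spider_MeD1", "diameter", 7.65e-6, 1e-2),
            ("cricket_cercal", "diameter", 8.15e-6, 1e-2),
        ],
    )
    def test_millimetre_values(self, species, quantity, expected, rel):
        assert allometric_morphology(1e-3, species, quantity) == pytest.approx(
            expected, rel=rel)

    def test_orders_of_magnitude(self):
        # both spring laws give O(1e-11) at 1 mm, both diameters O(1e-6)
        for sp in ("spider_MeD1", "cricket_cercal"):
            assert 1e-11 <= allometric_morphology(1e-3, sp, "spring") < 1e-10
            assert 1e-6 <= allometric_morphology(1e-3, sp, "diameter") < 1e-5

    def test_strictly_increasing_in_length(self):
        Ls = np.geomspace(1e-4, 1e-2, 20)
        for sp in ("spider_MeD1", "cricket_cercal"):
            vals = [allometric_morphology(L, sp, "spring") for L in Ls]
            assert np.all(np.diff(vals) > 0)

    def test_unknown_enumeration(self):
        with pytest.raises(InvalidParameterError):
            allometric_morphology(1e-3, "beetle", "spring")
        with pytest.raises(InvalidParameterError):
            allometric_morphology(1e-3, "spider_MeD1", "mass")


class TestChargeBound:
    def test_typical_hair(self):
        d = allometric_morphology(1e-3, "spider_MeD1", "diameter")
        assert hair_charge_upper_bound(d, 1e-3) == pytest.approx(2.40e-12, rel=1e-2)

    def test_zero_surface_density(self):
        assert hair_charge_upper_bound(1e-6, 1e-3, 0.0) == 0.0

    def test_linearity(self):
        q = hair_charge_upper_bound(1e-6, 1e-3, 1e-4)
        assert hair_charge_upper_bound(2e-6, 1e-3, 1e-4) == pytest.approx(2 * q)
        assert hair_charge_upper_bound(1e-6, 3e-3, 1e-4) == pytest.approx(3 * q)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            hair_charge_upper_bound(-1e-6, 1e-3)


def test_spacing_from_density():
    # 1000 hairs per square mm, 1 mm hairs: spacing ~0.03 hair lengths
    assert round(hair_spacing_from_density(1000.0), 2) == 0.03


def test_threshold_degrees():
    assert float(f"{threshold_degrees(1e-3):.2g}") == 0.057


class TestNondimensionalize:
    @staticmethod
    def _dim_hairs(rng, n):
        return [
            {
                "base_x": float(rng.uniform(-5e-3, 5e-3)),
                "base_y": float(rng.uniform(-5e-3, 5e-3)),
                "length": float(rng.uniform(0.5e-3, 2e-3)),
                "charge": float(rng.uniform(0.1e-12, 5e-12)),
                "spring": float(rng.uniform(0.5e-11, 2e-11)),
                "resting_angle": float(rng.uniform(-0.3, 0.3)),
            }
            for _ in range(n)
        ]

    def test_identity_scales(self):
        hairs = [{"base_x": 0.0, "base_y": 0.0, "length": 2.0,
                  "charge": 1.0, "spring": 1.0}]
        cfg = nondimensionalize(hairs, L=1.0, S=1.0, q=1.0)
        assert cfg.hairs[0].length == 2.0
        assert cfg.hairs[0].charge == 1.0

    def test_length_scaling(self):
        hairs = [{"base_x": 0.0, "base_y": 0.0, "length": 2e-3,
                  "charge": 1e-12, "spring": 1e-11}]
        cfg = nondimensionalize(hairs, L=1e-3, S=1e-11, q=1e-12)
        assert cfg.hairs[0].length == pytest.approx(2.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        hairs = self._dim_hairs(rng, 3)
        L, S, q = 1e-3, 1e-11, 1e-12
        back = redimensionalize(nondimensionalize(hairs, L, S, q), L, S, q)
        for orig, rec in zip(hairs, back):
            for key in orig:
                assert rec[key] == pytest.approx(orig[key], rel=1e-12, abs=1e-300)

    def test_zero_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            nondimensionalize([], L=0.0, S=1.0, q=1.0)


class TestMakeRowArray:
    def test_two_hairs(self):
        cfg = make_row_array(2, delta=10.0)
        assert [h.base_x for h in cfg.hairs] == [0.0, 10.0]
        assert all(h.base_y == 0.0 for h in cfg.hairs)

    def test_single_hair(self):
        cfg = make_row_array(1)
        assert cfg.n_hairs == 1
        assert (cfg.hairs[0].base_x, cfg.hairs[0].base_y) == (0.0, 0.0)

    def test_three_hair_spacing(self):
        cfg = make_row_array(3, delta=1.0)
        xs = [h.base_x for h in cfg.hairs]
        assert xs == [0.0, 1.0, 2.0]

    def test_invalid_spacing(self):
        with pytest.raises(InvalidParameterError):
            make_row_array(2, delta=0.0)

    def test_per_hair_lists(self):
        cfg = make_row_array(2, delta=1.0, lengths=[1.6, 0.4])
        assert [h.length for h in cfg.hairs] == [1.6, 0.4]


class TestConfigValidation:
    def test_threshold_range(self):
        hair = (HairSpec(0.0, 0.0),)
        with pytest.raises(InvalidParameterError):
            ArrayConfig(hairs=hair, threshold=0.0)
        with pytest.raises(InvalidParameterError):
            ArrayConfig(hairs=hair, threshold=0.2)

    def test_negative_K(self):
        with pytest.raises(InvalidParameterError):
            ArrayConfig(hairs=(HairSpec(0.0, 0.0),), K=-1.0)

    def test_coincident_bases(self):
        with pytest.raises(InvalidParameterError):
            ArrayConfig(hairs=(HairSpec(0.0, 0.0), HairSpec(0.0, 0.0)))
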
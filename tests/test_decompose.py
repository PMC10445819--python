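"""Unit standardisation, per-package masses, combination splitting, ATC↔API map."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmpec.decompose import (
    CONVERTED,
    MISSING,
    NON_MASS,
    UnknownUnitError,
    build_atc_api_map,
    grams_per_package,
    load_default_units,
    split_combination,
    standardise_concentration,
)
from pharmpec.ingest import ProductAPIRecord, ProductRecord


@pytest.fixture(scope="module")
def units():
    return load_default_units()


class TestStandardiseConcentration:
    @pytest.mark.parametrize(
        "value, unit, kind, expected",
        [
            (500, "mg/pill", "per_item", 0.5),
            (500, "mg", "per_item", 0.5),
            (50, "mg/mL", "per_volume", 50.0),
            (2, "g/L", "per_volume", 2.0),
            (20, "mg/g", "per_mass", 0.02),
            (5, "µg", "per_item", 5e-6),
            (5, "mcg", "per_item", 5e-6),
            (5, "ug", "per_item", 5e-6),
        ],
    )
    def test_metric_conversions(self, units, value, unit, kind, expected):
        k, v = standardise_concentration(value, unit, units)
        assert k == kind
        assert v == pytest.approx(expected, rel=1e-12)

    def test_international_units_are_non_mass(self, units):
        assert standardise_concentration(100, "IU/mL", units) == (NON_MASS, None)
        assert standardise_concentration(40, "IE", units) == (NON_MASS, None)

    def test_percent_depends_on_medium(self, units):
        k, v = standardise_concentration(2, "%", units, medium="fluid")
        assert (k, v) == ("per_volume", 20.0)  # 2% w/v = 20 g/L
        k, v = standardise_concentration(2, "%", units, medium="cream")
        assert (k, v) == ("per_mass", 0.02)  # 2% w/w = 0.02 g/g
        with pytest.raises(UnknownUnitError):
            standardise_concentration(2, "%", units, medium=None)

    def test_unknown_symbol_lists_it(self, units):
        with pytest.raises(UnknownUnitError, match="fortnight"):
            standardise_concentration(1, "stone/fortnight", units)

    @given(st.floats(min_value=1e-9, max_value=1e9))
    @settings(derandomize=True)
    def test_mass_unit_roundtrip(self, units, x):
        # x mg -> grams -> back to mg returns x to 1e-12 relative
        _, grams = standardise_concentration(x, "mg", units)
        assert grams / units.mass_units["mg"] == pytest.approx(x, rel=1e-12)


class TestGramsPerPackage:
    @pytest.mark.parametrize(
        "kind, conc, qty, unit, expected",
        [
            ("per_item", 0.5, 20, "pills", 10.0),
            ("per_volume", 50.0, 100, "ml", 5.0),
            ("per_mass", 0.02, 30, "g", 0.6),
        ],
    )
    def test_arithmetic(self, units, kind, conc, qty, unit, expected):
        pa = grams_per_package(kind, conc, qty, unit, units)
        assert pa.status == CONVERTED
        assert pa.grams_per_package == pytest.approx(expected, rel=1e-12)

    def test_dimensional_mismatch_is_missing_not_fatal(self, units):
        pa = grams_per_package("per_volume", 50.0, 20, "pills", units)
        assert pa.status == MISSING and "non-volume" in pa.reason

    def test_non_mass_propagates(self, units):
        pa = grams_per_package(NON_MASS, None, 20, "pills", units)
        assert pa.status == NON_MASS


class TestSplitCombination:
    def _product(self, **kw):
        defaults = dict(
            product_code=7, product_name="Duo", atc_code="N02BE51",
            product_type="pill", package_quantity_value=10.0,
            package_quantity_unit="pills", n_api_per_product=2,
        )
        defaults.update(kw)
        return ProductRecord(**defaults)

    def test_combination_yields_one_amount_per_api(self, units):
        strengths = [
            ProductAPIRecord(7, "paracetamol", 500, "mg"),
            ProductAPIRecord(7, "ibuprofen", 200, "mg"),
        ]
        out = split_combination(self._product(), strengths, units)
        assert [a.api_name for a in out] == ["paracetamol", "ibuprofen"]
        assert [a.grams_per_package for a in out] == pytest.approx([5.0, 2.0])

    def test_mass_additivity(self, units):
        strengths = [
            ProductAPIRecord(7, "a", 500, "mg"),
            ProductAPIRecord(7, "b", 200, "mg"),
        ]
        out = split_combination(self._product(), strengths, units)
        total = sum(a.grams_per_package for a in out)
        assert total == pytest.approx(0.7 * 10, rel=1e-12)

    def test_no_strength_rows_flagged_for_manual_sourcing(self, units):
        out = split_combination(self._product(), [], units)
        assert len(out) == 1 and out[0].status == MISSING
        assert "manual" in out[0].reason

    def test_direct_amount_wins_over_strength(self, units):
        s = ProductAPIRecord(
            7, "a", 500, "mg",
            amount_per_package_value=3.0, amount_per_package_unit="g",
        )
        out = split_combination(self._product(n_api_per_product=1), [s], units)
        assert out[0].grams_per_package == pytest.approx(3.0)

    def test_salt_mass_attributed_in_full(self, units):
        # no free-base correction: the stated strength mass is the API mass
        s = ProductAPIRecord(7, "diclofenac sodium", 50, "mg")
        out = split_combination(self._product(n_api_per_product=1), [s], units)
        assert out[0].grams_per_package == 50e-3 * 10


class TestAtcApiMap:
    def test_many_to_many_and_inverse(self):
        products = [
            ProductRecord(1, "A", "N02BE01"),
            ProductRecord(2, "B", "N02BE51", n_api_per_product=2),
            ProductRecord(3, "C", "N02BE71", n_api_per_product=2),
        ]
        apis = [
            ProductAPIRecord(1, "paracetamol", 500, "mg"),
            ProductAPIRecord(2, "paracetamol", 500, "mg"),
            ProductAPIRecord(2, "ibuprofen", 200, "mg"),
            ProductAPIRecord(3, "paracetamol", 500, "mg"),
            ProductAPIRecord(3, "caffeine", 50, "mg"),
        ]
        m = build_atc_api_map(apis, products)
        assert m.api_to_atcs["paracetamol"] == {"N02BE01", "N02BE51", "N02BE71"}
        assert m.atc_to_apis["N02BE51"] == {"paracetamol", "ibuprofen"}
        assert m.check_inverse()

    def test_reconstructed_map_matches_generator_tables(self, small_db):
        _, products, product_apis, _, _ = small_db
        m = build_atc_api_map(product_apis, products)
        atc_by_code = {p.product_code: p.atc_code for p in products}
        expected = {(atc_by_code[pa.product_code], pa.api_name) for pa in product_apis}
        observed = {(a, api) for a, apis in m.atc_to_apis.items() for api in apis}
        assert observed == expected
        assert m.check_inverse()
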
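"""Model reading, medium edits, denominator clearing and pool reports."""

from __future__ import annotations

from decimal import Decimal
from fractions import Fraction

import pytest

from moietypools.mc_search import IntegerPool, PoolBasis
from moietypools.model_io import (
    ConfigurationError,
    FormatError,
    MediumSpec,
    apply_medium,
    clear_denominators,
    format_pool,
    read_model,
    read_pools,
    write_pools,
)

from conftest import enumerate_solutions, make_model


TRIPLETS = """\
# two-metabolite conversion
A r1 -1
B r1 1
"""


def test_triplet_reader_single_reaction(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text(TRIPLETS)
    model = read_model(str(p), "triplets")
    assert model.metabolite_ids == ["A", "B"]
    assert model.reaction_ids == ["r1"]
    assert model.coeff[("A", "r1")] == Fraction(-1)
    assert model.coeff[("B", "r1")] == Fraction(1)


def test_decimal_coefficients_parsed_exactly(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("A r1 -0.02\nB r1 1\n")
    model = read_model(str(p), "triplets")
    # oracle: decimal-string parsing must agree with the Decimal module, not
    # with the binary float (Fraction(-0.02) != -1/50)
    assert model.coeff[("A", "r1")] == Fraction(Decimal("-0.02")) == Fraction(-1, 50)
    assert model.coeff[("A", "r1")] != Fraction(-0.02)


def test_unknown_format_and_parse_errors(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("A r1\n")
    with pytest.raises(FormatError, match="m.tsv:1"):
        read_model(str(p), "triplets")
    with pytest.raises(ValueError, match="unknown format"):
        read_model(str(p), "nope")


def test_bigg_json_reader_exact_and_exchange_detection(tmp_path):
    doc = """{
      "metabolites": [{"id": "glc"}, {"id": "g6p"}],
      "reactions": [
        {"id": "HEX", "metabolites": {"glc": -1, "g6p": 1}},
        {"id": "EX_glc", "metabolites": {"glc": 0.02}},
        {"id": "BIOMASS_core", "metabolites": {"g6p": -1}}
      ]
    }"""
    p = tmp_path / "m.json"
    p.write_text(doc)
    model = read_model(str(p), "bigg_json")
    assert model.coeff[("glc", "EX_glc")] == Fraction(1, 50)
    assert model.exchange_ids == {"EX_glc", "BIOMASS_core"}
    assert model.biomass_id == "BIOMASS_core"


SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="toy">
  <listOfSpecies>
   <species id="A" compartment="c"/>
   <species id="B" compartment="c"/>
   <species id="X" compartment="e" boundaryCondition="true"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="conv">
    <listOfReactants><speciesReference species="A" stoichiometry="0.5"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
   </reaction>
   <reaction id="EX_A">
    <listOfReactants><speciesReference species="X"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


def test_sbml_reader_boundary_species_and_exact_stoichiometry(tmp_path):
    p = tmp_path / "m.xml"
    p.write_text(SBML)
    model = read_model(str(p), "sbml")
    assert model.metabolite_ids == ["A", "B"]  # boundary species dropped
    assert model.coeff[("A", "conv")] == Fraction(-1, 2)
    assert model.exchange_ids == {"EX_A"}


def test_sbml_malformed(tmp_path):
    p = tmp_path / "bad.xml"
    p.write_text("<notsbml/>")
    with pytest.raises(FormatError):
        read_model(str(p), "sbml")


class TestApplyMedium:
    def _model(self):
        return make_model({
            ("A", "EX_A"): 1, ("B", "EX_B"): -1,
            ("A", "conv"): -1, ("B", "conv"): 1,
        })

    def test_rich_keeps_all_exchanges(self):
        m = self._model()
        out = apply_medium(m, MediumSpec("rich"))
        assert out.reaction_ids == m.reaction_ids

    def test_custom_empty_closes_the_network(self):
        out = apply_medium(self._model(), MediumSpec("custom", []))
        assert out.reaction_ids == ["conv"]
        assert out.metabolite_ids == ["A", "B"]  # rows never deleted

    def test_minimal_keeps_named_subset_and_is_idempotent(self):
        spec = MediumSpec("minimal", ["EX_A"])
        once = apply_medium(self._model(), spec)
        twice = apply_medium(once, spec)
        assert once.reaction_ids == twice.reaction_ids == ["EX_A", "conv"]

    def test_missing_exchange_id_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="EX_missing"):
            apply_medium(self._model(), MediumSpec("minimal", ["EX_missing"]))


class TestClearDenominators:
    def test_lcm_scaling_of_fractional_column(self):
        m = make_model({("A", "r"): Fraction(-1, 50), ("B", "r"): 1})
        out = clear_denominators(m)
        assert out.coeff[("A", "r")] == Fraction(-1)
        assert out.coeff[("B", "r")] == Fraction(50)

    def test_integer_model_unchanged(self):
        m = make_model({("A", "r"): -1, ("B", "r"): 1})
        assert clear_denominators(m) is m

    def test_reapplication_is_identity(self):
        m = make_model({("A", "r"): Fraction(1, 3), ("B", "r"): Fraction(-1, 2)})
        once = clear_denominators(m)
        assert once.is_integer()
        assert clear_denominators(once) is once

    def test_solution_set_preserved(self):
        # per-column positive scaling must not change the pool solution set
        m = make_model({
            ("A", "r1"): Fraction(-1, 50), ("B", "r1"): 1,
            ("B", "r2"): Fraction(-2, 3), ("C", "r2"): Fraction(1, 3),
        })
        before = enumerate_solutions(m, k_max=3)
        after = enumerate_solutions(clear_denominators(m), k_max=3)
        assert before == after


class TestPoolReports:
    BASIS = PoolBasis(pools=[
        IntegerPool.from_dict({"fldox[c]": 1, "fldrd[c]": 1}),
        IntegerPool.from_dict({"a": 2, "b": 1}),
    ])

    def test_formula_convention(self):
        assert format_pool({"fldox[c]": 1, "fldrd[c]": 1}) == "fldox[c] + fldrd[c]"
        assert format_pool({"a": 2, "b": 1}) == "(2) a + b"

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_round_trip(self, tmp_path, fmt):
        path = str(tmp_path / f"pools.{fmt}")
        write_pools(self.BASIS, path, fmt)
        back = read_pools(path, fmt)
        assert back == [p.coeffs_dict for p in self.BASIS]

    def test_empty_basis_writes_header_only(self, tmp_path):
        path = str(tmp_path / "pools.tsv")
        write_pools(PoolBasis(), path, "tsv")
        assert (tmp_path / "pools.tsv").read_text() == "pool_id\tsize\tformula\n"
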
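"""Forest-type registry, species weighting and volume-equation dispatch."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from forestcarbon import (ECOZONES, ForestType, ForestTypeRegistry,
                          SpeciesParams, SpeciesTable, VolumeEquationSpec,
                          effective_params, effective_volume_equation,
                          load_registry, load_stand_params, write_registry)
from forestcarbon.typology import TypologyError

ZONE = ECOZONES[0]


def species_table(rows, fallback=None):
    return SpeciesTable(rows, fallback_ecozone=fallback)


def linear_eq(c1):
    return VolumeEquationSpec(form="linear", coefficients=(0.0, c1, 0.0))


class TestRegistry:
    def test_default_registry_has_51_unique_types(self, default_registry):
        assert len(default_registry) == 51
        assert len(set(default_registry.abbreviations)) == 51

    def test_default_registry_taxonomy_counts(self, default_registry):
        by_wood = {}
        for ft in default_registry:
            by_wood[ft.wood_type] = by_wood.get(ft.wood_type, 0) + 1
        assert by_wood == {"coniferous": 16, "broadleaved": 12,
                           "bamboo": 14, "mixed": 9}

    def test_single_row_registry(self, tmp_path):
        f = tmp_path / "reg.csv"
        f.write_text("abbreviation,name,wood_type,regeneration,species_weights\n"
                     "X-NF,X Forest,coniferous,nature,sp1:1.0\n")
        reg = load_registry(f)
        assert len(reg) == 1
        assert reg["X-NF"].species_weights == (("sp1", 1.0),)

    def test_weights_must_sum_to_one(self, tmp_path):
        f = tmp_path / "reg.csv"
        f.write_text("abbreviation,name,wood_type,regeneration,species_weights\n"
                     "X-NF,X Forest,coniferous,nature,sp1:0.6;sp2:0.3\n")
        with pytest.raises(TypologyError, match="sum"):
            load_registry(f)

    @pytest.mark.parametrize("row,match", [
        ("X-NF,X,conifer,nature,sp1:1.0", "wood_type"),
        ("X-NF,X,coniferous,wild,sp1:1.0", "regeneration"),
    ])
    def test_unknown_tokens_rejected(self, tmp_path, row, match):
        f = tmp_path / "reg.csv"
        f.write_text("abbreviation,name,wood_type,regeneration,species_weights\n"
                     + row + "\n")
        with pytest.raises(TypologyError, match=match):
            load_registry(f)

    def test_duplicate_abbreviation_rejected(self):
        ft = ForestType("X-NF", "X", "coniferous", "nature", (("sp1", 1.0),))
        with pytest.raises(TypologyError, match="duplicate"):
            ForestTypeRegistry([ft, ft])

    def test_bamboo_mixed_weighting_rule(self, default_registry):
        """Bamboo-containing mixed types put 0.5 on bamboo, rest split evenly."""
        from forestcarbon.typology import DEFAULT_SPECIES_GROUPS
        for ft in default_registry:
            if ft.wood_type != "mixed":
                continue
            bamboo_w = sum(w for sp, w in ft.species_weights
                           if DEFAULT_SPECIES_GROUPS[sp] == "bamboo")
            if bamboo_w:
                assert bamboo_w == pytest.approx(0.5, abs=1e-12)
                others = [w for sp, w in ft.species_weights
                          if DEFAULT_SPECIES_GROUPS[sp] != "bamboo"]
                assert all(w == pytest.approx(0.5 / len(others)) for w in others)

    def test_bamboo_rule_violation_rejected(self):
        ft = ForestType("M-BAD-NF", "Bad", "mixed", "nature",
                        (("phyllostachys_makinoi", 0.7), ("mixed_conifer", 0.3)))
        with pytest.raises(TypologyError, match="bamboo"):
            ForestTypeRegistry([ft])

    def test_registry_round_trip(self, default_registry, tmp_path):
        out = tmp_path / "reg.csv"
        write_registry(default_registry, out)
        reloaded = load_registry(out)
        assert reloaded.abbreviations == default_registry.abbreviations
        for a, b in zip(default_registry, reloaded):
            assert a == b


class TestEffectiveParams:
    def test_two_cypress_species_average_density(self):
        """Equal-weight mix of the two cypress species averages D."""
        tbl = species_table([
            SpeciesParams("cyp_a", ef=1.3, d=0.40, cf=0.5),
            SpeciesParams("cyp_b", ef=1.3, d=0.44, cf=0.5)])
        ft = ForestType("CYP-NF", "Cypress", "coniferous", "nature",
                        (("cyp_a", 0.5), ("cyp_b", 0.5)))
        assert effective_params(ft, tbl).d == pytest.approx(0.42)

    def test_single_species_identity(self):
        tbl = species_table([SpeciesParams("sp", ef=1.6, d=0.5, cf=0.47)])
        ft = ForestType("X-NF", "X", "coniferous", "nature", (("sp", 1.0),))
        p = effective_params(ft, tbl)
        assert (p.ef, p.d, p.cf) == (1.6, 0.5, 0.47)

    def test_equal_components_equal_params(self):
        rows = [SpeciesParams(f"s{i}", ef=1.5, d=0.5, cf=0.48) for i in range(4)]
        ft = ForestType("X-NF", "X", "mixed", "nature",
                        tuple((f"s{i}", 0.25) for i in range(4)))
        p = effective_params(ft, species_table(rows))
        assert (p.ef, p.d, p.cf) == pytest.approx((1.5, 0.5, 0.48))

    def test_missing_species_errors(self):
        tbl = species_table([SpeciesParams("sp", ef=1.5, d=0.5, cf=0.48)])
        ft = ForestType("X-NF", "X", "coniferous", "nature", (("ghost", 1.0),))
        with pytest.raises(TypologyError, match="ghost"):
            effective_params(ft, tbl)

    @given(st.lists(st.tuples(st.floats(1.0, 2.9), st.floats(0.21, 0.89),
                              st.floats(0.41, 0.54)),
                    min_size=2, max_size=5),
           st.integers(0, 1000))
    def test_convexity_and_permutation_invariance(self, triples, perm_seed):
        """Weighted params stay inside the component envelope and ignore order."""
        rows = [SpeciesParams(f"s{i}", ef=a, d=b, cf=c)
                for i, (a, b, c) in enumerate(triples)]
        tbl = species_table(rows)
        k = len(rows)
        weights = np.full(k, 1.0 / k)
        weights[0] += 1.0 - weights.sum()  # exact sum
        pairs = tuple((f"s{i}", float(weights[i])) for i in range(k))
        ft = ForestType("X-NF", "X", "coniferous", "nature", pairs)
        p = effective_params(ft, tbl)
        for attr, col in (("ef", 0), ("d", 1), ("cf", 2)):
            vals = [t[col] for t in triples]
            assert min(vals) - 1e-12 <= getattr(p, attr) <= max(vals) + 1e-12
        perm = np.random.default_rng(perm_seed).permutation(k)
        ft2 = ForestType("X-NF", "X", "coniferous", "nature",
                         tuple(pairs[i] for i in perm))
        p2 = effective_params(ft2, tbl)
        assert (p.ef, p.d, p.cf) == (p2.ef, p2.d, p2.cf)


class TestVolumeEquations:
    def test_linear_substitution(self):
        tbl = species_table([SpeciesParams(
            "sp", ef=1.5, d=0.5, cf=0.48,
            volume_equations={ZONE: linear_eq(0.001)})])
        ft = ForestType("X-NF", "X", "coniferous", "nature", (("sp", 1.0),))
        v = effective_volume_equation(ft, tbl, ZONE)(10.0, 15.0)
        assert v == pytest.approx(0.01)

    def test_weighted_composite(self):
        const = lambda c: VolumeEquationSpec("linear", (c, 0.0, 0.0))
        tbl = species_table([
            SpeciesParams("a", ef=1.5, d=0.5, cf=0.48,
                          volume_equations={ZONE: const(0.2)}),
            SpeciesParams("b", ef=1.5, d=0.5, cf=0.48,
                          volume_equations={ZONE: const(0.4)})])
        ft = ForestType("X-NF", "X", "coniferous", "nature",
                        (("a", 0.5), ("b", 0.5)))
        assert effective_volume_equation(ft, tbl, ZONE)(20, 20) == pytest.approx(0.3)

    def test_log_log_form_matches_hand_calculation(self):
        """Independent evaluation of exp(a + b ln DBH + c ln H)."""
        a, b, c = -9.3, 1.85, 0.95
        eq = VolumeEquationSpec("schumacher_hall", (a, b, c))
        for dbh, h in [(12.0, 9.5), (30.0, 20.0), (55.0, 31.0)]:
            expected = math.exp(a + b * math.log(dbh) + c * math.log(h))
            assert eq.evaluate(dbh, h) == pytest.approx(expected, abs=1e-9)

    def test_missing_ecozone_falls_back_with_warning(self, caplog):
        tbl = species_table([SpeciesParams(
            "sp", ef=1.5, d=0.5, cf=0.48,
            volume_equations={ECOZONES[1]: linear_eq(0.002)})],
            fallback=ECOZONES[1])
        ft = ForestType("X-NF", "X", "coniferous", "nature", (("sp", 1.0),))
        with caplog.at_level("WARNING"):
            v = effective_volume_equation(ft, tbl, ZONE)(10, 10)
        assert v == pytest.approx(0.02)
        assert "falling back" in caplog.text

    def test_missing_ecozone_without_fallback_errors(self):
        tbl = species_table([SpeciesParams("sp", ef=1.5, d=0.5, cf=0.48)])
        ft = ForestType("X-NF", "X", "coniferous", "nature", (("sp", 1.0),))
        with pytest.raises(TypologyError, match="no volume equation"):
            effective_volume_equation(ft, tbl, ZONE)

    @pytest.mark.parametrize("form", ["cubic", ""])
    def test_unknown_form_rejected(self, form):
        with pytest.raises(TypologyError):
            VolumeEquationSpec(form, (1.0, 1.0, 1.0))


class TestStandParams:
    def test_percent_header_flag_rescales_rates(self, tmp_path):
        body = ("abbreviation,dbh_mean,dbh_sd,h_mean,h_sd,n_stems_ha,"
                "growth_rate,mortality_rate\nX-NF,30,3,20,2,500,5.0,1.0\n")
        frac = tmp_path / "frac.csv"
        frac.write_text(body.replace("5.0,1.0", "0.05,0.01"))
        pct = tmp_path / "pct.csv"
        pct.write_text("# rate_units: percent\n" + body)
        a = load_stand_params(frac)["X-NF"]
        b = load_stand_params(pct)["X-NF"]
        assert (a.growth_rate, a.mortality_rate) == (b.growth_rate, b.mortality_rate)
        assert b.growth_rate == pytest.approx(0.05)

    @pytest.mark.parametrize("kwargs", [
        {"dbh_mean": -1.0}, {"n_stems_ha": 0.0}, {"dbh_sd": -0.1},
        {"mortality_rate": 1.0}, {"growth_rate": -1.0}])
    def test_invalid_values_rejected(self, kwargs):
        from forestcarbon import StandParams
        base = dict(abbreviation="X-NF", dbh_mean=30.0, dbh_sd=3.0, h_mean=20.0,
                    h_sd=2.0, n_stems_ha=500.0, growth_rate=0.05,
                    mortality_rate=0.01)
        base.update(kwargs)
        with pytest.raises(TypologyError):
            StandParams(**base)
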
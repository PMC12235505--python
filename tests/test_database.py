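"""Oligoester species, database enumeration, and neutral-mass matching."""

import math
from math import comb

import pytest

from oligoscreen import (
    MONOMERS,
    OligoesterSpecies,
    match_neutral,
    monoisotopic_mass,
    species_formula,
    species_from_row,
)
from oligoscreen.database import (
    DatabaseConfig,
    EnumerationRule,
    FAMILY_ORDER,
    REPEAT_MASSES,
    enumerate_database,
    read_database_csv,
    read_database_json,
    write_database_csv,
    write_database_json,
)

WATER = monoisotopic_mass("H2O")


def naive_species_mass(species: OligoesterSpecies) -> float:
    """Independent oracle: sum free monomers, remove condensation waters.

    Each diacid-diol repeat is one diacid plus one butanediol minus two
    waters; each lactate repeat is lactic acid minus one water.  End caps
    add back water (free acid end), methanol, or a whole butanediol.
    """
    total, n_waters = 0.0, 0
    for family, count in species.composition:
        if family == "LA":
            total += count * monoisotopic_mass(MONOMERS["LA"].formula)
            n_waters += count
        else:
            diacid = {"AA-BD": "AA", "TA-BD": "TA", "SeA-BD": "SeA"}[family]
            total += count * (
                monoisotopic_mass(MONOMERS[diacid].formula)
                + monoisotopic_mass(MONOMERS["BD"].formula)
            )
            n_waters += 2 * count
    total -= n_waters * WATER
    if species.end_group == "free":
        total += WATER
    elif species.end_group == "methyl_capped":
        total += monoisotopic_mass("CH4O")
    elif species.end_group == "bd_capped":
        total += monoisotopic_mass(MONOMERS["BD"].formula)
    return total


class TestSpecies:
    @pytest.mark.parametrize(
        "topology, comp, end_group, label, formula, mass",
        [
            ("cyclic", {"AA-BD": 1}, None, "cyclic [AA-BD]", "C10H16O4", 200.10486),
            ("cyclic", {"LA": 2}, None, "cyclic [LA]2", "C6H8O4", 144.04226),
            ("linear", {"LA": 3}, "methyl_capped", "Me-[LA]3", "C10H16O7", 248.08960),
            ("linear", {"AA-BD": 2}, "bd_capped", "BD-[AA-BD]2", "C24H42O10", 490.27780),
            (
                "cyclic", {"AA-BD": 2, "TA-BD": 2}, None,
                "cyclic [AA-BD]2-[TA-BD]2", "C44H56O16", 840.35684,
            ),
        ],
    )
    def test_formula_label_and_mass(self, topology, comp, end_group, label, formula, mass):
        sp = OligoesterSpecies.make(topology, comp, end_group)
        assert sp.label == label
        assert str(species_formula(sp)) == formula
        assert round(sp.mass, 5) == mass

    def test_cyclic_species_reject_end_groups(self):
        with pytest.raises(ValueError):
            OligoesterSpecies.make("cyclic", {"LA": 2}, "free")

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            OligoesterSpecies.make("cyclic", {})

    def test_label_uses_fixed_family_order(self):
        sp = OligoesterSpecies.make("cyclic", {"LA": 1, "AA-BD": 1, "SeA-BD": 2})
        assert sp.label == "cyclic [AA-BD]-[SeA-BD]2-[LA]"

    def test_extension_below_zero_rejected(self):
        sp = OligoesterSpecies.make("cyclic", {"AA-BD": 1})
        with pytest.raises(ValueError):
            sp.extend("AA-BD", -2)


class TestEnumeration:
    def test_single_unit_homopolymers(self):
        config = DatabaseConfig(
            rules=(
                EnumerationRule("cyclic", "none", tuple((f, 1) for f in FAMILY_ORDER), 1, 1),
            ),
            min_cyclic_units=tuple((f, 1) for f in FAMILY_ORDER),
        )
        assert len(enumerate_database(config)) == 4

    def test_multiset_count_up_to_two_units(self):
        # multisets of size 1 or 2 over 4 families: 4 + C(5, 2) = 14
        config = DatabaseConfig(
            rules=(
                EnumerationRule("cyclic", "none", tuple((f, 2) for f in FAMILY_ORDER), 1, 2),
            ),
            min_cyclic_units=tuple((f, 1) for f in FAMILY_ORDER),
        )
        assert len(enumerate_database(config)) == 14

    @pytest.mark.parametrize("size", [3, 4, 5])
    def test_multiset_count_matches_closed_form(self, size):
        config = DatabaseConfig(
            rules=(
                EnumerationRule(
                    "cyclic", "none", tuple((f, size) for f in FAMILY_ORDER), 1, size
                ),
            ),
            min_cyclic_units=tuple((f, 1) for f in FAMILY_ORDER),
        )
        expected = sum(comb(n + 3, 3) for n in range(1, size + 1))
        assert len(enumerate_database(config)) == expected

    def test_default_includes_nine_unit_mixed_cyclic(self, db):
        assert (db["label"] == "cyclic [AA-BD]5-[TA-BD]4").any()

    def test_default_covers_observed_homopolymer_ranges(self, db):
        labels = set(db["label"])
        assert {"cyclic [LA]2", "cyclic [LA]12", "cyclic [AA-BD]", "cyclic [AA-BD]6",
                "cyclic [TA-BD]2", "cyclic [TA-BD]3", "cyclic [SeA-BD]",
                "cyclic [SeA-BD]4", "Me-[LA]2", "Me-[LA]20"} <= labels
        # lactide is the smallest lactate ring; no 1-unit LA cyclic
        assert "cyclic [LA]" not in labels

    def test_enumeration_is_duplicate_free_and_sorted(self, db):
        assert db["label"].is_unique
        assert db["mass"].is_monotonic_increasing

    def test_enumeration_is_stable_across_runs(self, db):
        again = enumerate_database()
        assert db.equals(again)

    def test_safety_cap_enforced(self):
        config = DatabaseConfig(
            rules=(
                EnumerationRule(
                    "cyclic", "none", tuple((f, 60) for f in FAMILY_ORDER), 1, 240
                ),
            ),
            safety_cap=1000,
        )
        with pytest.raises(ValueError, match="safety cap"):
            enumerate_database(config)

    def test_every_species_matches_naive_monomer_oracle(self, db):
        for _, row in db.iterrows():
            sp = species_from_row(row)
            assert math.isclose(sp.mass, naive_species_mass(sp), abs_tol=1e-9), row["label"]

    def test_cyclic_masses_are_integer_repeat_combinations(self, db):
        cyclic = db.loc[db["topology"] == "cyclic"]
        for _, row in cyclic.iterrows():
            combo = sum(
                int(row[f"n_{f.replace('-', '_')}"]) * REPEAT_MASSES[f]
                for f in FAMILY_ORDER
            )
            assert math.isclose(row["mass"], combo, abs_tol=1e-9)


class TestMatching:
    def test_exact_mass_lookup_ranks_true_species_first(self, db):
        hits = match_neutral(840.35684, db, tol=0.001)
        assert hits.iloc[0]["label"] == "cyclic [AA-BD]2-[TA-BD]2"

    def test_monomer_ring_not_confused_with_free_linear(self, db):
        hits = match_neutral(200.10486, db, tol=0.001)
        assert list(hits["label"]) == ["cyclic [AA-BD]"]

    def test_no_candidate_within_tolerance(self, db):
        assert len(match_neutral(500.0, db, tol=0.001)) == 0

    def test_tolerance_must_be_positive(self, db):
        with pytest.raises(ValueError):
            match_neutral(200.0, db, tol=0.0)


class TestRoundTrips:
    def test_csv_round_trip(self, db, tmp_path):
        path = tmp_path / "db.csv"
        write_database_csv(db, path)
        back = read_database_csv(path)
        assert list(back["label"]) == list(db["label"])
        # masses are re-derived from formulas at full precision
        assert max(abs(back["mass"] - db["mass"])) < 1e-9

    def test_json_round_trip(self, db, tmp_path):
        path = tmp_path / "db.json"
        write_database_json(db, path)
        back = read_database_json(path)
        assert list(back["label"]) == list(db["label"])
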
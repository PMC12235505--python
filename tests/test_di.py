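"""Direct-infusion ladder extraction, assignment and deduplication."""

import numpy as np
import pytest

from oligoscreen import (
    CentroidSpectrum,
    OligoesterSpecies,
    SeriesPlan,
    adduct_mz,
    assign_sequence,
    extract_ladders,
    flag_isotopologues,
    random_series_plans,
    run_di_extraction,
    simulate_di_spectrum,
    summarize_components,
    threshold_filter,
)
from oligoscreen.database import REPEAT_MASSES


def spectrum_from(mz, intensity=None):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.full_like(mz, 1e6)
    return CentroidSpectrum(mz, intensity)


AA_RING = OligoesterSpecies.make("cyclic", {"AA-BD": 1})
AA_LADDER_MZ = [adduct_mz(AA_RING.extend("AA-BD", k).formula, "[M+NH4]+") for k in range(3)]


class TestThresholdFilter:
    def test_boundary_is_inclusive(self):
        spec = spectrum_from([100.0, 200.0, 300.0], [9_999, 10_000, 10_001])
        kept = threshold_filter(spec, 1e4)
        assert len(kept) == 2
        assert kept.intensity.min() == 10_000

    def test_all_below_threshold_gives_empty(self):
        spec = spectrum_from([100.0], [9_999])
        assert len(threshold_filter(spec)) == 0

    def test_empty_spectrum_passes_through(self):
        assert len(threshold_filter(spectrum_from([]))) == 0


class TestExtractLadders:
    def test_planted_adipate_ladder_found(self):
        seqs = extract_ladders(spectrum_from(AA_LADDER_MZ))
        aa = [s for s in seqs if s.family == "AA-BD" and s.charge == 1]
        assert len(aa) == 1
        assert len(aa[0]) == 3

    def test_empty_spectrum_has_no_sequences(self):
        assert extract_ladders(spectrum_from([])) == []

    def test_half_spacing_detected_as_doubly_charged(self):
        spacing = REPEAT_MASSES["AA-BD"] / 2
        mzs = [618.34841 + k * spacing for k in range(3)]
        seqs = extract_ladders(spectrum_from(mzs))
        z2 = [s for s in seqs if s.charge == 2 and s.family == "AA-BD"]
        assert len(z2) == 1 and len(z2[0]) == 3

    def test_chains_are_maximal(self):
        """No reported chain extends by any in-spectrum peak within tolerance."""
        rng = np.random.default_rng(7)
        mzs = np.sort(rng.uniform(150, 2000, 300))
        spec = spectrum_from(mzs)
        seqs = extract_ladders(spec, min_length=2)
        for seq in seqs:
            spacing = REPEAT_MASSES[seq.family] / seq.charge
            before = np.abs(spec.mz - (seq.mzs[0] - spacing)) <= 0.001
            after = np.abs(spec.mz - (seq.mzs[-1] + spacing)) <= 0.001
            assert not before.any()
            assert not after.any()

    def test_contained_subchains_are_dropped(self):
        # four members: the 3-member suffix must not be reported separately
        mzs = [adduct_mz(AA_RING.extend("AA-BD", k).formula, "[M+NH4]+") for k in range(4)]
        seqs = extract_ladders(spectrum_from(mzs))
        aa = [s for s in seqs if s.family == "AA-BD" and s.charge == 1]
        assert len(aa) == 1 and len(aa[0]) == 4


class TestAssignment:
    def test_adipate_seed_assigns_whole_ladder(self, db):
        seqs = extract_ladders(spectrum_from(AA_LADDER_MZ))
        seq = next(s for s in seqs if s.family == "AA-BD" and s.charge == 1)
        assign_sequence(seq, db)
        assert seq.adduct == "[M+NH4]+"
        assert [a.species for a in seq.assigned] == [
            "cyclic [AA-BD]", "cyclic [AA-BD]2", "cyclic [AA-BD]3",
        ]

    def test_mixed_dimer_precursor_assignment(self, db):
        mz0 = 858.3907
        mzs = [mz0, mz0 + REPEAT_MASSES["AA-BD"]]
        seq = next(
            s for s in extract_ladders(spectrum_from(mzs))
            if s.family == "AA-BD" and s.charge == 1
        )
        assign_sequence(seq, db)
        assert seq.assigned[0].species == "cyclic [AA-BD]2-[TA-BD]2"
        assert seq.adduct == "[M+NH4]+"

    def test_unmatched_ladder_stays_unassigned(self, db):
        mzs = [500.123, 500.123 + REPEAT_MASSES["AA-BD"]]
        seq = extract_ladders(spectrum_from(mzs))[0]
        assign_sequence(seq, db)
        assert not seq.is_assigned

    def test_every_assigned_ion_within_tolerance(self, db):
        plans = random_series_plans(db.loc[db.topology == "cyclic"], 10, seed=3)
        spec, _ = simulate_di_spectrum(plans, jitter_sd=0.0002, seed=3)
        result = run_di_extraction(spec, db)
        errs = result.mass_errors_da
        assert len(errs) > 0
        assert np.max(np.abs(errs)) <= 0.001


class TestIsotopologues:
    def _assigned_ladder(self, db, extra_mz=(), extra_intensity=()):
        mzs = list(AA_LADDER_MZ[:2]) + list(extra_mz)
        intensities = [1e6, 7e5] + list(extra_intensity)
        spec = spectrum_from(mzs, intensities)
        seqs = extract_ladders(spec)
        for s in seqs:
            assign_sequence(s, db)
        return seqs, spec

    def test_carbon13_satellite_flagged(self, db):
        sat = AA_LADDER_MZ[0] + 1.00335
        seqs, spec = self._assigned_ladder(db, [sat], [1.1e5])
        flags = flag_isotopologues(seqs, spec)
        sat_index = int(np.argmin(np.abs(spec.mz - sat)))
        assert flags == {sat_index: "13C"}

    def test_oxygen18_satellite_flagged(self, db):
        sat = AA_LADDER_MZ[0] + 2.00425
        seqs, spec = self._assigned_ladder(db, [sat], [2e4])
        flags = flag_isotopologues(seqs, spec)
        assert list(flags.values()) == ["18O"]

    def test_no_satellite_no_flags(self, db):
        seqs, spec = self._assigned_ladder(db)
        assert flag_isotopologues(seqs, spec) == {}

    def test_stronger_companion_not_flagged(self, db):
        sat = AA_LADDER_MZ[0] + 1.00335
        seqs, spec = self._assigned_ladder(db, [sat], [5e6])
        assert flag_isotopologues(seqs, spec) == {}

    def test_singleton_ladders_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            extract_ladders(spectrum_from(AA_LADDER_MZ), min_length=1)


class TestComponents:
    def test_same_species_via_two_adducts_is_one_component(self, db):
        mz_nh4 = [adduct_mz(AA_RING.extend("AA-BD", k).formula, "[M+NH4]+") for k in range(2)]
        mz_na = [adduct_mz(AA_RING.extend("AA-BD", k).formula, "[M+Na]+") for k in range(2)]
        result = run_di_extraction(spectrum_from(mz_nh4 + mz_na), db)
        row = result.components.set_index("species").loc["cyclic [AA-BD]"]
        assert row["n_sequences"] == 2
        assert set(row["adducts"].split(";")) == {"[M+NH4]+", "[M+Na]+"}

    def test_no_sequences_gives_empty_table(self):
        table = summarize_components([])
        assert len(table) == 0
        assert "species" in table.columns

    def test_noiseless_catalogue_species_round_trip(self, db, catalogue):
        """Replaying the catalogue's DI-detected cyclic species recovers
        exactly the planted component list."""
        from oligoscreen import catalogue_species

        seen = {}
        for _, row in catalogue.iterrows():
            if row["di_detected"] and row["topology"] == "cyclic":
                sp = catalogue_species(row)
                if sp is not None:
                    seen[sp.label] = sp
        plans = [
            SeriesPlan(sp, "[M+NH4]+", n_members=1)
            for sp in seen.values()
            if 150 <= adduct_mz(sp.formula, "[M+NH4]+") <= 2000
        ]
        spec, truth = simulate_di_spectrum(plans, seed=0)
        result = run_di_extraction(spec, db, include_singletons=True)
        assert set(result.components["species"]) == truth.species


class TestRecallProperties:
    def test_noiseless_extraction_recovers_all_planted_species(self, db):
        plans = random_series_plans(db.loc[db.topology == "cyclic"], 12, seed=11)
        spec, truth = simulate_di_spectrum(plans, add_satellites=True, seed=11)
        result = run_di_extraction(spec, db)
        found = set(result.components["species"])
        assert found == truth.species

    def test_recall_robust_to_jitter_and_subthreshold_noise(self, db):
        plans = random_series_plans(db.loc[db.topology == "cyclic"], 12, seed=12)
        n_planted = sum(p.n_members for p in plans)
        spec, truth = simulate_di_spectrum(
            plans, jitter_sd=0.0002, n_noise=10 * n_planted,
            add_satellites=True, seed=12,
        )
        result = run_di_extraction(spec, db)
        assert set(result.components["species"]) == truth.species
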
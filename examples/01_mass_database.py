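"""Exact masses, adduct m/z and the predicted oligoester database.

Builds the default combinatorial database of cyclic/linear oligoesters and
matches a measured neutral mass against it.
"""

from oligoscreen import (
    OligoesterSpecies,
    adduct_mz,
    enumerate_database,
    match_neutral,
    monoisotopic_mass,
)

# The four repeat units whose masses space the oligomer ion ladders.
for name, formula in [
    ("lactate (LA)", "C3H4O2"),
    ("butylene adipate (AA-BD)", "C10H16O4"),
    ("butylene terephthalate (TA-BD)", "C12H12O4"),
    ("butylene sebacate (SeA-BD)", "C14H24O4"),
]:
    print(f"{name:32s} {formula:10s} {monoisotopic_mass(formula):.5f} Da")

# A PBAT-derived cyclic dimer-of-dimers and its ammonium adduct: the
# electron-mass correction matters at Orbitrap accuracy.
species = OligoesterSpecies.make("cyclic", {"AA-BD": 2, "TA-BD": 2})
print(f"\n{species.label}: {species.formula} ({species.mass:.5f} Da)")
print(f"[M+NH4]+ m/z = {adduct_mz(species.formula, '[M+NH4]+'):.4f}")

db = enumerate_database()
print(f"\npredicted database: {len(db)} species, "
      f"{db['mass'].min():.3f}-{db['mass'].max():.3f} Da")

# Match an observed neutral mass within +/-1 mDa.
hits = match_neutral(840.35684, db, tol=0.001)
print("\nneutral 840.35684 Da matches:")
print(hits[["label", "formula", "mass", "error"]].to_string(index=False))
# The single hit identifies the species; 'error' is observed minus theory in Da.
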
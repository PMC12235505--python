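"""LC-MS/MS annotation: isomer multiplicity and diagnostic fragments.

Builds a small feature table with two chromatographic isomer peaks for one
precursor, plus a ddMS2 event, and annotates them with Schymanski-style
confidence levels.
"""

import numpy as np
import pandas as pd

from oligoscreen import (
    MS2Event,
    OligoesterSpecies,
    adduct_mz,
    annotate_event,
    enumerate_database,
    extract_eic,
)

species = OligoesterSpecies.make("cyclic", {"AA-BD": 2, "TA-BD": 2})
precursor = adduct_mz(species.formula, "[M+NH4]+")

# Two isomers of the same composition elute at 27.10 and 27.35 min.
rows = []
for apex in (27.10, 27.35):
    for rt in np.linspace(apex - 0.08, apex + 0.08, 11):
        rows.append({"rt": rt, "mz": precursor,
                     "intensity": 1e6 * np.exp(-((rt - apex) / 0.04) ** 2 / 2)})
features = pd.DataFrame(rows)

peaks = extract_eic(features, precursor, tol_ppm=5)
print(f"EIC at m/z {precursor:.4f}: {len(peaks)} isomer peaks at "
      + ", ".join(f"{p.rt:.2f} min" for p in peaks))

# ddMS2 event with three oligoester diagnostic fragments: the
# terephthaloyl acylium, the protonated adipate repeat, and a water loss.
event = MS2Event(
    precursor_mz=precursor,
    rt=27.10,
    fragments=pd.DataFrame(
        {"mz": [149.02332, 201.11221, 183.10158], "intensity": [9e5, 6e5, 2e5]}
    ),
)
db = enumerate_database()
annotation = annotate_event(event, db)

print(f"\nprecursor {precursor:.4f} -> {annotation.species} as {annotation.adduct} "
      f"({annotation.error_ppm:+.2f} ppm)")
print("matched diagnostic fragments:")
print(annotation.matched_fragments.to_string(index=False))
print(f"confidence level: {annotation.confidence_level} "
      "(2 = probable structure: formula plus diagnostic fragments)")
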
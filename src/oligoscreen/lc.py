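"""LC-HRMS/MS annotation of oligoester precursors.

Reverse-phase LC separates the isomers that direct infusion collapses into
one m/z, and data-dependent MS/MS adds diagnostic fragments.  This module
covers the data-analysis side: extracted-ion chromatograms with isomer
multiplicity, precursor formula/adduct candidates against the predicted
structure database, matching of observed fragments to a conservative
theoretical diagnostic-ion set, and Schymanski-style confidence levels
(1 = confirmed with reference standard, 2 = probable structure with
diagnostic fragments, 3 = formula only).

Tolerances here are relative (ppm, default 5), unlike the absolute
+/-0.001 Da used at the direct-infusion stage.  The instrument's 3 ppm
dynamic-exclusion setting is kept as metadata, not reused for matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import formula as fm
from .database import (
    MONOMERS,
    REPEAT_UNITS,
    OligoesterSpecies,
    match_neutral,
    species_from_row,
)
from .di import DEFAULT_ADDUCTS, _ADDUCT_PRIORITY

__all__ = [
    "DYNAMIC_EXCLUSION_PPM",
    "EICPeak",
    "MS2Event",
    "Annotation",
    "extract_eic",
    "annotate_precursor",
    "diagnostic_ions",
    "match_fragments",
    "assign_confidence",
    "annotate_event",
]

#: Acquisition metadata: ddMS2 dynamic-exclusion mass tolerance.
DYNAMIC_EXCLUSION_PPM = 3.0

_WATER_MASS = fm.monoisotopic_mass("H2O")

#: Free diacid per repeat family (lactic acid for LA).
_FAMILY_ACID = {
    "AA-BD": MONOMERS["AA"].formula,
    "TA-BD": MONOMERS["TA"].formula,
    "SeA-BD": MONOMERS["SeA"].formula,
    "LA": MONOMERS["LA"].formula,
}

from .database import END_GROUPS  # noqa: E402  (shared end-group table)


@dataclass(frozen=True)
class EICPeak:
    rt: float
    intensity: float
    n_features: int


@dataclass
class MS2Event:
    """One data-dependent MS/MS event."""

    precursor_mz: float
    rt: float
    fragments: pd.DataFrame  # columns mz, intensity, sorted by mz
    precursor_intensity: float = 0.0

    def __post_init__(self):
        frags = pd.DataFrame(self.fragments)
        if len(frags) and not {"mz", "intensity"} <= set(frags.columns):
            raise ValueError("fragment table needs mz and intensity columns")
        self.fragments = frags.sort_values("mz").reset_index(drop=True) if len(frags) else frags


@dataclass
class Annotation:
    species: str | None
    adduct: str | None
    formula: str | None
    error_ppm: float | None
    matched_fragments: pd.DataFrame
    fragment_score: float
    confidence_level: int
    rt: float | None = None
    precursor_mz: float | None = None


def extract_eic(
    features: pd.DataFrame,
    target_mz: float,
    tol_ppm: float = 5.0,
    min_separation: float = 0.05,
) -> list[EICPeak]:
    """Chromatographic peaks for a narrow m/z window.

    Features within ``tol_ppm`` of ``target_mz`` are sorted by retention
    time; local intensity maxima become peak apexes, and apexes closer than
    ``min_separation`` minutes are merged (keeping the taller one).  The
    observed isomer RT gaps in these films are >= 0.25 min, so the default
    separation comfortably distinguishes real multiplicity from ripple.
    """
    if tol_ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    if not len(features):
        return []
    window = np.abs(features["mz"].to_numpy() - target_mz) / target_mz <= tol_ppm * 1e-6
    sub = features.loc[window].sort_values("rt")
    if not len(sub):
        return []
    rt = sub["rt"].to_numpy()
    inten = sub["intensity"].to_numpy()
    apexes = []
    for i in range(len(sub)):
        left = inten[i - 1] if i > 0 else -np.inf
        right = inten[i + 1] if i < len(sub) - 1 else -np.inf
        if inten[i] >= left and inten[i] > right or (i == len(sub) - 1 and inten[i] >= left):
            apexes.append(i)
    merged: list[int] = []
    for i in apexes:
        if merged and rt[i] - rt[merged[-1]] < min_separation:
            if inten[i] > inten[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    peaks = []
    for i in merged:
        members = np.abs(rt - rt[i]) < min_separation
        peaks.append(EICPeak(rt=float(rt[i]), intensity=float(inten[i]), n_features=int(members.sum())))
    return peaks


def annotate_precursor(
    precursor_mz: float,
    db: pd.DataFrame,
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
    fallback_formula_search: bool = True,
    fallback_tol_ppm: float = 3.0,
) -> pd.DataFrame:
    """Ranked candidate annotations for one precursor m/z.

    Every supported adduct hypothesis is inverted to a neutral mass and
    matched against the database within ``tol_ppm``; candidates are ranked
    by absolute ppm error with the adduct priority NH4+ > H+ > Na+ as the
    tie-break.  When nothing matches, a bounded CHNO formula search within
    ``fallback_tol_ppm`` supplies formula-only candidates.
    """
    rows = []
    for name in adducts:
        adduct = fm.get_adduct(name)
        neutral = fm.neutral_mass_from_mz(precursor_mz, adduct)
        tol_da = tol_ppm * 1e-6 * neutral
        hits = match_neutral(neutral, db, tol_da)
        for _, hit in hits.iterrows():
            theo_mz = fm.adduct_mz(float(hit["mass"]), adduct)
            err = fm.mass_error(precursor_mz, theo_mz)
            rows.append(
                {
                    "species": hit["label"],
                    "adduct": name,
                    "formula": hit["formula"],
                    "neutral_mass": hit["mass"],
                    "theoretical_mz": theo_mz,
                    "error_ppm": err.delta_ppm,
                    "source": "database",
                }
            )
    if not rows and fallback_formula_search:
        for name in adducts:
            adduct = fm.get_adduct(name)
            neutral = fm.neutral_mass_from_mz(precursor_mz, adduct)
            for f, theo, err_ppm in fm.formula_search(neutral, fallback_tol_ppm):
                rows.append(
                    {
                        "species": None,
                        "adduct": name,
                        "formula": str(f),
                        "neutral_mass": theo,
                        "theoretical_mz": fm.adduct_mz(theo, adduct),
                        "error_ppm": err_ppm,
                        "source": "formula-search",
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "species", "adduct", "formula", "neutral_mass",
            "theoretical_mz", "error_ppm", "source",
        ],
    )
    if len(out):
        out["abs_ppm"] = out["error_ppm"].abs()
        out["priority"] = out["adduct"].map(_ADDUCT_PRIORITY).fillna(99)
        out = (
            out.sort_values(["abs_ppm", "priority"], kind="mergesort")
            .drop(columns=["abs_ppm", "priority"])
            .reset_index(drop=True)
        )
    return out


def diagnostic_ions(species: OligoesterSpecies) -> pd.DataFrame:
    """Theoretical diagnostic fragment m/z values for a candidate species.

    Deliberately conservative generator: protonated sub-oligomers of the
    candidate's repeat-unit multiset, their water losses, the same with one
    free diacid attached (which covers acylium-type ions: the diacid
    acylium is exactly [acid + H - H2O]+), double water losses of the
    acid-bearing forms, and end-group-bearing sub-oligomers for linear
    species (e.g. protonated methyl lactate for methyl-capped PLA).
    """
    counts = species.counts
    families = list(counts)
    sub_masses: dict[tuple, float] = {}
    for combo in itertools.product(*(range(counts[f] + 1) for f in families)):
        mass = sum(
            c * fm.monoisotopic_mass(REPEAT_UNITS[f]) for f, c in zip(families, combo)
        )
        sub_masses[combo] = mass
    rows = []

    def add(mass: float, label: str):
        if mass > 2 * fm.PROTON_MASS:
            rows.append({"mz": mass, "label": label})

    for combo, mass in sub_masses.items():
        total = sum(combo)
        parts = [f"{c}x{f}" for f, c in zip(families, combo) if c]
        name = "+".join(parts)
        if total:
            add(mass + fm.PROTON_MASS, f"[{name}+H]+")
            add(mass + fm.PROTON_MASS - _WATER_MASS, f"[{name}+H-H2O]+")
            if species.end_group != "none":
                eg = fm.monoisotopic_mass(END_GROUPS[species.end_group])
                add(mass + eg + fm.PROTON_MASS, f"[{name}+endgroup+H]+")
        for f in families:
            acid_name = f.split("-")[0]
            stem = "+".join(parts + [acid_name])
            acid = fm.monoisotopic_mass(_FAMILY_ACID[f])
            add(mass + acid + fm.PROTON_MASS, f"[{stem}+H]+")
            add(mass + acid + fm.PROTON_MASS - _WATER_MASS, f"[{stem}+H-H2O]+")
            add(mass + acid + fm.PROTON_MASS - 2 * _WATER_MASS, f"[{stem}+H-2H2O]+")
    out = pd.DataFrame(rows).drop_duplicates(subset="mz").sort_values("mz")
    return out.reset_index(drop=True)


def match_fragments(
    candidate: OligoesterSpecies,
    fragments: Sequence[float],
    tol_ppm: float = 5.0,
) -> tuple[pd.DataFrame, float]:
    """Match observed fragment m/z values against the diagnostic set.

    Returns the matched fragments (observed, theoretical, label, ppm) and a
    coverage score = matched diagnostics / generated diagnostics.
    """
    theo = diagnostic_ions(candidate)
    matches = []
    matched_theo = set()
    for obs in fragments:
        if not len(theo):
            break
        errs = np.abs(theo["mz"].to_numpy() - obs)
        best = int(np.argmin(errs))
        theo_mz = float(theo["mz"].iloc[best])
        if abs(obs - theo_mz) / theo_mz * 1e6 <= tol_ppm:
            matches.append(
                {
                    "observed_mz": obs,
                    "theoretical_mz": theo_mz,
                    "label": theo["label"].iloc[best],
                    "error_ppm": (obs - theo_mz) / theo_mz * 1e6,
                }
            )
            matched_theo.add(best)
    matched = pd.DataFrame(
        matches, columns=["observed_mz", "theoretical_mz", "label", "error_ppm"]
    )
    score = len(matched_theo) / len(theo) if len(theo) else 0.0
    return matched, score


def assign_confidence(has_reference_standard: bool, n_matched_fragments: int) -> int:
    """Schymanski-style level: 1 reference standard, 2 diagnostic evidence,
    3 formula only.  Pure function of its evidence inputs."""
    if has_reference_standard:
        return 1
    if n_matched_fragments >= 1:
        return 2
    return 3


def annotate_event(
    event: MS2Event,
    db: pd.DataFrame,
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
    has_reference_standard: bool = False,
) -> Annotation:
    """Annotate one ddMS2 event end to end (top candidate only)."""
    candidates = annotate_precursor(event.precursor_mz, db, adducts, tol_ppm)
    if not len(candidates):
        return Annotation(
            species=None, adduct=None, formula=None, error_ppm=None,
            matched_fragments=pd.DataFrame(
                columns=["observed_mz", "theoretical_mz", "label", "error_ppm"]
            ),
            fragment_score=0.0,
            confidence_level=assign_confidence(False, 0),
            rt=event.rt, precursor_mz=event.precursor_mz,
        )
    top = candidates.iloc[0]
    matched = pd.DataFrame(columns=["observed_mz", "theoretical_mz", "label", "error_ppm"])
    score = 0.0
    if top["species"] is not None and top["source"] == "database":
        row = db.loc[db["label"] == top["species"]].iloc[0]
        species = species_from_row(row)
        frag_mzs = event.fragments["mz"].tolist() if len(event.fragments) else []
        matched, score = match_fragments(species, frag_mzs, tol_ppm)
    level = assign_confidence(has_reference_standard, len(matched))
    return Annotation(
        species=top["species"], adduct=top["adduct"], formula=top["formula"],
        error_ppm=float(top["error_ppm"]), matched_fragments=matched,
        fragment_score=score, confidence_level=level,
        rt=event.rt, precursor_mz=event.precursor_mz,
    )
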
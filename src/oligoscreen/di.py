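"""Direct-infusion oligomer sequence extraction.

In a direct-infusion Orbitrap spectrum of a polyester extract, oligomer
series appear as ion ladders: peaks separated by a constant m/z difference
equal to a repeat-unit mass divided by the charge.  This module implements
the screening workflow around that observation:

1. intensity threshold filtering (default 1e4, inclusive),
2. maximal-ladder detection for each repeat family and charge state within
   an absolute tolerance (default +/-0.001 Da per step),
3. adduct/charge inference and species assignment of each ladder against a
   predicted structure database (anchored on the first matchable ion, then
   propagated one repeat unit at a time),
4. isotopologue (13C/18O satellite) flagging, and
5. deduplication of assigned ions into a component table, one row per
   unique species regardless of how many adducts or ladders support it.

Assigned components carry formula-level plus ladder-context evidence only,
i.e. Schymanski confidence level 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import formula as fm
from .database import (
    _COUNT_COLUMNS,
    REPEAT_MASSES,
    OligoesterSpecies,
    match_neutral,
    species_from_row,
)

__all__ = [
    "Peak",
    "CentroidSpectrum",
    "IonSequence",
    "AssignedIon",
    "DIResult",
    "threshold_filter",
    "infer_peak_charges",
    "extract_ladders",
    "assign_sequence",
    "validate_charge_states",
    "flag_isotopologues",
    "summarize_components",
    "match_singletons",
    "run_di_extraction",
]

DEFAULT_ADDUCTS = ("[M+NH4]+", "[M+H]+", "[M+Na]+", "[M+2NH4]2+")

#: Tie-break priority among equally good adduct hypotheses (lower wins).
_ADDUCT_PRIORITY = {"[M+NH4]+": 0, "[M+H]+": 1, "[M+Na]+": 2, "[M+2NH4]2+": 3}


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if not (np.isfinite(self.mz) and np.isfinite(self.intensity)):
            raise ValueError("peak m/z and intensity must be finite")
        if self.mz <= 0 or self.intensity < 0:
            raise ValueError("peak m/z must be > 0 and intensity >= 0")


class CentroidSpectrum:
    """An m/z-sorted centroided peak list.

    Duplicated m/z values (within 1e-6 Da) are merged at construction with
    summed intensity.  ``metadata`` carries acquisition context such as the
    scan range and polarity.
    """

    __slots__ = ("mz", "intensity", "metadata")

    def __init__(
        self,
        mz: Sequence[float],
        intensity: Sequence[float],
        metadata: dict | None = None,
    ):
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("m/z and intensity must be 1-D arrays of equal length")
        if len(mz) and (not np.all(np.isfinite(mz)) or not np.all(np.isfinite(intensity))):
            raise ValueError("non-finite values in spectrum")
        if np.any(mz <= 0) or np.any(intensity < 0):
            raise ValueError("m/z must be positive and intensities non-negative")
        order = np.argsort(mz, kind="mergesort")
        mz, intensity = mz[order], intensity[order]
        if len(mz) > 1:
            # merge near-duplicates (< 1e-6 Da apart), summing intensity
            keep_mz, keep_int = [mz[0]], [intensity[0]]
            for m, i in zip(mz[1:], intensity[1:]):
                if m - keep_mz[-1] < 1e-6:
                    keep_int[-1] += i
                else:
                    keep_mz.append(m)
                    keep_int.append(i)
            mz, intensity = np.array(keep_mz), np.array(keep_int)
        self.mz = mz
        self.intensity = intensity
        self.metadata = dict(metadata or {"polarity": "positive"})

    def __len__(self) -> int:
        return len(self.mz)

    def peak(self, index: int) -> Peak:
        return Peak(float(self.mz[index]), float(self.intensity[index]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})


@dataclass
class AssignedIon:
    """One ladder member with its inferred identity."""

    index: int              # peak index in the extracted spectrum
    mz: float
    intensity: float
    adduct: str
    charge: int
    species: str | None     # canonical species label, None if formula-only
    ion_formula: str | None
    error_da: float | None
    error_ppm: float | None
    isotopologue: str | None = None  # None | "13C" | "18O"
    charge_consistent: bool = True   # False if satellite spacing contradicts z


@dataclass
class IonSequence:
    """A maximal ion ladder for one repeat family and charge state."""

    family: str
    charge: int
    indices: tuple[int, ...]
    mzs: tuple[float, ...]
    intensities: tuple[float, ...]
    adduct: str | None = None
    anchor_species: OligoesterSpecies | None = None
    assigned: list[AssignedIon] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def is_assigned(self) -> bool:
        return self.anchor_species is not None


def threshold_filter(
    spectrum: CentroidSpectrum, min_intensity: float = 1e4
) -> CentroidSpectrum:
    """Keep peaks with intensity >= ``min_intensity`` (inclusive boundary)."""
    if min_intensity < 0:
        raise ValueError("intensity threshold must be >= 0")
    keep = spectrum.intensity >= min_intensity
    return CentroidSpectrum(spectrum.mz[keep], spectrum.intensity[keep], spectrum.metadata)


def _candidates(mz: np.ndarray, target: float, tol: float) -> np.ndarray:
    lo = np.searchsorted(mz, target - tol, side="left")
    hi = np.searchsorted(mz, target + tol, side="right")
    return np.arange(lo, hi)


def infer_peak_charges(
    spectrum: CentroidSpectrum,
    charges: Iterable[int] = (1, 2),
    tol: float = 0.001,
) -> list[frozenset[int]]:
    """Charge states supported by each peak's 13C satellite, if any.

    A peak whose spectrum contains a weaker companion at +1.00335/z carries
    evidence for charge z.  Peaks with no satellite at any considered
    charge return an empty set, meaning "charge unknown" — they stay usable
    at every charge.  This is how the degeneracy between [M+2NH4]2+ of a
    composition X2 and [M+NH4]+ of X (numerically identical m/z) is
    resolved, exactly as an analyst reads isotope spacing on the instrument.
    """
    charges = tuple(charges)
    out = []
    for idx in range(len(spectrum)):
        support = frozenset(
            z
            for z in charges
            if _has_satellite(
                spectrum, float(spectrum.mz[idx]), float(spectrum.intensity[idx]), z, tol
            )
        )
        out.append(support)
    return out


def extract_ladders(
    spectrum: CentroidSpectrum,
    repeats: Mapping[str, float] | None = None,
    tol: float = 0.001,
    charges: Iterable[int] = (1, 2),
    min_length: int = 2,
    peak_charges: Sequence[frozenset[int]] | None = None,
) -> list[IonSequence]:
    """Find maximal ion ladders for each repeat family and charge.

    A ladder is a chain of peaks whose successive m/z values differ by
    ``repeat_mass / z`` within ``+/-tol``.  Chains are grown greedily from
    the lowest-m/z member (a peak with no in-tolerance predecessor), always
    choosing the candidate with the smallest deviation from the expected
    m/z, ties broken by higher intensity.  Chains wholly contained in a
    longer chain of the same family and charge are dropped.

    ``peak_charges`` (from :func:`infer_peak_charges`) restricts each peak
    to chains of a charge its isotope satellite supports; peaks without
    satellite evidence remain usable at every charge.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if min_length < 2:
        raise ValueError(
            "a ladder needs at least 2 ions; match isolated peaks with "
            "match_singletons (run_di_extraction(include_singletons=True))"
        )
    repeats = dict(repeats) if repeats is not None else dict(REPEAT_MASSES)
    mz, inten = spectrum.mz, spectrum.intensity

    def compatible(idx: int, z: int) -> bool:
        if peak_charges is None:
            return True
        support = peak_charges[idx]
        return not support or z in support

    chains: list[IonSequence] = []
    for family, repeat_mass in repeats.items():
        for z in charges:
            spacing = repeat_mass / z
            for start in range(len(mz)):
                if not compatible(start, z):
                    continue
                # only seed where the chain cannot extend to the left
                left = [
                    i for i in _candidates(mz, mz[start] - spacing, tol)
                    if compatible(int(i), z)
                ]
                if left:
                    continue
                members = [start]
                while True:
                    cand = [
                        int(i)
                        for i in _candidates(mz, mz[members[-1]] + spacing, tol)
                        if compatible(int(i), z)
                    ]
                    if not cand:
                        break
                    cand = np.asarray(cand)
                    dev = np.abs(mz[cand] - (mz[members[-1]] + spacing))
                    best = cand[np.lexsort((-inten[cand], dev))][0]
                    members.append(int(best))
                if len(members) >= min_length:
                    chains.append(
                        IonSequence(
                            family=family,
                            charge=z,
                            indices=tuple(members),
                            mzs=tuple(float(m) for m in mz[members]),
                            intensities=tuple(float(i) for i in inten[members]),
                        )
                    )
    # drop chains contained in a longer chain of the same family and charge
    kept: list[IonSequence] = []
    sets = [set(c.indices) for c in chains]
    for i, chain in enumerate(chains):
        contained = any(
            j != i
            and chains[j].family == chain.family
            and chains[j].charge == chain.charge
            and len(chains[j]) > len(chain)
            and sets[i] <= sets[j]
            for j in range(len(chains))
        )
        if not contained:
            kept.append(chain)
    kept.sort(key=lambda c: (c.mzs[0], c.family, c.charge))
    return kept


def _best_hypothesis(mz_value, db, adducts, charge, tol):
    best = None
    for name in adducts:
        adduct = fm.get_adduct(name)
        if adduct.z != charge:
            continue
        neutral = fm.neutral_mass_from_mz(mz_value, adduct)
        hits = match_neutral(neutral, db, tol)
        if len(hits):
            top = hits.iloc[0]
            key = (abs(top["error"]), _ADDUCT_PRIORITY.get(name, 99))
            if best is None or key < best[0]:
                best = (key, name, top)
    return best


def _db_family_sets(db: pd.DataFrame) -> set[frozenset]:
    """Repeat-family combinations present in the predicted database."""
    cols = [c for c in _COUNT_COLUMNS.values() if c in db.columns]
    sets = set()
    for _, row in db[cols].drop_duplicates().iterrows():
        sets.add(
            frozenset(
                family
                for family, col in _COUNT_COLUMNS.items()
                if col in db.columns and int(row[col]) > 0
            )
        )
    return sets


def assign_sequence(
    seq: IonSequence,
    db: pd.DataFrame,
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    tol: float = 0.001,
    allowed_family_sets: set[frozenset] | None = None,
) -> IonSequence:
    """Assign species, adduct and charge to a ladder via the database.

    The lowest-m/z ion is converted to a neutral mass under every supported
    adduct hypothesis at the ladder's charge; the database match with the
    smallest absolute error fixes the adduct for the whole ladder (ties go
    to NH4+ over H+ over Na+), and consecutive members are assigned as the
    anchor species plus one repeat unit per step.  If the first ion matches
    nothing, the anchor slides to later members and earlier ions stay
    formula-only; a ladder with no matchable member is returned unassigned.

    Extension is only propagated into repeat-family combinations that the
    predicted database itself contains: one repeat unit of family B weighs
    exactly the same wherever it is attached, so without this constraint a
    ladder could "grow" a copolymer family the material cannot produce
    (e.g. a lactate ring extended by butylene sebacate is an exact-mass
    isomer of an adipate ring).  Members whose extension is rejected stay
    formula-only.
    """
    if not len(seq):
        raise ValueError("cannot assign an empty sequence")
    if allowed_family_sets is None:
        allowed_family_sets = _db_family_sets(db)
    anchor_pos, best = 0, None
    for pos in range(len(seq)):
        best = _best_hypothesis(seq.mzs[pos], db, adducts, seq.charge, tol)
        if best is not None:
            anchor_pos = pos
            break
    if best is None:
        seq.adduct = None
        seq.anchor_species = None
        seq.assigned = []
        return seq
    _, adduct_name, row = best
    adduct = fm.get_adduct(adduct_name)
    anchor = species_from_row(row)
    seq.adduct = adduct_name
    seq.anchor_species = anchor
    assigned: list[AssignedIon] = []
    for pos in range(len(seq)):
        step = pos - anchor_pos
        try:
            species = anchor.extend(seq.family, step) if step else anchor
        except ValueError:
            species = None  # backwards extension below zero units
        if species is not None and not any(
            frozenset(species.counts) <= allowed for allowed in allowed_family_sets
        ):
            species = None  # family combination outside the predicted grammar
        if species is None:
            assigned.append(
                AssignedIon(
                    index=seq.indices[pos], mz=seq.mzs[pos],
                    intensity=seq.intensities[pos], adduct=adduct_name,
                    charge=seq.charge, species=None, ion_formula=None,
                    error_da=None, error_ppm=None,
                )
            )
            continue
        theo = fm.adduct_mz(species.formula, adduct)
        err = fm.mass_error(seq.mzs[pos], theo)
        ion_formula = species.formula + adduct.k * adduct.delta
        assigned.append(
            AssignedIon(
                index=seq.indices[pos], mz=seq.mzs[pos],
                intensity=seq.intensities[pos], adduct=adduct_name,
                charge=seq.charge, species=species.label,
                ion_formula=str(ion_formula),
                error_da=err.delta_da, error_ppm=err.delta_ppm,
            )
        )
    seq.assigned = assigned
    return seq


def _has_satellite(
    spectrum: CentroidSpectrum,
    mz_value: float,
    intensity: float,
    z: int,
    tol: float,
    require_weaker: bool = False,
) -> bool:
    """Is there a 13C companion at +1.00335/z?

    ``require_weaker`` additionally demands the companion be less intense
    than the parent.  That is appropriate when deciding which peak is the
    isotopologue, but not for charge inference: above roughly 91 carbons
    the one-13C isotopologue is genuinely more intense than the
    monoisotopic peak, so charge support relies on spacing alone.
    """
    for idx in _candidates(spectrum.mz, mz_value + fm.C13_SHIFT / z, tol):
        companion = spectrum.intensity[idx]
        if companion > 0 and (not require_weaker or companion < intensity):
            return True
    return False


def validate_charge_states(
    sequences: Iterable[IonSequence],
    spectrum: CentroidSpectrum,
    charges: Iterable[int] = (1, 2),
    tol: float = 0.001,
) -> None:
    """Cross-check each assigned ion's charge against its 13C satellite.

    The m/z of [M+2NH4]2+ for a composition X2 coincides exactly with
    [M+NH4]+ of X, so a peak's charge cannot always be inferred from ladder
    spacing alone.  The 13C satellite disambiguates: it sits at +1.00335/z.
    An ion whose claimed charge has no supporting satellite, while another
    allowed charge does have one, is marked charge-inconsistent and excluded
    from component summaries.  Spectra without satellites are unaffected.
    """
    charges = tuple(charges)
    for seq in sequences:
        for ion in seq.assigned or []:
            if ion.species is None:
                continue
            if _has_satellite(spectrum, ion.mz, ion.intensity, ion.charge, tol):
                continue
            for other in charges:
                if other != ion.charge and _has_satellite(
                    spectrum, ion.mz, ion.intensity, other, tol
                ):
                    ion.charge_consistent = False
                    break


def flag_isotopologues(
    sequences: Iterable[IonSequence],
    spectrum: CentroidSpectrum,
    tol: float = 0.001,
) -> dict[int, str]:
    """Flag 13C/18O satellite peaks of assigned ions.

    A peak at parent m/z + 1.00335/z (13C) or + 2.00425/z (18O), within
    ``tol`` and strictly less intense than its parent, is an isotopologue;
    flagged peak indices are excluded from component summaries.  Satellites
    of consecutive ladder members are themselves repeat-spaced, so whole
    satellite ladders are removed this way.
    """
    flags: dict[int, str] = {}
    shifts = {"13C": fm.C13_SHIFT, "18O": fm.O18_SHIFT}
    for seq in sequences:
        for ion in seq.assigned or []:
            if ion.species is None:
                continue
            for kind, shift in shifts.items():
                for idx in _candidates(spectrum.mz, ion.mz + shift / seq.charge, tol):
                    if spectrum.intensity[idx] < ion.intensity:
                        # 13C takes precedence if both windows hit
                        flags.setdefault(int(idx), kind)
    # mark flags on any assigned ions that sit on flagged peaks
    for seq in sequences:
        for ion in seq.assigned or []:
            if ion.index in flags:
                ion.isotopologue = flags[ion.index]
    return flags


def summarize_components(
    sequences: Iterable[IonSequence],
    iso_flags: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Deduplicate assigned ions into one row per unique species.

    Isotopologue-flagged peaks and formula-only ions are excluded.  The
    table reports, per species, the supporting ion/ladder counts and the
    set of adducts and charges observed.
    """
    iso_flags = iso_flags or {}
    records: dict[str, dict] = {}
    for seq_id, seq in enumerate(sequences):
        for ion in seq.assigned or []:
            if (
                ion.species is None
                or ion.index in iso_flags
                or ion.isotopologue
                or not ion.charge_consistent
            ):
                continue
            rec = records.setdefault(
                ion.species,
                {
                    "species": ion.species,
                    "formula": ion.ion_formula,
                    "n_ions": 0,
                    "sequence_ids": set(),
                    "adducts": set(),
                    "charges": set(),
                    "max_abs_error_da": 0.0,
                },
            )
            rec["n_ions"] += 1
            rec["sequence_ids"].add(seq_id)
            rec["adducts"].add(ion.adduct)
            rec["charges"].add(ion.charge)
            rec["max_abs_error_da"] = max(rec["max_abs_error_da"], abs(ion.error_da))
    rows = []
    for rec in records.values():
        rows.append(
            {
                "species": rec["species"],
                "n_ions": rec["n_ions"],
                "n_sequences": len(rec["sequence_ids"]),
                "adducts": ";".join(sorted(rec["adducts"])),
                "charges": ";".join(str(z) for z in sorted(rec["charges"])),
                "max_abs_error_da": rec["max_abs_error_da"],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "species", "n_ions", "n_sequences", "adducts", "charges",
            "max_abs_error_da",
        ],
    )
    return out.sort_values("species", kind="mergesort").reset_index(drop=True) if len(out) else out


def match_singletons(
    spectrum: CentroidSpectrum,
    db: pd.DataFrame,
    used_indices: set[int],
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    tol: float = 0.001,
    charges: Iterable[int] = (1,),
) -> list[IonSequence]:
    """Match ladder-orphan peaks directly against the database.

    Single-charge adduct hypotheses only by default: without ladder spacing
    there is no independent evidence for a higher charge state, and the
    doubly charged reading of an [M+NH4]+ ion is numerically degenerate
    with the dimer composition.
    """
    out = []
    for idx in range(len(spectrum)):
        if idx in used_indices:
            continue
        for z in charges:
            best = _best_hypothesis(spectrum.mz[idx], db, adducts, z, tol)
            if best is None:
                continue
            seq = IonSequence(
                family="singleton",
                charge=z,
                indices=(idx,),
                mzs=(float(spectrum.mz[idx]),),
                intensities=(float(spectrum.intensity[idx]),),
            )
            assign_sequence(seq, db, adducts, tol)
            if seq.is_assigned:
                out.append(seq)
            break
    return out


@dataclass
class DIResult:
    """Everything the direct-infusion stage produces."""

    spectrum: CentroidSpectrum          # threshold-filtered spectrum
    sequences: list[IonSequence]
    iso_flags: dict[int, str]
    components: pd.DataFrame
    counts: dict[str, int]

    @property
    def mass_errors_da(self) -> np.ndarray:
        errs = [
            ion.error_da
            for seq in self.sequences
            for ion in seq.assigned or []
            if ion.error_da is not None and not ion.isotopologue
        ]
        return np.asarray(errs)

    def sequences_frame(self) -> pd.DataFrame:
        rows = []
        for seq_id, seq in enumerate(self.sequences):
            for pos in range(len(seq)):
                ion = (seq.assigned or [None] * len(seq))[pos] if seq.assigned else None
                rows.append(
                    {
                        "sequence_id": seq_id,
                        "family": seq.family,
                        "charge": seq.charge,
                        "adduct": seq.adduct,
                        "position": pos,
                        "mz": seq.mzs[pos],
                        "intensity": seq.intensities[pos],
                        "species": ion.species if ion else None,
                        "ion_formula": ion.ion_formula if ion else None,
                        "error_da": ion.error_da if ion else None,
                        "error_ppm": ion.error_ppm if ion else None,
                        "isotopologue": ion.isotopologue if ion else None,
                    }
                )
        return pd.DataFrame(rows)


def run_di_extraction(
    spectrum: CentroidSpectrum,
    db: pd.DataFrame,
    min_intensity: float = 1e4,
    tol: float = 0.001,
    charges: Iterable[int] = (1, 2),
    min_length: int = 2,
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    include_singletons: bool = False,
    validate_charges: bool = True,
) -> DIResult:
    """Threshold, extract, assign, de-isotope and summarize in one call."""
    filtered = threshold_filter(spectrum, min_intensity)
    peak_charges = (
        infer_peak_charges(filtered, charges, tol) if validate_charges else None
    )
    sequences = extract_ladders(
        filtered, tol=tol, charges=charges, min_length=min_length,
        peak_charges=peak_charges,
    )
    family_sets = _db_family_sets(db)
    for seq in sequences:
        assign_sequence(seq, db, adducts, tol, allowed_family_sets=family_sets)
    if validate_charges:
        validate_charge_states(sequences, filtered, charges, tol)
    iso_flags = flag_isotopologues(sequences, filtered, tol)
    if include_singletons:
        used = {i for s in sequences for i in s.indices} | set(iso_flags)
        sequences = sequences + match_singletons(filtered, db, used, adducts, tol)
        if validate_charges:
            validate_charge_states(sequences, filtered, charges, tol)
        iso_flags = flag_isotopologues(sequences, filtered, tol)
    components = summarize_components(sequences, iso_flags)
    counts = {
        "peaks": len(filtered),
        "sequences": len(sequences),
        "assigned_sequences": sum(1 for s in sequences if s.is_assigned),
        "isotopologue_peaks": len(iso_flags),
        "components": len(components),
    }
    return DIResult(filtered, sequences, iso_flags, components, counts)
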
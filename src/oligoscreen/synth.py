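"""Seeded synthetic data and the packaged component catalogue.

Every pipeline stage in this package can be exercised without instrument
data: this module simulates direct-infusion spectra containing oligomer ion
ladders (with adducts, 13C satellites, intensity decay, mass jitter and
noise peaks), NMR signal tables, and GC run tables, each from a fixed seed
with byte-identical output, and each paired with the ground truth needed to
score the analysis stages.

It also ships the catalogue of components reported for the reference
PLA/PBAT mulch film (assignments, characteristic ions, concentrations) as a
versioned CSV inside the package.

What the spectrum generator emulates -- and what it does not: planted peaks
sit at the theoretical adduct m/z plus bounded jitter, series intensities
decay geometrically (as observed for real oligoester series), satellites
use a crude one-13C abundance heuristic (1.1% per carbon), and noise is
uniform in m/z.  Real electrospray ionisation efficiency, ion suppression
and full isotope patterns are deliberately out of scope.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import formula as fm
from .database import OligoesterSpecies
from .di import CentroidSpectrum

__all__ = [
    "SeriesPlan",
    "GroundTruth",
    "random_series_plans",
    "simulate_di_spectrum",
    "simulate_nmr_integrals",
    "simulate_gc_run",
    "component_catalogue",
    "parse_ions",
    "catalogue_species",
]

DEFAULT_SCAN_RANGE = (150.0, 2000.0)


@dataclass(frozen=True)
class SeriesPlan:
    """One planted oligomer series.

    ``seed_species`` is the smallest member; ``extend_family`` the repeat
    unit added per step (must already be present or addable); ``n_members``
    the series length (1 = a single species).  Intensities decay
    geometrically: member k has intensity ``base_intensity * decay**k``.
    """

    seed_species: OligoesterSpecies
    adduct: str
    n_members: int = 1
    extend_family: str | None = None
    base_intensity: float = 1e6
    decay: float = 0.7

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("a series needs at least one member")
        if not self.base_intensity > 0:
            raise ValueError("base intensity must be positive")
        if not (0 < self.decay <= 1):
            raise ValueError("decay factor must be in (0, 1]")
        if self.n_members > 1 and self.extend_family is None:
            raise ValueError("multi-member series need an extension family")

    def members(self) -> list[OligoesterSpecies]:
        out = [self.seed_species]
        for k in range(1, self.n_members):
            out.append(self.seed_species.extend(self.extend_family, k))
        return out


@dataclass
class GroundTruth:
    """Everything needed to score an extraction run against the truth."""

    seed: int
    species: set[str]
    ions: pd.DataFrame    # label, adduct, charge, theoretical/observed m/z, ...
    noise: pd.DataFrame   # mz, intensity

    @property
    def parent_ions(self) -> pd.DataFrame:
        return self.ions.loc[~self.ions["is_satellite"]]


def random_series_plans(
    db: pd.DataFrame,
    n_plans: int,
    seed: int = 0,
    adducts: Sequence[str] = ("[M+NH4]+", "[M+H]+", "[M+Na]+", "[M+2NH4]2+"),
    n_members: tuple[int, int] = (2, 5),
    base_intensity_log10: tuple[float, float] = (6.0, 7.0),
    decay: tuple[float, float] = (0.5, 0.9),
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
) -> list[SeriesPlan]:
    """Sample random but acquisition-consistent series plans from a database.

    Seeds are drawn from the database rows, the extension family from the
    families present in the seed, and the adduct/length/intensity/decay from
    the given ranges.  Candidate plans whose members would fall outside the
    scan range are rejected and redrawn, so every planted ladder is fully
    acquirable.
    """
    rng = np.random.default_rng(seed)
    plans: list[SeriesPlan] = []
    attempts = 0
    while len(plans) < n_plans:
        attempts += 1
        if attempts > 200 * n_plans:
            raise RuntimeError("could not sample enough in-range series plans")
        row = db.iloc[int(rng.integers(len(db)))]
        from .database import species_from_row

        species = species_from_row(row)
        families = list(species.counts)
        family = families[int(rng.integers(len(families)))]
        adduct_name = str(adducts[int(rng.integers(len(adducts)))])
        adduct = fm.get_adduct(adduct_name)
        members = int(rng.integers(n_members[0], n_members[1] + 1))
        first = fm.adduct_mz(species.formula, adduct)
        last = fm.adduct_mz(
            species.extend(family, members - 1).formula, adduct
        )
        if not (scan_range[0] <= first and last <= scan_range[1]):
            continue
        plans.append(
            SeriesPlan(
                seed_species=species,
                adduct=adduct_name,
                n_members=members,
                extend_family=family,
                base_intensity=float(10 ** rng.uniform(*base_intensity_log10)),
                decay=float(rng.uniform(*decay)),
            )
        )
    return plans


def simulate_di_spectrum(
    plans: Sequence[SeriesPlan],
    jitter_sd: float = 0.0,
    n_noise: int = 0,
    noise_intensity_range: tuple[float, float] = (1e2, 9.9e3),
    seed: int = 0,
    add_satellites: bool = False,
    satellite_abundance_per_c: float = 0.011,
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
    guard_band: float = 0.005,
    clip_to_scan_range: bool = True,
) -> tuple[CentroidSpectrum, GroundTruth]:
    """Simulate a centroided positive-mode direct-infusion spectrum.

    Planted peaks sit at the theoretical adduct m/z plus Gaussian jitter
    truncated at +/-2.5 sigma (so a jitter_sd of 0.0002 Da keeps every
    deviation within 0.0005 Da, half the extraction tolerance).  Optional
    one-13C satellites are planted at +1.00335/z with relative intensity
    ``satellite_abundance_per_c`` per carbon atom.  Noise peaks are uniform
    in m/z but excluded from a ``guard_band`` window around planted peaks so
    ground-truth scoring stays unambiguous.  Members falling outside the
    scan range are clipped (with a warning in the metadata) unless
    ``clip_to_scan_range`` is False, in which case they raise.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for plan_id, plan in enumerate(plans):
        adduct = fm.get_adduct(plan.adduct)
        for k, species in enumerate(plan.members()):
            theo = fm.adduct_mz(species.formula, adduct)
            in_range = scan_range[0] <= theo <= scan_range[1]
            if not in_range and not clip_to_scan_range:
                raise ValueError(
                    f"{species.label} at m/z {theo:.4f} is outside the scan range"
                )
            jitter = float(np.clip(rng.normal(0.0, jitter_sd), -2.5 * jitter_sd, 2.5 * jitter_sd)) if jitter_sd else 0.0
            intensity = plan.base_intensity * plan.decay**k
            records.append(
                {
                    "plan_id": plan_id,
                    "label": species.label,
                    "formula": str(species.formula),
                    "adduct": plan.adduct,
                    "charge": adduct.z,
                    "theoretical_mz": theo,
                    "observed_mz": theo + jitter,
                    "intensity": intensity,
                    "is_satellite": False,
                    "in_scan_range": in_range,
                }
            )
            if add_satellites:
                n_carbon = species.formula.get("C", 0) + adduct.k * adduct.delta.get("C", 0)
                sat_mz = theo + fm.C13_SHIFT / adduct.z
                sat_int = satellite_abundance_per_c * n_carbon * intensity
                records.append(
                    {
                        "plan_id": plan_id,
                        "label": species.label,
                        "formula": str(species.formula),
                        "adduct": plan.adduct,
                        "charge": adduct.z,
                        "theoretical_mz": sat_mz,
                        "observed_mz": sat_mz + (float(np.clip(rng.normal(0.0, jitter_sd), -2.5 * jitter_sd, 2.5 * jitter_sd)) if jitter_sd else 0.0),
                        "intensity": sat_int,
                        "is_satellite": True,
                        "in_scan_range": scan_range[0] <= sat_mz <= scan_range[1],
                    }
                )
    ions = pd.DataFrame(
        records,
        columns=[
            "plan_id", "label", "formula", "adduct", "charge",
            "theoretical_mz", "observed_mz", "intensity",
            "is_satellite", "in_scan_range",
        ],
    )
    clipped = ions.loc[~ions["in_scan_range"]] if len(ions) else ions
    kept = ions.loc[ions["in_scan_range"]] if len(ions) else ions

    planted_mz = kept["observed_mz"].to_numpy() if len(kept) else np.empty(0)
    noise_mz: list[float] = []
    while len(noise_mz) < n_noise:
        draw = rng.uniform(scan_range[0], scan_range[1], size=max(n_noise, 16))
        for value in draw:
            if len(noise_mz) >= n_noise:
                break
            if len(planted_mz) and np.min(np.abs(planted_mz - value)) < guard_band:
                continue
            noise_mz.append(float(value))
    noise_int = rng.uniform(*noise_intensity_range, size=len(noise_mz))
    noise = pd.DataFrame({"mz": noise_mz, "intensity": noise_int})

    all_mz = np.concatenate([planted_mz, noise["mz"].to_numpy()])
    all_int = np.concatenate(
        [kept["intensity"].to_numpy() if len(kept) else np.empty(0), noise_int]
    )
    metadata = {
        "polarity": "positive",
        "scan_range": scan_range,
        "seed": seed,
    }
    if len(clipped):
        metadata["clipped_ions"] = len(clipped)
    spectrum = CentroidSpectrum(all_mz, all_int, metadata)
    truth = GroundTruth(
        seed=seed,
        species=set(kept.loc[~kept["is_satellite"], "label"]),
        ions=kept.reset_index(drop=True),
        noise=noise,
    )
    return spectrum, truth


def simulate_nmr_integrals(
    mol_percents: Sequence[float] | dict[str, float],
    proton_counts: Sequence[int] | dict[str, int],
    mws: Sequence[float] | dict[str, float] | None = None,
    noise_sd: float = 0.0,
    scale: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an NMR signal table from a known molar composition.

    Inverts the molar-percentage equation: the integral of polymer i is
    proportional to mol%_i * m_i, scaled arbitrarily, with optional
    multiplicative Gaussian noise.  ``mol_percents`` must sum to 100.
    """
    if isinstance(mol_percents, dict):
        polymers = list(mol_percents)
        percents = np.array([mol_percents[p] for p in polymers], dtype=float)
    else:
        percents = np.asarray(mol_percents, dtype=float)
        polymers = [f"polymer{i + 1}" for i in range(len(percents))]
    if abs(percents.sum() - 100.0) > 1e-6:
        raise ValueError(f"mol percents must sum to 100, got {percents.sum()!r}")
    if isinstance(proton_counts, dict):
        protons = np.array([proton_counts[p] for p in polymers], dtype=int)
    else:
        protons = np.asarray(proton_counts, dtype=int)
    if len(protons) != len(percents):
        raise ValueError("proton counts and mol percents differ in length")
    rng = np.random.default_rng(seed)
    integrals = scale * percents * protons
    if noise_sd:
        integrals = integrals * (1.0 + rng.normal(0.0, noise_sd, size=len(integrals)))
    table = pd.DataFrame(
        {
            "polymer": polymers,
            "signal": [chr(ord("a") + i) for i in range(len(polymers))],
            "integral": integrals,
            "protons": protons,
        }
    )
    if mws is not None:
        if isinstance(mws, dict):
            table["mw"] = [mws[p] for p in polymers]
        else:
            table["mw"] = np.asarray(mws, dtype=float)
    return table


def simulate_gc_run(
    concentrations: dict[str, float],
    rfs: dict[str, float],
    m_is_ug: float = 250.0,
    sample_g: float = 0.1,
    area_is: float = 1e6,
    noise_sd: float = 0.0,
    seed: int = 0,
    is_name: str = "BBP",
) -> pd.DataFrame:
    """Generate a GC run table (analyte areas plus the IS row).

    Inverts the quantification equation: area_i = conc_i * RF_i * m_sample
    / m_IS * area_IS, with optional multiplicative Gaussian noise applied to
    every area including the internal standard.
    """
    for name, value in (("m_is_ug", m_is_ug), ("sample_g", sample_g), ("area_is", area_is)):
        if not value > 0:
            raise ValueError(f"{name} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for analyte, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {analyte!r}")
        area = conc * rfs[analyte] * sample_g / m_is_ug * area_is
        rows.append({"analyte": analyte, "area": area})
    rows.append({"analyte": is_name, "area": area_is})
    run = pd.DataFrame(rows)
    if noise_sd:
        run["area"] = run["area"] * (1.0 + rng.normal(0.0, noise_sd, size=len(run)))
    return run


# -- packaged catalogue ---------------------------------------------------

def component_catalogue() -> pd.DataFrame:
    """The packaged catalogue of reported mulch-film components.

    One row per printed catalogue entry: assignment label, component type,
    size ranges, GC-MS and HPLC-MS/MS characteristic ions (semicolon
    separated; "ND" = not detected), a raw direct-infusion detection note,
    reference-standard confirmation, concentration (ug per g film, with sd;
    surrogate-RF-quantified values flagged), and -- for oligoester rows -- a
    representative composition (the top of the printed range) used by the
    diagnostic-ion regression.
    """
    ref = importlib.resources.files("oligoscreen.data") / "mulch_film_catalogue.csv"
    with importlib.resources.as_file(ref) as path:
        cat = pd.read_csv(
            path,
            dtype={"n": "string", "m": "string"},
        )
    cat["di_detected"] = ~cat["di_orbitrap"].isin(["ND", "-"])
    for col in ("confirmed", "surrogate_rf", "mstfa_derivatised"):
        cat[col] = cat[col].fillna("no").eq("yes")
    return cat


def parse_ions(cell: str) -> list[float]:
    """Parse a semicolon-separated characteristic-ion cell; ND -> []."""
    if not isinstance(cell, str) or cell.strip() in ("", "ND", "-"):
        return []
    return [float(tok) for tok in cell.split(";")]


def catalogue_species(row: pd.Series) -> OligoesterSpecies | None:
    """Representative species behind a catalogue row (None for additives)."""
    if not isinstance(row.get("topology"), str) or row["topology"] not in ("cyclic", "linear"):
        return None
    comp = {
        family: int(row[f"rep_{family.replace('-', '_')}"])
        for family in ("AA-BD", "TA-BD", "SeA-BD", "LA")
        if int(row[f"rep_{family.replace('-', '_')}"]) > 0
    }
    return OligoesterSpecies.make(row["topology"], comp, row["end_group"])
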
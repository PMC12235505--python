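"""Predicted oligoester structure database.

Biodegradable PLA/PBAT(/PBSeT) mulch films shed short cyclic and linear
oligoesters built from four condensed repeat units: lactate (LA) and the
diacid-butanediol esters butylene adipate (AA-BD), butylene terephthalate
(TA-BD) and butylene sebacate (SeA-BD).  This module defines those building
blocks, enumerates a combinatorial database of candidate species with exact
formulas and monoisotopic masses, and matches observed neutral masses
against it.

A species is a multiset of repeat units plus a topology/end-group choice:

* ``cyclic`` — no end group; the formula is exactly the sum of its repeats.
* ``linear`` with a ``free`` end (add H2O), a ``methyl_capped`` end (add
  CH4O, e.g. methyl-capped PLA oligomers), or a ``bd_capped`` end (add a
  whole 1,4-butanediol, C4H10O2).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formula import ElementalFormula, monoisotopic_mass

__all__ = [
    "Monomer",
    "MONOMERS",
    "REPEAT_UNITS",
    "REPEAT_MASSES",
    "FAMILY_ORDER",
    "END_GROUPS",
    "OligoesterSpecies",
    "EnumerationRule",
    "DatabaseConfig",
    "default_config",
    "species_formula",
    "enumerate_database",
    "match_neutral",
    "species_from_row",
    "write_database_csv",
    "read_database_csv",
    "write_database_json",
    "read_database_json",
]


@dataclass(frozen=True)
class Monomer:
    """A free monomer as dosed into the polymer synthesis."""

    name: str
    formula: ElementalFormula


MONOMERS: dict[str, Monomer] = {
    "AA": Monomer("AA", ElementalFormula.from_string("C6H10O4")),   # adipic acid
    "TA": Monomer("TA", ElementalFormula.from_string("C8H6O4")),    # terephthalic acid
    "SeA": Monomer("SeA", ElementalFormula.from_string("C10H18O4")),  # sebacic acid
    "BD": Monomer("BD", ElementalFormula.from_string("C4H10O2")),   # 1,4-butanediol
    "LA": Monomer("LA", ElementalFormula.from_string("C3H6O3")),    # lactic acid
}

_WATER = ElementalFormula.from_string("H2O")

#: Condensed repeat units: diacid + BD - 2 H2O, or LA - H2O for lactate.
REPEAT_UNITS: dict[str, ElementalFormula] = {
    "AA-BD": MONOMERS["AA"].formula + MONOMERS["BD"].formula - 2 * _WATER,
    "TA-BD": MONOMERS["TA"].formula + MONOMERS["BD"].formula - 2 * _WATER,
    "SeA-BD": MONOMERS["SeA"].formula + MONOMERS["BD"].formula - 2 * _WATER,
    "LA": MONOMERS["LA"].formula - _WATER,
}

#: Monoisotopic repeat-unit masses; these are the ladder spacings used by
#: direct-infusion sequence extraction.
REPEAT_MASSES: dict[str, float] = {
    name: monoisotopic_mass(f) for name, f in REPEAT_UNITS.items()
}

#: Canonical family order for labels, making deduplication string-stable.
FAMILY_ORDER: tuple[str, ...] = ("AA-BD", "TA-BD", "SeA-BD", "LA")

#: End-group formula additions per linear cap (cyclic species add nothing).
END_GROUPS: dict[str, ElementalFormula] = {
    "none": ElementalFormula(),
    "free": _WATER,
    "methyl_capped": ElementalFormula.from_string("CH4O"),
    "bd_capped": MONOMERS["BD"].formula,
}

TOPOLOGIES = ("cyclic", "linear")


def _normalize_composition(composition: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
    comp = {}
    for family, count in composition.items():
        if family not in REPEAT_UNITS:
            raise ValueError(
                f"unknown repeat-unit family {family!r}; known: {sorted(REPEAT_UNITS)}"
            )
        if count < 0:
            raise ValueError(f"negative repeat count for {family!r}")
        if count > 0:
            comp[family] = int(count)
    return tuple((f, comp[f]) for f in FAMILY_ORDER if f in comp)


@dataclass(frozen=True)
class OligoesterSpecies:
    """A candidate oligoester: topology, repeat-unit multiset, end group."""

    topology: str
    composition: tuple[tuple[str, int], ...]
    end_group: str = "none"

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        if self.end_group not in END_GROUPS:
            raise ValueError(f"end group must be one of {sorted(END_GROUPS)}")
        comp = _normalize_composition(dict(self.composition))
        object.__setattr__(self, "composition", comp)
        if self.total_units == 0:
            raise ValueError("species must contain at least one repeat unit")
        if self.topology == "cyclic" and self.end_group != "none":
            raise ValueError("cyclic species cannot carry an end group")
        if self.topology == "linear" and self.end_group == "none":
            raise ValueError("linear species must declare an end group")

    @classmethod
    def make(
        cls,
        topology: str,
        composition: Mapping[str, int],
        end_group: str | None = None,
    ) -> "OligoesterSpecies":
        if end_group is None:
            end_group = "none" if topology == "cyclic" else "free"
        return cls(topology, tuple(composition.items()), end_group)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.composition)

    @property
    def total_units(self) -> int:
        return sum(c for _, c in self.composition)

    @property
    def formula(self) -> ElementalFormula:
        return species_formula(self)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(species_formula(self))

    @property
    def label(self) -> str:
        core = "-".join(
            f"[{family}]{count if count > 1 else ''}" for family, count in self.composition
        )
        if self.topology == "cyclic":
            return f"cyclic {core}"
        prefix = {"free": "linear ", "methyl_capped": "Me-", "bd_capped": "BD-"}[self.end_group]
        return f"{prefix}{core}"

    def extend(self, family: str, n: int = 1) -> "OligoesterSpecies":
        """Return the species with ``n`` extra repeat units of ``family``.

        ``n`` may be negative (used when a ladder is assigned backwards from
        an anchor ion); the result must keep all counts non-negative.
        """
        counts = self.counts
        counts[family] = counts.get(family, 0) + n
        if counts[family] < 0:
            raise ValueError(f"extension drives {family!r} count negative")
        return replace(self, composition=tuple(counts.items()))


def species_formula(species: OligoesterSpecies) -> ElementalFormula:
    """Elemental formula of a species: sum of repeats plus the end group."""
    total = ElementalFormula()
    for family, count in species.composition:
        total = total + count * REPEAT_UNITS[family]
    return total + END_GROUPS[species.end_group]


@dataclass(frozen=True)
class EnumerationRule:
    """One block of the database grammar.

    Enumerates every composition with per-family counts up to ``max_counts``
    (families absent from the map are excluded) and total repeat count in
    ``[min_total, max_total]``, at the given topology/end group.
    """

    topology: str
    end_group: str
    max_counts: tuple[tuple[str, int], ...]
    min_total: int = 1
    max_total: int = 9
    #: require every listed family to appear at least once (true mixed rule)
    require_all_families: bool = False

    def __post_init__(self):
        object.__setattr__(self, "max_counts", tuple(dict(self.max_counts).items()))


@dataclass(frozen=True)
class DatabaseConfig:
    """Enumeration bounds for :func:`enumerate_database`."""

    rules: tuple[EnumerationRule, ...]
    #: Minimum ring size (in repeat units) when a family is present in a
    #: cyclic species; lactide ([LA]2) is the smallest lactate ring observed,
    #: while cyclic [AA-BD] shows that single diacid-diol rings occur.
    min_cyclic_units: tuple[tuple[str, int], ...] = (
        ("AA-BD", 1), ("TA-BD", 1), ("SeA-BD", 1), ("LA", 2),
    )
    safety_cap: int = 100_000

    def __post_init__(self):
        object.__setattr__(self, "min_cyclic_units", tuple(dict(self.min_cyclic_units).items()))


def default_config() -> DatabaseConfig:
    """Default database mirroring the component ranges observed in the film.

    Homopolymer cyclics at the observed ranges ([LA]n n=2-12, [AA-BD]n
    n=1-6, [TA-BD]n n=2-3, [SeA-BD]n n=1-4); mixed cyclics only for the two
    copolymer pairs the material actually contains (AA-BD/TA-BD from PBAT
    and TA-BD/SeA-BD from PBSeT) up to 9 total units; methyl-capped PLA
    oligomers up to 20 lactate units, optionally carrying AA-BD units; and
    free or BD-capped linear PBAT species up to 7 units.  Unrestricted
    four-family mixing is deliberately excluded: it creates exact isomer
    collisions (e.g. [SeA-BD]+2[LA] shares C20H32O8 with 2[AA-BD]) that
    would make exact-mass matching ambiguous.
    """
    rules = (
        # homopolymer cyclics
        EnumerationRule("cyclic", "none", (("LA", 12),), 2, 12),
        EnumerationRule("cyclic", "none", (("AA-BD", 6),), 1, 6),
        EnumerationRule("cyclic", "none", (("TA-BD", 3),), 2, 3),
        EnumerationRule("cyclic", "none", (("SeA-BD", 4),), 1, 4),
        # mixed cyclics, observed copolymer pairs only
        EnumerationRule("cyclic", "none", (("AA-BD", 8), ("TA-BD", 8)), 2, 9,
                        require_all_families=True),
        EnumerationRule("cyclic", "none", (("TA-BD", 8), ("SeA-BD", 8)), 2, 9,
                        require_all_families=True),
        # methyl-capped PLA oligomers, optionally with AA-BD units
        EnumerationRule("linear", "methyl_capped", (("LA", 20), ("AA-BD", 4)), 2, 24),
        # free and BD-capped linear PBAT species
        EnumerationRule("linear", "free", (("AA-BD", 7), ("TA-BD", 7)), 1, 7),
        EnumerationRule("linear", "bd_capped", (("AA-BD", 7), ("TA-BD", 7)), 1, 7),
    )
    return DatabaseConfig(rules=rules)


_COUNT_COLUMNS = {f: f"n_{f.replace('-', '_')}" for f in FAMILY_ORDER}


def enumerate_database(config: DatabaseConfig | None = None) -> pd.DataFrame:
    """Enumerate the predicted species table.

    Returns a DataFrame sorted by monoisotopic mass (label as tie-break)
    with one row per unique (topology, end group, composition).  Raises if
    the bounds would generate more than ``config.safety_cap`` species.
    """
    config = config or default_config()
    min_ring = dict(config.min_cyclic_units)
    seen: set[tuple] = set()
    rows = []
    for rule in config.rules:
        families = [f for f, _ in rule.max_counts]
        maxima = [m for _, m in rule.max_counts]
        for counts in itertools.product(*(range(m + 1) for m in maxima)):
            total = sum(counts)
            if not (rule.min_total <= total <= rule.max_total):
                continue
            comp = {f: c for f, c in zip(families, counts) if c > 0}
            if not comp:
                continue
            if rule.require_all_families and len(comp) < len(families):
                continue
            if rule.topology == "cyclic":
                if total < max(min_ring.get(f, 1) for f in comp):
                    continue
            species = OligoesterSpecies.make(rule.topology, comp, rule.end_group)
            key = (species.topology, species.end_group, species.composition)
            if key in seen:
                continue
            seen.add(key)
            if len(seen) > config.safety_cap:
                raise ValueError(
                    f"enumeration exceeds the safety cap of {config.safety_cap} "
                    "species; tighten the rule bounds"
                )
            row = {
                "label": species.label,
                "topology": species.topology,
                "end_group": species.end_group,
                "formula": str(species.formula),
                "mass": species.mass,
            }
            for family, col in _COUNT_COLUMNS.items():
                row[col] = species.counts.get(family, 0)
            rows.append(row)
    db = pd.DataFrame(rows)
    db = db.sort_values(["mass", "label"], kind="mergesort").reset_index(drop=True)
    return db


def species_from_row(row: Mapping) -> OligoesterSpecies:
    """Rebuild the :class:`OligoesterSpecies` behind a database row."""
    comp = {
        family: int(row[col])
        for family, col in _COUNT_COLUMNS.items()
        if int(row[col]) > 0
    }
    return OligoesterSpecies.make(str(row["topology"]), comp, str(row["end_group"]))


def match_neutral(mass: float, db: pd.DataFrame, tol: float = 0.001) -> pd.DataFrame:
    """Candidate species within ``tol`` Da of a neutral mass.

    Returns the matching database rows with an ``error`` column (observed
    minus theoretical), ranked by absolute error; empty frame if nothing
    matches.
    """
    if tol <= 0:
        raise ValueError("mass tolerance must be positive")
    errors = mass - db["mass"].to_numpy()
    hits = db.loc[np.abs(errors) <= tol].copy()
    hits["error"] = errors[np.abs(errors) <= tol]
    hits["abs_error"] = np.abs(hits["error"])
    return hits.sort_values(["abs_error", "label"], kind="mergesort").drop(
        columns="abs_error"
    )


# -- import/export -------------------------------------------------------

def write_database_csv(db: pd.DataFrame, path) -> None:
    db.to_csv(path, index=False, float_format="%.5f")


def read_database_csv(path) -> pd.DataFrame:
    db = pd.read_csv(path)
    missing = {"label", "topology", "end_group", "formula", "mass"} - set(db.columns)
    if missing:
        raise ValueError(f"database file missing columns: {sorted(missing)}")
    # re-derive masses at full precision from the formulas
    db["mass"] = [monoisotopic_mass(f) for f in db["formula"]]
    return db


def write_database_json(db: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(db.to_dict(orient="records"), fh, indent=1)


def read_database_json(path) -> pd.DataFrame:
    with open(path) as fh:
        records = json.load(fh)
    db = pd.DataFrame(records)
    db["mass"] = [monoisotopic_mass(f) for f in db["formula"]]
    return db
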
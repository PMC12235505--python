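"""Exact-mass arithmetic for positive-mode electrospray screening.

This module is the unit of all mass computation in the package: elemental
formulas, monoisotopic and average masses, adduct m/z with electron-mass
correction, mass-error metrics, and a bounded CHNO formula search used as a
fallback when database matching fails.

Atomic masses are pinned below rather than fetched from any external source.
Monoisotopic masses follow the AME2020/CODATA evaluation (C-12 exact by
definition); average masses follow the IUPAC 2021 standard atomic weights.
The electron mass matters here: a singly charged positive ion is one electron
short of its neutral-plus-cation-former composition, a correction of
~0.55 mDa that is resolvable at Orbitrap accuracy.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MONOISOTOPIC_MASSES",
    "AVERAGE_MASSES",
    "ElementalFormula",
    "UnknownElementError",
    "Adduct",
    "ADDUCTS",
    "get_adduct",
    "monoisotopic_mass",
    "average_mass",
    "adduct_mz",
    "neutral_mass_from_mz",
    "MassError",
    "mass_error",
    "formula_search",
]

#: Monoisotopic masses of the elements handled here, in Da.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}

#: IUPAC 2021 conventional standard atomic weights, in g mol^-1.
AVERAGE_MASSES: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.98976928,
}

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: Mass of a proton (H minus one electron) in Da.
PROTON_MASS = MONOISOTOPIC_MASSES["H"] - ELECTRON_MASS

# Mass differences of heavy-isotope substitutions, used for isotopologue
# satellite detection (13C - 12C and 18O - 16O).
C13_SHIFT = 1.0033548378
O18_SHIFT = 2.0042450

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised when a formula contains an element with no pinned mass."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"unknown element symbol {symbol!r}; supported elements: "
            + ", ".join(sorted(MONOISOTOPIC_MASSES))
        )


class ElementalFormula(Mapping):
    """An element -> count map with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive any count
    negative raises ``ValueError``.  Instances are immutable and hashable so
    they can key dictionaries and live in frozen dataclasses.

    >>> ElementalFormula.from_string("C10H16O4") + ElementalFormula({"H": 2, "O": 1})
    ElementalFormula('C10H18O5')
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        cleaned: dict[str, int] = {}
        for symbol, count in (counts or {}).items():
            if not isinstance(count, int):
                raise TypeError(f"count for {symbol!r} must be an integer, got {count!r}")
            if count < 0:
                raise ValueError(f"negative count for element {symbol!r}: {count}")
            if count > 0:
                cleaned[symbol] = count
        object.__setattr__(self, "_counts", cleaned)

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-like formula string such as ``"C10H16O4"``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            symbol, digits = match.groups()
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    # Mapping protocol ----------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, symbol: str, default: int = 0) -> int:
        return self._counts.get(symbol, default)

    # Arithmetic ----------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for symbol, count in other.items():
            counts[symbol] = counts.get(symbol, 0) + count
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for symbol, count in other.items():
            new = counts.get(symbol, 0) - count
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {symbol!r}"
                )
            counts[symbol] = new
        return ElementalFormula(counts)

    def __mul__(self, factor: int) -> "ElementalFormula":
        if not isinstance(factor, int) or factor < 0:
            raise ValueError("formula scaling factor must be a non-negative integer")
        return ElementalFormula({s: c * factor for s, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def hill_string(self) -> str:
        """Hill notation: C first, then H, then remaining elements sorted."""
        parts = []
        for symbol in ("C", "H"):
            count = self._counts.get(symbol, 0)
            if count:
                parts.append(f"{symbol}{count if count > 1 else ''}")
        for symbol in sorted(set(self._counts) - {"C", "H"}):
            count = self._counts[symbol]
            parts.append(f"{symbol}{count if count > 1 else ''}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill_string()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill_string()!r})"


FormulaLike = "ElementalFormula | str"


def _as_formula(formula: ElementalFormula | str) -> ElementalFormula:
    if isinstance(formula, str):
        return ElementalFormula.from_string(formula)
    return formula


def _mass(formula: ElementalFormula | str, table: Mapping[str, float]) -> float:
    total = 0.0
    for symbol, count in _as_formula(formula).items():
        try:
            total += table[symbol] * count
        except KeyError:
            raise UnknownElementError(symbol) from None
    return total


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass of a neutral formula in Da.

    >>> round(monoisotopic_mass("C3H4O2"), 5)   # lactate repeat unit
    72.02113
    """
    return _mass(formula, MONOISOTOPIC_MASSES)


def average_mass(formula: ElementalFormula | str) -> float:
    """Average (standard atomic weight) mass in g mol^-1.

    Used for NMR weight-percentage work, where the sample is the full
    isotopic mixture rather than the monoisotopic species.
    """
    return _mass(formula, AVERAGE_MASSES)


@dataclass(frozen=True)
class Adduct:
    """A positive-mode ESI adduct: z charges from k added cation-former units.

    The observed m/z of a neutral M is ``(M + k*mass(delta) - z*m_e) / z``:
    the ion carries the adduct atoms but is z electrons short of the combined
    neutral composition.
    """

    name: str
    delta: ElementalFormula
    k: int
    z: int

    def __post_init__(self):
        if self.z < 1:
            raise ValueError("adduct charge z must be >= 1")


ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", ElementalFormula({"H": 1}), k=1, z=1),
    "[M+NH4]+": Adduct("[M+NH4]+", ElementalFormula({"N": 1, "H": 4}), k=1, z=1),
    "[M+Na]+": Adduct("[M+Na]+", ElementalFormula({"Na": 1}), k=1, z=1),
    "[M+2NH4]2+": Adduct("[M+2NH4]2+", ElementalFormula({"N": 1, "H": 4}), k=2, z=2),
}


def get_adduct(adduct: Adduct | str) -> Adduct:
    """Resolve an adduct by its literal name, e.g. ``"[M+NH4]+"``."""
    if isinstance(adduct, Adduct):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported adducts: "
            + ", ".join(ADDUCTS)
        ) from None


def adduct_mz(neutral: ElementalFormula | str | float, adduct: Adduct | str) -> float:
    """m/z of an adduct ion of a neutral molecule.

    ``neutral`` may be a formula (string or :class:`ElementalFormula`) or a
    precomputed neutral monoisotopic mass in Da.

    >>> round(adduct_mz("C44H56O16", "[M+NH4]+"), 4)
    858.3907
    """
    ad = get_adduct(adduct)
    if isinstance(neutral, (int, float)):
        neutral_mass = float(neutral)
    else:
        neutral_mass = monoisotopic_mass(neutral)
    return (neutral_mass + ad.k * monoisotopic_mass(ad.delta) - ad.z * ELECTRON_MASS) / ad.z


def neutral_mass_from_mz(mz: float, adduct: Adduct | str) -> float:
    """Exact algebraic inverse of :func:`adduct_mz`."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    ad = get_adduct(adduct)
    return mz * ad.z - ad.k * monoisotopic_mass(ad.delta) + ad.z * ELECTRON_MASS


@dataclass(frozen=True)
class MassError:
    """Signed mass error, observed minus theoretical."""

    delta_da: float
    delta_ppm: float


def mass_error(observed: float, theoretical: float) -> MassError:
    """Signed Da and ppm error of an observed m/z against theory."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    delta = observed - theoretical
    return MassError(delta_da=delta, delta_ppm=delta / theoretical * 1e6)


def formula_search(
    mass: float,
    tol_ppm: float = 3.0,
    max_n: int = 2,
    max_rdbe: float = 40.0,
) -> list[tuple[ElementalFormula, float, float]]:
    """Exhaustive CHNO formula candidates for a neutral monoisotopic mass.

    Enumerates C/N/O counts, solves for the hydrogen count, and keeps
    chemically sensible candidates (0 <= H <= 2C+2+N, ring-double-bond
    equivalents in [0, max_rdbe]) within ``tol_ppm``.  Returns
    ``(formula, theoretical_mass, error_ppm)`` sorted by absolute error.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    tol_da = tol_ppm * 1e-6 * mass
    mC, mH = MONOISOTOPIC_MASSES["C"], MONOISOTOPIC_MASSES["H"]
    mN, mO = MONOISOTOPIC_MASSES["N"], MONOISOTOPIC_MASSES["O"]
    out = []
    for c in range(0, int(mass / mC) + 1):
        for n in range(0, max_n + 1):
            base_cn = c * mC + n * mN
            if base_cn > mass + tol_da:
                break
            for o in range(0, int((mass + tol_da - base_cn) / mO) + 1):
                remainder = mass - base_cn - o * mO
                h = round(remainder / mH)
                if h < 0 or h > 2 * c + 2 + n:
                    continue
                rdbe = c - h / 2 + n / 2 + 1
                if rdbe < 0 or rdbe > max_rdbe:
                    continue
                theo = base_cn + o * mO + h * mH
                if abs(theo - mass) <= tol_da:
                    f = ElementalFormula({"C": c, "H": h, "N": n, "O": o})
                    out.append((f, theo, (mass - theo) / theo * 1e6 if theo else 0.0))
    out.sort(key=lambda t: abs(t[2]))
    return out
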
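"""Copolymer blend quantification from assigned 1H NMR signals.

For a polyester blend, one well-resolved proton environment is assigned per
polymer (PBA, PBT, PLA, PBSe, ...).  With signal integral I and proton
count m, the molar fraction of polymer i is

    mol%_i = (I_i / m_i) / sum_j (I_j / m_j) * 100

and the weight fraction additionally weights each molar equivalent by the
average molecular weight of the repeat unit,

    wt%_i = (I_i / m_i) Mw_i / sum_j (I_j / m_j) Mw_j * 100.

End-group contributions are neglected (oligomer ends are a vanishing mass
fraction of high polymer), and average -- not monoisotopic -- repeat-unit
weights are used, as is conventional for NMR mass fractions.

The input table has one row per polymer: columns ``polymer``, ``signal``
(assignment letter, informational), ``integral``, ``protons`` and ``mw``
(average repeat-unit weight in g mol^-1; only needed for weight percent).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_signal_table",
    "mole_percent",
    "weight_percent",
    "compute_composition",
]

REQUIRED_COLUMNS = ("polymer", "integral", "protons")


def validate_signal_table(table: pd.DataFrame, need_mw: bool = False) -> pd.DataFrame:
    """Validate an NMR signal table, naming the offending row on error."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"signal table missing columns: {sorted(missing)}")
    if need_mw and "mw" not in table.columns:
        raise ValueError("signal table missing column 'mw' needed for weight percent")
    if table["polymer"].duplicated().any():
        dupes = table.loc[table["polymer"].duplicated(), "polymer"].tolist()
        raise ValueError(f"duplicate polymer rows: {dupes}")
    for _, row in table.iterrows():
        name = row["polymer"]
        if not row["integral"] > 0:
            raise ValueError(f"non-positive integral for polymer {name!r}")
        if not float(row["protons"]).is_integer() or row["protons"] < 1:
            raise ValueError(f"proton count for polymer {name!r} must be an integer >= 1")
        if need_mw and not row["mw"] > 0:
            raise ValueError(f"non-positive repeat-unit weight for polymer {name!r}")
    return table


def mole_percent(table: pd.DataFrame) -> pd.Series:
    """Per-polymer molar percentages; sums to 100 before any rounding."""
    table = validate_signal_table(table)
    equivalents = table["integral"] / table["protons"]
    out = 100.0 * equivalents / equivalents.sum()
    out.index = table["polymer"]
    return out.rename("mol_percent")


def weight_percent(table: pd.DataFrame) -> pd.Series:
    """Per-polymer weight percentages on the average-mass basis."""
    table = validate_signal_table(table, need_mw=True)
    weighted = table["integral"] / table["protons"] * table["mw"]
    out = 100.0 * weighted / weighted.sum()
    out.index = table["polymer"]
    return out.rename("wt_percent")


def compute_composition(table: pd.DataFrame) -> pd.DataFrame:
    """Molar and weight percentages in one table.

    The ``end_groups_neglected`` flag is carried in ``DataFrame.attrs`` to
    make the approximation explicit in machine-readable output.
    """
    out = pd.DataFrame(
        {
            "mol_percent": mole_percent(table).to_numpy(),
            "wt_percent": weight_percent(table).to_numpy(),
        },
        index=pd.Index(table["polymer"], name="polymer"),
    )
    out.attrs["end_groups_neglected"] = True
    return out
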
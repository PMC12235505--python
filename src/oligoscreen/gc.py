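"""Internal-standard GC quantification.

Analytes are quantified against a known amount of internal standard (IS,
butyl benzyl phthalate in the reference workflow) added post-extraction.
The response factor of an analyte is its area-per-concentration response
relative to the IS,

    RF = (area_ref / conc_ref) / (area_IS / conc_IS)

so the concentration in the film is

    conc (ug g^-1) = (area / area_IS) * m_IS(ug) / (RF * m_sample(g)).

When no reference compound exists, the RF of a chemically similar surrogate
is used and the result is flagged so downstream reports can distinguish
surrogate-quantified values (the italics convention in screening tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationRecord",
    "response_factor",
    "quantify",
    "quantify_run",
    "summarize_replicates",
    "recovery",
]


@dataclass(frozen=True)
class CalibrationRecord:
    analyte: str
    rf: float
    surrogate: bool = False

    def __post_init__(self):
        if not self.rf > 0:
            raise ValueError(f"response factor for {self.analyte!r} must be > 0")


def response_factor(area_ref: float, conc_ref: float, area_is: float, conc_is: float) -> float:
    """RF of a reference compound relative to the internal standard."""
    for name, value in (
        ("area_ref", area_ref), ("conc_ref", conc_ref),
        ("area_is", area_is), ("conc_is", conc_is),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    return (area_ref / conc_ref) / (area_is / conc_is)


def quantify(
    areas: dict[str, float],
    area_is: float,
    calibration: dict[str, CalibrationRecord],
    m_is_ug: float,
    sample_g: float,
) -> pd.DataFrame:
    """Concentrations in ug per g film for a single run.

    Every analyte must have a calibration record (own or surrogate RF);
    a missing record raises, naming the analyte.
    """
    if not area_is > 0:
        raise ValueError("internal-standard area must be > 0")
    if not sample_g > 0:
        raise ValueError("sample mass must be > 0")
    if not m_is_ug > 0:
        raise ValueError("internal-standard amount must be > 0")
    missing = sorted(set(areas) - set(calibration))
    if missing:
        raise ValueError(f"no response factor for analytes: {missing}")
    rows = []
    for analyte, area in areas.items():
        if area < 0:
            raise ValueError(f"negative area for {analyte!r}")
        cal = calibration[analyte]
        conc = (area / area_is) * m_is_ug / (cal.rf * sample_g)
        rows.append(
            {"analyte": analyte, "conc_ug_g": conc, "surrogate_rf": cal.surrogate}
        )
    return pd.DataFrame(rows, columns=["analyte", "conc_ug_g", "surrogate_rf"])


def quantify_run(
    run: pd.DataFrame,
    calibration: pd.DataFrame,
    m_is_ug: float,
    sample_g: float,
    is_name: str = "BBP",
) -> pd.DataFrame:
    """DataFrame front-end to :func:`quantify`.

    ``run`` has columns analyte, area (the IS row identified by ``is_name``);
    ``calibration`` has analyte, rf and optionally surrogate (bool).
    """
    if not {"analyte", "area"} <= set(run.columns):
        raise ValueError("run table needs columns analyte, area")
    if not {"analyte", "rf"} <= set(calibration.columns):
        raise ValueError("calibration table needs columns analyte, rf")
    is_rows = run.loc[run["analyte"] == is_name]
    if len(is_rows) != 1:
        raise ValueError(f"run table must contain exactly one {is_name!r} row")
    area_is = float(is_rows["area"].iloc[0])
    calib = {}
    for _, row in calibration.iterrows():
        calib[row["analyte"]] = CalibrationRecord(
            row["analyte"], float(row["rf"]), bool(row.get("surrogate", False))
        )
    areas = {
        row["analyte"]: float(row["area"])
        for _, row in run.iterrows()
        if row["analyte"] != is_name
    }
    return quantify(areas, area_is, calib, m_is_ug, sample_g)


def summarize_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- sd over replicate quantification tables."""
    if not replicates:
        raise ValueError("no replicates given")
    stacked = pd.concat(replicates)
    out = (
        stacked.groupby("analyte")
        .agg(
            conc_ug_g=("conc_ug_g", "mean"),
            conc_sd=("conc_ug_g", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            surrogate_rf=("surrogate_rf", "any"),
            n=("conc_ug_g", "size"),
        )
        .reset_index()
    )
    return out


def recovery(measured_amount: float, spiked_amount: float) -> float:
    """Recovery percentage of a spiked compound."""
    if not spiked_amount > 0:
        raise ValueError("spiked amount must be > 0")
    if measured_amount < 0:
        raise ValueError("measured amount must be >= 0")
    return 100.0 * measured_amount / spiked_amount
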
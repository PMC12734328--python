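"""Phenotype statistics: relative growth inhibition and ECAR.

RGI compares mean colony diameters between control (Dc) and stressed
(Ds) plates, net of the 5 mm inoculum plug d:

    RGI = (Dc − Ds) / (Ds − d) × 100

implemented exactly as printed; the more common convention with
denominator (Dc − d) is available behind ``formula="conventional"`` and
is always labelled in output.

ECAR is the least-squares slope of plate-reader signal over time,
blank-corrected. The hexokinase-mediated component is the measurement
slope minus the 2-DG control slope (2-deoxy-D-glucose competitively
inhibits hexokinases, so what it abolishes is hexokinase-dependent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PLUG_MM = 5.0


def rgi(dc: float, ds: float, d: float = PLUG_MM, formula: str = "printed") -> float:
    """Relative growth inhibition in percent."""
    if formula == "printed":
        denom = ds - d
    elif formula == "conventional":
        denom = dc - d
    else:
        raise ValueError(f"unknown formula {formula!r}")
    if denom <= 0:
        raise ValueError(f"degenerate denominator: diameter {ds if formula == 'printed' else dc} ≤ plug {d}")
    return (dc - ds) / denom * 100.0


def rgi_table(records: pd.DataFrame, d: float = PLUG_MM,
              formula: str = "printed") -> pd.DataFrame:
    """Per strain × medium × stress: mean diameters, RGI, and the SD of
    replicate-paired RGI values.

    `records` columns: strain, medium, stress, replicate, diameter_mm,
    is_control. Replicates are paired by index for the per-replicate RGI SD.
    """
    rows = []
    for (strain, medium, stress), grp in records.groupby(
            ["strain", "medium", "stress"], sort=True):
        ctrl = grp[grp["is_control"]].set_index("replicate")["diameter_mm"]
        strs = grp[~grp["is_control"]].set_index("replicate")["diameter_mm"]
        if ctrl.empty or strs.empty:
            raise ValueError(f"missing control/stress pairing for "
                             f"{strain}/{medium}/{stress}")
        value = rgi(ctrl.mean(), strs.mean(), d, formula)
        shared = ctrl.index.intersection(strs.index)
        per_rep = [rgi(ctrl[i], strs[i], d, formula) for i in shared]
        sd = float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else np.nan
        rows.append((strain, medium, stress, ctrl.mean(), strs.mean(),
                     value, sd, formula))
    return pd.DataFrame(rows, columns=["strain", "medium", "stress", "mean_dc",
                                       "mean_ds", "rgi_pct", "rgi_sd", "formula"])


def radar_export(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format RGI table (axis, series, value) for radar plotting."""
    out = table.copy()
    out["axis"] = out["stress"] + "_" + out["medium"]
    out["series"] = out["strain"]
    return out[["axis", "series", "rgi_pct"]].rename(columns={"rgi_pct": "value"})


@dataclass
class EcarResult:
    """Blank-corrected group slopes (signal units/min) for one plate."""
    well_slopes: pd.DataFrame   # well, strain, well_type, slope
    group_slopes: pd.DataFrame  # strain, well_type, ecar (blank-corrected)
    blank_slope: float


def ecar_slopes(plate: pd.DataFrame, window: tuple = (30.0, 100.0)) -> EcarResult:
    """OLS slope of signal vs time per well within the window; group ECAR is
    the mean slope over wells of a type minus the mean blank slope.

    The default window starts after the 30 min dark equilibration.
    """
    lo, hi = window
    sub = plate[(plate["t_min"] >= lo) & (plate["t_min"] <= hi)]
    rows = []
    for (well, strain, wtype), grp in sub.groupby(["well", "strain", "well_type"],
                                                  sort=True):
        if len(grp) < 2:
            raise ValueError(f"well {well} has fewer than 2 readings in window")
        slope = float(np.polyfit(grp["t_min"], grp["signal"], 1)[0])
        rows.append((well, strain, wtype, slope))
    wells = pd.DataFrame(rows, columns=["well", "strain", "well_type", "slope"])
    blanks = wells[wells["well_type"] == "blank"]["slope"]
    if blanks.empty:
        warnings.warn("no blank wells: skipping blank correction")
        blank = 0.0
    else:
        blank = float(blanks.mean())
    grows = []
    for (strain, wtype), grp in wells[wells["well_type"] != "blank"].groupby(
            ["strain", "well_type"], sort=True):
        grows.append((strain, wtype, float(grp["slope"].mean()) - blank))
    groups = pd.DataFrame(grows, columns=["strain", "well_type", "ecar"])
    return EcarResult(wells, groups, blank)


def hexokinase_ecar(result: EcarResult) -> pd.DataFrame:
    """Per-strain hexokinase-mediated ECAR (measurement − 2-DG control)."""
    piv = result.group_slopes.pivot(index="strain", columns="well_type",
                                    values="ecar")
    missing = [c for c in ("measurement", "2dg_control") if c not in piv.columns]
    if missing:
        raise ValueError(f"well type(s) {missing} absent from plate")
    piv = piv.dropna(subset=["measurement", "2dg_control"])
    out = pd.DataFrame({
        "ecar_total": piv["measurement"],
        "ecar_2dg": piv["2dg_control"],
        "hexokinase_ecar": piv["measurement"] - piv["2dg_control"],
    })
    return out


def percent_difference(hex_a: float, hex_b: float) -> float:
    """Percent by which strain A's hexokinase ECAR exceeds strain B's:
    100 × (hex_A − hex_B) / hex_B; undefined (NaN) when hex_B ≤ 0."""
    if hex_b <= 0:
        return float("nan")
    return 100.0 * (hex_a - hex_b) / hex_b
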
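"""Sample design handling for the strain × stress × time layout.

Samples are named ``Strain_Stress_Time`` (e.g. ``dHog1_SOB_0.5``): the
wild type plus three MAPK deletion mutants, each profiled under its
sensitive stress at an acute (0.5 h) and a sustained (12 h) time point,
with an unstressed time-0 baseline per strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STRAINS = ("WT", "dHog1", "dSlt2", "dMpk1")

#: short sample-name codes for each stress condition
STRESS_CODES = {
    "none": "CK",
    "sorbitol": "SOB",
    "menadione": "MND",
    "congo_red": "CR",
    "heat": "HT",
}
CODE_TO_STRESS = {v: k for k, v in STRESS_CODES.items()}

#: stress each mutant is hypersensitive (or, for dMpk1, tolerant) to
MUTANT_SENSITIVE_STRESS = {
    "dHog1": "sorbitol",
    "dSlt2": "heat",
    "dMpk1": "menadione",
}

TIMES_H = (0.0, 0.5, 12.0)


def default_design() -> list[tuple[str, str, float]]:
    """The 18-library layout: WT control + 4 stresses × 2 times, and each
    mutant's control + its sensitive stress × 2 times."""
    design = [("WT", "none", 0.0)]
    for stress in ("sorbitol", "menadione", "congo_red", "heat"):
        for t in (0.5, 12.0):
            design.append(("WT", stress, t))
    for mutant, stress in MUTANT_SENSITIVE_STRESS.items():
        design.append((mutant, "none", 0.0))
        for t in (0.5, 12.0):
            design.append((mutant, stress, t))
    return design


def sample_id(strain: str, stress: str, time_h: float) -> str:
    t = int(time_h) if float(time_h) == int(time_h) else time_h
    return f"{strain}_{STRESS_CODES[stress]}_{t}"


def parse_sample_id(sid: str) -> tuple[str, str, float]:
    parts = sid.split("_")
    if len(parts) != 3:
        raise ValueError(f"sample id {sid!r} is not of the form Strain_Stress_Time")
    strain, code, t = parts
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r} in sample id {sid!r}")
    if code not in CODE_TO_STRESS:
        raise ValueError(f"unknown stress code {code!r} in sample id {sid!r}")
    return strain, CODE_TO_STRESS[code], float(t)


@dataclass
class SampleDesign:
    """Per-sample (strain, stress, time_h) metadata, indexed by sample id."""

    table: pd.DataFrame  # columns: strain, stress, time_h

    @classmethod
    def from_sample_ids(cls, sample_ids) -> "SampleDesign":
        rows = [parse_sample_id(s) for s in sample_ids]
        table = pd.DataFrame(rows, columns=["strain", "stress", "time_h"],
                             index=pd.Index(sample_ids, name="sample"))
        design = cls(table)
        design.validate()
        return design

    @classmethod
    def from_conditions(cls, conditions) -> "SampleDesign":
        ids = [sample_id(*c) for c in conditions]
        return cls.from_sample_ids(ids)

    def validate(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in design")
        stressed = self.table[self.table["time_h"] > 0]
        for strain in stressed["strain"].unique():
            if not ((self.table["strain"] == strain) & (self.table["time_h"] == 0)).any():
                raise ValueError(f"strain {strain} has stressed samples but no time-0 baseline")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def baseline_of(self, strain: str) -> str:
        """Sample id of the strain's unstressed time-0 baseline."""
        mask = (self.table["strain"] == strain) & (self.table["time_h"] == 0)
        hits = self.table.index[mask]
        if len(hits) == 0:
            raise ValueError(f"no time-0 baseline sample for strain {strain}")
        return hits[0]

    def stressed_samples(self) -> pd.DataFrame:
        return self.table[self.table["time_h"] > 0]

    def trait_matrix(self) -> pd.DataFrame:
        """Binary trait indicators (samples × traits): one column per strain,
        per stress (non-stress included) and per time point."""
        cols = {}
        for strain in STRAINS:
            if (self.table["strain"] == strain).any():
                cols[strain] = (self.table["strain"] == strain).astype(int)
        for stress, code in STRESS_CODES.items():
            if (self.table["stress"] == stress).any():
                name = "non_stress" if stress == "none" else stress
                cols[name] = (self.table["stress"] == stress).astype(int)
        for t in sorted(self.table["time_h"].unique()):
            label = f"t{int(t) if t == int(t) else t}h"
            cols[label] = (self.table["time_h"] == t).astype(int)
        return pd.DataFrame(cols, index=self.table.index)
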
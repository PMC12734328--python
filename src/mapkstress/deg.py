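"""Fold-change screening and the mutant-responsiveness DEG classifier.

Fold change per stressed sample is log2((FPKM_st + 1)/(FPKM_nor + 1))
against the same strain's unstressed time-0 baseline. A gene is a DEG at
|log2FC| ≥ 2 and silent at |log2FC| ≤ 0.5 (boundaries inclusive).

The mutant-responsiveness labels compare the WT and a mutant under the
same stress × time:

* ``up_in_mutant``   — WT down-responds (log2FC_WT ≤ −2) while the mutant
  does not (log2FC_mut ≥ −0.5), i.e. relative up-regulation in the mutant;
* ``down_in_mutant`` — WT up-responds (log2FC_WT ≥ 2) while the mutant
  does not (log2FC_mut ≤ 0.5).

The default silent criterion bounds the mutant fold change on one side
only, exactly as the screening rule is written; a symmetric
|log2FC_mut| ≤ 0.5 band is available as ``silent_mode="two_sided"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SampleDesign
from .matrix import ExpressionMatrix

LABELS = ("up_in_mutant", "down_in_mutant", "none")


@dataclass
class ResponseThresholds:
    deg_cut: float = 2.0
    silent_cut: float = 0.5
    silent_mode: str = "one_sided_as_printed"

    def __post_init__(self) -> None:
        if not self.deg_cut > self.silent_cut > 0:
            raise ValueError("need deg_cut > silent_cut > 0")
        if self.silent_mode not in ("one_sided_as_printed", "two_sided"):
            raise ValueError(f"unknown silent_mode {self.silent_mode!r}")


@dataclass
class FoldChangeTable:
    """log2 fold changes, genes × stressed samples, plus the baseline used."""
    values: pd.DataFrame
    baselines: dict  # stressed sample id -> baseline sample id


def fold_changes(fpkm_expr: ExpressionMatrix, design: SampleDesign,
                 pseudocount: float = 1.0) -> FoldChangeTable:
    """log2((FPKM_st + pc)/(FPKM_nor + pc)) for every stressed sample."""
    if fpkm_expr.transform != "fpkm":
        raise ValueError(f"fold_changes expects fpkm values, got {fpkm_expr.transform!r}")
    stressed = design.stressed_samples()
    cols, baselines = {}, {}
    for sid, row in stressed.iterrows():
        base = design.baseline_of(row["strain"])
        if sid not in fpkm_expr.values.columns:
            raise ValueError(f"sample {sid} missing from expression matrix")
        cols[sid] = np.log2((fpkm_expr.values[sid] + pseudocount)
                            / (fpkm_expr.values[base] + pseudocount))
        baselines[sid] = base
    return FoldChangeTable(pd.DataFrame(cols), baselines)


def screen_degs(fc: pd.DataFrame | pd.Series,
                th: ResponseThresholds | None = None):
    """Per-gene screening label: ``deg`` at |fc| ≥ deg_cut, ``silent`` at
    |fc| ≤ silent_cut, else ``intermediate``. Boundaries inclusive."""
    th = th or ResponseThresholds()
    absfc = fc.abs()
    out = absfc.copy().astype(object)
    out[:] = "intermediate"
    out[absfc >= th.deg_cut] = "deg"
    out[absfc <= th.silent_cut] = "silent"
    return out


def classify_mutant_response(fc_wt, fc_mut,
                             th: ResponseThresholds | None = None):
    """Vectorized mutant-responsiveness labels (see module docstring).

    Accepts scalars or aligned arrays/Series; returns a scalar label or an
    object array/Series of labels.
    """
    th = th or ResponseThresholds()
    wt = np.asarray(fc_wt, dtype=float)
    mut = np.asarray(fc_mut, dtype=float)
    if not (np.isfinite(wt).all() and np.isfinite(mut).all()):
        raise ValueError("fold changes must be finite")
    if th.silent_mode == "two_sided":
        silent_up = silent_dn = np.abs(mut) <= th.silent_cut
    else:
        silent_up = mut >= -th.silent_cut
        silent_dn = mut <= th.silent_cut
    up = (wt <= -th.deg_cut) & silent_up
    dn = (wt >= th.deg_cut) & silent_dn
    labels = np.where(up, "up_in_mutant", np.where(dn, "down_in_mutant", "none"))
    if np.isscalar(fc_wt) or (labels.ndim == 0):
        return str(labels)
    if isinstance(fc_wt, pd.Series):
        return pd.Series(labels, index=fc_wt.index)
    return labels


@dataclass
class DEGSet:
    """Labelled genes for one mutant contrast (mutant, stress, time)."""
    labels: pd.Series            # gene -> label
    mutant: str
    stress: str
    time_h: float
    thresholds: ResponseThresholds = field(default_factory=ResponseThresholds)
    n_dropped: int = 0           # genes missing from either strain's table

    @property
    def up_genes(self) -> set:
        return set(self.labels.index[self.labels == "up_in_mutant"])

    @property
    def down_genes(self) -> set:
        return set(self.labels.index[self.labels == "down_in_mutant"])

    @property
    def labelled_genes(self) -> set:
        return set(self.labels.index[self.labels != "none"])

    @property
    def n_up(self) -> int:
        return int((self.labels == "up_in_mutant").sum())

    @property
    def n_down(self) -> int:
        return int((self.labels == "down_in_mutant").sum())

    @property
    def total(self) -> int:
        return self.n_up + self.n_down

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("label").rename_axis("gene_id").reset_index()


def mutant_deg_set(fc: FoldChangeTable, design: SampleDesign, mutant: str,
                   stress: str, time_h: float,
                   th: ResponseThresholds | None = None) -> DEGSet:
    """Build the DEGSet for one mutant contrast from the fold-change table."""
    th = th or ResponseThresholds()

    def find(strain):
        tab = design.table
        hits = tab.index[(tab["strain"] == strain) & (tab["stress"] == stress)
                         & (tab["time_h"] == time_h)]
        if len(hits) != 1:
            raise ValueError(f"no unique sample for {strain}/{stress}/{time_h}")
        return hits[0]

    wt_col = fc.values[find("WT")]
    mut_col = fc.values[find(mutant)]
    shared = wt_col.index.intersection(mut_col.index)
    n_dropped = len(wt_col.index.union(mut_col.index)) - len(shared)
    labels = classify_mutant_response(wt_col.loc[shared], mut_col.loc[shared], th)
    return DEGSet(labels=labels, mutant=mutant, stress=stress, time_h=time_h,
                  thresholds=th, n_dropped=n_dropped)


@dataclass
class OverlapResult:
    co_up: int
    co_down: int
    total: int          # genes labelled (non-none) in both sets
    discordant: int     # labelled in both but with opposite direction
    co_up_genes: list = field(default_factory=list)
    co_down_genes: list = field(default_factory=list)


def overlap_degs(set_a: DEGSet, set_b: DEGSet) -> OverlapResult:
    """Time-point overlap of one mutant's DEG sets (symmetric)."""
    co_up = set_a.up_genes & set_b.up_genes
    co_down = set_a.down_genes & set_b.down_genes
    both = set_a.labelled_genes & set_b.labelled_genes
    return OverlapResult(co_up=len(co_up), co_down=len(co_down), total=len(both),
                         discordant=len(both) - len(co_up) - len(co_down),
                         co_up_genes=sorted(co_up), co_down_genes=sorted(co_down))


def crosstalk_degs(sets: list[DEGSet]) -> tuple[list[str], list[str]]:
    """Jointly up-/down-regulated genes across all three MAPK mutants."""
    if len(sets) != 3:
        raise ValueError(f"crosstalk needs exactly 3 mutant DEG sets, got {len(sets)}")
    up = set.intersection(*(s.up_genes for s in sets))
    down = set.intersection(*(s.down_genes for s in sets))
    return sorted(up), sorted(down)
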
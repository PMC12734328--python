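"""End-to-end convenience wrappers tying the simulator to the analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deg import ResponseThresholds, fold_changes, mutant_deg_set
from .design import MUTANT_SENSITIVE_STRESS, SampleDesign
from .matrix import CountMatrix
from .normalize import filter_zero_genes, fpkm
from .simulate import GroundTruth


def mutant_contrasts(design: SampleDesign) -> list[tuple[str, str, float]]:
    """Every (mutant, stress, time) contrast present in the design."""
    out = []
    tab = design.table
    for mutant, stress in MUTANT_SENSITIVE_STRESS.items():
        times = tab[(tab["strain"] == mutant) & (tab["stress"] == stress)
                    & (tab["time_h"] > 0)]["time_h"]
        out.extend((mutant, stress, float(t)) for t in sorted(times.unique()))
    return out


def classify_all_contrasts(cm: CountMatrix, design: SampleDesign,
                           th: ResponseThresholds | None = None,
                           max_zero_samples: int = 12) -> dict:
    """Filter → FPKM → fold changes → mutant-responsiveness labels for every
    mutant contrast. Returns {(mutant, stress, time): DEGSet}."""
    th = th or ResponseThresholds()
    filtered = filter_zero_genes(cm, max_zero_samples)
    fc = fold_changes(fpkm(filtered), design)
    return {c: mutant_deg_set(fc, design, *c, th=th)
            for c in mutant_contrasts(design)}


def classification_recovery(deg_sets: dict, truth: GroundTruth,
                            deg_cut: float = 2.0) -> dict:
    """Precision/recall of the mutant-responsiveness labels against the
    planted ground truth, pooled over all contrasts.

    A call is correct only if the direction matches the planted label.
    Genes belonging to planted co-expression blocks are excluded: their
    realized per-sample effects are random latent draws, so no expected
    label is derivable for them.
    """
    module_genes = set(truth.module_id.index[truth.module_id >= 0])
    tp = fp = fn = 0
    for (mutant, stress, time_h), deg_set in deg_sets.items():
        idx = deg_set.labels.index.difference(module_genes)
        expected = truth.expected_labels(stress, time_h, deg_cut).reindex(
            idx, fill_value="none")
        called = deg_set.labels.loc[idx]
        tp += int(((called != "none") & (called == expected)).sum())
        fp += int(((called != "none") & (called != expected)).sum())
        fn += int(((called == "none") & (expected != "none")).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall}


def adjusted_rand_index(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """ARI between two clusterings over the shared gene index."""
    from sklearn.metrics import adjusted_rand_score
    shared = labels_a.index.intersection(labels_b.index)
    return float(adjusted_rand_score(labels_a.loc[shared].astype(str),
                                     labels_b.loc[shared].astype(str)))
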
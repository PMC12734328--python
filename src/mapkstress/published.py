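"""Reported DEG counts for the B. bassiana MAPK stress study, and the
set-algebra accounting that recomputes every derived number from them.

The study's per-contrast up/down DEG counts (six mutant-vs-WT contrasts:
each mutant under its sensitive stress at 0.5 h and 12 h) are inputs
here. The derived quantities — totals, percentages, time-point overlap
breakdowns and the three-mutant crosstalk — are recomputed by building
explicit gene-label sets with exactly the reported cardinalities and
running them through the same :mod:`mapkstress.deg` set algebra the
pipeline uses, so the arithmetic is exercised rather than transcribed.
"""

from __future__ import annotations

import pandas as pd

from .deg import DEGSet, OverlapResult, crosstalk_degs, overlap_degs

#: reported up/down DEG counts per mutant contrast (mutant, stress, time_h).
#: For the oxidative-stress mutant at 0.5 h the published total is 441 with
#: 26 genes on the minor side; the direction breakdown of its time-point
#: overlap is only consistent with the major side carrying the up labels,
#: so that orientation is used for the overlap and crosstalk constructions.
REPORTED_DEG_COUNTS = {
    ("dHog1", "sorbitol", 0.5): {"up": 68, "down": 341},
    ("dHog1", "sorbitol", 12.0): {"up": 126, "down": 226},
    ("dSlt2", "heat", 0.5): {"up": 694, "down": 24},
    ("dSlt2", "heat", 12.0): {"up": 269, "down": 204},
    ("dMpk1", "menadione", 0.5): {"up": 415, "down": 26},
    ("dMpk1", "menadione", 12.0): {"up": 555, "down": 114},
}

#: reported time-point overlap structure (acute ∩ sustained, same mutant)
REPORTED_OVERLAPS = {
    "dSlt2": {"total": 107, "co_up": 99, "co_down": 2},
    "dMpk1": {"total": 97, "co_up": 88, "co_down": 7},
}

#: reported three-mutant crosstalk (jointly regulated in all mutants)
REPORTED_CROSSTALK = {0.5: {"up": 44, "down": 1}, 12.0: {"up": 19, "down": 4}}


def _label_set(mutant, stress, time_h, up_genes, down_genes) -> DEGSet:
    labels = pd.Series(
        ["up_in_mutant"] * len(up_genes) + ["down_in_mutant"] * len(down_genes),
        index=list(up_genes) + list(down_genes))
    return DEGSet(labels=labels, mutant=mutant, stress=stress, time_h=time_h)


def reported_contrast_sets(mutant: str) -> tuple[DEGSet, DEGSet]:
    """Acute and sustained label sets for one mutant with the reported
    cardinalities and, where reported, the right overlap structure."""
    keys = sorted((k for k in REPORTED_DEG_COUNTS if k[0] == mutant),
                  key=lambda k: k[2])
    (m, stress, t_a), (_, _, t_s) = keys
    a, s = REPORTED_DEG_COUNTS[keys[0]], REPORTED_DEG_COUNTS[keys[1]]
    ov = REPORTED_OVERLAPS.get(mutant, {"total": 0, "co_up": 0, "co_down": 0})
    n_disc = ov["total"] - ov["co_up"] - ov["co_down"]
    gid = (f"{mutant}_g{i}" for i in range(10**6)).__next__

    shared_up = [gid() for _ in range(ov["co_up"])]
    shared_down = [gid() for _ in range(ov["co_down"])]
    disc = [gid() for _ in range(n_disc)]  # up acutely, down later
    up_a = shared_up + disc + [gid() for _ in range(a["up"] - ov["co_up"] - n_disc)]
    dn_a = shared_down + [gid() for _ in range(a["down"] - ov["co_down"])]
    up_s = shared_up + [gid() for _ in range(s["up"] - ov["co_up"])]
    dn_s = shared_down + disc + [gid() for _ in range(s["down"] - ov["co_down"] - n_disc)]
    return (_label_set(m, stress, t_a, up_a, dn_a),
            _label_set(m, stress, t_s, up_s, dn_s))


def reported_crosstalk_sets(time_h: float) -> list[DEGSet]:
    """One label set per mutant at the given time point, sharing exactly the
    reported numbers of jointly up-/down-regulated genes."""
    joint = REPORTED_CROSSTALK[time_h]
    shared_up = [f"joint_up_{i}" for i in range(joint["up"])]
    shared_down = [f"joint_dn_{i}" for i in range(joint["down"])]
    sets = []
    for (mutant, stress, t), counts in sorted(REPORTED_DEG_COUNTS.items()):
        if t != time_h:
            continue
        up = shared_up + [f"{mutant}_{t}_up{i}"
                          for i in range(counts["up"] - joint["up"])]
        down = shared_down + [f"{mutant}_{t}_dn{i}"
                              for i in range(counts["down"] - joint["down"])]
        sets.append(_label_set(mutant, stress, t, up, down))
    return sets


def recompute_reported_arithmetic() -> dict:
    """All derived numbers of the study's DEG accounting, recomputed.

    Totals and percentages come from DEGSet counting; overlap breakdowns
    from :func:`overlap_degs`; crosstalk totals from :func:`crosstalk_degs`.
    Percentages are rounded to one decimal as reported.
    """
    out = {}
    hog1_a, hog1_s = reported_contrast_sets("dHog1")
    slt2_a, slt2_s = reported_contrast_sets("dSlt2")
    mpk1_a, mpk1_s = reported_contrast_sets("dMpk1")

    out["hog1_osmotic_acute_deg_total"] = hog1_a.total
    out["hog1_osmotic_sustained_deg_total"] = hog1_s.total
    out["slt2_heat_acute_deg_total"] = slt2_a.total
    out["slt2_heat_acute_up_pct"] = round(100 * slt2_a.n_up / slt2_a.total, 1)
    out["slt2_heat_sustained_deg_total"] = slt2_s.total
    out["mpk1_oxidative_acute_deg_total"] = mpk1_a.total
    out["mpk1_oxidative_acute_minor_side_pct"] = round(
        100 * min(mpk1_a.n_up, mpk1_a.n_down) / mpk1_a.total, 1)
    out["mpk1_oxidative_sustained_deg_total"] = mpk1_s.total

    ov_slt2: OverlapResult = overlap_degs(slt2_a, slt2_s)
    out["slt2_heat_overlap_total"] = ov_slt2.total
    out["slt2_heat_overlap_co_up"] = ov_slt2.co_up
    out["slt2_heat_overlap_co_down"] = ov_slt2.co_down
    ov_mpk1 = overlap_degs(mpk1_a, mpk1_s)
    out["mpk1_oxidative_overlap_total"] = ov_mpk1.total
    out["mpk1_oxidative_overlap_concordant"] = ov_mpk1.co_up + ov_mpk1.co_down

    for t, tag in ((0.5, "acute"), (12.0, "sustained")):
        up, down = crosstalk_degs(reported_crosstalk_sets(t))
        out[f"crosstalk_{tag}_joint_up"] = len(up)
        out[f"crosstalk_{tag}_joint_down"] = len(down)
        out[f"crosstalk_{tag}_total"] = len(up) + len(down)
    return out
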
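"""Expression-matrix preprocessing.

The pipeline filters genes that are zero in too many libraries, converts
counts to FPKM, stabilizes with log2(FPKM + 1) followed by quantile
normalization, and — for the co-expression compendium — applies a
log-centered log-ratio (logCLR) transform to TMM-scaled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import rankdata

from .matrix import CountMatrix, ExpressionMatrix


@dataclass
class NormalizationConfig:
    pseudocount: float = 1.0
    zero_filter_max_zero_samples: int = 12
    tmm_trim_m: float = 0.30   # two-sided trim on M (log-ratio) values
    tmm_trim_a: float = 0.05   # two-sided trim on A (abundance) values

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        for f in (self.tmm_trim_m, self.tmm_trim_a):
            if not 0 <= f < 0.5:
                raise ValueError("trim fractions must lie in [0, 0.5)")


def filter_zero_genes(cm: CountMatrix, max_zero_samples: int = 12) -> CountMatrix:
    """Drop genes whose count is zero in more than `max_zero_samples` libraries.

    With the 18-library design and the default threshold of 12 this keeps
    genes detected in at least 6 libraries. Idempotent; preserves gene order.
    """
    n_samples = cm.counts.shape[1]
    if not 0 <= max_zero_samples <= n_samples:
        raise ValueError(f"max_zero_samples must be in [0, {n_samples}]")
    n_zero = (cm.counts == 0).sum(axis=1)
    keep = n_zero <= max_zero_samples
    if not keep.any():
        warnings.warn("zero-count filter removed every gene")
    return CountMatrix(cm.counts.loc[keep], cm.lengths_bp.loc[keep])


def fpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    value = count * 1e9 / (length_bp * library_size), with library size the
    post-filter column sum.
    """
    libsize = cm.library_sizes()
    zero_libs = libsize.index[libsize == 0].tolist()
    if zero_libs:
        raise ValueError(f"zero library size for sample(s) {zero_libs}")
    values = cm.counts * 1e9
    values = values.div(cm.lengths_bp, axis=0).div(libsize, axis=1)
    return ExpressionMatrix(values, "fpkm")


def log2_quantile(expr: ExpressionMatrix, pseudocount: float = 1.0,
                  tie_policy: str = "exact") -> ExpressionMatrix:
    """log2(value + pseudocount), then quantile normalization across samples.

    Each column's order statistics are replaced by the across-column mean of
    order statistics (the reference distribution). With the default
    ``tie_policy="exact"``, tied values are assigned reference quantiles by
    stable sort position, so every column shares an identical sorted value
    multiset afterwards (the defining property of quantile normalization).
    ``tie_policy="mean"`` instead gives each tied group the mean of the
    reference quantiles it spans (as limma's normalizeQuantiles does with
    ties), which sacrifices exact multiset equality between columns.
    """
    if expr.transform != "fpkm":
        raise ValueError(f"log2_quantile expects an fpkm matrix, got {expr.transform!r}")
    if tie_policy not in ("exact", "mean"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    logged = np.log2(expr.values + pseudocount)
    meta = {"pseudocount": pseudocount, "tie_policy": tie_policy}
    if logged.shape[1] < 2:
        warnings.warn("single-column input: quantile step is the identity")
        return ExpressionMatrix(logged, "log2_quantile", meta)
    arr = logged.to_numpy(float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = reference
        if tie_policy == "mean":
            ranks = rankdata(col, method="average")
            df = pd.DataFrame({"r": ranks, "v": mapped})
            mapped = df.groupby("r")["v"].transform("mean").to_numpy()
        out[:, j] = mapped
    values = pd.DataFrame(out, index=logged.index, columns=logged.columns)
    return ExpressionMatrix(values, "log2_quantile", meta)


def logclr(cm: CountMatrix) -> ExpressionMatrix:
    """Log-centered log-ratio transform of each gene's across-sample profile.

    Per gene: p_j = (count_j + 1) / sum_j (count_j + 1);
    logclr_j = ln p_j − mean_j ln p_j. Rows sum to zero.
    """
    shifted = cm.counts.to_numpy(float) + 1.0
    p = shifted / shifted.sum(axis=1, keepdims=True)
    logp = np.log(p)
    clr = logp - logp.mean(axis=1, keepdims=True)
    values = pd.DataFrame(clr, index=cm.counts.index, columns=cm.counts.columns)
    return ExpressionMatrix(values, "logclr")


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, normalized to geometric mean 1.

    Reference column: the sample whose 75th percentile of library-size-scaled
    counts is closest to the mean of those percentiles. Per sample, gene-wise
    log2 ratios (M) against the reference are doubly trimmed — the most
    extreme `trim_m` fraction on each side by M and `trim_a` by average
    abundance (A) — and averaged with inverse asymptotic-variance weights.
    """
    counts = cm.counts.to_numpy(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = cm.counts.columns[libsize == 0].tolist()
        raise ValueError(f"all-zero column(s): {bad}")
    f75 = np.quantile(counts / libsize, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(counts[:, j], counts[:, ref],
                                   libsize[j], libsize[ref], trim_m, trim_a)
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    """Doubly-trimmed weighted mean of M values for one sample vs the reference."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / ((n_obs - obs[keep]) / (n_obs * obs[keep])
               + (n_ref - ref[keep]) / (n_ref * ref[keep]))
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_scaled_counts(cm: CountMatrix, trim_m: float = 0.30,
                      trim_a: float = 0.05) -> CountMatrix:
    """Counts rescaled by effective library size (libsize × TMM factor) to the
    mean effective size, rounded back to integers for downstream transforms."""
    factors = tmm_factors(cm, trim_m, trim_a)
    eff = cm.library_sizes() * factors
    scaled = cm.counts * (eff.mean() / eff)
    return CountMatrix(scaled.round().astype(int), cm.lengths_bp)


def tmm_logclr(cm: CountMatrix) -> ExpressionMatrix:
    """Co-expression compendium transform: TMM-scaled counts, then logCLR."""
    out = logclr(tmm_scaled_counts(cm))
    out.meta["order"] = "tmm_then_logclr"
    return out


def sample_correlation(expr: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between samples over genes, plus an average-linkage
    leaf order on 1 − r for heatmap display.

    Zero-variance samples yield missing (NaN) correlations, not 0.
    """
    if expr.values.shape[0] < 2:
        raise ValueError("need at least two genes")
    corr = expr.values.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    finite = corr.fillna(0.0).to_numpy()
    dist = sch.distance.squareform(1.0 - finite, checks=False)
    order_idx = sch.leaves_list(sch.linkage(dist, method="average"))
    leaf_order = [corr.columns[i] for i in order_idx]
    return corr, leaf_order
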
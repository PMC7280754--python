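"""Normalization, abundance filters and the differential-expression stage.

Counts are depth-normalized with median-of-ratios size factors; features are
filtered on detection breadth (fraction of samples with a nonzero count),
RPM and baseMean; tumor-vs-normal deregulation is called with a Wilcoxon
rank-sum test on normalized counts, Benjamini-Hochberg adjusted, and
declared significant when |log2FC| > 1.5 and adjusted p < 0.05.

This is a deliberately lightweight DE stage: no dispersion shrinkage, no
covariates.  Its contract is planted-effect recovery on simulated data, not
numerical equality with any particular negative-binomial GLM fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix
from .stats import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "DeregulationRecord",
    "size_factors",
    "normalized_counts",
    "rpm_normalize",
    "detection_filter",
    "expression_filters",
    "differential_expression",
    "results_frame",
    "LOG2FC_THRESHOLD",
    "ALPHA",
    "PSEUDOCOUNT",
]

LOG2FC_THRESHOLD = 1.5  # |log2 fold change| above which a feature can be called
ALPHA = 0.05            # BH-adjusted significance level
PSEUDOCOUNT = 0.5       # added to group means before the log-ratio


@dataclass(frozen=True)
class DeregulationRecord:
    feature_id: str
    base_mean: float
    log2fc: float
    p_value: float
    adjusted_p: float
    direction: str  # up / down / ns
    significant: bool


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over all-positive features of
    count / geometric-mean(count across samples).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has a nonzero count in every sample; cannot compute size factors")
    ref = counts[positive]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean, axis=0))
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


def normalized_counts(matrix: CountMatrix) -> pd.DataFrame:
    return matrix.counts / size_factors(matrix)


def rpm_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Reads-per-million: each count scaled by 1e6 over its sample total."""
    totals = matrix.counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total count: {zero[:5]}")
    return matrix.counts * 1e6 / totals


def detection_filter(matrix: CountMatrix, min_fraction: float = 0.5) -> CountMatrix:
    """Drop features detected (raw count > 0) in fewer than
    ceil(min_fraction * n_samples) samples."""
    n = len(matrix.sample_ids)
    need = math.ceil(min_fraction * n)
    detected = (matrix.counts > 0).sum(axis=1)
    keep = detected >= need
    return CountMatrix(counts=matrix.counts.loc[keep], sample_groups=matrix.sample_groups,
                       pair_id=matrix.pair_id)


def expression_filters(
    base_means: pd.Series,
    rpm: pd.DataFrame,
    min_rpm: float = 50.0,
    min_base_mean: float = 500.0,
) -> list[str]:
    """Features whose max RPM >= min_rpm and baseMean >= min_base_mean.

    Thresholds are inclusive ("not less than").  The 50/500 preset selects
    reliably expressed features; a 500-RPM preset selects the dominant ones.
    """
    max_rpm = rpm.max(axis=1)
    keep = (max_rpm >= min_rpm) & (base_means.reindex(rpm.index) >= min_base_mean)
    return list(rpm.index[keep])


def differential_expression(
    matrix: CountMatrix,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    alpha: float = ALPHA,
) -> list[DeregulationRecord]:
    """Tumor-vs-normal deregulation calls on a count matrix.

    log2FC = log2((mean_T + 0.5) / (mean_N + 0.5)) of size-factor-normalized
    group means; p from a Wilcoxon rank-sum test on normalized counts;
    BH adjustment across features.
    """
    tumor = matrix.samples_in_group(tumor_group)
    normal = matrix.samples_in_group(normal_group)
    if not tumor or not normal:
        raise ValueError(f"both groups must be nonempty (tumor={len(tumor)}, normal={len(normal)})")
    norm = normalized_counts(matrix)
    base_mean = norm.mean(axis=1)
    mean_t = norm[tumor].mean(axis=1)
    mean_n = norm[normal].mean(axis=1)
    log2fc = np.log2((mean_t + PSEUDOCOUNT) / (mean_n + PSEUDOCOUNT))

    pvals = np.empty(len(norm.index))
    t_arr = norm[tumor].to_numpy()
    n_arr = norm[normal].to_numpy()
    for i in range(len(pvals)):
        pvals[i] = wilcoxon_rank_sum(t_arr[i], n_arr[i]).p_value
    adj = bh_adjust(pvals)

    records = []
    for i, feature in enumerate(norm.index):
        fc = float(log2fc.iloc[i])
        sig = bool(abs(fc) > log2fc_threshold and adj[i] < alpha)
        direction = ("up" if fc > 0 else "down") if sig else "ns"
        records.append(DeregulationRecord(
            feature_id=str(feature), base_mean=float(base_mean.iloc[i]), log2fc=fc,
            p_value=float(pvals[i]), adjusted_p=float(adj[i]), direction=direction,
            significant=sig,
        ))
    return records


def results_frame(records: list[DeregulationRecord]) -> pd.DataFrame:
    """Tabular view of DE results, one row per feature."""
    return pd.DataFrame(
        [
            {"feature_id": r.feature_id, "baseMean": r.base_mean, "log2FC": r.log2fc,
             "p": r.p_value, "adjusted_p": r.adjusted_p, "direction": r.direction,
             "significant": r.significant}
            for r in records
        ]
    )
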
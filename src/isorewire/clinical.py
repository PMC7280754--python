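"""Median-split survival analysis and drug-response comparison per isomiR.

Patients (or cell lines) are split at the median of one isomiR's expression:
samples strictly above the median are "high", the rest "low".  Survival
differences between the two strata are assessed with the standard two-group
log-rank test; drug response with the difference of group means of a
[0, 1]-scaled sensitivity (DR) plus a Wilcoxon rank-sum p-value, calling a
difference when |DR| > 0.1 and p < 0.05.  Positive DR means the shifted/high
group is less sensitive (resistant); negative DR means more sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .stats import wilcoxon_rank_sum

__all__ = [
    "SurvivalResult",
    "DrugResponseRecord",
    "median_split",
    "logrank_test",
    "drug_response_test",
    "DR_THRESHOLD",
    "DR_ALPHA",
]

DR_THRESHOLD = 0.1  # |difference of mean sensitivity| required for a call
DR_ALPHA = 0.05


@dataclass(frozen=True)
class SurvivalResult:
    isomir_id: str
    n_high: int
    n_low: int
    chi_square: float
    p: float
    reliable: bool = True


@dataclass(frozen=True)
class DrugResponseRecord:
    isomir_id: str
    drug: str
    dr: float  # mean(shifted/high) - mean(comparison/low)
    p: float
    call: str  # sensitive / resistant / ns


def median_split(expression: Mapping[str, float]) -> dict[str, str]:
    """Split samples at the median expression value.

    Strictly above the median -> ``high``; at or below -> ``low``.  With an
    even number of distinct configurations this can be unbalanced; ties at
    the median all go to the low stratum.  Fewer than two distinct values is
    a degenerate split and raises.
    """
    values = np.array(list(expression.values()), dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("cannot median-split: fewer than 2 distinct expression values")
    med = float(np.median(values))
    return {sample: ("high" if value > med else "low") for sample, value in expression.items()}


def logrank_test(
    time: Sequence[float],
    event: Sequence[bool],
    group: Sequence[str],
    isomir_id: str = "",
) -> SurvivalResult:
    """Two-group log-rank test.

    chi^2 = (sum_j (O1j - E1j))^2 / sum_j Vj over distinct event times, with
    the hypergeometric variance Vj at each time; p from chi^2 with 1 df.
    If one group has no events the result is computed but flagged
    unreliable.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    g = np.asarray(group)
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {labels}")
    in_a = g == labels[0]
    if (t <= 0).any():
        raise ValueError("survival times must be positive")

    observed_minus_expected = 0.0
    variance = 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int((e & (t == tj)).sum())
        d_a = int((e & (t == tj) & in_a).sum())
        observed_minus_expected += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    if variance <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = observed_minus_expected**2 / variance
        p = float(sps.chi2.sf(chi2, df=1))
    reliable = bool((e & in_a).any() and (e & ~in_a).any())
    n_high = int(in_a.sum()) if labels[0] == "high" else int((~in_a).sum())
    n_low = len(t) - n_high
    return SurvivalResult(isomir_id=isomir_id, n_high=n_high, n_low=n_low,
                          chi_square=float(chi2), p=float(min(p, 1.0)), reliable=reliable)


def drug_response_test(
    sensitivity: Mapping[str, float],
    groups: Mapping[str, str],
    isomir_id: str = "",
    drug: str = "",
    shifted_label: str = "shifted",
    comparison_label: str = "comparison",
    dr_threshold: float = DR_THRESHOLD,
    alpha: float = DR_ALPHA,
) -> DrugResponseRecord:
    """Group comparison of normalized drug sensitivity.

    DR = mean(shifted group) - mean(comparison group); p from a Wilcoxon
    rank-sum test.  The call is ``ns`` unless |DR| > 0.1 and p < 0.05;
    otherwise ``resistant`` for positive DR, ``sensitive`` for negative.
    """
    shifted = [sensitivity[c] for c, lab in groups.items() if lab == shifted_label and c in sensitivity]
    comparison = [sensitivity[c] for c, lab in groups.items() if lab == comparison_label and c in sensitivity]
    if not shifted or not comparison:
        raise ValueError("both drug-response groups must be nonempty")
    bad = [v for v in list(shifted) + list(comparison) if not 0.0 <= v <= 1.0]
    if bad:
        raise ValueError(f"sensitivity values must be pre-normalized to [0, 1]; got {bad[:3]}")
    dr = float(np.mean(shifted) - np.mean(comparison))
    p = wilcoxon_rank_sum(shifted, comparison).p_value
    if abs(dr) > dr_threshold and p < alpha:
        call = "resistant" if dr > 0 else "sensitive"
    else:
        call = "ns"
    return DrugResponseRecord(isomir_id=isomir_id, drug=drug, dr=dr, p=p, call=call)
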
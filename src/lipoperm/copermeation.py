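"""Copermeation comparison: fold changes of permeability and partitioning
against the probe-alone reference.

A copermeant is classified as an *enhancer* or *retardant* of the
probe's permeation (and as increasing or decreasing its membrane
partitioning) by the ratio of condition means to the reference mean.  A
condition whose mean ± SD interval overlaps the reference interval is
*neutral* — with only replicate standard deviations reported, interval
overlap is the honest significance proxy; a Welch t-test is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitting import ConditionSummary

__all__ = ["ComparisonResult", "compare_conditions", "max_fold_change"]


@dataclass(frozen=True)
class ComparisonResult:
    """Fold changes of one condition relative to the reference.

    ``fold_P``/``fold_K`` are condition-over-reference mean ratios;
    ``direction_P`` is one of enhancer/retardant/neutral and
    ``direction_K`` one of increase/decrease/neutral.  ``overlap_flag``
    records whether *both* mean ± SD intervals overlapped the reference
    (the neutrality rule: neutral ⇔ the respective interval overlaps).
    """

    condition_label: str
    fold_P: float
    fold_K: float
    direction_P: str
    direction_K: str
    overlap_P: bool
    overlap_K: bool

    def __post_init__(self) -> None:
        if not (self.fold_P > 0 and self.fold_K > 0):
            raise ValueError("fold changes must be positive")


def _intervals_overlap(m1: float, s1: float, m2: float, s2: float) -> bool:
    return (m1 - s1) <= (m2 + s2) and (m2 - s2) <= (m1 + s1)


def _welch_neutral(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, alpha: float
) -> bool:
    if min(n1, n2) < 2 or (s1 == 0 and s2 == 0):
        return m1 == m2
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    return bool(res.pvalue > alpha)


def compare_conditions(
    summaries: list[ConditionSummary],
    reference_label: str,
    use_ttest: bool = False,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Compare every non-reference condition against the reference.

    Direction labels come from the fold and the neutrality rule:
    interval overlap (default) or a Welch t-test at ``alpha`` when
    ``use_ttest``.  Output order follows the input order; the
    classification itself does not depend on ordering.
    """
    by_label = {s.condition_label: s for s in summaries}
    if reference_label not in by_label:
        raise ValueError(f"reference condition '{reference_label}' not found")
    ref = by_label[reference_label]

    results: list[ComparisonResult] = []
    for s in summaries:
        if s.condition_label == reference_label:
            continue
        fold_P = s.P_mean / ref.P_mean
        fold_K = s.K_mean / ref.K_mean if ref.K_mean > 0 else float("inf")
        if use_ttest:
            neutral_P = _welch_neutral(
                s.P_mean, s.P_sd, s.n, ref.P_mean, ref.P_sd, ref.n, alpha
            )
            neutral_K = _welch_neutral(
                s.K_mean, s.K_sd, s.n, ref.K_mean, ref.K_sd, ref.n, alpha
            )
        else:
            neutral_P = _intervals_overlap(s.P_mean, s.P_sd, ref.P_mean, ref.P_sd)
            neutral_K = _intervals_overlap(s.K_mean, s.K_sd, ref.K_mean, ref.K_sd)
        direction_P = (
            "neutral" if neutral_P else ("enhancer" if fold_P > 1 else "retardant")
        )
        direction_K = (
            "neutral" if neutral_K else ("increase" if fold_K > 1 else "decrease")
        )
        results.append(
            ComparisonResult(
                condition_label=s.condition_label,
                fold_P=fold_P,
                fold_K=fold_K,
                direction_P=direction_P,
                direction_K=direction_K,
                overlap_P=neutral_P,
                overlap_K=neutral_K,
            )
        )
    return results


def max_fold_change(results: list[ComparisonResult], quantity: str = "P") -> float:
    """Largest fold-change magnitude max(fold, 1/fold) over all conditions.

    Always ≥ 1; measures the strongest copermeation effect on the chosen
    quantity ('P' or 'K') in either direction.
    """
    if not results:
        raise ValueError("no comparison results")
    if quantity not in ("P", "K"):
        raise ValueError("quantity must be 'P' or 'K'")
    folds = np.array(
        [r.fold_P if quantity == "P" else r.fold_K for r in results], dtype=float
    )
    return float(np.max(np.maximum(folds, 1.0 / folds)))
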
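"""Method-comparison statistics for manual vs automated quantification.

Bland-Altman limits of agreement, the 2x2 detection contingency table
(count = 0 vs count >= 1), hot-spot overlap-category tallies, and diagnostic
performance (sensitivity/specificity/PPV/NPV with exact binomial CIs plus a
rank-based ROC area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .hotspot import OverlapCategory, OverlapResult


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float  # automated - manual
    sd_difference: float  # sample SD (n - 1)
    lower_limit: float  # mean - 1.96 sd
    upper_limit: float  # mean + 1.96 sd
    n: int
    excluded_ids: tuple = ()


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification of manual x automated detection (0 vs >= 1)."""

    counts: np.ndarray  # [[manual0_auto0, manual0_auto1], [manual1_auto0, manual1_auto1]]
    n: int

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.n if self.n else np.zeros((2, 2))

    @property
    def percentages_rounded(self) -> np.ndarray:
        return np.rint(self.percentages).astype(int)

    @property
    def row_totals(self) -> np.ndarray:  # manual marginal (0, >= 1)
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:  # automated marginal (0, >= 1)
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Percent-scale diagnostic metrics; CIs are exact (Clopper-Pearson)."""

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float | None
    ppv_ci: tuple[float, float] | None
    npv: float | None
    npv_ci: tuple[float, float] | None
    roc_area: float | None  # in [0, 1]; None when one outcome class is absent
    cutoff: float
    counts: dict = field(default_factory=dict)  # tp/fp/tn/fn for audit


def bland_altman(
    manual: Sequence[float],
    automated: Sequence[float],
    case_ids: Sequence | None = None,
    exclude_ids: Iterable = (),
) -> BlandAltmanResult:
    """Agreement of paired measurements: differences are automated - manual.

    Limits of agreement are mean +/- 1.96 x sample SD.  Outlier exclusion is
    caller-specified by case id and echoed in the result.
    """
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.shape != automated.shape:
        raise ValueError("manual and automated must have equal length")
    excluded = tuple(exclude_ids)
    if case_ids is not None:
        case_ids = list(case_ids)
        if len(case_ids) != len(manual):
            raise ValueError("case_ids length mismatch")
        keep = np.array([cid not in set(excluded) for cid in case_ids])
        manual, automated = manual[keep], automated[keep]
    elif excluded:
        raise ValueError("exclude_ids given without case_ids")
    n = len(manual)
    if n < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    diff = automated - manual
    d_bar = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(d_bar, sd, d_bar - 1.96 * sd, d_bar + 1.96 * sd, n, excluded)


def detection_table(pairs: Sequence[tuple[float, float]]) -> ContingencyTable:
    """Bin (manual, automated) count pairs into the 2x2 detection table."""
    counts = np.zeros((2, 2), dtype=int)
    for manual, automated in pairs:
        if manual < 0 or automated < 0:
            raise ValueError("counts must be non-negative")
        counts[int(manual >= 1), int(automated >= 1)] += 1
    return ContingencyTable(counts, int(counts.sum()))


def overlap_tally(
    results: Sequence[OverlapResult | OverlapCategory],
) -> dict[OverlapCategory, tuple[int, float]]:
    """Counts and percentages per overlap category, in category order."""
    cats = [r.category if isinstance(r, OverlapResult) else r for r in results]
    n = len(cats)
    out = {}
    for cat in OverlapCategory:
        k = sum(1 for c in cats if c == cat)
        out[cat] = (k, 100.0 * k / n if n else 0.0)
    return out


def _exact_ci(k: int, n: int) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return (100.0 * ci.low, 100.0 * ci.high)


def roc_area(values: Sequence[float], outcomes: Sequence[int]) -> float | None:
    """Rank-based ROC area: P(value_positive > value_negative), ties count 1/2."""
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    n1 = int((outcomes == 1).sum())
    n0 = int((outcomes == 0).sum())
    if n1 == 0 or n0 == 0:
        return None
    ranks = stats.rankdata(values)  # midranks handle ties
    r1 = ranks[outcomes == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def diagnostic_performance(
    values: Sequence[float], outcomes: Sequence[int], cutoff: float
) -> DiagnosticPerformance:
    """Diagnostic metrics of the rule "test positive iff value >= cutoff"."""
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if values.shape != outcomes.shape:
        raise ValueError("values and outcomes must have equal length")
    test_pos = values >= cutoff
    tp = int(np.sum(test_pos & (outcomes == 1)))
    fn = int(np.sum(~test_pos & (outcomes == 1)))
    fp = int(np.sum(test_pos & (outcomes == 0)))
    tn = int(np.sum(~test_pos & (outcomes == 0)))

    def prop(k: int, n: int):
        if n == 0:
            return None, None
        return 100.0 * k / n, _exact_ci(k, n)

    sens, sens_ci = prop(tp, tp + fn)
    spec, spec_ci = prop(tn, tn + fp)
    if sens is None or spec is None:
        raise ValueError("outcomes must contain both classes")
    ppv, ppv_ci = prop(tp, tp + fp)
    npv, npv_ci = prop(tn, tn + fn)
    return DiagnosticPerformance(
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        ppv=ppv,
        ppv_ci=ppv_ci,
        npv=npv,
        npv_ci=npv_ci,
        roc_area=roc_area(values, outcomes),
        cutoff=float(cutoff),
        counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )
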
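"""Survival/translocation frequency arithmetic and cohort statistics.

Frequencies follow the plating scheme of the assays: cells are counted on
glucose plates before break induction (SC, total cells), then on galactose
plates after induction with (SGal) and without leucine (SGal-Leu).
Survival is SGal/SC and the translocation frequency SGal-Leu/SC, each
corrected by its dilution factor.  Replicate frequencies are summarised by
the median (standard deviation reported alongside), genotypes are compared
with the two-sided Mann-Whitney test, and repair-type distributions with a
Pearson chi-square on the count tables.

The in-cis deletion assay reuses the same arithmetic with 5-FOA-resistant
colony counts in place of the Leu+ counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsError",
    "PlatingExperiment",
    "FrequencyResult",
    "FoldChange",
    "frequencies",
    "summarize_replicates",
    "fold_change",
    "mann_whitney",
    "compare_type_distributions",
]


class StatsError(ValueError):
    """Contract violation in a statistics operation."""


@dataclass(frozen=True)
class PlatingExperiment:
    """Colony counts for one plating experiment.

    ``colonies_sc``: glucose plate, pre-induction (total cells);
    ``colonies_sgal``: survivors after induction; ``colonies_sgal_leu``:
    Leu+ translocants (or 5-FOA-resistant colonies for the in-cis assay).
    Dilution factors scale a plate count up to the culture: a count ``c``
    plated at dilution ``d`` represents ``c * d`` culture cells.  They
    default to 1 and must be supplied explicitly otherwise.
    """

    colonies_sc: int
    colonies_sgal: int
    colonies_sgal_leu: int
    dilution_sc: float = 1.0
    dilution_sgal: float = 1.0
    dilution_sgal_leu: float = 1.0

    def __post_init__(self):
        for name in ("colonies_sc", "colonies_sgal", "colonies_sgal_leu"):
            if getattr(self, name) < 0:
                raise StatsError(f"{name} must be non-negative")
        for name in ("dilution_sc", "dilution_sgal", "dilution_sgal_leu"):
            if getattr(self, name) <= 0:
                raise StatsError(f"{name} must be positive")


@dataclass(frozen=True)
class FrequencyResult:
    """Survival and translocation frequency of one experiment (or summary)."""

    survival: float
    transloc_freq: float
    replicates: tuple[float, ...] = ()
    median: float | None = None
    sd: float | None = None


@dataclass(frozen=True)
class FoldChange:
    """A fold-change descriptor between two medians."""

    ratio: float
    rounded: float
    direction: str   # 'increase', 'decrease' or 'none'

    def __str__(self) -> str:
        r = int(self.rounded) if float(self.rounded).is_integer() else self.rounded
        if self.direction == "none":
            return f"{r}-fold"
        return f"{r}-fold {self.direction}"


def frequencies(exp: PlatingExperiment) -> FrequencyResult:
    """Survival and translocation frequency from one plating experiment."""
    total = exp.colonies_sc * exp.dilution_sc
    if total <= 0:
        raise StatsError("undefined frequency: no cells counted on SC")
    survival = (exp.colonies_sgal * exp.dilution_sgal) / total
    freq = (exp.colonies_sgal_leu * exp.dilution_sgal_leu) / total
    return FrequencyResult(survival=survival, transloc_freq=freq)


def summarize_replicates(freqs: list[float]) -> FrequencyResult:
    """Median (headline summary) and standard deviation over replicates."""
    if not freqs:
        raise StatsError("at least one replicate frequency is required")
    arr = np.asarray(freqs, dtype=float)
    return FrequencyResult(
        survival=math.nan,
        transloc_freq=float(np.median(arr)),
        replicates=tuple(float(x) for x in arr),
        median=float(np.median(arr)),
        sd=float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0,
    )


def fold_change(ref_median: float, test_median: float) -> FoldChange:
    """Fold change between two medians, rendered the way results are quoted.

    The ratio is max/min; direction is relative to the reference.  Ratios
    below 100 round to the nearest integer, larger ones to one significant
    figure (so 298 reports as 300).
    """
    if ref_median <= 0 or test_median <= 0:
        raise StatsError("fold change undefined for non-positive medians")
    hi, lo = max(ref_median, test_median), min(ref_median, test_median)
    ratio = hi / lo
    if ratio < 100:
        rounded = float(int(ratio + 0.5))
    else:
        exp10 = math.floor(math.log10(ratio))
        rounded = round(ratio / 10 ** exp10) * 10 ** exp10
    if test_median > ref_median:
        direction = "increase"
    elif test_median < ref_median:
        direction = "decrease"
    else:
        direction = "none"
    return FoldChange(ratio=ratio, rounded=float(rounded), direction=direction)


def mann_whitney(group_a: list[float], group_b: list[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between replicate frequency groups.

    Uses the exact permutation null when the smaller group has at most 8
    observations and there are no ties across groups, and the
    tie-corrected normal approximation otherwise.  Returns (U, p) with U
    the statistic of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_type_distributions(a, b) -> tuple[float, float, float]:
    """Pearson chi-square comparison of two repair-type count distributions.

    ``a`` and ``b`` are TypeDistribution objects (or plain count sequences)
    over the same categories.  No continuity correction is applied;
    df = (categories - 1) * (groups - 1).  Categories empty in both groups
    are dropped (they contribute no information and would make the
    expected counts degenerate).  A warning is issued when any expected
    count falls below 5.
    """
    va = _counts_vector(a)
    vb = _counts_vector(b)
    if len(va) != len(vb):
        raise StatsError("distributions have different category sets")
    if sum(va) < 1 or sum(vb) < 1:
        raise StatsError("each distribution needs n >= 1")
    sa = getattr(a, "system", None)
    sb = getattr(b, "system", None)
    if sa is not None and sb is not None and sa != sb:
        raise StatsError(f"cannot compare {sa} and {sb} distributions")
    table = np.array([va, vb], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 0.0, 1.0
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn(
            "chi-square approximation is doubtful: some expected counts < 5",
            stacklevel=2,
        )
    return float(chi2), float(dof), float(p)


def _counts_vector(dist) -> list[int]:
    if hasattr(dist, "as_vector"):
        return list(dist.as_vector())
    return [int(x) for x in dist]
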
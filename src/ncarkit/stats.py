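"""Growth rates between imaging days and family-wise group comparison.

A colony is measured at two imaging days (day 9 and day 13 in the
standard design, i.e. a 96-hour window) either as NCAR (%) or as colony
diameter (mm).  The growth rate is the plain difference quotient

    rate = (value(d2) - value(d1)) / (d2 - d1)

in percentage points per day or mm per day.  Negative rates are kept —
thresholding noise can produce them on near-static colonies — but logged
as anomalous, since colonies do not shrink.

Group rates are compared by one-way ANOVA followed by Tukey's HSD at a
family-wise error level alpha, summarized as a compact letter display:
two groups share a letter if and only if their Tukey-adjusted comparison
is non-significant.  Letters are assigned from the largest group mean
downwards, starting at "a", via the insert-and-absorb algorithm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger("ncarkit")

METRIC_NCAR = "ncar"
METRIC_DIAMETER = "diameter"


class StatisticsError(ValueError):
    """Raised on insufficient replication or degenerate variance."""


class FoldChangeError(ValueError):
    """Raised when a fold change is undefined (denominator <= 0)."""


@dataclass(frozen=True)
class PlateMeasurement:
    """One plate measured on one day: NCAR in percent or diameter in mm."""

    group: str
    plate_id: str
    day: int
    value: float
    metric: str = METRIC_NCAR


@dataclass(frozen=True)
class GrowthRate:
    """Per-plate growth rate: pp/day for NCAR, mm/day for diameter."""

    group: str
    plate_id: str
    rate: float
    metric: str = METRIC_NCAR

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate):
            raise ValueError(f"rate must be finite, got {self.rate}")


@dataclass(frozen=True)
class GroupComparison:
    """All-pairs Tukey comparison summarized by a compact letter display.

    Groups are ordered by decreasing mean rate.  ``significant`` holds the
    Tukey-rejected pairs at level ``alpha``; sharing a letter is exactly
    equivalent to a pair NOT being in it.
    """

    groups: tuple[str, ...]
    means: Mapping[str, float]
    sds: Mapping[str, float]
    ns: Mapping[str, int]
    letters: Mapping[str, str]
    alpha: float = 0.05
    significant: frozenset[frozenset[str]] = frozenset()
    anova_f: float = math.nan
    anova_p: float = math.nan

    def different(self, a: str, b: str) -> bool:
        """Whether groups a and b differ at the family-wise level."""
        return frozenset((a, b)) in self.significant


def growth_rate(before: PlateMeasurement, after: PlateMeasurement) -> GrowthRate:
    """Difference-quotient growth rate between two measurements of a plate."""
    if after.day <= before.day:
        raise ValueError(f"need day_after > day_before, got {before.day} -> {after.day}")
    if before.plate_id != after.plate_id:
        raise ValueError(f"plate id mismatch: {before.plate_id!r} vs {after.plate_id!r}")
    if before.metric != after.metric:
        raise ValueError(f"metric mismatch: {before.metric!r} vs {after.metric!r}")
    rate = (after.value - before.value) / (after.day - before.day)
    if rate < 0:
        logger.warning(
            "plate %s: negative growth rate %.4g %s/day (colonies do not shrink)",
            before.plate_id, rate, "pp" if before.metric == METRIC_NCAR else "mm",
        )
    return GrowthRate(group=before.group, plate_id=before.plate_id, rate=rate, metric=before.metric)


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio of two mean growth rates (a over b)."""
    if rate_b <= 0:
        raise FoldChangeError(f"fold change undefined for denominator rate {rate_b}")
    return rate_a / rate_b


def _compact_letters(
    ordered: Sequence[str], significant: frozenset[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``ordered`` lists groups by decreasing mean (ties pre-broken).  Starts
    from one column holding every group; each significant pair splits any
    column containing both; columns that are subsets of another are
    absorbed.  Guarantees: a significant pair never shares a column, and
    every non-significant pair shares at least one.
    """
    columns: list[set[str]] = [set(ordered)]
    pairs = [
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
        if frozenset((ordered[i], ordered[j])) in significant
    ]
    for a, b in pairs:
        nxt: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                nxt.append(col - {a})
                nxt.append(col - {b})
            else:
                nxt.append(col)
        # absorb: drop any column contained in another (keep one of duplicates)
        columns = []
        for i, col in enumerate(nxt):
            contained = any(
                (col < other) or (col == other and j < i) for j, other in enumerate(nxt) if j != i
            )
            if not contained:
                columns.append(col)
    rank = {g: i for i, g in enumerate(ordered)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in ordered}
    for k, col in enumerate(columns):
        letter = alphabet[k] if k < 26 else f"z{k}"
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def compare_groups(rates: Sequence[GrowthRate], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA + Tukey HSD + compact letter display over group rates.

    Raises
    ------
    StatisticsError
        If, with >= 2 groups, any group has < 2 replicates or zero
        within-group variance.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if len(rates) == 0:
        raise StatisticsError("no growth rates supplied")
    by_group: dict[str, list[float]] = {}
    for r in rates:
        by_group.setdefault(r.group, []).append(r.rate)

    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    sds = {g: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0) for g, v in by_group.items()}
    ns = {g: len(v) for g, v in by_group.items()}
    # decreasing mean; ties broken lexicographically by group label
    ordered = tuple(sorted(by_group, key=lambda g: (-means[g], g)))

    if len(ordered) == 1:
        g = ordered[0]
        return GroupComparison(
            groups=ordered, means=means, sds=sds, ns=ns, letters={g: "a"}, alpha=alpha
        )

    for g in ordered:
        if ns[g] < 2:
            raise StatisticsError(f"group {g!r} has {ns[g]} replicate(s); need >= 2")
        if np.var(by_group[g]) == 0.0:
            raise StatisticsError(f"group {g!r} has zero within-group variance")

    values = np.concatenate([np.asarray(by_group[g], dtype=float) for g in ordered])
    labels = np.concatenate([np.full(ns[g], g, dtype=object) for g in ordered])
    f_stat, p_val = sps.f_oneway(*(by_group[g] for g in ordered))
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    # pairwise results follow combinations() order over the sorted unique groups
    uniq = [str(g) for g in tukey.groupsunique]
    sig = frozenset(
        frozenset(pair)
        for pair, rej in zip(combinations(uniq, 2), np.asarray(tukey.reject))
        if rej
    )
    letters = _compact_letters(ordered, sig)
    return GroupComparison(
        groups=ordered,
        means=means,
        sds=sds,
        ns=ns,
        letters=letters,
        alpha=alpha,
        significant=sig,
        anova_f=float(f_stat),
        anova_p=float(p_val),
    )
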
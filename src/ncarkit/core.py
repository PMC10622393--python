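"""Dual-threshold segmentation and the normalized colony area ratio (NCAR).

Two critical red-intensity thresholds partition a plate raster into three
domains: background, Petri-dish (plate + medium + colony), and mycelial
colony.  With a white colony on darker medium on a dark background
(``light_colony`` orientation), the dish domain is every pixel at least as
bright as ``t_dish`` and the colony domain is every dish pixel at least as
bright as ``t_colony``; for ``dark_colony`` the comparisons reverse.  The
colony domain is intersected with the dish domain by construction, so the
per-plate ratio A_c / A_d is always in [0, 1].

The group statistic is

    eta = 100 * (1/n) * sum_i (A_c^i / A_d^i),   i = 1..n replicates,

the normalized colony area ratio, approximating the percentage of the
dish covered by the colony.

Thresholds are meant to be chosen manually from the red histogram; an
automatic mode (three-class Otsu by exhaustive search over threshold
pairs) is provided for unattended runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import RedChannelImage, RedHistogram

LIGHT_COLONY = "light_colony"
DARK_COLONY = "dark_colony"


class SegmentationError(ValueError):
    """Raised when a plate yields an empty dish domain."""


class ThresholdError(ValueError):
    """Raised when automatic thresholding is impossible for a histogram."""


@dataclass(frozen=True)
class ThresholdPair:
    """The two critical red-intensity thresholds.

    ``t_dish`` screens dish pixels, ``t_colony`` screens colony pixels.
    Comparisons are inclusive on the selected side (``>=`` for
    ``light_colony``, ``<=`` for ``dark_colony``), a fixed convention so
    results are bit-reproducible.
    """

    t_dish: int
    t_colony: int
    orientation: str = LIGHT_COLONY

    def __post_init__(self) -> None:
        for name, t in (("t_dish", self.t_dish), ("t_colony", self.t_colony)):
            if not (0 <= t <= 255):
                raise ValueError(f"{name} must be in [0, 255], got {t}")
        if self.orientation == LIGHT_COLONY:
            if self.t_dish > self.t_colony:
                raise ValueError(
                    f"light_colony requires t_dish <= t_colony, got ({self.t_dish}, {self.t_colony})"
                )
        elif self.orientation == DARK_COLONY:
            if self.t_colony > self.t_dish:
                raise ValueError(
                    f"dark_colony requires t_colony <= t_dish, got ({self.t_dish}, {self.t_colony})"
                )
        else:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class AreaIndices:
    """Per-plate pixel counts of the dish (A_d) and colony (A_c) domains."""

    A_d: int
    A_c: int
    plate_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.A_c <= self.A_d):
            raise ValueError(f"need 0 <= A_c <= A_d, got A_c={self.A_c}, A_d={self.A_d}")

    @property
    def ratio(self) -> float:
        """Colony-to-dish pixel-count ratio A_c / A_d."""
        if self.A_d == 0:
            raise SegmentationError(f"no dish detected in plate {self.plate_id!r}")
        return self.A_c / self.A_d


@dataclass(frozen=True)
class NCARSummary:
    """Group-level NCAR over n replicate plates.

    ``eta`` is the group mean of per-plate ratios in percent; ``sd`` is
    the sample standard deviation (n-1 denominator) of those ratios in
    percentage points, reported as 0 for a single replicate.
    """

    group: str
    day: int
    n: int
    eta: float
    sd: float
    per_plate_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n < 1 or len(self.per_plate_ratios) != self.n:
            raise ValueError("per_plate_ratios length must equal n >= 1")
        if not (0.0 <= self.eta <= 100.0 + 1e-9):
            raise ValueError(f"eta must be in [0, 100], got {self.eta}")


def segment_plate(img: RedChannelImage, thr: ThresholdPair) -> AreaIndices:
    """Count dish and colony pixels under a threshold pair.

    Raises
    ------
    SegmentationError
        If no pixel qualifies as dish ("no dish detected"), carrying the
        plate id.
    """
    v = img.values
    if thr.orientation == LIGHT_COLONY:
        dish = v >= thr.t_dish
        colony = dish & (v >= thr.t_colony)
    else:
        dish = v <= thr.t_dish
        colony = dish & (v <= thr.t_colony)
    a_d = int(np.count_nonzero(dish))
    if a_d == 0:
        raise SegmentationError(f"no dish detected in plate {img.source_id!r}")
    a_c = int(np.count_nonzero(colony))
    return AreaIndices(A_d=a_d, A_c=a_c, plate_id=img.source_id, day=img.day)


def group_ncar(plates: Sequence[AreaIndices], group: str, day: int) -> NCARSummary:
    """Compute the group NCAR eta (%) and its dispersion over replicates."""
    if len(plates) == 0:
        raise ValueError(f"group {group!r}: no plates supplied")
    ratios = tuple(p.ratio for p in plates)  # raises SegmentationError on A_d == 0
    n = len(ratios)
    eta = 100.0 * math.fsum(ratios) / n
    sd = 100.0 * float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    return NCARSummary(group=group, day=day, n=n, eta=eta, sd=sd, per_plate_ratios=ratios)


def auto_thresholds(hist: RedHistogram) -> ThresholdPair:
    """Three-class Otsu by exhaustive search over all threshold pairs.

    Finds the partition of [0, 255] into classes ``[0..t1]``,
    ``[t1+1..t2]``, ``[t2+1..255]`` minimizing the total within-class
    intensity variance, considering only pairs where all three classes
    are populated.  Ties break to the lexicographically smallest
    ``(t1, t2)``.  The class boundaries are returned as
    ``ThresholdPair(t_dish=t1+1, t_colony=t2+1)`` under ``light_colony``
    orientation.

    Raises
    ------
    ThresholdError
        If fewer than 3 distinct intensity levels are present
        ("histogram not trimodal-capable").
    """
    counts = hist.counts.astype(np.float64)
    if hist.n_nonzero_levels() < 3:
        raise ThresholdError(
            f"histogram not trimodal-capable: {hist.n_nonzero_levels()} distinct levels"
        )

    levels = np.arange(256, dtype=np.float64)
    c = np.concatenate([[0.0], np.cumsum(counts)])            # c[k] = count of [0..k-1]
    s = np.concatenate([[0.0], np.cumsum(counts * levels)])
    q = np.concatenate([[0.0], np.cumsum(counts * levels**2)])

    def within_ss(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # Weighted within-class sum of squares of intensity range [a, b].
        w = c[b + 1] - c[a]
        m = s[b + 1] - s[a]
        v = q[b + 1] - q[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            ss = v - np.where(w > 0, m * m / np.maximum(w, 1e-300), 0.0)
        return np.where(w > 0, ss, np.inf)

    best = (math.inf, -1, -1)
    t2_all = np.arange(1, 255, dtype=np.intp)
    for t1 in range(0, 254):
        t2 = t2_all[t2_all > t1]
        total = (
            within_ss(np.array([0]), np.array([t1]))
            + within_ss(np.full(t2.shape, t1 + 1), t2)
            + within_ss(t2 + 1, np.full(t2.shape, 255))
        )
        k = int(np.argmin(total))
        if total[k] < best[0]:
            best = (float(total[k]), t1, int(t2[k]))
    if not math.isfinite(best[0]):
        raise ThresholdError("histogram not trimodal-capable: no populated 3-class split")
    return ThresholdPair(t_dish=best[1] + 1, t_colony=best[2] + 1, orientation=LIGHT_COLONY)
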
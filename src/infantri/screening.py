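"""Outlier screening and subgroup partition testing.

Two gatekeeping procedures applied before reference-interval estimation:

* the one-third-of-range outlier rule (Dixon/Reed form): an extreme
  observation is deleted when its gap to its nearest neighbour exceeds one
  third of the whole sample range, re-testing after each deletion;
* the Harris–Boyd criterion: subgroups (sexes, feeding groups) warrant
  separate reference intervals when the standardized difference of their
  means exceeds a sample-size-scaled critical value, or when their standard
  deviations differ by more than a fixed ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Gap-to-range ratio above which an extreme value is deleted.
DIXON_RATIO = 1.0 / 3.0

#: Cap on total deletions, as a fraction of the original sample size.
MAX_REMOVED_FRACTION = 0.05

#: Default limit on the subgroup SD ratio in the partition test.
SD_RATIO_LIMIT = 1.5


@dataclass(frozen=True)
class OutlierReport:
    """What the one-third-range screen removed, and what survived."""

    removed_values: tuple[float, ...]
    tails: tuple[str, ...]  # "low" | "high", parallel to removed_values
    surviving_n: int
    kept_indices: tuple[int, ...]  # indices into the input, original order

    def __post_init__(self) -> None:
        assert len(self.removed_values) == len(self.tails)
        assert self.surviving_n == len(self.kept_indices)

    @property
    def removed_count(self) -> int:
        return len(self.removed_values)


def dixon_screen(values: Sequence[float]) -> OutlierReport:
    """Apply the one-third-of-range rule iteratively to a sample.

    Sorted ``x(1..n)``: the maximum is deleted when
    ``(x(n) - x(n-1)) / (x(n) - x(1)) > 1/3``; the minimum symmetrically via
    ``x(2) - x(1)``.  When both tails fire, the larger ratio goes first.
    After each deletion the reduced sample is re-tested.  Deletions stop when
    no tail fires, when the range is zero, or when another deletion would
    exceed 5% of the original n.  Censored measurements participate at their
    LOQ value (a tied censored block has zero gap and can never fire).

    For n < 3 the test is undefined: a warning is issued and nothing is
    removed.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 3:
        warnings.warn(
            f"outlier screen undefined for n={n} (< 3); no removals", stacklevel=2
        )
        return OutlierReport((), (), n, tuple(range(n)))

    order = list(np.argsort(vals, kind="stable"))
    max_removed = math.floor(n * MAX_REMOVED_FRACTION)
    removed_vals: list[float] = []
    tails: list[str] = []

    while len(removed_vals) < max_removed and len(order) >= 3:
        x = vals[order]
        rng = x[-1] - x[0]
        if rng == 0:
            break
        hi = (x[-1] - x[-2]) / rng
        lo = (x[1] - x[0]) / rng
        if hi > DIXON_RATIO and hi >= lo:
            removed_vals.append(float(x[-1]))
            tails.append("high")
            order.pop()
        elif lo > DIXON_RATIO:
            removed_vals.append(float(x[0]))
            tails.append("low")
            order.pop(0)
        else:
            break

    kept = tuple(sorted(order))
    return OutlierReport(tuple(removed_vals), tuple(tails), len(kept), kept)


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one subgroup for the partition test."""

    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class PartitionDecision:
    """Harris–Boyd verdict: partition when z exceeds its critical value or
    the subgroup SDs are too unequal."""

    z: float
    z_star: float
    sd_ratio: float
    partition: bool
    sd_ratio_limit: float = SD_RATIO_LIMIT


def harris_boyd(
    group1: GroupSummary | tuple,
    group2: GroupSummary | tuple,
    sd_ratio_limit: float = SD_RATIO_LIMIT,
) -> PartitionDecision:
    """Test whether two subgroups need separate reference intervals.

    ``z = |mean1 - mean2| / sqrt(sd1²/n1 + sd2²/n2)`` is compared against
    ``z* = 3·sqrt(((n1+n2)/2)/120)``, a 3-SD criterion normalized to the
    minimum recommended reference sample of 120; the secondary criterion
    fires when ``max(sd)/min(sd)`` exceeds ``sd_ratio_limit``.
    """
    g1 = group1 if isinstance(group1, GroupSummary) else GroupSummary(*group1)
    g2 = group2 if isinstance(group2, GroupSummary) else GroupSummary(*group2)
    for g in (g1, g2):
        if g.n < 2:
            raise ValueError(f"partition test needs n >= 2 per group, got {g.n}")
        if g.sd < 0:
            raise ValueError("standard deviations must be non-negative")
    if g1.sd == 0 and g2.sd == 0:
        raise ValueError("partition test undefined when both SDs are zero")

    se = math.sqrt(g1.sd**2 / g1.n + g2.sd**2 / g2.n)
    z = abs(g1.mean - g2.mean) / se
    z_star = 3.0 * math.sqrt(((g1.n + g2.n) / 2.0) / 120.0)
    lo_sd, hi_sd = sorted((g1.sd, g2.sd))
    sd_ratio = math.inf if lo_sd == 0 else hi_sd / lo_sd
    return PartitionDecision(
        z=z,
        z_star=z_star,
        sd_ratio=sd_ratio,
        partition=(z > z_star) or (sd_ratio > sd_ratio_limit),
        sd_ratio_limit=sd_ratio_limit,
    )
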
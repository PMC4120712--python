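"""Agreement analysis of paired diameter measurements.

Bland-Altman limits of agreement at mean +/- 2 SD of the paired
differences (the 2-SD convention used throughout; 1.96 is available via
``loa_multiplier``), the coefficient of determination of an ordinary
least-squares fit of the second series on the first, and a paired
two-sided t-test of zero mean difference. Differences are taken as
(reference - algorithm) throughout.

Size-group summaries follow the BCLC-motivated cuts: d <= 3 cm,
3 < d <= 5 cm and d > 5 cm of the reference diameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementStats",
    "PairingError",
    "bland_altman",
    "group_summary",
    "GROUP_LABELS",
]

GROUP_LABELS = ("d<=3cm", "3cm<d<=5cm", "d>5cm")


class PairingError(ValueError):
    """The two measurement series cannot be paired."""


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman and linear-agreement summary of two paired series.

    ``mean_diff`` etc. are in the units of the inputs (cm here);
    ``loa_low/high`` are mean_diff -/+ k*sd_diff with k the LoA multiplier
    used; ``r`` is the sample correlation (signed), ``r_squared`` its
    square; ``p_value`` is NaN (flagged by ``degenerate``) when the paired
    differences have zero variance.
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r: float
    r_squared: float
    t_statistic: float
    p_value: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    loa_multiplier: float = 2.0,
) -> AgreementStats:
    """Agreement between reference series ``a`` and test series ``b``.

    Differences d = a - b; sd uses the n-1 denominator; LoA at
    mean +/- ``loa_multiplier`` * sd. R² comes from the OLS fit of b on a
    (equal to the squared sample correlation). Swapping the two series
    negates the mean difference and mirrors the limits; adding a common
    constant to both leaves every field unchanged.
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.size != y.size:
        raise PairingError(f"series lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise PairingError(f"need at least 3 pairs, got {x.size}")

    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    degenerate = sd_diff == 0.0

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # constant series: the linear fit is undefined; perfect-agreement
        # input (a == b) still deserves r^2 = 1
        r = 1.0 if np.array_equal(x, y) else float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)

    if degenerate:
        t_stat = float("nan") if mean_diff == 0 else math.copysign(math.inf, mean_diff)
        p_val = float("nan")
    else:
        res = stats.ttest_rel(x, y)
        t_stat, p_val = float(res.statistic), float(res.pvalue)

    return AgreementStats(
        n=int(x.size),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - loa_multiplier * sd_diff,
        loa_high=mean_diff + loa_multiplier * sd_diff,
        r=r,
        r_squared=r * r,
        t_statistic=t_stat,
        p_value=p_val,
        degenerate=degenerate,
    )


def group_summary(
    pairs: Sequence[tuple[float, float]],
    bounds: tuple[float, float] = (3.0, 5.0),
    loa_multiplier: float = 2.0,
) -> dict[str, AgreementStats]:
    """Per-size-group agreement of (reference, measured) pairs.

    Pairs are partitioned on the reference value into d <= bounds[0],
    bounds[0] < d <= bounds[1], d > bounds[1]. A group with fewer than 3
    pairs is reported with its count, the mean difference when computable,
    and NaN (flagged degenerate) for every statistic that needs more data;
    an empty group has n = 0 and all-NaN stats.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"bounds must be ascending, got {bounds}")
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    ref, meas = arr[:, 0], arr[:, 1]

    nan = float("nan")
    masks = (ref <= lo, (ref > lo) & (ref <= hi), ref > hi)
    out: dict[str, AgreementStats] = {}
    for label, m in zip(GROUP_LABELS, masks):
        n = int(m.sum())
        if n >= 3:
            out[label] = bland_altman(ref[m], meas[m], loa_multiplier)
        else:
            out[label] = AgreementStats(
                n=n,
                mean_diff=float((ref[m] - meas[m]).mean()) if n else nan,
                sd_diff=nan,
                loa_low=nan,
                loa_high=nan,
                r=nan,
                r_squared=nan,
                t_statistic=nan,
                p_value=nan,
                degenerate=True,
            )
    return out
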
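"""Fragment-size fetal-fraction estimation and the size-ratio gate.

Fetal cfDNA is shorter than maternal cfDNA, so the ratio of short to long
fragment counts rises with the fetal fraction. The pipeline uses the ratio in
two ways: as an evaluability gate (a sample must show size ratio strictly
greater than 0.84 to be analysed) and, optionally, mapped to a fetal-fraction
estimate through a positive linear calibration.

Default windows follow the size-analysis convention this gate derives from:
short = [100, 150] bp, long = [163, 169] bp, both endpoint-inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

SHORT_WINDOW: tuple[int, int] = (100, 150)
LONG_WINDOW: tuple[int, int] = (163, 169)
SIZE_RATIO_GATE = 0.84


class NonEvaluableSample(ValueError):
    """No fragments in the long window: the size ratio is undefined.

    Distinct from a gate *failure* (ratio defined but ≤ gate) so reports can
    separate "could not be measured" from "measured and insufficient".
    """


@dataclass(frozen=True)
class SizeRatioResult:
    size_ratio: float
    n_short: int
    n_long: int
    passes_gate: bool


@dataclass(frozen=True)
class SizeCalibration:
    """Least-squares line mapping size ratio → fetal fraction."""

    slope: float
    intercept: float
    r: float
    n: int


def size_ratio(
    lengths: Sequence[int],
    short_window: tuple[float, float] = SHORT_WINDOW,
    long_window: tuple[float, float] = LONG_WINDOW,
    gate_cutoff: float = SIZE_RATIO_GATE,
) -> SizeRatioResult:
    """Count fragments in the short and long windows and form their ratio.

    Windows are endpoint-inclusive and must be disjoint. Raises
    :class:`NonEvaluableSample` when the long window is empty.
    """
    arr = np.asarray(lengths)
    if arr.size == 0:
        raise ValueError("empty length sample")
    s_lo, s_hi = short_window
    l_lo, l_hi = long_window
    if s_lo > s_hi or l_lo > l_hi:
        raise ValueError("windows must be nonempty intervals")
    if max(s_lo, l_lo) <= min(s_hi, l_hi):
        raise ValueError("short and long windows must be disjoint")
    n_short = int(np.count_nonzero((arr >= s_lo) & (arr <= s_hi)))
    n_long = int(np.count_nonzero((arr >= l_lo) & (arr <= l_hi)))
    if n_long == 0:
        raise NonEvaluableSample(
            "no fragments in the long window; size ratio undefined"
        )
    ratio = n_short / n_long
    return SizeRatioResult(ratio, n_short, n_long, ratio > gate_cutoff)


def gate(result: SizeRatioResult, cutoff: float = SIZE_RATIO_GATE) -> bool:
    """Strict gate: the sample is evaluable only when size_ratio > cutoff."""
    return result.size_ratio > cutoff


def fit_calibration(
    pairs: Sequence[tuple[float, float]]
) -> SizeCalibration:
    """Fit the size-ratio → fetal-fraction line by ordinary least squares.

    *pairs* are (size_ratio, known fetal fraction). Requires at least three
    pairs with non-degenerate ratios.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (ratio, ff) pairs")
    ratios = np.array([p[0] for p in pairs], dtype=float)
    ffs = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(ratios) == 0:
        raise ValueError("degenerate design: all size ratios identical")
    fit = stats.linregress(ratios, ffs)
    return SizeCalibration(float(fit.slope), float(fit.intercept), float(fit.rvalue), len(pairs))


def apply_calibration(calibration: SizeCalibration, ratio: float) -> float:
    """Map a size ratio to a fetal-fraction estimate, clamped to [0, 1]."""
    ff = calibration.slope * ratio + calibration.intercept
    return float(min(max(ff, 0.0), 1.0))
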
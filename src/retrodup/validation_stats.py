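"""Statistical utilities for the validation analyses.

Fisher's exact test on 2x2 tables (two-sided, point-probability method),
qPCR relative quantification (2^-dCt x 1e6 with a Ct cutoff of 32 cycles),
and window-of-linearity amplification-efficiency estimation on the 1-2
per-cycle scale, with 1.8 as the strict acceptability bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

CT_CUTOFF_DEFAULT = 32.0
EFFICIENCY_ACCEPTABLE_MIN = 1.8


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    With margins fixed, all tables whose hypergeometric point probability
    does not exceed the observed table's are summed (the common
    minimum-likelihood convention; a relative tolerance of 1e-7 guards the
    tie comparison against rounding).  A zero margin gives p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cells must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    rv = stats.hypergeom(n, r1, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


@dataclass
class CtRecord:
    """One qPCR measurement: target and endogenous-reference Ct values."""

    sample: str
    target: str
    ct_target: float
    ct_reference: float
    cutoff: float = CT_CUTOFF_DEFAULT

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")


def qpcr_relative_quantity(record: CtRecord) -> Optional[float]:
    """Relative quantity 2^-(Ct_target - Ct_reference) x 1e6, or None
    (not expressed) when the target Ct exceeds the cutoff."""
    if record.ct_target > record.cutoff:
        return None
    delta_ct = record.ct_target - record.ct_reference
    return float(2.0 ** (-delta_ct) * 1e6)


@dataclass
class EfficiencyEstimate:
    efficiency: float
    acceptable: bool  # strictly above 1.8
    window: Tuple[int, int]  # [start, end) cycle indices (0-based)
    r_squared: float


def estimate_efficiency(fluorescence: Sequence[float],
                        window_size: int = 4,
                        n_baseline_cycles: int = 3) -> EfficiencyEstimate:
    """Window-of-linearity efficiency estimate.

    The baseline is the mean of the first *n_baseline_cycles* cycles and
    is subtracted; among all runs of *window_size* consecutive
    above-baseline cycles, the window maximising the R-squared of a line
    fit to log10(signal) wins (ties go to the brighter window, which sits
    deeper in the exponential phase).  Efficiency is 10^slope; values
    above 1.8 are flagged acceptable.
    """
    f = np.asarray(fluorescence, dtype=float)
    if len(f) < n_baseline_cycles + window_size:
        raise ValueError("curve too short")
    baseline = f[:n_baseline_cycles].mean()
    signal = f - baseline
    max_signal = signal.max()
    if max_signal <= 0:
        raise ValueError("no above-baseline window of the requested size")
    # exponential-phase band: high enough to clear baseline-subtraction
    # error, low enough to avoid plateau suppression of the slope
    lo, hi = 1e-3 * max_signal, 2e-2 * max_signal
    ok = (signal > lo) & (signal <= hi)
    if not _has_run(ok, window_size):  # short or truncated curves
        ok = signal > 0
        if not _has_run(ok, window_size):
            raise ValueError("no above-baseline window of the requested size")

    def fit(start: int, size: int) -> Tuple[float, float, float]:
        x = np.arange(size, dtype=float)
        y = np.log10(signal[start:start + size])
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - ((y - pred) ** 2).sum() / sst if sst > 0 else 0.0
        return slope, r2, y.mean()

    best: Optional[Tuple[float, float, int]] = None  # (r2, mean_log, start)
    for start in range(n_baseline_cycles, len(f) - window_size + 1):
        if not ok[start:start + window_size].all():
            continue
        _, r2, mean_log = fit(start, window_size)
        if (best is None or r2 > best[0] + 1e-12
                or (r2 > best[0] - 1e-12 and mean_log > best[1])):
            best = (r2, mean_log, start)
    if best is None:
        raise ValueError("no above-baseline window of the requested size")
    r2, _, start = best
    size = window_size
    # widen the window of linearity while the fit stays straight
    while True:
        grown = False
        for s2, z2 in ((start - 1, size + 1), (start, size + 1)):
            if s2 < n_baseline_cycles or s2 + z2 > len(f):
                continue
            if not ok[s2:s2 + z2].all():
                continue
            _, r2_new, _ = fit(s2, z2)
            if r2_new >= min(0.995, r2 - 0.002):
                start, size, r2 = s2, z2, r2_new
                grown = True
                break
        if not grown:
            break
    slope, r2, _ = fit(start, size)
    eff = float(10.0 ** slope)
    return EfficiencyEstimate(
        efficiency=eff, acceptable=eff > EFFICIENCY_ACCEPTABLE_MIN,
        window=(start, start + size), r_squared=float(r2))


def _has_run(mask: np.ndarray, size: int) -> bool:
    run = 0
    for m in mask:
        run = run + 1 if m else 0
        if run >= size:
            return True
    return False
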
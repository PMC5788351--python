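"""Treated-vs-untreated comparison: effect curves and two-proportion tests.

The treatment effect at a time point is the mean difference between the
proportion of AD cases in the untreated and treated groups.  Statistical
significance uses the classical pooled-variance z test for the equality of
two binomial proportions, two-tailed at the 95% confidence level:

    p̂ = (x1 + x2) / (n1 + n2)
    z  = (x1/n1 − x2/n2) / sqrt(p̂ (1 − p̂) (1/n1 + 1/n2))

Two usage modes are provided, since a simulated trial yields a whole
distribution of AD counts: :func:`effect_curve` applies the test once per
time point to the expected counts (mean proportion × N, rounded), and
:func:`rejection_rate` applies it per realisation and reports the fraction
of simulated trial pairs in which the null is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .states import DiseaseState, InvalidParameterError
from .trial import TrialOutcome

__all__ = ["GroupComparison", "two_proportion_test", "effect_curve", "rejection_rate"]


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-proportion equality test."""

    x1: int
    n1: int
    x2: int
    n2: int
    effect: float
    z: float
    p_value: float
    significant: bool
    degenerate: bool = False
    time_month: int | None = None


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05
) -> GroupComparison:
    """Pooled-variance two-tailed z test for p1 = p2.

    ``x1``/``n1`` are the untreated AD count and group size, ``x2``/``n2``
    the treated ones; the reported effect is ``x1/n1 − x2/n2``.  When the
    pooled proportion is 0 or 1 the statistic is undefined: the comparison
    is flagged degenerate with p-value 1.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidParameterError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise InvalidParameterError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return GroupComparison(
            x1, n1, x2, n2, effect=p1 - p2, z=0.0, p_value=1.0,
            significant=False, degenerate=True,
        )
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p_value = 2.0 * stats.norm.sf(abs(z))
    return GroupComparison(
        x1, n1, x2, n2, effect=p1 - p2, z=float(z), p_value=float(p_value),
        significant=bool(p_value < alpha),
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def effect_curve(
    untreated: TrialOutcome, treated: TrialOutcome, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-time-point mean effect and equality test on expected counts.

    Both outcomes must share the time grid and group size.  The test at
    each time point uses the realisation-mean AD counts rounded to
    integers.  The returned frame carries columns ``time_month``,
    ``effect``, ``z``, ``p_value``, ``significant`` and, in
    ``.attrs["earliest_sustained_significance"]``, the first time point
    from which every later test is significant (``None`` if none).
    """
    if not np.array_equal(untreated.times_months, treated.times_months):
        raise InvalidParameterError("outcomes have different time grids")
    if untreated.n_individuals != treated.n_individuals:
        raise InvalidParameterError("outcomes have different group sizes")
    n = untreated.n_individuals
    mean_u = untreated.mean_proportion(DiseaseState.AD)
    mean_t = treated.mean_proportion(DiseaseState.AD)
    x_u = _round_half_away(mean_u * n).astype(int)
    x_t = _round_half_away(mean_t * n).astype(int)
    rows = []
    for t, xu, xt, pu, pt in zip(untreated.times_months, x_u, x_t, mean_u, mean_t):
        cmp = two_proportion_test(int(xu), n, int(xt), n, alpha=alpha)
        rows.append(
            {
                "time_month": int(t),
                "effect": pu - pt,
                "z": cmp.z,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
            }
        )
    frame = pd.DataFrame(rows)
    sig = frame["significant"].to_numpy()
    earliest = None
    for k in range(len(sig)):
        if sig[k:].all() and sig[k]:
            earliest = int(frame["time_month"].iloc[k])
            break
    frame.attrs["earliest_sustained_significance"] = earliest
    return frame


def rejection_rate(
    untreated: TrialOutcome,
    treated: TrialOutcome,
    time_month: int,
    alpha: float = 0.05,
) -> float:
    """Fraction of realisation pairs rejecting equality at one time point.

    Pairs realisation r of each arm, applies the two-proportion test to
    the realised AD counts at ``time_month`` and returns the rejection
    fraction — the Monte-Carlo power (or size, under the null) of the
    trial design.
    """
    if untreated.n_realisations != treated.n_realisations:
        raise InvalidParameterError("outcomes have different realisation counts")
    grid = list(untreated.times_months)
    if time_month not in grid:
        raise InvalidParameterError(f"time {time_month} not on the outcome grid")
    k = grid.index(time_month)
    xu = untreated.counts[:, k, DiseaseState.AD]
    xt = treated.counts[:, k, DiseaseState.AD]
    rejected = 0
    for a, b in zip(xu, xt):
        cmp = two_proportion_test(
            int(a), untreated.n_individuals, int(b), treated.n_individuals,
            alpha=alpha,
        )
        if cmp.significant:
            rejected += 1
    return rejected / untreated.n_realisations
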
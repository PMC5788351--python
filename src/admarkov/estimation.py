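"""Interval MLE, pooled average one-year probabilities, bootstrap, Normal fit.

The interval maximum-likelihood estimate of a transition probability is the
observed transition fraction

    p̂(S_i → S_j, t) = τ(S_i → S_j, t) / Σ_l τ(S_i → S_l, t),

computed independently for each one-year interval t under piecewise
homogeneity.  The *average* one-year probability pools the counts over all
intervals before applying the same ratio — equivalent to a sample-size
weighted average of the interval estimates.  Sampling uncertainty is
quantified by a stratified bootstrap: within every (interval, origin
state) stratum the observed transitions are resampled with replacement at
their original size, each replicate is pooled, and a Normal distribution
is fitted to the replicate averages by maximum likelihood (divisor-B
standard deviation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import (
    N_STATES,
    STATE_LABELS,
    DiseaseState,
    OFFDIAG_EDGES,
    TransitionParamTable,
    InvalidParameterError,
)

__all__ = [
    "mle_interval",
    "pooled_average",
    "bootstrap_average",
    "fit_normal",
    "estimate_param_table",
    "BootstrapDistribution",
    "counts_to_array",
]

_ORIGINS = (DiseaseState.CN, DiseaseState.MCI, DiseaseState.AD)


def counts_to_array(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a tidy counts table into a (T, 4, 4) array.

    Returns ``(intervals, arr)`` where ``intervals`` are the sorted
    interval indices present and ``arr[k, i, j]`` is the count for
    ``intervals[k]``.
    """
    required = {"interval", "from", "to", "count"}
    if not required.issubset(counts.columns):
        raise InvalidParameterError(f"counts table needs columns {sorted(required)}")
    intervals = np.array(sorted(counts["interval"].unique()), dtype=int)
    pos = {t: k for k, t in enumerate(intervals)}
    arr = np.zeros((len(intervals), N_STATES, N_STATES))
    for t, src, dst, n in zip(
        counts["interval"], counts["from"], counts["to"], counts["count"]
    ):
        if n < 0:
            raise InvalidParameterError("negative transition count")
        arr[pos[t], DiseaseState[src], DiseaseState[dst]] += n
    return intervals, arr


def _ratio_frame(totals: np.ndarray, interval=None) -> pd.DataFrame:
    """Apply the MLE ratio to a (4, 4) count matrix; unobserved origins → NaN."""
    rows = []
    for origin in _ORIGINS:
        denom = totals[origin].sum()
        for dest in DiseaseState:
            prob = np.nan if denom == 0 else totals[origin, dest] / denom
            rows.append(
                {
                    "interval": interval,
                    "from": origin.name,
                    "to": dest.name,
                    "prob": prob,
                }
            )
    frame = pd.DataFrame(rows, columns=["interval", "from", "to", "prob"])
    if interval is None:
        frame = frame.drop(columns=["interval"])
    return frame


def mle_interval(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-interval MLE transition probabilities.

    Returns a tidy frame ``interval,from,to,prob`` covering every origin
    state and destination for each interval present in ``counts``.  Origin
    states with zero observations in an interval are flagged with ``NaN``
    probabilities rather than zeros.
    """
    intervals, arr = counts_to_array(counts)
    frames = [_ratio_frame(arr[k], interval=int(t)) for k, t in enumerate(intervals)]
    return pd.concat(frames, ignore_index=True)


def pooled_average(counts: pd.DataFrame) -> pd.DataFrame:
    """Average one-year probabilities: counts summed over intervals, then Eq-ratio."""
    _, arr = counts_to_array(counts)
    if arr.shape[0] == 0:
        raise InvalidParameterError("no observed intervals")
    return _ratio_frame(arr.sum(axis=0))


@dataclass
class BootstrapDistribution:
    """Replicate average one-year transition matrices.

    ``samples`` has shape (B, 4, 4); each replicate's CN/MCI/AD rows are
    row-stochastic (origins never observed are NaN).
    """

    samples: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.samples.shape[0]

    def edge_samples(self, origin: DiseaseState, dest: DiseaseState) -> np.ndarray:
        return self.samples[:, origin, dest]


def bootstrap_average(
    counts: pd.DataFrame, n_replicates: int = 10_000, rng_seed=None
) -> BootstrapDistribution:
    """Stratified bootstrap of the pooled average one-year probabilities.

    Within each (interval, origin state) stratum the observed transitions
    are resampled with replacement at their original size (a multinomial
    draw over the observed destination fractions), the replicate counts
    are pooled over intervals, and the MLE ratio is applied.  Deterministic
    given ``rng_seed``.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    _, arr = counts_to_array(counts)
    B = int(n_replicates)
    pooled = np.zeros((B, N_STATES, N_STATES))
    for origin in _ORIGINS:
        for k in range(arr.shape[0]):
            row = arr[k, origin]
            n = int(row.sum())
            if n == 0:
                continue
            pooled[:, origin, :] += rng.multinomial(n, row / n, size=B)
    out = np.full((B, N_STATES, N_STATES), np.nan)
    for origin in _ORIGINS:
        denom = pooled[:, origin, :].sum(axis=1)
        observed = denom > 0
        if observed.all():
            out[:, origin, :] = pooled[:, origin, :] / denom[:, None]
    return BootstrapDistribution(out)


def fit_normal(dist: BootstrapDistribution) -> TransitionParamTable:
    """Fit Normal(mean, sd) per edge to the bootstrap replicates.

    The fit is the maximum-likelihood one: sample mean and divisor-B
    standard deviation of each edge's replicate vector.  A degenerate
    (constant) replicate vector yields sd 0 with a warning.
    """
    if dist.n_replicates < 2:
        raise InvalidParameterError("need at least 2 bootstrap replicates")
    means = {}
    sds = {}
    for edge in OFFDIAG_EDGES:
        vec = dist.edge_samples(*edge)
        if np.isnan(vec).all():
            means[edge] = 0.0
            sds[edge] = 0.0
            warnings.warn(
                f"origin {edge[0].name} never observed; edge {edge[0].name}->"
                f"{edge[1].name} set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        means[edge] = float(np.mean(vec))
        sds[edge] = float(np.std(vec))  # divisor B (MLE)
        if sds[edge] == 0.0:
            warnings.warn(
                f"degenerate bootstrap distribution on edge "
                f"{edge[0].name}->{edge[1].name}: sd = 0",
                RuntimeWarning,
                stacklevel=2,
            )
    return TransitionParamTable(means, sds)


def estimate_param_table(
    counts: pd.DataFrame, n_replicates: int = 10_000, rng_seed=None
) -> TransitionParamTable:
    """Counts → bootstrap → Normal fit, the full uncertainty pipeline."""
    return fit_normal(bootstrap_average(counts, n_replicates, rng_seed))
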
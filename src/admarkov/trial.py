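"""Monte-Carlo clinical-trial simulator for the disease-progression chain.

A trial simulates ``n_individuals`` over ``duration_months`` in monthly
steps (configurable).  At the beginning of every realisation each
individual is assigned their own annual transition probabilities, drawn
from the parameter table's per-edge Normal distributions; individuals then
walk the chain independently with synchronous updates.  Annual
probabilities are converted to the step scale with the per-edge
complement-root ``q = 1 − (1 − p)**(1/steps_per_year)``.

Hypothetical preventative treatments multiply the annual probability of a
progression edge (CN→MCI and/or MCI→AD) by ``1 − E`` for efficacy
``E ∈ [0, 1]``, homogeneously across individuals, optionally only after an
activation delay.  Outcome summaries follow the trial-endpoint
conventions: per-time-point mean, standard deviation and equal-tailed 95%
credible interval of the AD proportion across realisations, plus secondary
endpoints (AD incidence proportion, expected time per state, time and
probability to reach a state).

Proportions are always relative to the enrolled ``n_individuals``;
withdrawn individuals stay in the denominator, counted in the WITHDRAWN
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import (
    N_STATES,
    STATE_LABELS,
    DiseaseState,
    TREATABLE_EDGES,
    TransitionParamTable,
    InvalidParameterError,
    annual_to_step,
    draw_cohort_probs,
)

__all__ = [
    "TreatmentSpec",
    "TrialConfig",
    "TrialOutcome",
    "SecondaryEndpoints",
    "apply_treatment",
    "run_trial",
    "summarize",
    "secondary_endpoints",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """Multiplicative reduction of progression-edge transition probabilities.

    ``e_cn_mci`` and ``e_mci_ad`` are the efficacies E on the CN→MCI and
    MCI→AD edges (0 = no effect, 1 = full block).  ``delay_months`` is the
    activation delay: transitions occurring before it use the untreated
    probabilities.  Treatment effects are homogeneous across individuals.
    """

    e_cn_mci: float = 0.0
    e_mci_ad: float = 0.0
    delay_months: int = 0

    def __post_init__(self) -> None:
        for name, e in (("e_cn_mci", self.e_cn_mci), ("e_mci_ad", self.e_mci_ad)):
            if not (np.isfinite(e) and 0.0 <= e <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {e}")
        if self.delay_months < 0 or int(self.delay_months) != self.delay_months:
            raise InvalidParameterError("delay_months must be a non-negative integer")

    @property
    def efficacies(self) -> dict:
        return {
            (DiseaseState.CN, DiseaseState.MCI): self.e_cn_mci,
            (DiseaseState.MCI, DiseaseState.AD): self.e_mci_ad,
        }


def apply_treatment(
    probs: np.ndarray, spec: TreatmentSpec, current_month: int = 0
) -> np.ndarray:
    """Scale treated edges of annual matrices by (1 − E) and re-close.

    If ``current_month`` is before the activation delay the input is
    returned unchanged (as a copy).  Accepts a single (4, 4) matrix or a
    batch (..., 4, 4); the freed probability mass moves to the origin's
    self-loop, so row-stochasticity is preserved.
    """
    probs = np.asarray(probs, dtype=float)
    out = probs.copy()
    if current_month < spec.delay_months:
        return out
    for (i, j), e in spec.efficacies.items():
        if e == 0.0:
            continue
        assert (i, j) in TREATABLE_EDGES
        freed = out[..., i, j] * e
        out[..., i, j] -= freed
        out[..., i, i] += freed
    return out


@dataclass
class TrialConfig:
    """Configuration of one simulated trial arm."""

    n_individuals: int = 1000
    initial_composition: dict = field(default_factory=lambda: {"CN": 1.0})
    duration_months: int = 120
    steps_per_year: int = 12
    realisations: int = 10_000
    treatment: TreatmentSpec | None = None
    table: TransitionParamTable | None = None
    seed: int = 0
    track_individuals: bool = False

    def __post_init__(self) -> None:
        if self.table is None:
            self.table = TransitionParamTable.default()
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be >= 1")
        if self.realisations < 1:
            raise InvalidParameterError("realisations must be >= 1")
        if self.steps_per_year < 1 or 12 % self.steps_per_year != 0:
            raise InvalidParameterError("steps_per_year must divide 12")
        self.step_months = 12 // self.steps_per_year
        if self.duration_months % self.step_months != 0:
            raise InvalidParameterError(
                "duration_months must be a multiple of the step length "
                f"({self.step_months} months)"
            )
        bad = set(self.initial_composition) - {"CN", "MCI", "AD"}
        if bad:
            raise InvalidParameterError(
                f"initial composition keys must be CN/MCI/AD, got {sorted(bad)}"
            )
        vals = list(self.initial_composition.values())
        if any(v < 0 for v in vals) or sum(vals) <= 0:
            raise InvalidParameterError("initial composition must be non-negative")

    def initial_states(self) -> np.ndarray:
        """Deterministic initial state vector matching the composition."""
        fracs = np.array(
            [self.initial_composition.get(s, 0.0) for s in ("CN", "MCI", "AD")],
            dtype=float,
        )
        fracs = fracs / fracs.sum()
        counts = np.floor(fracs * self.n_individuals).astype(int)
        remainder = self.n_individuals - counts.sum()
        order = np.argsort(-(fracs * self.n_individuals - counts))
        for k in range(remainder):
            counts[order[k % 3]] += 1
        return np.repeat(np.arange(3), counts).astype(np.int64)


@dataclass
class TrialOutcome:
    """Per-time-point state counts across realisations, plus endpoint data.

    ``counts`` has shape (R, T+1, 4) with integer occupant counts per
    realisation, time point and state; ``times_months`` has length T+1.
    The per-individual endpoint aggregates (``incidence``,
    ``months_in_state``, ``reach_fraction``, ``first_passage_mean``) are
    populated only when the trial was run with ``track_individuals``.
    """

    times_months: np.ndarray
    counts: np.ndarray
    n_individuals: int
    seed: int
    incidence: np.ndarray | None = None
    months_in_state: np.ndarray | None = None
    reach_fraction: np.ndarray | None = None
    first_passage_mean: np.ndarray | None = None

    @property
    def n_realisations(self) -> int:
        return self.counts.shape[0]

    @property
    def proportions(self) -> np.ndarray:
        """(R, T+1, 4) state proportions relative to the enrolled cohort."""
        return self.counts / self.n_individuals

    def state_proportions(self, state: DiseaseState) -> np.ndarray:
        return self.counts[:, :, int(state)] / self.n_individuals

    def mean_proportion(self, state: DiseaseState) -> np.ndarray:
        return self.state_proportions(state).mean(axis=0)


def _step_matrices(config: TrialConfig, annual: np.ndarray) -> tuple:
    """Cumulative step-scale transition matrices (untreated, treated)."""
    untreated = annual_to_step(annual, config.steps_per_year)
    cum_untreated = np.cumsum(untreated, axis=-1)
    if config.treatment is None:
        return cum_untreated, cum_untreated
    treated_annual = apply_treatment(
        annual, config.treatment, current_month=config.treatment.delay_months
    )
    treated = annual_to_step(treated_annual, config.steps_per_year)
    return cum_untreated, np.cumsum(treated, axis=-1)


def run_trial(config: TrialConfig) -> TrialOutcome:
    """Simulate all realisations of a trial arm.

    Per realisation: draw per-individual annual probabilities, build the
    untreated and (post-delay) treated step matrices, and walk all
    individuals forward with synchronous updates.  Realisations are
    independent; each uses the substream ``SeedSequence([seed, r])`` so
    results are reproducible and unchanged by increasing ``realisations``.
    """
    N = config.n_individuals
    R = config.realisations
    n_steps = config.duration_months // config.step_months
    delay = config.treatment.delay_months if config.treatment else 0

    times = np.arange(n_steps + 1) * config.step_months
    counts = np.zeros((R, n_steps + 1, N_STATES), dtype=np.int32)
    init = config.initial_states()
    track = config.track_individuals
    if track:
        incidence = np.zeros(R)
        months_in_state = np.zeros((R, N_STATES))
        reach_fraction = np.zeros((R, N_STATES))
        first_passage_mean = np.full((R, N_STATES), np.nan)

    idx = np.arange(N)
    for r in range(R):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        annual = draw_cohort_probs(config.table, N, rng)
        cum_untreated, cum_treated = _step_matrices(config, annual)

        states = init.copy()
        counts[r, 0] = np.bincount(states, minlength=N_STATES)
        if track:
            first_entry = np.full((N, N_STATES), -1, dtype=np.int32)
            first_entry[idx, states] = 0
            occupancy = np.zeros((N, N_STATES))
        for t in range(1, n_steps + 1):
            if track:
                occupancy[idx, states] += config.step_months
            # transition t-1 -> t occurs at elapsed time (t-1) steps
            active = cum_treated if (t - 1) * config.step_months >= delay else cum_untreated
            rows = active[idx, states]
            u = rng.random(N)
            states = (rows < u[:, None]).sum(axis=1).astype(np.int64)
            np.clip(states, 0, N_STATES - 1, out=states)
            counts[r, t] = np.bincount(states, minlength=N_STATES)
            if track:
                new = first_entry[idx, states] < 0
                first_entry[idx[new], states[new]] = t * config.step_months
        if track:
            reached = first_entry >= 0
            incidence[r] = reached[:, DiseaseState.AD].mean()
            months_in_state[r] = occupancy.mean(axis=0)
            reach_fraction[r] = reached.mean(axis=0)
            with np.errstate(invalid="ignore"):
                for s in range(N_STATES):
                    if reached[:, s].any():
                        first_passage_mean[r, s] = first_entry[reached[:, s], s].mean()

    outcome = TrialOutcome(
        times_months=times, counts=counts, n_individuals=N, seed=config.seed
    )
    if track:
        outcome.incidence = incidence
        outcome.months_in_state = months_in_state
        outcome.reach_fraction = reach_fraction
        outcome.first_passage_mean = first_passage_mean
    return outcome


def summarize(outcome: TrialOutcome, level: float = 0.95) -> pd.DataFrame:
    """Per-time-point summary of the state-proportion distributions.

    Returns a tidy frame ``time_month,state,mean,sd,ci_lo,ci_hi`` where
    ``sd`` uses divisor R−1 and the credible interval is the equal-tailed
    empirical (order-statistic) quantile interval at ``level``.
    """
    if outcome.n_realisations < 2:
        raise InvalidParameterError("summaries need at least 2 realisations")
    props = outcome.proportions
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(props, alpha, axis=0, method="inverted_cdf")
    hi = np.quantile(props, 1.0 - alpha, axis=0, method="inverted_cdf")
    mean = props.mean(axis=0)
    sd = props.std(axis=0, ddof=1)
    frames = []
    for s in DiseaseState:
        frames.append(
            pd.DataFrame(
                {
                    "time_month": outcome.times_months,
                    "state": s.name,
                    "mean": mean[:, s],
                    "sd": sd[:, s],
                    "ci_lo": lo[:, s],
                    "ci_hi": hi[:, s],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["n"] = outcome.n_individuals
    return out


@dataclass
class SecondaryEndpoints:
    """Realisation-averaged secondary trial endpoints."""

    incidence_ad: float
    mean_months_in_state: dict
    reach_probability: dict
    mean_first_passage_month: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": list(STATE_LABELS),
                "mean_months_in_state": [
                    self.mean_months_in_state[s] for s in STATE_LABELS
                ],
                "reach_probability": [self.reach_probability[s] for s in STATE_LABELS],
                "mean_first_passage_month": [
                    self.mean_first_passage_month[s] for s in STATE_LABELS
                ],
            }
        )


def secondary_endpoints(outcome: TrialOutcome) -> SecondaryEndpoints:
    """Averaged incidence, time-in-state, and first-passage endpoints.

    ``mean_months_in_state`` counts person-time over the trial horizon
    (occupancy at the start of each step, times the step length), so with
    all transition probabilities zero the time spent in the baseline state
    equals the trial duration.  First-passage means are averaged over the
    realisations in which at least one individual reached the state.
    """
    if outcome.incidence is None:
        raise InvalidParameterError(
            "per-individual trajectories were not tracked; rerun the trial "
            "with track_individuals=True"
        )
    fp = np.empty(N_STATES)
    for k in range(N_STATES):
        col = outcome.first_passage_mean[:, k]
        col = col[~np.isnan(col)]
        fp[k] = col.mean() if col.size else np.nan
    return SecondaryEndpoints(
        incidence_ad=float(outcome.incidence.mean()),
        mean_months_in_state={
            s: float(outcome.months_in_state[:, k].mean())
            for k, s in enumerate(STATE_LABELS)
        },
        reach_probability={
            s: float(outcome.reach_fraction[:, k].mean())
            for k, s in enumerate(STATE_LABELS)
        },
        mean_first_passage_month={
            s: float(fp[k]) for k, s in enumerate(STATE_LABELS)
        },
    )
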
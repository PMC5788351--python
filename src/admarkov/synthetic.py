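"""Synthetic ADNI-like longitudinal cohorts with known ground truth.

The generator emulates the structure of a staggered multi-protocol
observational study: subjects enter in enrolment waves with different
maximum follow-up (later waves have inherently shorter follow-up), are
assessed yearly, carry a baseline diagnosis mix that includes the
SMC category excluded at analysis time, and can withdraw from any state.
Each subject's trajectory is a Markov walk driven by annual transition
probabilities drawn once per subject from a ground-truth parameter table
(zero SDs make the probabilities shared), so estimation code can be tested
for exact parameter recovery.

Determinism: a single integer seed drives a counter-based per-subject
substream (``SeedSequence([seed, subject_index])``), so each subject's
trajectory is reproducible independently of the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import (
    DiseaseState,
    TransitionParamTable,
    InvalidParameterError,
    annual_to_step,
    draw_cohort_probs,
)

__all__ = ["CohortSpec", "generate_cohort", "subject_plan", "make_filter_fixture"]

#: Baseline diagnosis mix loosely matching a memory-clinic recruitment
#: profile (MCI-enriched, with a small SMC stratum).
DEFAULT_COMPOSITION = {"CN": 0.30, "MCI": 0.47, "AD": 0.17, "SMC": 0.06}

#: Enrolment waves as (fraction of subjects, follow-up cap in years) —
#: three protocols with decreasing follow-up depth.
DEFAULT_WAVES = ((0.50, 10), (0.25, 7), (0.25, 5))


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort draw."""

    n_subjects: int = 1000
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    waves: tuple = DEFAULT_WAVES
    table: TransitionParamTable | None = None
    interval_months: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.table is None:
            self.table = TransitionParamTable.default()
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.composition.values()):
            raise InvalidParameterError("composition fractions must be >= 0 and sum to 1")
        if any(k not in ("CN", "MCI", "AD", "SMC") for k in self.composition):
            raise InvalidParameterError("composition keys must be CN/MCI/AD/SMC")
        wave_total = sum(f for f, _ in self.waves)
        if abs(wave_total - 1.0) > 1e-9 or any(c < 1 for _, c in self.waves):
            raise InvalidParameterError("wave fractions must sum to 1, caps >= 1 year")
        if self.interval_months < 1 or 12 % self.interval_months != 0:
            raise InvalidParameterError("interval_months must divide 12")


def _proportional_sequence(n: int, fractions: list[float]) -> np.ndarray:
    """Deterministic proportional assignment, stable under growth of n.

    Subject i receives the category with the largest current deficit
    ``fraction * (i+1) − assigned``, so prefixes are independent of n.
    """
    fracs = np.asarray(fractions, dtype=float)
    assigned = np.zeros(len(fracs))
    out = np.empty(n, dtype=int)
    for i in range(n):
        deficit = fracs * (i + 1) - assigned
        j = int(np.argmax(deficit))
        out[i] = j
        assigned[j] += 1
    return out


def subject_plan(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic per-subject baseline state and follow-up cap.

    Returns columns ``subject_id``, ``baseline``, ``cap_years``.
    """
    comp_labels = list(spec.composition)
    state_idx = _proportional_sequence(
        spec.n_subjects, [spec.composition[k] for k in comp_labels]
    )
    wave_idx = _proportional_sequence(spec.n_subjects, [f for f, _ in spec.waves])
    caps = np.array([c for _, c in spec.waves], dtype=int)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(spec.n_subjects)],
            "baseline": [comp_labels[k] for k in state_idx],
            "cap_years": caps[wave_idx],
        }
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate visit records for a whole cohort.

    Each non-SMC subject walks the chain at the assessment interval using
    annual probabilities drawn once from ``spec.table``; a move into
    WITHDRAWN ends the record and sets the ``withdrew`` flag on the last
    observed visit.  SMC subjects are static (they are excluded before any
    transition counting).  Forbidden transitions can never be generated
    because the drawn matrices carry the structural zero pattern.
    """
    plan = subject_plan(spec)
    steps_per_year = 12 // spec.interval_months

    ids: list[str] = []
    months: list[int] = []
    dxs: list[str] = []
    flags: list[int] = []

    for idx, (sid, baseline, cap_years) in enumerate(
        zip(plan["subject_id"], plan["baseline"], plan["cap_years"])
    ):
        n_steps = int(cap_years) * steps_per_year
        if baseline == "SMC":
            for t in range(n_steps + 1):
                ids.append(sid)
                months.append(t * spec.interval_months)
                dxs.append("SMC")
                flags.append(0)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        annual = draw_cohort_probs(spec.table, 1, rng)[0]
        step = annual_to_step(annual, steps_per_year)
        cum = np.cumsum(step, axis=1)
        state = DiseaseState[baseline]
        ids.append(sid)
        months.append(0)
        dxs.append(baseline)
        flags.append(0)
        for t in range(1, n_steps + 1):
            u = rng.random()
            state = DiseaseState(int(np.searchsorted(cum[state], u, side="right")))
            if state == DiseaseState.WITHDRAWN:
                flags[-1] = 1
                break
            ids.append(sid)
            months.append(t * spec.interval_months)
            dxs.append(state.name)
            flags.append(0)

    return pd.DataFrame(
        {"subject_id": ids, "visit_month": months, "diagnosis": dxs, "withdrew": flags}
    )


# ---------------------------------------------------------------------------
# fixed filter fixture

#: Small catalogue of structurally valid yearly trajectories (all with at
#: least one follow-up visit), cycled over the analysable subjects.
_TRAJECTORIES = (
    ("CN", "CN", "CN", "CN"),
    ("CN", "CN", "MCI", "MCI"),
    ("CN", "MCI", "AD"),
    ("MCI", "MCI", "AD", "AD"),
    ("MCI", "CN", "CN"),
    ("AD", "AD"),
    ("CN", "CN"),
    ("MCI", "MCI", "MCI"),
)


def make_filter_fixture() -> pd.DataFrame:
    """Deterministic 1737-subject cohort for exercising the baseline filters.

    Contains exactly 106 baseline-SMC subjects, 7 screening-only subjects
    (a single visit and nothing after) and 1624 analysable subjects with
    yearly trajectories drawn round-robin from a fixed catalogue.
    """
    ids: list[str] = []
    months: list[int] = []
    dxs: list[str] = []

    def add(sid: str, traj) -> None:
        for t, dx in enumerate(traj):
            ids.append(sid)
            months.append(t * 12)
            dxs.append(dx)

    for i in range(1624):
        add(f"A{i:04d}", _TRAJECTORIES[i % len(_TRAJECTORIES)])
    for i in range(106):
        add(f"SMC{i:03d}", ("SMC", "SMC", "SMC"))
    for i in range(7):
        add(f"SCR{i:03d}", ("CN",))

    return pd.DataFrame(
        {"subject_id": ids, "visit_month": months, "diagnosis": dxs}
    )
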
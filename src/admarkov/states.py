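"""Disease-state space, transition structure and transition-probability draws.

The model tracks four states: Cognitively Normal (CN), Mild Cognitive
Impairment (MCI), Alzheimer's Disease (AD) and Withdrawal (death or loss to
follow-up).  Transitions are allowed between CN and MCI in both directions
(cognitive recovery is possible), from MCI to AD, and from every clinical
state into Withdrawal.  AD is clinically irreversible: its only exit is
withdrawal.  Direct CN→AD conversion and AD→MCI reversal are excluded from
the structure; observed instances in cohort data are treated as
misclassification and reported separately by :mod:`admarkov.cohort`.

Average one-year transition probabilities are parameterised per edge as
independent Normal(mean, sd) distributions.  The packaged default table
holds estimates fitted to the ADNI-1/GO/2 longitudinal cohort.  Self-
transition probabilities are never parameters: each row's diagonal is the
closure 1 − Σ(off-diagonal), which guarantees row-stochasticity.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseState",
    "N_STATES",
    "STATE_LABELS",
    "OFFDIAG_EDGES",
    "TREATABLE_EDGES",
    "ALLOWED_MASK",
    "REPORTED_SELF_TRANSITION_MEANS",
    "TransitionParamTable",
    "InvalidParameterError",
    "DegenerateParametersError",
    "draw_individual_probs",
    "draw_cohort_probs",
    "annual_to_step",
    "validate_matrix",
    "MatrixValidation",
]


class DiseaseState(enum.IntEnum):
    """The four states of the progression model, in canonical matrix order."""

    CN = 0
    MCI = 1
    AD = 2
    WITHDRAWN = 3


N_STATES = 4
STATE_LABELS = tuple(s.name for s in DiseaseState)

#: Off-diagonal edges with a free transition probability.
OFFDIAG_EDGES: tuple[tuple[DiseaseState, DiseaseState], ...] = (
    (DiseaseState.CN, DiseaseState.MCI),
    (DiseaseState.CN, DiseaseState.WITHDRAWN),
    (DiseaseState.MCI, DiseaseState.CN),
    (DiseaseState.MCI, DiseaseState.AD),
    (DiseaseState.MCI, DiseaseState.WITHDRAWN),
    (DiseaseState.AD, DiseaseState.WITHDRAWN),
)

#: Progression edges a preventative treatment may act on.
TREATABLE_EDGES: tuple[tuple[DiseaseState, DiseaseState], ...] = (
    (DiseaseState.CN, DiseaseState.MCI),
    (DiseaseState.MCI, DiseaseState.AD),
)


def _allowed_mask() -> np.ndarray:
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    for i, j in OFFDIAG_EDGES:
        mask[i, j] = True
    for s in (DiseaseState.CN, DiseaseState.MCI, DiseaseState.AD,
              DiseaseState.WITHDRAWN):
        mask[s, s] = True
    return mask


#: Boolean (4, 4) mask of structurally allowed transitions (incl. self-loops).
ALLOWED_MASK = _allowed_mask()
ALLOWED_MASK.setflags(write=False)

#: Published fitted means of the self-transition probabilities for the
#: default parameter set, kept for cross-checking only (self-loops in this
#: package are always derived by closure).  Note the CN value differs from
#: the exact closure 1 − 0.0432 − 0.0372 = 0.9196 by one unit in the last
#: printed digit (rounding in the source table); MCI and AD close exactly.
REPORTED_SELF_TRANSITION_MEANS = {
    DiseaseState.CN: 0.9197,
    DiseaseState.MCI: 0.8300,
    DiseaseState.AD: 0.8235,
}


class InvalidParameterError(ValueError):
    """A transition-parameter value is non-finite or out of range."""


class DegenerateParametersError(RuntimeError):
    """Row rejection failed too many consecutive times during a draw."""


Edge = tuple[DiseaseState, DiseaseState]


@dataclass(frozen=True)
class TransitionParamTable:
    """Per-edge Normal(mean, sd) average one-year transition probabilities.

    Only the six off-diagonal allowed edges carry parameters; self-loop
    probabilities are closures.  ``means`` / ``sds`` map each edge to its
    Normal parameters on the probability scale.
    """

    means: dict[Edge, float]
    sds: dict[Edge, float]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.means) != set(OFFDIAG_EDGES) or set(self.sds) != set(OFFDIAG_EDGES):
            missing = set(OFFDIAG_EDGES) - set(self.means)
            extra = set(self.means) - set(OFFDIAG_EDGES)
            raise InvalidParameterError(
                f"parameter table must cover exactly the allowed off-diagonal "
                f"edges; missing={sorted(missing)}, extra={sorted(extra)}"
            )
        for edge in OFFDIAG_EDGES:
            m, s = self.means[edge], self.sds[edge]
            if not (np.isfinite(m) and np.isfinite(s)):
                raise InvalidParameterError(f"non-finite parameter on edge {edge}")
            if not 0.0 <= m <= 1.0:
                raise InvalidParameterError(f"mean {m} outside [0, 1] on edge {edge}")
            if s < 0.0:
                raise InvalidParameterError(f"negative sd {s} on edge {edge}")
        for origin in (DiseaseState.CN, DiseaseState.MCI, DiseaseState.AD):
            total = sum(self.means[e] for e in OFFDIAG_EDGES if e[0] == origin)
            if total > 1.0 + 1e-12:
                raise InvalidParameterError(
                    f"off-diagonal means from {origin.name} sum to {total} > 1"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransitionParamTable":
        """Build from a DataFrame with columns ``from``, ``to``, ``mean``, ``sd``."""
        required = {"from", "to", "mean", "sd"}
        if not required.issubset(frame.columns):
            raise InvalidParameterError(
                f"parameter frame needs columns {sorted(required)}"
            )
        means: dict[Edge, float] = {}
        sds: dict[Edge, float] = {}
        for src, dst, m, s in zip(
            frame["from"], frame["to"], frame["mean"], frame["sd"]
        ):
            try:
                edge = (DiseaseState[src], DiseaseState[dst])
            except KeyError as exc:
                raise InvalidParameterError(f"unknown state label {exc}") from exc
            means[edge] = float(m)
            sds[edge] = float(s)
        return cls(means, sds)

    @classmethod
    def from_csv(cls, path) -> "TransitionParamTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default(cls) -> "TransitionParamTable":
        """The packaged default: one-year probabilities fitted to ADNI."""
        with resources.files("admarkov.data").joinpath(
            "default_transition_params.csv"
        ).open("r") as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_means(cls, means: dict[Edge, float]) -> "TransitionParamTable":
        """Degenerate table with the given means and all SDs zero."""
        full = {e: means.get(e, 0.0) for e in OFFDIAG_EDGES}
        return cls(full, {e: 0.0 for e in OFFDIAG_EDGES})

    # -- views -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": i.name, "to": j.name, "mean": self.means[(i, j)],
             "sd": self.sds[(i, j)]}
            for i, j in OFFDIAG_EDGES
        ]
        return pd.DataFrame(rows, columns=["from", "to", "mean", "sd"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def with_zero_sds(self) -> "TransitionParamTable":
        return TransitionParamTable(dict(self.means), {e: 0.0 for e in OFFDIAG_EDGES})

    def mean_matrix(self) -> np.ndarray:
        """Annual (4, 4) matrix of the means, self-loops closed."""
        m = np.zeros((N_STATES, N_STATES))
        for (i, j), p in self.means.items():
            m[i, j] = p
        for s in (DiseaseState.CN, DiseaseState.MCI, DiseaseState.AD):
            m[s, s] = 1.0 - m[s].sum()
        m[DiseaseState.WITHDRAWN, DiseaseState.WITHDRAWN] = 1.0
        return m

    def self_loop_closures(self) -> dict[DiseaseState, float]:
        """Closure self-transition means 1 − Σ(off-diagonal means) per origin."""
        m = self.mean_matrix()
        return {
            s: float(m[s, s])
            for s in (DiseaseState.CN, DiseaseState.MCI, DiseaseState.AD)
        }


# ---------------------------------------------------------------------------
# probability draws


def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def draw_cohort_probs(
    table: TransitionParamTable,
    n: int,
    rng_or_seed,
    max_rejects: int = 1000,
) -> np.ndarray:
    """Draw annual transition matrices for ``n`` individuals.

    One independent Normal draw per off-diagonal edge, truncated (clipped)
    to [0, 1].  If a row's off-diagonal draws sum above 1 the whole row is
    redrawn; after ``max_rejects`` consecutive failures for any individual a
    :class:`DegenerateParametersError` is raised.  Self-loops are closed,
    so every returned matrix is row-stochastic.

    Returns an array of shape ``(n, 4, 4)``.
    """
    table.validate()
    rng = _as_rng(rng_or_seed)
    out = np.zeros((n, N_STATES, N_STATES))
    for origin in (DiseaseState.CN, DiseaseState.MCI, DiseaseState.AD):
        edges = [e for e in OFFDIAG_EDGES if e[0] == origin]
        mu = np.array([table.means[e] for e in edges])
        sigma = np.array([table.sds[e] for e in edges])
        draws = np.clip(rng.normal(mu, sigma, size=(n, len(edges))), 0.0, 1.0)
        bad = draws.sum(axis=1) > 1.0
        tries = 0
        while bad.any():
            tries += 1
            if tries > max_rejects:
                raise DegenerateParametersError(
                    f"row rejection for origin {origin.name} failed "
                    f"{max_rejects} consecutive times"
                )
            k = int(bad.sum())
            draws[bad] = np.clip(rng.normal(mu, sigma, size=(k, len(edges))), 0.0, 1.0)
            bad = draws.sum(axis=1) > 1.0
        for col, (_, dest) in enumerate(edges):
            out[:, origin, dest] = draws[:, col]
        out[:, origin, origin] = 1.0 - draws.sum(axis=1)
    out[:, DiseaseState.WITHDRAWN, DiseaseState.WITHDRAWN] = 1.0
    return out


def draw_individual_probs(table: TransitionParamTable, rng_or_seed) -> np.ndarray:
    """One individual's annual (4, 4) transition matrix (row-stochastic)."""
    return draw_cohort_probs(table, 1, rng_or_seed)[0]


# ---------------------------------------------------------------------------
# time-scale conversion


def annual_to_step(annual: np.ndarray, steps_per_year: int) -> np.ndarray:
    """Convert annual transition matrices to the simulation step scale.

    Each off-diagonal annual probability ``p`` becomes the per-step
    ``q = 1 − (1 − p)**(1/steps_per_year)`` and the self-loops are
    re-closed.  The conversion is exact for rows with a single exit (the
    per-step survival compounds back to the annual self-loop) and is a
    per-edge approximation for competing exits.  ``steps_per_year == 1``
    is the identity.  Accepts a single ``(4, 4)`` matrix or a batch
    ``(..., 4, 4)``.
    """
    annual = np.asarray(annual, dtype=float)
    if steps_per_year < 1 or int(steps_per_year) != steps_per_year:
        raise InvalidParameterError("steps_per_year must be a positive integer")
    if steps_per_year == 1:
        return annual.copy()

    offdiag = ALLOWED_MASK & ~np.eye(N_STATES, dtype=bool)
    offsums = np.where(offdiag, annual, 0.0).sum(axis=-1)
    npos = (np.where(offdiag, annual, 0.0) > 0).sum(axis=-1)
    if np.any((np.abs(offsums - 1.0) <= 1e-12) & (npos > 1)):
        warnings.warn(
            "row with competing exits and zero self-loop: the per-edge "
            "complement-root conversion is not exact for competing risks",
            RuntimeWarning,
            stacklevel=2,
        )

    step = np.zeros_like(annual)
    q = 1.0 - (1.0 - annual) ** (1.0 / steps_per_year)
    step[..., offdiag] = q[..., offdiag]
    rowsum = step.sum(axis=-1)
    diag = np.eye(N_STATES, dtype=bool)
    step[..., diag] = 1.0 - rowsum
    return step


# ---------------------------------------------------------------------------
# validation


@dataclass
class MatrixValidation:
    """Outcome of a structural check on a transition matrix."""

    ok: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_matrix(m: np.ndarray, tol: float = 1e-12) -> MatrixValidation:
    """Check a (4, 4) matrix for row-stochasticity and the allowed pattern.

    Returns a truthy :class:`MatrixValidation`; on failure ``reasons``
    names each violated rule (``"row sum"``, ``"forbidden edge"``, ...).
    """
    reasons: list[str] = []
    m = np.asarray(m, dtype=float)
    if m.shape != (N_STATES, N_STATES):
        return MatrixValidation(False, [f"shape {m.shape} != (4, 4)"])
    if not np.all(np.isfinite(m)):
        reasons.append("non-finite entry")
    if np.any(m < -tol) or np.any(m > 1.0 + tol):
        reasons.append("entry outside [0, 1]")
    rowsums = m.sum(axis=1)
    for s in DiseaseState:
        if abs(rowsums[s] - 1.0) > tol:
            reasons.append(f"row sum {rowsums[s]:.15f} != 1 for {s.name}")
    forbidden = ~ALLOWED_MASK
    if np.any(np.abs(m[forbidden]) > tol):
        for i in DiseaseState:
            for j in DiseaseState:
                if forbidden[i, j] and abs(m[i, j]) > tol:
                    reasons.append(f"forbidden edge {i.name}->{j.name}")
    return MatrixValidation(not reasons, reasons)
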
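"""Diagnose-time priors, the observation model and the cohort likelihood.

A patient's hidden involvement evolves from the all-healthy state for an
unobserved number of time-steps ``t_D`` before diagnosis; ``t_D`` carries a
binomial prior whose success probability depends on T-category (early vs
advanced tumors are diagnosed after fewer vs more steps on average).  The
observed diagnosis is the hidden state seen through a diagnostic modality's
sensitivity and specificity, independently per level.  Levels with no
reported status are marginalized exactly by summing the likelihood vector
over their completions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .graph import (
    GraphError,
    ModelParams,
    SpreadGraph,
    StateSpace,
    build_transition_matrix,
)

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import Cohort

UNKNOWN = -1  #: sentinel for a level with no reported involvement status


class DataError(ValueError):
    """Cohort data inconsistent with the model."""


@dataclass(frozen=True)
class Modality:
    """A diagnostic modality with per-level sensitivity and specificity.

    ``P(Z=1 | X=1) = sensitivity`` and ``P(Z=0 | X=0) = specificity``;
    a perfect modality (pathology / consensus treated as ground truth) has
    both equal to 1, making the observation matrix the identity.
    """

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise DataError("sensitivity and specificity must be in [0, 1]")

    @property
    def is_perfect(self) -> bool:
        return self.sensitivity == 1.0 and self.specificity == 1.0

    def confusion(self) -> np.ndarray:
        """2x2 table ``P(Z=z | X=x)`` indexed ``[x, z]``."""
        sn, sp = self.sensitivity, self.specificity
        return np.array([[sp, 1.0 - sp], [1.0 - sn, sn]])


def _load_default_modalities() -> dict[str, Modality]:
    from importlib import resources

    import yaml

    raw = yaml.safe_load(
        resources.files("lyspread").joinpath("data", "modalities.yaml").read_text()
    )
    return {
        name: Modality(name, spec["sensitivity"], spec["specificity"])
        for name, spec in raw.items()
    }


#: Literature sensitivity/specificity values used for consensus resolution.
MODALITIES: dict[str, Modality] = _load_default_modalities()

#: The modality assumed for clinical nodal staging in risk predictions (CT).
CLINICAL_MODALITY = MODALITIES["CT"]
#: Ground-truth modality used during parameter inference.
PERFECT_MODALITY = MODALITIES["consensus"]

T_CATEGORIES = ("early", "late")


@dataclass(frozen=True)
class DiagnoseTimePrior:
    """Binomial prior over the number of time-steps elapsed at diagnosis."""

    pmf: np.ndarray
    p: float

    @property
    def t_max(self) -> int:
        return len(self.pmf) - 1

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.pmf)) @ self.pmf)


def binomial_time_prior(p: float, t_max: int = 10) -> DiagnoseTimePrior:
    """Binomial(t_max, p) pmf over t in {0, ..., t_max}; mean t_max * p."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"binomial parameter must be in [0, 1], got {p}")
    t = np.arange(t_max + 1)
    coef = np.array([math.comb(t_max, k) for k in t], dtype=float)
    pmf = coef * p**t * (1.0 - p) ** (t_max - t)
    return DiagnoseTimePrior(pmf=pmf, p=p)


class ObservationMatrix:
    """Row-stochastic matrix ``B[k, l] = P(Z = state_l | X = state_k)``."""

    def __init__(self, B: np.ndarray, state_space: StateSpace):
        self.B = B
        self.state_space = state_space

    def __getitem__(self, key):
        return self.B[key]


def build_observation_matrix(
    modality: Modality, state_space: StateSpace
) -> ObservationMatrix:
    """Product over levels of the per-level 2x2 confusion table."""
    conf = modality.confusion()
    bits = state_space.bits
    B = np.ones((state_space.n_states, state_space.n_states))
    for v in range(state_space.V):
        B *= conf[np.ix_(bits[:, v], bits[:, v])]
    return ObservationMatrix(B, state_space)


def _as_pattern(
    diagnosis: Mapping[str, int | None] | Sequence[int | None],
    lnl_names: Sequence[str],
) -> tuple[int, ...]:
    """Normalize a diagnosis to a ternary tuple in level order (-1 unknown)."""
    if isinstance(diagnosis, Mapping):
        unknown_keys = set(diagnosis) - set(lnl_names)
        if unknown_keys:
            raise DataError(f"diagnosis references unknown levels {sorted(unknown_keys)}")
        seq: list[int | None] = [diagnosis.get(name) for name in lnl_names]
    else:
        seq = list(diagnosis)
        if len(seq) != len(lnl_names):
            raise DataError(
                f"diagnosis length {len(seq)} != number of levels {len(lnl_names)}"
            )
    out = []
    for s in seq:
        if s is None or (isinstance(s, float) and math.isnan(s)) or s == UNKNOWN:
            out.append(UNKNOWN)
        elif int(s) in (0, 1):
            out.append(int(s))
        else:
            raise DataError(f"involvement status must be 0, 1 or unknown, got {s!r}")
    return tuple(out)


def observation_weights(
    state_space: StateSpace,
    diagnosis: Mapping[str, int | None] | Sequence[int | None],
    modality: Modality,
) -> np.ndarray:
    """``w[k] = P(observed diagnosis | hidden state k)``.

    Unknown levels contribute a factor of 1 (exact marginalization over
    their two completions).
    """
    pattern = _as_pattern(diagnosis, state_space.lnl_names)
    conf = modality.confusion()
    w = np.ones(state_space.n_states)
    for v, z in enumerate(pattern):
        if z == UNKNOWN:
            continue
        w *= conf[state_space.bits[:, v], z]
    return w


def _time_prior_for(
    params: ModelParams, t_category: str
) -> DiagnoseTimePrior:
    if t_category not in T_CATEGORIES:
        raise DataError(f"t_category must be one of {T_CATEGORIES}, got {t_category!r}")
    p = params.p_early if t_category == "early" else params.p_late
    return binomial_time_prior(p, params.t_max)


def state_distribution(
    graph: SpreadGraph,
    params: ModelParams,
    time_prior: DiagnoseTimePrior | str,
    state_space: StateSpace | None = None,
) -> np.ndarray:
    """Marginal distribution over hidden states at diagnosis.

    ``sum_t P(t) * A^t @ pi`` with ``pi`` one-hot on the all-healthy state.
    ``time_prior`` may be a T-category name, resolved through ``params``.
    """
    if isinstance(time_prior, str):
        time_prior = _time_prior_for(params, time_prior)
    ss = state_space or StateSpace(graph.lnl_names)
    A = build_transition_matrix(graph, params, ss).A
    x = np.zeros(ss.n_states)
    x[0] = 1.0
    out = np.zeros(ss.n_states)
    for t in range(len(time_prior.pmf)):
        out += time_prior.pmf[t] * x
        if t < len(time_prior.pmf) - 1:
            x = A @ x
    return out


def diagnosis_likelihoods(
    graph: SpreadGraph,
    params: ModelParams,
    modality: Modality,
    t_category: str,
    state_space: StateSpace | None = None,
) -> np.ndarray:
    """Probability of every complete diagnosis: ``B.T @ state_distribution``."""
    ss = state_space or StateSpace(graph.lnl_names)
    dist = state_distribution(graph, params, t_category, ss)
    B = build_observation_matrix(modality, ss).B
    return B.T @ dist


class CohortLikelihood:
    """Cached cohort log-likelihood evaluator for repeated MCMC calls.

    Patients are grouped by (T-category, ternary diagnosis pattern); each
    unique pattern contributes an observation-weight vector over hidden
    states, so one evaluation costs a transition-matrix build, one chain
    evolution shared by both T-categories, and two small matrix products.
    """

    def __init__(
        self,
        graph: SpreadGraph,
        cohort: "Cohort",
        modality: Modality = PERFECT_MODALITY,
        t_max: int = 10,
        p_early: float = 0.3,
    ):
        if tuple(cohort.lnl_names) != tuple(graph.lnl_names):
            raise DataError(
                f"cohort levels {cohort.lnl_names} != graph levels {graph.lnl_names}"
            )
        self.graph = graph
        self.modality = modality
        self.t_max = t_max
        self.p_early = p_early
        self.state_space = StateSpace(graph.lnl_names)
        ss = self.state_space

        counts: dict[tuple[str, tuple[int, ...]], int] = {}
        for rec in cohort.records:
            if rec.t_category not in T_CATEGORIES:
                raise DataError(
                    f"patient {rec.patient_id}: bad t_category {rec.t_category!r}"
                )
            pattern = _as_pattern(rec.status(modality.name), cohort.lnl_names)
            key = (rec.t_category, pattern)
            counts[key] = counts.get(key, 0) + 1

        rows, self._counts_early, self._counts_late = [], [], []
        for (tcat, pattern), c in sorted(counts.items()):
            rows.append(observation_weights(ss, pattern, modality))
            self._counts_early.append(c if tcat == "early" else 0)
            self._counts_late.append(c if tcat == "late" else 0)
        self._O = np.array(rows) if rows else np.zeros((0, ss.n_states))
        self._counts_early = np.array(self._counts_early, dtype=float)
        self._counts_late = np.array(self._counts_late, dtype=float)
        self.n_patients = len(cohort.records)

        # static pieces of the transition-matrix build
        bits = ss.bits
        self._bits = bits
        self._pidx = np.array([ss.level_index(p) for p, _ in graph.lnl_arcs], dtype=int)
        self._cidx = np.array([ss.level_index(c) for _, c in graph.lnl_arcs], dtype=int)
        self._t_range = np.arange(t_max + 1)
        self._binom_coef = np.array(
            [math.comb(t_max, int(k)) for k in self._t_range], dtype=float
        )
        self._pmf_early = self._pmf(p_early)

    def _pmf(self, p: float) -> np.ndarray:
        t = self._t_range
        return self._binom_coef * p**t * (1.0 - p) ** (self.t_max - t)

    def _transition(self, theta: np.ndarray) -> np.ndarray:
        nv = self.graph.n_lnls
        b = theta[:nv]
        tvals = theta[nv:-1]
        bits = self._bits
        stay = np.repeat((1.0 - b)[None, :], bits.shape[0], axis=0)
        for r, c, t in zip(self._pidx, self._cidx, tvals):
            np.multiply(
                stay[:, c], np.where(bits[:, r] == 1, 1.0 - t, 1.0), out=stay[:, c]
            )
        p_inv = 1.0 - stay
        A = np.ones((bits.shape[0], bits.shape[0]))
        for v in range(bits.shape[1]):
            src = bits[:, v][None, :]
            dst = bits[:, v][:, None]
            p = p_inv[:, v][None, :]
            A *= np.where(
                src == 1,
                np.where(dst == 1, 1.0, 0.0),
                np.where(dst == 1, p, 1.0 - p),
            )
        return A

    def state_distributions(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Hidden-state distributions at diagnosis for (early, late)."""
        A = self._transition(theta)
        n = A.shape[0]
        traj = np.empty((self.t_max + 1, n))
        x = np.zeros(n)
        x[0] = 1.0
        for t in range(self.t_max + 1):
            traj[t] = x
            if t < self.t_max:
                x = A @ x
        return self._pmf_early @ traj, self._pmf(theta[-1]) @ traj

    def __call__(self, theta: np.ndarray) -> float:
        """Cohort log-likelihood; -inf if any patient has zero probability."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.graph.n_params,):
            raise DataError(
                f"theta must have length {self.graph.n_params}, got {theta.shape}"
            )
        if self.n_patients == 0:
            return 0.0
        dist_early, dist_late = self.state_distributions(theta)
        probs = self._O @ dist_early
        probs_late = self._O @ dist_late
        ll = 0.0
        for counts, p in ((self._counts_early, probs), (self._counts_late, probs_late)):
            active = counts > 0
            if not np.any(active):
                continue
            pa = p[active]
            if np.any(pa <= 0.0):
                return -np.inf
            ll += float(counts[active] @ np.log(pa))
        return ll


def cohort_log_likelihood(
    graph: SpreadGraph,
    params: ModelParams,
    cohort: "Cohort",
    modality: Modality = PERFECT_MODALITY,
) -> float:
    """Sum over patients of the log-probability of their (possibly
    incomplete) diagnosis; an empty cohort contributes 0."""
    evaluator = CohortLikelihood(
        graph, cohort, modality, t_max=params.t_max, p_early=params.p_early
    )
    return evaluator(params.to_vector(graph))
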
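"""Bayes-inverted involvement probabilities and prevalence predictions.

Given a new patient's clinical diagnosis, the posterior over hidden
involvement states is proportional to the probability of the diagnosis
under each state (through the modality's sensitivity/specificity) times the
model's prior over states for the patient's T-category.  Marginalizing that
posterior over all states in which a clinically negative level is involved
gives the occult-metastasis risk that drives elective treatment decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .graph import ModelParams, SpreadGraph, StateSpace
from .inference import PosteriorSamples
from .likelihood import (
    CLINICAL_MODALITY,
    DataError,
    Modality,
    _as_pattern,
    observation_weights,
    state_distribution,
)


class RiskError(ValueError):
    """Diagnosis impossible under the model (zero total probability)."""


def pattern_vector(
    state_space: StateSpace, pattern: Mapping[str, int | None] | Sequence[int | None]
) -> np.ndarray:
    """Marginalization vector: 1 on states matching every pinned level.

    Levels set to ``None`` (or omitted) are ignored/marginalized.
    """
    tern = _as_pattern(pattern, state_space.lnl_names)
    m = np.ones(state_space.n_states)
    for v, s in enumerate(tern):
        if s >= 0:
            m *= state_space.bits[:, v] == s
    return m


def posterior_state_distribution(
    graph: SpreadGraph,
    params: ModelParams,
    diagnosis: Mapping[str, int | None] | Sequence[int | None],
    t_category: str,
    modality: Modality = CLINICAL_MODALITY,
    state_space: StateSpace | None = None,
) -> np.ndarray:
    """P(hidden state | observed diagnosis) for one patient.

    Unknown levels in the diagnosis are marginalized inside the observation
    probability.  Raises :class:`RiskError` for a diagnosis the model gives
    zero probability (possible only with a perfect modality).
    """
    ss = state_space or StateSpace(graph.lnl_names)
    prior = state_distribution(graph, params, t_category, ss)
    w = observation_weights(ss, diagnosis, modality)
    post = w * prior
    total = post.sum()
    if total <= 0.0:
        raise RiskError(f"diagnosis {diagnosis!r} has zero probability under the model")
    return post / total


def marginal_risk(
    state_posterior: np.ndarray,
    pattern: Mapping[str, int | None] | Sequence[int | None],
    state_space: StateSpace,
) -> float:
    """Dot product of the posterior with the pattern's marginalization vector."""
    return float(pattern_vector(state_space, pattern) @ state_posterior)


def occult_risk(
    graph: SpreadGraph,
    params: ModelParams,
    level: str,
    diagnosis: Mapping[str, int | None] | Sequence[int | None],
    t_category: str,
    modality: Modality = CLINICAL_MODALITY,
    state_space: StateSpace | None = None,
) -> float:
    """P(level truly involved | clinical diagnosis).

    The convention for "occult" is a diagnosis in which ``level`` is
    clinically negative; the function itself imposes no such restriction.
    """
    ss = state_space or StateSpace(graph.lnl_names)
    post = posterior_state_distribution(graph, params, diagnosis, t_category, modality, ss)
    return marginal_risk(post, {level: 1}, ss)


def predicted_prevalence(
    graph: SpreadGraph,
    params: ModelParams,
    pattern: Mapping[str, int | None] | Sequence[int | None],
    t_category: str,
    state_space: StateSpace | None = None,
) -> float:
    """Model probability of a hidden involvement pattern for a T-category
    (the quantity compared against observed cohort frequencies)."""
    ss = state_space or StateSpace(graph.lnl_names)
    dist = state_distribution(graph, params, t_category, ss)
    return float(pattern_vector(ss, pattern) @ dist)


@dataclass
class RiskResult:
    """A risk evaluated over posterior parameter draws."""

    values: np.ndarray
    point: float | None = None

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0

    def interval(self, level: float = 0.99) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(self.values, [lo, 1.0 - lo]))


def risk_over_samples(
    graph: SpreadGraph,
    samples: PosteriorSamples | np.ndarray,
    diagnosis: Mapping[str, int | None] | Sequence[int | None],
    t_category: str,
    modality: Modality = CLINICAL_MODALITY,
    pattern: Mapping[str, int | None] | Sequence[int | None] | None = None,
    subsample_fraction: float = 0.1,
    seed: int = 0,
    p_early: float = 0.3,
    t_max: int = 10,
) -> RiskResult:
    """Propagate posterior parameter uncertainty into a risk histogram.

    Draws ``subsample_fraction`` of the rows (without replacement, seeded)
    and evaluates the marginal risk of ``pattern`` given ``diagnosis`` at
    each draw.  ``pattern`` defaults to nothing pinned, i.e. probability 1.
    """
    theta = samples.samples if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if theta.ndim != 2 or theta.shape[0] == 0:
        raise DataError("need a non-empty (S, k) array of parameter draws")
    rng = np.random.default_rng(seed)
    n_draw = max(1, int(round(subsample_fraction * theta.shape[0])))
    idx = rng.choice(theta.shape[0], size=n_draw, replace=False)
    ss = StateSpace(graph.lnl_names)
    pattern = pattern if pattern is not None else {}
    values = np.empty(n_draw)
    for i, row in enumerate(theta[idx]):
        params = ModelParams.from_vector(row, graph, p_early=p_early, t_max=t_max)
        post = posterior_state_distribution(
            graph, params, diagnosis, t_category, modality, ss
        )
        values[i] = marginal_risk(post, pattern, ss)
    return RiskResult(values=values)


@dataclass(frozen=True)
class BetaPrevalence:
    """Beta posterior over an observed prevalence (uniform prior)."""

    alpha: float
    beta: float

    @property
    def mode(self) -> float:
        if self.alpha + self.beta <= 2.0:
            return float("nan")  # uniform or improper mode
        return (self.alpha - 1.0) / (self.alpha + self.beta - 2.0)

    @property
    def dist(self):
        return stats.beta(self.alpha, self.beta)


def beta_posterior_prevalence(count: int, total: int) -> BetaPrevalence:
    """Beta(count+1, total-count+1); its mode is the raw data prevalence."""
    if not 0 <= count <= total:
        raise DataError(f"need 0 <= count <= total, got {count}/{total}")
    if total == 0:
        return BetaPrevalence(1.0, 1.0)
    return BetaPrevalence(count + 1.0, total - count + 1.0)
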
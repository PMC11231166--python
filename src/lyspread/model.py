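"""Statsmodels-style front end: a model built from a cohort, fitted by MCMC.

:class:`LymphSpreadModel` binds a spread graph to a patient cohort and
exposes ``loglike``, ``fit`` (ensemble MCMC posterior), ``evidence``
(thermodynamic integration) and ``simulate``.  ``fit`` returns a
:class:`LymphSpreadResults` carrying the posterior draws, their summaries,
and the clinically interesting derived quantities: occult-metastasis risks
and predicted prevalences, with uncertainty propagated from the posterior.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import risk as _risk
from .data_io import Cohort, read_cohort, simulate_cohort
from .evidence import (
    EvidenceEstimate,
    SamplerConfig,
    TemperatureLadder,
    model_evidence,
    temperature_ladder,
)
from .graph import ModelParams, SpreadGraph, StateSpace
from .inference import PosteriorSamples, sample_posterior
from .likelihood import (
    CLINICAL_MODALITY,
    PERFECT_MODALITY,
    CohortLikelihood,
    Modality,
)


class LymphSpreadModel:
    """Hidden Markov model of lymphatic spread bound to a cohort.

    Parameters
    ----------
    cohort
        Patient records whose level set matches the graph.
    graph
        Spread topology; its arcs define the parameter vector.
    modality
        How the cohort's statuses relate to the true hidden states during
        fitting.  The default treats them as ground-truth consensus
        (sensitivity = specificity = 1).
    t_max, p_early
        Diagnose-time horizon and the fixed early-T binomial parameter.
    """

    def __init__(
        self,
        cohort: Cohort,
        graph: SpreadGraph,
        modality: Modality = PERFECT_MODALITY,
        t_max: int = 10,
        p_early: float = 0.3,
    ):
        self.cohort = cohort
        self.graph = graph
        self.modality = modality
        self.t_max = t_max
        self.p_early = p_early
        self.state_space = StateSpace(graph.lnl_names)
        self._loglike = CohortLikelihood(
            graph, cohort, modality, t_max=t_max, p_early=p_early
        )

    @classmethod
    def from_csv(cls, path: str | Path, graph: SpreadGraph, **kwargs) -> "LymphSpreadModel":
        cohort = read_cohort(path, lnl_names=graph.lnl_names)
        return cls(cohort, graph, **kwargs)

    @property
    def nobs(self) -> int:
        return len(self.cohort)

    @property
    def k_params(self) -> int:
        return self.graph.n_params

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.graph.parameter_names

    def loglike(self, params: ModelParams | np.ndarray) -> float:
        """Cohort log-likelihood at a parameter point."""
        theta = (
            params.to_vector(self.graph)
            if isinstance(params, ModelParams)
            else np.asarray(params, dtype=float)
        )
        return self._loglike(theta)

    def fit(self, config: SamplerConfig | None = None, **config_kwargs) -> "LymphSpreadResults":
        """Sample the posterior; keyword arguments override config fields."""
        if config is None:
            config = SamplerConfig(**config_kwargs)
        elif config_kwargs:
            raise TypeError("pass either a SamplerConfig or keyword overrides, not both")
        samples = sample_posterior(
            self.graph,
            self.cohort,
            config,
            modality=self.modality,
            t_max=self.t_max,
            p_early=self.p_early,
        )
        return LymphSpreadResults(self, samples)

    def evidence(
        self,
        ladder: TemperatureLadder | None = None,
        config: SamplerConfig | None = None,
    ) -> EvidenceEstimate:
        """Log model evidence by thermodynamic integration."""
        return model_evidence(
            self.graph,
            self.cohort,
            ladder or temperature_ladder(63),
            config or SamplerConfig(),
            modality=self.modality,
            t_max=self.t_max,
            p_early=self.p_early,
        )

    def simulate(
        self,
        params: ModelParams,
        n: int,
        fraction_late: float = 0.5,
        modality: Modality | None = None,
        seed: int = 0,
    ) -> Cohort:
        """Generate a synthetic cohort from this model's graph."""
        return simulate_cohort(
            self.graph,
            params,
            n,
            fraction_late=fraction_late,
            modality=modality or self.modality,
            seed=seed,
        )


class LymphSpreadResults:
    """Posterior fit results: estimates, uncertainties and predictions."""

    def __init__(self, model: LymphSpreadModel, samples: PosteriorSamples):
        self.model = model
        self.posterior = samples
        self.params = samples.mean()
        self.bse = samples.std()

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.posterior.parameter_names

    def mean_params(self) -> ModelParams:
        """Posterior-mean parameters as a structured object."""
        return ModelParams.from_vector(
            self.params, self.model.graph, p_early=self.model.p_early, t_max=self.model.t_max
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo, hi = np.quantile(
            self.posterior.samples, [alpha / 2, 1 - alpha / 2], axis=0
        )
        return pd.DataFrame(
            {"lower": lo, "upper": hi}, index=list(self.parameter_names)
        )

    def summary(self) -> str:
        """Plain-text fit summary in the style of regression results."""
        ci = self.conf_int()
        lines = [
            "Lymphatic spread HMM — posterior summary",
            "=" * 58,
            f"No. patients: {self.model.nobs:>6}    "
            f"No. parameters: {self.model.k_params}",
            f"Posterior draws: {self.posterior.n_samples}    "
            f"Mean acceptance: {self.posterior.acceptance_fraction:.2f}",
            f"Mean log-likelihood: {np.mean(self.posterior.log_likelihoods):.2f}",
            "-" * 58,
            f"{'parameter':<12}{'mean':>10}{'std':>10}{'2.5%':>12}{'97.5%':>12}",
        ]
        for i, name in enumerate(self.parameter_names):
            lines.append(
                f"{name:<12}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{ci['lower'].iloc[i]:>12.4f}{ci['upper'].iloc[i]:>12.4f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- predictions ------------------------------------------------------
    def risk(
        self,
        level: str,
        diagnosis: Mapping[str, int | None] | Sequence[int | None],
        t_category: str,
        modality: Modality = CLINICAL_MODALITY,
        subsample_fraction: float = 0.1,
        seed: int = 0,
    ) -> _risk.RiskResult:
        """Posterior histogram of P(level involved | clinical diagnosis)."""
        result = _risk.risk_over_samples(
            self.model.graph,
            self.posterior,
            diagnosis,
            t_category,
            modality=modality,
            pattern={level: 1},
            subsample_fraction=subsample_fraction,
            seed=seed,
            p_early=self.model.p_early,
            t_max=self.model.t_max,
        )
        result.point = _risk.occult_risk(
            self.model.graph,
            self.mean_params(),
            level,
            diagnosis,
            t_category,
            modality,
            self.model.state_space,
        )
        return result

    def predicted_prevalence(
        self,
        pattern: Mapping[str, int | None] | Sequence[int | None],
        t_category: str,
    ) -> float:
        """Prevalence of a hidden pattern at the posterior-mean parameters."""
        return _risk.predicted_prevalence(
            self.model.graph, self.mean_params(), pattern, t_category,
            self.model.state_space,
        )

    # -- plotting ---------------------------------------------------------
    def plot_risk(
        self,
        level: str,
        diagnoses: Mapping[str, Mapping[str, int | None]],
        t_category: str,
        modality: Modality = CLINICAL_MODALITY,
        ax=None,
        bins: int = 40,
    ):
        """Overlaid risk histograms for several diagnosis scenarios."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, diagnosis in diagnoses.items():
            res = self.risk(level, diagnosis, t_category, modality)
            ax.hist(100 * res.values, bins=bins, alpha=0.5, density=True, label=label)
        ax.set_xlabel(f"risk of involvement in level {level} (%)")
        ax.set_ylabel("posterior density")
        ax.set_title(f"{t_category} T-category")
        ax.legend()
        return ax
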
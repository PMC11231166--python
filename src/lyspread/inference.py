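"""Posterior sampling with an affine-invariant ensemble MCMC scheme.

The prior over all spread probabilities and the late diagnose-time
parameter is uniform on the unit hypercube, so the (power) posterior is
``beta * log-likelihood`` inside the cube and impossible outside.  Sampling
uses an ensemble of walkers with differential-evolution proposal moves;
after a burn-in phase, 200 further steps are run of which every tenth is
kept, leaving ``S = 20 * W`` draws for ``W`` walkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import emcee
import h5py
import numpy as np
import pandas as pd

from .graph import SpreadGraph
from .likelihood import CohortLikelihood, Modality, PERFECT_MODALITY


class ConfigError(ValueError):
    """Invalid sampler configuration."""


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble schedule: W = walkers_per_dim * k walkers, burn-in, then
    keep_steps steps thinned by ``thin``."""

    walkers_per_dim: int = 20
    burn_in: int = 1000
    keep_steps: int = 200
    thin: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.walkers_per_dim, self.burn_in, self.keep_steps, self.thin) < 1:
            raise ConfigError("all sampler schedule fields must be positive")
        if self.keep_steps % self.thin != 0:
            raise ConfigError("keep_steps must be divisible by thin")

    def n_walkers(self, ndim: int) -> int:
        w = self.walkers_per_dim * ndim
        if w < 2 * ndim + 2:
            raise ConfigError(
                f"{w} walkers insufficient for the ensemble scheme in {ndim} dims"
            )
        return w


@dataclass
class PosteriorSamples:
    """Retained draws plus their data log-likelihoods.

    ``samples`` has shape (S, k) with S = keep_steps/thin * W; the flat
    ordering is (kept step, walker), so the i-th row at one inverse
    temperature pairs with the i-th row at the next when chains are
    warm-started (as thermodynamic integration requires).
    """

    samples: np.ndarray
    log_likelihoods: np.ndarray
    parameter_names: tuple[str, ...]
    final_positions: np.ndarray
    beta: float = 1.0
    acceptance_fraction: float = float("nan")
    config: SamplerConfig | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def ndim(self) -> int:
        return self.samples.shape[1]

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def std(self) -> np.ndarray:
        return self.samples.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.parameter_names))
        df["log_likelihood"] = self.log_likelihoods
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("samples", data=self.samples)
            fh.create_dataset("log_likelihoods", data=self.log_likelihoods)
            fh.create_dataset("final_positions", data=self.final_positions)
            fh.attrs["parameter_names"] = list(self.parameter_names)
            fh.attrs["beta"] = self.beta
            fh.attrs["acceptance_fraction"] = self.acceptance_fraction
            if self.config is not None:
                for key, val in vars(self.config).items():
                    fh.attrs[f"config_{key}"] = val

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with h5py.File(path, "r") as fh:
            cfg_keys = {"walkers_per_dim", "burn_in", "keep_steps", "thin", "seed"}
            cfg_attrs = {
                k[len("config_"):]: int(v)
                for k, v in fh.attrs.items()
                if k.startswith("config_") and k[len("config_"):] in cfg_keys
            }
            return cls(
                samples=fh["samples"][...],
                log_likelihoods=fh["log_likelihoods"][...],
                parameter_names=tuple(fh.attrs["parameter_names"]),
                final_positions=fh["final_positions"][...],
                beta=float(fh.attrs["beta"]),
                acceptance_fraction=float(fh.attrs["acceptance_fraction"]),
                config=SamplerConfig(**cfg_attrs) if cfg_attrs else None,
            )


def log_posterior(
    theta: np.ndarray, log_likelihood, beta: float = 1.0
) -> tuple[float, float]:
    """Power-posterior log-density and the raw data log-likelihood.

    Returns ``(beta * loglike, loglike)``; outside the unit cube both are
    -inf (uniform prior support), and at ``beta = 0`` the density is the
    flat prior restricted to the cube.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0.0) or np.any(theta > 1.0):
        return -np.inf, -np.inf
    ll = log_likelihood(theta)
    if not np.isfinite(ll):
        return -np.inf, ll
    return beta * ll, ll


_MOVES = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]


def sample_log_likelihood(
    log_likelihood,
    ndim: int,
    parameter_names: tuple[str, ...],
    config: SamplerConfig,
    beta: float = 1.0,
    init: np.ndarray | None = None,
) -> PosteriorSamples:
    """Run the ensemble sampler against an arbitrary log-likelihood callable.

    ``init`` warm-starts the walkers (shape (W, k)); otherwise they start
    uniformly in the cube.  Deterministic given ``config.seed``.
    """
    n_walkers = config.n_walkers(ndim)
    rng = np.random.RandomState(config.seed % 2**31)
    if init is None:
        positions = rng.uniform(size=(n_walkers, ndim))
    else:
        positions = np.array(init, dtype=float)
        if positions.shape != (n_walkers, ndim):
            raise ConfigError(
                f"init must have shape {(n_walkers, ndim)}, got {positions.shape}"
            )

    sampler = emcee.EnsembleSampler(
        n_walkers,
        ndim,
        log_posterior,
        args=(log_likelihood, beta),
        moves=_MOVES,
        blobs_dtype=float,
    )
    sampler.random_state = rng.get_state()
    state = sampler.run_mcmc(positions, config.burn_in, progress=False)
    sampler.reset()
    state = sampler.run_mcmc(state, config.keep_steps, progress=False)

    chain = sampler.get_chain(thin=config.thin)  # (kept, W, k)
    blobs = sampler.get_blobs(thin=config.thin)  # (kept, W)
    kept, W, k = chain.shape
    return PosteriorSamples(
        samples=chain.reshape(kept * W, k),
        log_likelihoods=np.asarray(blobs, dtype=float).reshape(kept * W),
        parameter_names=tuple(parameter_names),
        final_positions=np.array(state.coords),
        beta=beta,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        config=config,
    )


def sample_posterior(
    graph: SpreadGraph,
    cohort,
    config: SamplerConfig,
    beta: float = 1.0,
    init: np.ndarray | None = None,
    modality: Modality = PERFECT_MODALITY,
    t_max: int = 10,
    p_early: float = 0.3,
) -> PosteriorSamples:
    """Sample the (power) posterior over a graph's parameters given a cohort."""
    loglike = CohortLikelihood(graph, cohort, modality, t_max=t_max, p_early=p_early)
    return sample_log_likelihood(
        loglike, graph.n_params, graph.parameter_names, config, beta=beta, init=init
    )
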
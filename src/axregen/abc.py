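"""Likelihood-free inference: a small ABC-SMC engine for discrete parameters.

Sequential Monte Carlo Approximate Bayesian Computation with integer-uniform
priors, a discretized Gaussian random-walk perturbation kernel, standard SMC
importance weights and a median-of-last-population epsilon schedule:
generation g accepts particles whose distance is below eps_g, and eps_{g+1}
is the median of generation g's accepted distances.  Convergence is followed
through the epsilon and acceptance-rate traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ABCConfig",
    "Generation",
    "PosteriorSample",
    "abc_smc_fit",
    "posterior_summary",
    "weighted_quantile",
]


@dataclass(frozen=True)
class ABCConfig:
    """ABC-SMC settings.

    ``priors`` maps parameter names to inclusive integer ranges (lo, hi).
    A generation ends when ``population_size`` particles are accepted or the
    proposal budget (``max_attempts_factor`` x population) is exhausted; the
    fit stops at ``max_generations`` or when the acceptance rate falls below
    ``min_acceptance_rate``.
    """

    priors: Mapping[str, tuple[int, int]]
    population_size: int = 1000
    max_generations: int = 12
    min_acceptance_rate: float = 0.05
    max_attempts_factor: int = 50

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        for name, (lo, hi) in self.priors.items():
            if hi < lo:
                raise ValueError(f"prior range for {name!r} is empty: ({lo}, {hi})")

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.priors)


@dataclass
class Generation:
    """Accepted particles, distances and normalized weights of one generation."""

    particles: pd.DataFrame
    distances: np.ndarray
    weights: np.ndarray
    epsilon: float
    acceptance_rate: float


@dataclass
class PosteriorSample:
    """Full output of an ABC-SMC run: one :class:`Generation` per iteration."""

    generations: list[Generation] = field(default_factory=list)

    @property
    def final(self) -> Generation:
        if not self.generations:
            raise ValueError("no generations recorded")
        return self.generations[-1]

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([g.epsilon for g in self.generations])

    @property
    def acceptance_rates(self) -> np.ndarray:
        return np.array([g.acceptance_rate for g in self.generations])

    def to_frame(self) -> pd.DataFrame:
        """Long table of all particles: generation, params, weight, distance."""
        frames = []
        for i, g in enumerate(self.generations):
            df = g.particles.copy()
            df.insert(0, "generation", i)
            df["weight"] = g.weights
            df["distance"] = g.distances
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def weighted_quantile(
    values: np.ndarray, q, weights: np.ndarray
) -> np.ndarray | float:
    """Quantile(s) of a weighted sample (inverse of the weighted ECDF)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    out = np.interp(np.atleast_1d(q), cw, v)
    return float(out[0]) if np.ndim(q) == 0 else out


def _sample_prior(
    config: ABCConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {
        name: rng.integers(lo, hi + 1, size=n)
        for name, (lo, hi) in config.priors.items()
    }
    return pd.DataFrame(cols)


def _evaluate(
    params: pd.DataFrame,
    distance_fn: Callable[[dict], float] | None,
    batch_distance_fn: Callable[[pd.DataFrame], np.ndarray] | None,
) -> np.ndarray:
    if batch_distance_fn is not None:
        return np.asarray(batch_distance_fn(params), float)
    return np.array(
        [distance_fn(row._asdict()) for row in params.itertuples(index=False)],
        dtype=float,
    )


def abc_smc_fit(
    distance_fn: Callable[[dict], float] | None,
    config: ABCConfig,
    rng: np.random.Generator | int | None = None,
    *,
    batch_distance_fn: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> PosteriorSample:
    """Run ABC-SMC and return the per-generation posterior populations.

    ``distance_fn`` maps a parameter dict to a scalar distance (stochastic
    simulators consume the rng stream they close over); alternatively a
    vectorized ``batch_distance_fn`` over a particle DataFrame can be given.
    """
    if distance_fn is None and batch_distance_fn is None:
        raise ValueError("provide distance_fn or batch_distance_fn")
    rng = np.random.default_rng(rng)
    names = list(config.param_names)
    pop = config.population_size
    post = PosteriorSample()

    # Generation 0: sample straight from the prior (epsilon = inf).
    particles = _sample_prior(config, pop, rng)
    distances = _evaluate(particles, distance_fn, batch_distance_fn)
    weights = np.full(pop, 1.0 / pop)
    post.generations.append(
        Generation(particles, distances, weights, float("inf"), 1.0)
    )

    lows = np.array([config.priors[n][0] for n in names])
    highs = np.array([config.priors[n][1] for n in names])

    for _ in range(1, config.max_generations):
        prev = post.generations[-1]
        eps = float(np.median(prev.distances))
        if eps == 0:
            break
        prev_arr = prev.particles[names].to_numpy(float)
        mean = np.average(prev_arr, axis=0, weights=prev.weights)
        var = np.average((prev_arr - mean) ** 2, axis=0, weights=prev.weights)
        # Random-walk scale ~ sqrt(2 var) of the last population, floored so
        # the discretized kernel never degenerates.
        scales = np.maximum(np.sqrt(2.0 * var), 0.5)

        acc_parts: list[np.ndarray] = []
        acc_dists: list[float] = []
        attempts = 0
        budget = config.max_attempts_factor * pop
        batch = max(pop, 64)
        while len(acc_dists) < pop and attempts < budget:
            n_try = min(batch, budget - attempts)
            cand = _propose(prev_arr, prev.weights, scales, lows, highs, n_try, rng)
            cand_df = pd.DataFrame(cand, columns=names)
            d = _evaluate(cand_df, distance_fn, batch_distance_fn)
            attempts += n_try
            ok = d < eps
            if ok.any():
                acc_parts.append(cand[ok])
                acc_dists.extend(d[ok].tolist())

        if not acc_dists:
            if eps <= float(prev.distances.min()) * (1 + 1e-12):
                # epsilon has shrunk onto the smallest attainable distance:
                # the population has converged and cannot improve strictly
                break
            warnings.warn(
                f"ABC-SMC: no acceptances at epsilon={eps:.4g}; "
                "returning the last valid posterior",
                RuntimeWarning,
            )
            break

        accepted = np.concatenate(acc_parts)[:pop]
        dists = np.array(acc_dists[: accepted.shape[0]])
        rate = accepted.shape[0] / attempts
        w = _smc_weights(accepted, prev_arr, prev.weights, scales)
        post.generations.append(
            Generation(
                pd.DataFrame(accepted, columns=names),
                dists,
                w,
                eps,
                rate,
            )
        )
        if accepted.shape[0] < pop or rate < config.min_acceptance_rate:
            break
    return post


def _propose(
    prev: np.ndarray,
    weights: np.ndarray,
    scales: np.ndarray,
    lows: np.ndarray,
    highs: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resample + perturb n candidates inside the prior box (rejection)."""
    out = np.empty((n, prev.shape[1]), dtype=np.int64)
    need = np.arange(n)
    while need.size:
        j = rng.choice(prev.shape[0], size=need.size, p=weights)
        cand = np.rint(
            prev[j] + rng.normal(0.0, 1.0, size=(need.size, prev.shape[1])) * scales
        ).astype(np.int64)
        inside = ((cand >= lows) & (cand <= highs)).all(axis=1)
        out[need[inside]] = cand[inside]
        need = need[~inside]
    return out


def _smc_weights(
    accepted: np.ndarray,
    prev: np.ndarray,
    prev_weights: np.ndarray,
    scales: np.ndarray,
) -> np.ndarray:
    """Importance weights w_i ∝ prior / sum_j w_j K(theta_i | theta_j).

    The prior is uniform on the box, so only the kernel mixture matters; the
    Gaussian kernel's normalization is common to all particles and cancels.
    """
    # (n_accepted, n_prev) squared Mahalanobis distances under the diagonal kernel
    diff = (accepted[:, None, :] - prev[None, :, :]) / scales
    log_k = -0.5 * np.sum(diff**2, axis=2)
    denom = (np.exp(log_k) * prev_weights).sum(axis=1)
    # Guard against underflow for particles far from the whole population.
    denom = np.maximum(denom, 1e-300)
    w = 1.0 / denom
    return w / w.sum()


def posterior_summary(post: PosteriorSample) -> pd.DataFrame:
    """Weighted mean, sd and credible intervals per parameter (final generation)."""
    gen = post.final
    rows = []
    arr = gen.particles.to_numpy(float)
    for i, name in enumerate(gen.particles.columns):
        v = arr[:, i]
        mean = float(np.average(v, weights=gen.weights))
        sd = float(np.sqrt(np.average((v - mean) ** 2, weights=gen.weights)))
        q = weighted_quantile(v, [0.025, 0.5, 0.975], gen.weights)
        rows.append(
            {
                "parameter": name,
                "mean": mean,
                "sd": sd,
                "ci2.5": q[0],
                "median": q[1],
                "ci97.5": q[2],
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
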
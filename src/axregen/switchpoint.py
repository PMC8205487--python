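"""ABC-SMC fit of the recruitment model to switchpoint data.

The experimental switchpoint is the AP position separating the
high-proliferation (posterior) from the low-proliferation (anterior) zone of
the regenerating spinal cord, measured as a mean +/- sd per day
post-amputation.  The model counterpart is the recruitment limit xi(t), the
position of the most anterior recruited cell.  Fitting xi(t) to the
switchpoint identifies the free parameters: the initial cell count N0, the
maximal recruited length lambda (um) and the maximal recruitment time tau
(hours).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .abc import ABCConfig, PosteriorSample, abc_smc_fit, posterior_summary, weighted_quantile
from .recruitment import RecruitmentSignal
from .simulator import SimConfig, run_simulation

__all__ = [
    "SwitchpointDataset",
    "switchpoint_distance",
    "DEFAULT_PRIORS",
    "SwitchpointModel",
    "SwitchpointResults",
]

#: Printed prior box: N0 ~ unif{100,300}, lambda ~ unif{500,1500} um,
#: tau ~ unif{1,192} h (the whole 8-day observation window).
DEFAULT_PRIORS = {"n0": (100, 300), "lam": (500, 1500), "tau": (1, 192)}


@dataclass(frozen=True)
class SwitchpointDataset:
    """Per-day switchpoint mean/sd: columns day, mu_um, sigma_um."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day", "mu_um", "sigma_um"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        days = self.frame["day"].to_numpy(float)
        if len(days) == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(self.frame["sigma_um"].to_numpy(float) > 0):
            raise ValueError("sigma_um must be > 0")

    @property
    def days(self) -> np.ndarray:
        return self.frame["day"].to_numpy(float)

    @property
    def mu(self) -> np.ndarray:
        return self.frame["mu_um"].to_numpy(float)

    @property
    def sigma(self) -> np.ndarray:
        return self.frame["sigma_um"].to_numpy(float)

    @classmethod
    def from_csv(cls, path) -> "SwitchpointDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def switchpoint_distance(sim_xi, data: SwitchpointDataset) -> float:
    """Chi-square-style distance: sum_i (x_i - mu_i)^2 / sigma_i^2."""
    x = np.asarray(sim_xi, float)
    if x.shape != data.mu.shape:
        raise ValueError(
            f"need one simulated value per dataset day "
            f"({data.mu.size}), got {x.size}"
        )
    return float(np.sum((x - data.mu) ** 2 / data.sigma**2))


class SwitchpointModel:
    """Recruitment-limit model of a switchpoint dataset (ABC-SMC fit).

    Parameters
    ----------
    data : the switchpoint dataset to fit.
    sim_config : base simulation configuration; ``n0`` and the signal's
        ``lam``/``tau`` are overridden by each candidate particle.  The
        duration is extended to cover the last dataset day if needed.
    n_sim_replicates : simulations averaged per particle (default 1: one
        stochastic simulation stands in for the likelihood).
    """

    def __init__(
        self,
        data: SwitchpointDataset,
        sim_config: SimConfig | None = None,
        n_sim_replicates: int = 1,
    ):
        self.data = data
        base = sim_config if sim_config is not None else SimConfig()
        duration = max(base.duration, float(data.days.max() * 24))
        self.sim_config = replace(
            base, duration=duration, snapshot_times=(), record_events=False
        )
        self.n_sim_replicates = int(n_sim_replicates)
        self._day_hours = data.days * 24.0

    def simulate_xi(
        self, n0: int, lam: float, tau: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Mean simulated recruitment limit at the dataset days."""
        mode = (
            self.sim_config.signal.shortening_mode
            if self.sim_config.signal is not None
            else "both"
        )
        cfg = replace(
            self.sim_config,
            n0=int(n0),
            signal=RecruitmentSignal(
                lam=float(lam), tau=float(tau), shortening_mode=mode
            ),
        )
        acc = np.zeros(self._day_hours.size)
        for _ in range(self.n_sim_replicates):
            res = run_simulation(cfg, rng)
            acc += [res.value_at("xi", t) for t in self._day_hours]
        return acc / self.n_sim_replicates

    def fit(
        self,
        population_size: int = 1000,
        max_generations: int = 12,
        min_acceptance_rate: float = 0.05,
        priors: dict | None = None,
        seed: int | np.random.Generator | None = None,
    ) -> "SwitchpointResults":
        rng = np.random.default_rng(seed)
        config = ABCConfig(
            priors=priors if priors is not None else DEFAULT_PRIORS,
            population_size=population_size,
            max_generations=max_generations,
            min_acceptance_rate=min_acceptance_rate,
        )

        def distance(params: dict) -> float:
            xi = self.simulate_xi(params["n0"], params["lam"], params["tau"], rng)
            if np.isnan(xi).any():
                return float("inf")
            return switchpoint_distance(xi, self.data)

        posterior = abc_smc_fit(distance, config, rng)
        return SwitchpointResults(self, posterior)


class SwitchpointResults:
    """Posterior over (N0, lambda, tau) from an ABC-SMC switchpoint fit."""

    def __init__(self, model: SwitchpointModel, posterior: PosteriorSample):
        self.model = model
        self.posterior = posterior
        self._summary = posterior_summary(posterior)

    @property
    def params(self) -> dict[str, float]:
        """Weighted posterior means."""
        return self._summary["mean"].to_dict()

    @property
    def sd(self) -> dict[str, float]:
        """Weighted posterior standard deviations."""
        return self._summary["sd"].to_dict()

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        """Weighted central credible interval per parameter."""
        gen = self.posterior.final
        a = (1.0 - level) / 2.0
        rows = {}
        for name in gen.particles.columns:
            lo, hi = weighted_quantile(
                gen.particles[name].to_numpy(float), [a, 1.0 - a], gen.weights
            )
            rows[name] = {"lo": lo, "hi": hi}
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            "Switchpoint recruitment-model fit (ABC-SMC)",
            "=" * 46,
            f"generations: {len(self.posterior.generations)}   "
            f"final epsilon: {self.posterior.final.epsilon:.4g}   "
            f"final acceptance rate: {self.posterior.final.acceptance_rate:.3f}",
            "",
            self._summary.to_string(float_format=lambda v: f"{v:.2f}"),
            "",
            "n0 in cells, lam in um, tau in hours.",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.posterior.to_frame()
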
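"""Synthetic data generators with known ground truth.

Both experimental inputs of the inference pipeline are emulated here so every
stage is testable end-to-end without external data:

* switchpoint datasets — per-day (mean, sd) of the AP position separating the
  high- from the low-proliferation zone, emulated by running the simulator at
  known (N0, lambda, tau) and adding Gaussian noise;
* binned FUCCI phase-percentage profiles — per-animal two-zone profiles with
  multinomial (finite-cell-count) sampling noise, emulating ~300 scored cells
  per tail in 100 um bins over 1600 um of spinal cord.

The emulated day-0 baseline (85% G0/G1, 11% S/G2) and day-4 posterior levels
(~50% S/G2) follow the reported AxFUCCI measurements.  Shipped fixtures made
with these generators are synthetic stand-ins, never real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulator import SimConfig, run_replicates
from .recruitment import RecruitmentSignal
from .switchpoint import SwitchpointDataset
from .zones import FucciProfile

__all__ = [
    "SwitchpointTruth",
    "FucciTruth",
    "generate_switchpoint_dataset",
    "generate_fucci_profiles",
    "day0_fucci_truth",
    "day4_fucci_truth",
]


@dataclass(frozen=True)
class SwitchpointTruth:
    """Ground truth for a synthetic switchpoint dataset.

    Defaults sit inside the ABC prior box; sigma is the per-day Gaussian
    noise sd (um), also reported as the dataset's sigma.
    """

    n0: int = 200
    lam: float = 800.0
    tau: float = 96.0
    days: tuple[float, ...] = (4.0, 6.0, 8.0)
    sigma: float = 50.0
    n_replicates: int = 20
    noise_sd: float | None = None  # Gaussian noise on mu; defaults to sigma

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_switchpoint_dataset(
    truth: SwitchpointTruth,
    rng: np.random.Generator | int | None = None,
    sim_config: SimConfig | None = None,
) -> SwitchpointDataset:
    """Simulate the recruitment limit at the truth parameters and add noise."""
    rng = np.random.default_rng(rng)
    base = sim_config if sim_config is not None else SimConfig()
    mode = base.signal.shortening_mode if base.signal is not None else "both"
    cfg = replace(
        base,
        n0=truth.n0,
        signal=RecruitmentSignal(lam=truth.lam, tau=truth.tau, shortening_mode=mode),
        duration=max(base.duration, max(truth.days) * 24.0),
        snapshot_times=(),
        record_events=False,
    )
    seed = int(rng.integers(0, 2**31 - 1))
    results = run_replicates(cfg, truth.n_replicates, seed=seed)
    noise = truth.sigma if truth.noise_sd is None else truth.noise_sd
    rows = []
    for day in truth.days:
        xi = np.mean([r.value_at("xi", day * 24.0) for r in results])
        mu = xi + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        rows.append({"day": day, "mu_um": mu, "sigma_um": truth.sigma})
    return SwitchpointDataset(pd.DataFrame(rows))


@dataclass(frozen=True)
class FucciTruth:
    """Ground truth for synthetic FUCCI profiles at one day.

    ``border_um=None`` gives a flat (day-0-like) profile with the anterior
    levels everywhere.  Percentages are per zone; the remainder of each zone
    is 'other' (transition/M/negative) and is not modeled downstream.
    """

    day: float = 4.0
    border_um: float | None = -700.0
    g0g1_a: float = 85.0
    sg2_a: float = 11.0
    g0g1_p: float = 45.0
    sg2_p: float = 50.0
    n_animals: int = 4
    cells_per_animal: int = 300
    bin_width: float = 100.0
    ap_range: tuple[float, float] = (-1600.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("g0g1_a", "sg2_a", "g0g1_p", "sg2_p"):
            if not (0 <= getattr(self, name) <= 100):
                raise ValueError(f"{name} must be in [0, 100]")
        if self.g0g1_a + self.sg2_a > 100 or self.g0g1_p + self.sg2_p > 100:
            raise ValueError("zone percentages must sum to <= 100")
        if self.n_animals < 1 or self.cells_per_animal < 1:
            raise ValueError("n_animals and cells_per_animal must be >= 1")


def day0_fucci_truth(**overrides) -> FucciTruth:
    """Uninjured baseline: uniform 85% G0/G1, 11% S/G2, no border step."""
    defaults = dict(day=0.0, border_um=None, g0g1_p=85.0, sg2_p=11.0)
    defaults.update(overrides)
    return FucciTruth(**defaults)


def day4_fucci_truth(**overrides) -> FucciTruth:
    """Day-4-like truth: border at -700 um, posterior S/G2 at ~50%."""
    return FucciTruth(**overrides)


def generate_fucci_profiles(
    truth: FucciTruth, rng: np.random.Generator | int | None = None
) -> list[FucciProfile]:
    """Draw per-animal binned profiles with multinomial counting noise.

    Cells are allocated to bins with equal expected counts; each cell's
    reporter class is drawn from its zone's true percentages; per-bin
    percentages are computed from the integer counts (so pct = 100 k / n
    always).  Empty bins are emitted with n_cells = 0 and NaN percentages.
    """
    rng = np.random.default_rng(rng)
    lo, hi = truth.ap_range
    n_bins = int(round((hi - lo) / truth.bin_width))
    starts = lo + truth.bin_width * np.arange(n_bins)
    centers = starts + truth.bin_width / 2.0

    if truth.border_um is None:
        posterior = np.zeros(n_bins, dtype=bool)
    else:
        posterior = centers >= truth.border_um
    p_g = np.where(posterior, truth.g0g1_p, truth.g0g1_a) / 100.0
    p_s = np.where(posterior, truth.sg2_p, truth.sg2_a) / 100.0

    profiles = []
    for a in range(truth.n_animals):
        n_per_bin = rng.multinomial(
            truth.cells_per_animal, np.full(n_bins, 1.0 / n_bins)
        )
        rows = []
        for b in range(n_bins):
            n = int(n_per_bin[b])
            if n == 0:
                rows.append(
                    {
                        "ap_start_um": starts[b],
                        "ap_end_um": starts[b] + truth.bin_width,
                        "n_cells": 0,
                        "pct_g0g1": np.nan,
                        "pct_sg2": np.nan,
                    }
                )
                continue
            counts = rng.multinomial(n, [p_g[b], p_s[b], 1.0 - p_g[b] - p_s[b]])
            rows.append(
                {
                    "ap_start_um": starts[b],
                    "ap_end_um": starts[b] + truth.bin_width,
                    "n_cells": n,
                    "pct_g0g1": 100.0 * counts[0] / n,
                    "pct_sg2": 100.0 * counts[1] / n,
                }
            )
        profiles.append(
            FucciProfile(
                animal=f"synthetic-{a + 1}", day=truth.day, bins=pd.DataFrame(rows)
            )
        )
    return profiles
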
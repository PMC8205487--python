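"""Cell-cycle primitives: phase-length distributions, stationary ages, phase lookup.

The model describes axolotl spinal cord ependymal cells whose cell cycle is the
sum of three phases, G1, S and G2+M.  Each phase duration is lognormally
distributed; cells in uninjured tissue ("long" regime) cycle in ~14 days while
cells recruited by the injury signal ("short" regime) cycle in ~5 days.
Internal units are hours and micrometres throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Regime",
    "PhaseLengthParams",
    "PhaseLengths",
    "LONG_PARAMS",
    "SHORT_PARAMS",
    "T_G0_G1",
    "CELL_DIAMETER_UM",
    "QUIESCENT_FRACTION",
    "GROWTH_FRACTION",
    "lognormal_from_moments",
    "sample_phase_lengths",
    "total_cycle_length",
    "sample_initial_age",
    "initial_age_density",
    "initial_age_cdf",
    "phase_of",
]


class Regime(enum.Enum):
    """Cell-cycle regime: slow/uninjured (``long``) or regenerating (``short``).

    Daughters inherit their mother's regime.
    """

    LONG = "long"
    SHORT = "short"


@dataclass(frozen=True)
class PhaseLengthParams:
    """Arithmetic mean/sd (hours) of the lognormal phase-length distributions.

    One instance per regime.  ``t_g0_g1`` is the delay between recruitment of a
    quiescent (G0) cell and its entry into G1; it only applies on recruitment.
    """

    g1_mean: float
    g1_sd: float
    s_mean: float
    s_sd: float
    g2m_mean: float
    g2m_sd: float
    t_g0_g1: float = 48.0

    def __post_init__(self) -> None:
        for name in ("g1_mean", "s_mean", "g2m_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("g1_sd", "s_sd", "g2m_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.t_g0_g1 < 0:
            raise ValueError(f"t_g0_g1 must be >= 0, got {self.t_g0_g1}")

    @property
    def means(self) -> tuple[float, float, float]:
        return (self.g1_mean, self.s_mean, self.g2m_mean)

    @property
    def sds(self) -> tuple[float, float, float]:
        return (self.g1_sd, self.s_sd, self.g2m_sd)


@dataclass(frozen=True)
class PhaseLengths:
    """One cell's realized phase durations (hours)."""

    g1: float
    s: float
    g2m: float

    def __post_init__(self) -> None:
        if min(self.g1, self.s, self.g2m) <= 0:
            raise ValueError("phase lengths must be strictly positive")

    @property
    def total(self) -> float:
        return self.g1 + self.s + self.g2m


#: Non-regenerating (uninjured) phase-length parametrization, hours.
LONG_PARAMS = PhaseLengthParams(
    g1_mean=152.0, g1_sd=54.0, s_mean=179.0, s_sd=21.0, g2m_mean=9.0, g2m_sd=6.0
)

#: Regenerating phase-length parametrization, hours.
SHORT_PARAMS = PhaseLengthParams(
    g1_mean=22.0, g1_sd=19.0, s_mean=88.0, s_sd=9.0, g2m_mean=9.0, g2m_sd=2.0
)

#: G0 -> G1 delay on recruitment of a quiescent cell, hours.
T_G0_G1 = 48.0

#: Ependymal cell length along the AP axis, micrometres.
CELL_DIAMETER_UM = 13.2

#: Quiescent fraction of ependymal cells in uninjured tissue.
QUIESCENT_FRACTION = 0.12

#: Fraction of cells actively cycling at initialization (growth fraction).
GROWTH_FRACTION = 1.0 - QUIESCENT_FRACTION


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Convert arithmetic mean/sd to the lognormal (mu, sigma) parameters.

    Solves ``sigma^2 = ln(1 + sd^2/mean^2)``, ``mu = ln(mean) - sigma^2/2`` so
    that the resulting lognormal has exactly the requested arithmetic moments.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_lognormal(
    mean: float, sd: float, rng: np.random.Generator, size=None
) -> np.ndarray | float:
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    mu, sigma = lognormal_from_moments(mean, sd)
    return rng.lognormal(mu, sigma, size=size)


def sample_phase_lengths(
    params: PhaseLengthParams, rng: np.random.Generator
) -> PhaseLengths:
    """Draw one cell's (G1, S, G2+M) durations from the regime's lognormals."""
    return PhaseLengths(
        g1=float(_draw_lognormal(params.g1_mean, params.g1_sd, rng)),
        s=float(_draw_lognormal(params.s_mean, params.s_sd, rng)),
        g2m=float(_draw_lognormal(params.g2m_mean, params.g2m_sd, rng)),
    )


def sample_phase_length_arrays(
    params: PhaseLengthParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draw of n cells' (g1, s, g2m) durations."""
    g1 = _draw_lognormal(params.g1_mean, params.g1_sd, rng, size=n)
    s = _draw_lognormal(params.s_mean, params.s_sd, rng, size=n)
    g2m = _draw_lognormal(params.g2m_mean, params.g2m_sd, rng, size=n)
    return np.asarray(g1, float), np.asarray(s, float), np.asarray(g2m, float)


def total_cycle_length(params: PhaseLengthParams) -> float:
    """Sum of the three phase means (hours): the regime's mean cycle length."""
    return params.g1_mean + params.s_mean + params.g2m_mean


def initial_age_density(age, T: float):
    """Stationary age density f(a) = (ln2/T) * 2^(1 - a/T) on [0, T).

    This is the age distribution of an exponentially growing population in
    steady state: newborns are twice as abundant as cells about to divide.
    """
    if T <= 0:
        raise ValueError(f"T must be > 0, got {T}")
    age = np.asarray(age, float)
    out = (math.log(2) / T) * np.exp2(1.0 - age / T)
    return np.where((age >= 0) & (age < T), out, 0.0)


def initial_age_cdf(age, T: float):
    """Closed-form CDF of the stationary age density: F(a) = 2(1 - 2^(-a/T))."""
    if T <= 0:
        raise ValueError(f"T must be > 0, got {T}")
    age = np.asarray(age, float)
    return np.clip(2.0 * (1.0 - np.exp2(-age / T)), 0.0, 1.0)


def sample_initial_age(T, rng: np.random.Generator, size=None):
    """Draw initial cell-cycle ages from the stationary age distribution.

    Inverse-CDF sampling: a = -T * log2(1 - u/2) with u ~ U(0, 1), which lands
    in [0, T) with the stationary density.  ``T`` may be an array (one cycle
    length per cell), in which case one age is drawn per element.
    """
    T_arr = np.asarray(T, float)
    if np.any(T_arr <= 0):
        raise ValueError("T must be > 0")
    if size is None and T_arr.ndim > 0:
        size = T_arr.shape
    u = rng.uniform(0.0, 1.0, size=size)
    ages = -T_arr * np.log2(1.0 - u / 2.0)
    if np.ndim(ages) == 0:
        return float(ages)
    return ages


def phase_of(clock: float, lengths: PhaseLengths) -> str:
    """Map a cell-cycle clock to its phase label, half-open windows.

    [0, g1) -> G1, [g1, g1+s) -> S, [g1+s, T) -> G2M.
    """
    if not (0 <= clock < lengths.total):
        raise ValueError(f"clock {clock} outside [0, {lengths.total})")
    if clock < lengths.g1:
        return "G1"
    if clock < lengths.g1 + lengths.s:
        return "S"
    return "G2M"
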
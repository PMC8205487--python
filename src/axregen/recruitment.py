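"""The amputation-triggered recruitment signal and cell-cycle coordinate maps.

Amputation releases a signal that sweeps anteriorly from the injury plane at
constant speed, recruiting ependymal cells it passes.  Recruitment is an
irreversible switch from the long (uninjured) to the short (regenerating)
cell-cycle regime; the cell's clock is remapped according to the phase it is
in when the signal arrives:

* G1, early part: the clock is reset to 0 (partial G1 skipping, which
  synchronizes cells at the start of the short G1).
* G1, late part: the time to S entry is unchanged.
* S: fractional S-phase progress is preserved (proportional mapping) -- DNA
  replication cannot be skipped.
* G2+M: remaining time to division is preserved (G2/M lengths do not change
  on amputation); daughters enter the short cycle.
* G0 (quiescent): the cell enters short G1 after a fixed delay t_G0_G1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phases import PhaseLengthParams, PhaseLengths, Regime

__all__ = [
    "ShorteningMode",
    "RecruitmentSignal",
    "signal_front",
    "effective_short_params",
    "transform_clock",
    "recruit_quiescent",
]

#: Allowed shortening modes for the recruitment response.
SHORTENING_MODES = ("both", "s_only", "g1_only", "none")

ShorteningMode = str


@dataclass(frozen=True)
class RecruitmentSignal:
    """Constant-speed anterior sweep: front at -(lam/tau)*min(t, tau).

    ``lam`` is the maximal recruited length (micrometres anterior to the
    amputation plane) and ``tau`` the time (hours) at which recruitment stops,
    so the front reaches -lam exactly at t = tau.
    """

    lam: float
    tau: float
    shortening_mode: ShorteningMode = "both"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.shortening_mode not in SHORTENING_MODES:
            raise ValueError(
                f"shortening_mode must be one of {SHORTENING_MODES}, "
                f"got {self.shortening_mode!r}"
            )

    @property
    def speed(self) -> float:
        """Sweep speed, micrometres per hour."""
        return self.lam / self.tau


def signal_front(t: float, signal: RecruitmentSignal) -> float:
    """AP position (um) of the recruitment front at time t (hours).

    Moves linearly from 0 at t=0 to -lam at t=tau, then stops.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t >= signal.tau:
        return -signal.lam
    return -(signal.lam / signal.tau) * t


def effective_short_params(
    long_params: PhaseLengthParams,
    short_params: PhaseLengthParams,
    mode: ShorteningMode,
) -> PhaseLengthParams:
    """Short-regime distribution actually in force under a shortening mode.

    ``s_only`` keeps the long G1 distribution, ``g1_only`` keeps the long S
    distribution; the untouched phase keeps its long distribution in daughters
    too.  ``none`` returns the long parametrization unchanged.
    """
    if mode == "both":
        return short_params
    if mode == "s_only":
        return PhaseLengthParams(
            g1_mean=long_params.g1_mean,
            g1_sd=long_params.g1_sd,
            s_mean=short_params.s_mean,
            s_sd=short_params.s_sd,
            g2m_mean=short_params.g2m_mean,
            g2m_sd=short_params.g2m_sd,
            t_g0_g1=short_params.t_g0_g1,
        )
    if mode == "g1_only":
        return PhaseLengthParams(
            g1_mean=short_params.g1_mean,
            g1_sd=short_params.g1_sd,
            s_mean=long_params.s_mean,
            s_sd=long_params.s_sd,
            g2m_mean=short_params.g2m_mean,
            g2m_sd=short_params.g2m_sd,
            t_g0_g1=short_params.t_g0_g1,
        )
    if mode == "none":
        return long_params
    raise ValueError(f"unknown shortening mode {mode!r}")


def transform_clock(
    clock: float,
    long: PhaseLengths,
    short: PhaseLengths,
    mode: ShorteningMode = "both",
) -> tuple[float, Regime]:
    """Remap a recruited cell's clock from long- to short-cycle coordinates.

    ``long`` are the cell's realized phase durations before recruitment and
    ``short`` the durations it adopts (under ``s_only``/``g1_only`` the caller
    passes short lengths whose untouched phase equals the long one).  Returns
    the transformed clock and the cell's new regime.  ``mode='none'`` is the
    identity.
    """
    if not (0 <= clock < long.total):
        raise ValueError(f"clock {clock} outside [0, {long.total})")
    if mode == "none":
        return clock, Regime.LONG

    g1_skip = long.g1 - short.g1
    if clock < long.g1:
        # G1: skip the early part, preserve time-to-S for the late part.
        if clock <= g1_skip:
            new = 0.0
        else:
            new = clock - g1_skip
    elif clock < long.g1 + long.s:
        # S: preserve fractional S-phase progress.
        new = (clock - long.g1) * (short.s / long.s) + short.g1
    else:
        # G2+M: preserve remaining time to division.
        new = clock + (short.total - long.total)
    return new, Regime.SHORT


def recruit_quiescent(t: float, params: PhaseLengthParams) -> float:
    """G0-exit time for a quiescent cell recruited at time t (hours).

    The cell is scheduled to start cycling (short regime, clock 0) at
    t + t_G0_G1.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return t + params.t_g0_g1
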
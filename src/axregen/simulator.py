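"""1D cell-pushing simulator of the regenerating axolotl spinal cord.

The spinal cord is modeled as a densely packed row of ependymal cells along
the anterior-posterior (AP) axis.  Space is measured in micrometres with the
amputation plane at 0 and anterior positions negative; time in hours with
amputation at t = 0.  Each cycling cell advances a deterministic cell-cycle
clock; when the clock reaches the cell's cycle length the cell divides, one
daughter keeping the mother's AP coordinate and the other intercalated
immediately posterior, displacing every more-posterior cell by one cell
diameter (the "cell pushing" mechanism).  An optional recruitment signal
sweeps anteriorly after amputation and switches swept cells to the short
(regenerating) cycle regime.

State is held in flat numpy arrays (struct-of-arrays) so that replicate
ensembles and ABC fits stay cheap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phases import (
    CELL_DIAMETER_UM,
    GROWTH_FRACTION,
    LONG_PARAMS,
    SHORT_PARAMS,
    PhaseLengthParams,
    sample_initial_age,
    sample_phase_length_arrays,
)
from .recruitment import (
    RecruitmentSignal,
    effective_short_params,
    signal_front,
)

__all__ = [
    "SimConfig",
    "Tissue",
    "SimulationResult",
    "initialize_tissue",
    "divide_cell",
    "step",
    "run_simulation",
    "run_replicates",
    "phase_occupancy_map",
    "summarize_replicates",
]

_LONG, _SHORT = 0, 1

#: Default snapshot times: daily over the 8-day observation window.
DEFAULT_SNAPSHOT_TIMES = tuple(float(24 * d) for d in range(9))


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration.

    Parameters
    ----------
    n0 : initial cell count anterior to the amputation plane.
    gf : growth fraction — probability that a cell is cycling at t = 0.
        Defaults to 0.88 (quiescent fraction 0.12).
    cell_diameter : cell length along the AP axis, micrometres.
    cell_length_sd : if > 0, per-cell lengths are drawn from a normal
        distribution truncated at > 0 instead of being constant.
    dt : time step, hours.
    duration : total simulated time, hours (default 8 days).
    signal : recruitment signal, or None for uninjured growth.
    long_params, short_params : phase-length parametrizations of the two
        regimes.  The signal's shortening mode modifies which short
        distributions are actually in force.
    snapshot_times : times (hours) at which full cell tables are recorded.
    record_events : whether to log division / G1->S / recruitment events.
    """

    n0: int = 196
    gf: float = GROWTH_FRACTION
    cell_diameter: float = CELL_DIAMETER_UM
    cell_length_sd: float = 0.0
    dt: float = 1.0
    duration: float = 192.0
    signal: RecruitmentSignal | None = None
    long_params: PhaseLengthParams = LONG_PARAMS
    short_params: PhaseLengthParams = SHORT_PARAMS
    snapshot_times: tuple[float, ...] = ()
    record_events: bool = False

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError(f"n0 must be >= 1, got {self.n0}")
        if not (0.0 <= self.gf <= 1.0):
            raise ValueError(f"gf must be in [0, 1], got {self.gf}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.cell_diameter <= 0:
            raise ValueError(f"cell_diameter must be > 0, got {self.cell_diameter}")
        if self.cell_length_sd < 0:
            raise ValueError(f"cell_length_sd must be >= 0, got {self.cell_length_sd}")

    @property
    def shortening_mode(self) -> str:
        return self.signal.shortening_mode if self.signal is not None else "both"


class Tissue:
    """Mutable ordered row of cells, anterior -> posterior.

    Cell attributes live in parallel numpy arrays indexed anterior to
    posterior.  Positions are posterior-edge coordinates derived from the
    (fixed) anterior tissue edge plus the cumulative cell lengths, so a
    division automatically displaces every more-posterior cell.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        n = config.n0
        self.config = config
        self.time = 0.0
        self.division_count = 0
        ell = config.cell_diameter
        if config.cell_length_sd > 0:
            self.lengths = _truncated_normal(ell, config.cell_length_sd, n, rng)
        else:
            self.lengths = np.full(n, ell)
        # Posterior-most cell's posterior edge sits at 0 (amputation plane).
        self.anterior_edge = -float(self.lengths.sum())

        self.cycling = rng.uniform(size=n) < config.gf
        self.clock = np.zeros(n)
        self.g1 = np.full(n, np.nan)
        self.s = np.full(n, np.nan)
        self.g2m = np.full(n, np.nan)
        idx = np.nonzero(self.cycling)[0]
        g1, s, g2m = sample_phase_length_arrays(config.long_params, idx.size, rng)
        self.g1[idx], self.s[idx], self.g2m[idx] = g1, s, g2m
        self.clock[idx] = sample_initial_age(g1 + s + g2m, rng)

        self.regime = np.full(n, _LONG, dtype=np.int8)
        self.recruited = np.zeros(n, dtype=bool)
        self.pending_transform = np.zeros(n, dtype=bool)
        self.recruitment_time = np.full(n, np.nan)
        self.g0_exit_time = np.full(n, np.nan)
        self.clone_id = np.arange(n)
        self.generation = np.zeros(n, dtype=np.int32)
        self.cell_id = np.arange(n)
        self._next_id = n
        # Short-regime distribution actually in force under the signal's mode.
        self.eff_short = effective_short_params(
            config.long_params, config.short_params, config.shortening_mode
        )

    @property
    def n_cells(self) -> int:
        return self.clock.size

    @property
    def positions(self) -> np.ndarray:
        """Posterior-edge coordinate of each cell (um)."""
        return self.anterior_edge + np.cumsum(self.lengths)

    @property
    def total_T(self) -> np.ndarray:
        return self.g1 + self.s + self.g2m

    @property
    def outgrowth(self) -> float:
        """Posterior tissue extent beyond the amputation plane (um)."""
        return self.anterior_edge + float(self.lengths.sum())

    @property
    def xi(self) -> float:
        """Recruitment limit: position of the most anterior recruited cell."""
        if not self.recruited.any():
            return math.nan
        return float(self.positions[np.nonzero(self.recruited)[0][0]])

    def phase_labels(self) -> np.ndarray:
        """Per-cell phase label; quiescent cells are G0."""
        lab = np.select(
            [
                ~self.cycling,
                self.clock < self.g1,
                self.clock < self.g1 + self.s,
            ],
            ["G0", "G1", "S"],
            default="G2M",
        )
        return lab.astype("U4")

    def snapshot(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "cell_id": self.cell_id,
                "clone_id": self.clone_id,
                "generation": self.generation,
                "position_um": self.positions,
                "length_um": self.lengths,
                "phase": self.phase_labels(),
                "regime": np.where(self.regime == _SHORT, "short", "long"),
                "recruited": self.recruited,
                "cycling": self.cycling,
            }
        )


def _truncated_normal(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def initialize_tissue(
    config: SimConfig, rng: np.random.Generator
) -> Tissue:
    """Build the tissue at the amputation instant (t = 0).

    N0 long-regime cells, each cycling with probability gf; cycling cells get
    lognormal phase lengths and a stationary-age clock; the posterior-most
    cell's posterior edge sits at 0.
    """
    return Tissue(config, rng)


def _divide(tissue: Tissue, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Divide all cells in ``mask`` simultaneously, anterior-first.

    Returns the post-insertion indices of the first daughters (which keep
    their mothers' AP coordinates).
    """
    cfg = tissue.config
    idx = np.nonzero(mask)[0]
    reps = np.ones(tissue.n_cells, dtype=np.int64)
    reps[idx] = 2

    for name in ("regime", "recruited", "recruitment_time", "clone_id", "cell_id"):
        setattr(tissue, name, np.repeat(getattr(tissue, name), reps))
    tissue.generation = np.repeat(tissue.generation, reps)
    tissue.cycling = np.repeat(tissue.cycling, reps)
    tissue.pending_transform = np.repeat(tissue.pending_transform, reps)
    tissue.g0_exit_time = np.repeat(tissue.g0_exit_time, reps)
    tissue.clock = np.repeat(tissue.clock, reps)
    tissue.g1 = np.repeat(tissue.g1, reps)
    tissue.s = np.repeat(tissue.s, reps)
    tissue.g2m = np.repeat(tissue.g2m, reps)
    tissue.lengths = np.repeat(tissue.lengths, reps)

    # Post-insertion indices: each earlier division shifts later ones by +1.
    first = idx + np.arange(idx.size)
    second = first + 1

    n_new = idx.size
    daughters = np.concatenate([first, second])
    tissue.clock[daughters] = 0.0
    tissue.generation[daughters] += 1
    tissue.pending_transform[daughters] = False
    # Daughters of recruited mothers adopt the short regime (heritable).
    if cfg.shortening_mode != "none":
        newly_short = daughters[tissue.recruited[daughters]]
        tissue.regime[newly_short] = _SHORT

    for regime_code, params in ((_LONG, cfg.long_params), (_SHORT, tissue.eff_short)):
        sel = daughters[tissue.regime[daughters] == regime_code]
        if sel.size:
            g1, s, g2m = sample_phase_length_arrays(params, sel.size, rng)
            tissue.g1[sel], tissue.s[sel], tissue.g2m[sel] = g1, s, g2m

    # The intercalated daughter is a new cell with a fresh id (and, in
    # variable-length mode, a fresh length); the first keeps the mother's.
    tissue.cell_id[second] = np.arange(tissue._next_id, tissue._next_id + n_new)
    tissue._next_id += n_new
    if cfg.cell_length_sd > 0:
        tissue.lengths[second] = _truncated_normal(
            cfg.cell_diameter, cfg.cell_length_sd, n_new, rng
        )
    else:
        tissue.lengths[second] = cfg.cell_diameter
    tissue.division_count += n_new
    return first


def divide_cell(tissue: Tissue, index: int, rng: np.random.Generator) -> Tissue:
    """Divide the single cell at ``index`` (must be cycling with clock >= T)."""
    if not (0 <= index < tissue.n_cells):
        raise IndexError(f"cell index {index} out of range")
    if not tissue.cycling[index]:
        raise ValueError(f"cell {index} is not cycling")
    if tissue.clock[index] < tissue.total_T[index]:
        raise ValueError(
            f"cell {index} not ready to divide "
            f"(clock {tissue.clock[index]:.3f} < T {tissue.total_T[index]:.3f})"
        )
    mask = np.zeros(tissue.n_cells, dtype=bool)
    mask[index] = True
    _divide(tissue, mask, rng)
    return tissue


def _mark_swept(tissue: Tissue, t: float, events: list | None) -> None:
    """Flag un-recruited cells at/posterior to the front; effects apply next step."""
    signal = tissue.config.signal
    if signal is None or signal.lam == 0 or t > signal.tau:
        return
    front = signal_front(t, signal)
    # small tolerance absorbs cumulative-sum rounding in the positions
    new = ~tissue.recruited & (tissue.positions >= front - 1e-9)
    if not new.any():
        return
    tissue.recruited[new] = True
    tissue.recruitment_time[new] = t
    if tissue.config.shortening_mode == "none":
        return  # no cell-cycle consequences: identical to lambda = 0
    tissue.pending_transform[new & tissue.cycling] = True
    quiescent = new & ~tissue.cycling
    tissue.g0_exit_time[quiescent] = t + tissue.eff_short.t_g0_g1


def _apply_transforms(tissue: Tissue, rng: np.random.Generator, events: list | None) -> None:
    """Apply the clock coordinate maps to cells recruited in an earlier step."""
    pend = tissue.pending_transform & tissue.cycling
    # Cells already past their long cycle length divide untransformed this
    # step; their daughters enter the short regime anyway.
    ready = pend & (tissue.clock < tissue.total_T)
    tissue.pending_transform &= ~ready
    idx = np.nonzero(ready)[0]
    if idx.size == 0:
        return
    g1l, sl, g2ml = tissue.g1[idx], tissue.s[idx], tissue.g2m[idx]
    tl = g1l + sl + g2ml
    g1s, ss, g2ms = sample_phase_length_arrays(tissue.eff_short, idx.size, rng)
    # G2+M length is conserved on recruitment: keep the realized value.
    in_g2m = tissue.clock[idx] >= g1l + sl
    g2ms = np.where(in_g2m, g2ml, g2ms)
    ts = g1s + ss + g2ms

    c = tissue.clock[idx]
    skip = g1l - g1s
    new = np.select(
        [c <= skip, c < g1l, c < g1l + sl],
        [0.0, c - skip, (c - g1l) * (ss / sl) + g1s],
        default=c + (ts - tl),
    )
    if events is not None:
        phase = np.select([c < g1l, c < g1l + sl], ["G1", "S"], default="G2M")
        pos = tissue.positions[idx]
        for j in range(idx.size):
            events.append(
                (
                    tissue.time,
                    int(tissue.cell_id[idx[j]]),
                    float(pos[j]),
                    phase[j],
                    float(c[j]),
                    float(new[j]),
                )
            )
    tissue.clock[idx] = new
    tissue.g1[idx], tissue.s[idx], tissue.g2m[idx] = g1s, ss, g2ms
    tissue.regime[idx] = _SHORT


def step(
    tissue: Tissue,
    dt: float,
    rng: np.random.Generator,
    *,
    g1s_events: list | None = None,
    division_events: list | None = None,
    recruitment_events: list | None = None,
) -> Tissue:
    """Advance the tissue by one time step.

    Order of operations: clocks advance; pending G0-exits activate; clock
    transformations of cells recruited last step apply; ready cells divide
    (anterior-first); newly swept cells are flagged for recruitment (their
    transformation takes effect in the next step).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    t_new = tissue.time + dt

    cyc = tissue.cycling
    pre = tissue.clock[cyc]
    tissue.clock[cyc] = pre + dt
    if g1s_events is not None and cyc.any():
        crossed = (pre < tissue.g1[cyc]) & (tissue.clock[cyc] >= tissue.g1[cyc])
        if crossed.any():
            ci = np.nonzero(cyc)[0][crossed]
            pos = tissue.positions[ci]
            for j, i in enumerate(ci):
                g1s_events.append(
                    (
                        t_new,
                        float(pos[j]),
                        int(tissue.clone_id[i]),
                        bool(tissue.recruited[i]),
                    )
                )

    tissue.time = t_new

    # G0 exits: recruited quiescent cells whose delay has elapsed start a
    # short cycle from its beginning.
    exits = ~tissue.cycling & (tissue.g0_exit_time <= t_new)
    if exits.any():
        idx = np.nonzero(exits)[0]
        g1, s, g2m = sample_phase_length_arrays(tissue.eff_short, idx.size, rng)
        tissue.g1[idx], tissue.s[idx], tissue.g2m[idx] = g1, s, g2m
        tissue.clock[idx] = 0.0
        tissue.cycling[idx] = True
        tissue.regime[idx] = _SHORT
        tissue.g0_exit_time[idx] = np.nan

    _apply_transforms(tissue, rng, recruitment_events)

    div = tissue.cycling & (tissue.clock >= tissue.total_T)
    if div.any():
        clone_ids = tissue.clone_id[div].copy()
        first = _divide(tissue, div, rng)
        if division_events is not None:
            pos = tissue.positions[first]
            for j in range(first.size):
                division_events.append((t_new, float(pos[j]), int(clone_ids[j])))

    _mark_swept(tissue, t_new, recruitment_events)
    return tissue


@dataclass
class SimulationResult:
    """Trajectory of one simulation run.

    ``times``/``outgrowth``/``xi``/``n_cells`` share a common grid;
    ``xi`` is NaN before the first recruitment (and throughout for runs
    without a signal).  ``events`` holds division / G1->S / recruitment logs
    and ``snapshots`` full cell tables at the requested times.
    """

    times: np.ndarray
    outgrowth: np.ndarray
    xi: np.ndarray
    n_cells: np.ndarray
    snapshots: dict[float, pd.DataFrame]
    events: dict[str, pd.DataFrame]
    config: SimConfig
    founder_positions: np.ndarray

    def series_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "outgrowth_um": self.outgrowth,
                "xi_um": self.xi,
                "n_cells": self.n_cells,
            }
        )

    def value_at(self, series: str, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        if not math.isclose(self.times[i], t, abs_tol=1e-9):
            raise ValueError(f"time {t} not on the simulation grid")
        return float(getattr(self, series)[i])


def run_simulation(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> SimulationResult:
    """Run one full simulation over ``config.duration`` hours."""
    rng = np.random.default_rng(rng)
    tissue = initialize_tissue(config, rng)

    n_steps = int(round(config.duration / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    outgrowth = np.empty(n_steps + 1)
    xi = np.empty(n_steps + 1)
    n_cells = np.empty(n_steps + 1, dtype=np.int64)

    g1s_ev = [] if config.record_events else None
    div_ev = [] if config.record_events else None
    rec_ev = [] if config.record_events else None

    snap_times = set(float(t) for t in config.snapshot_times)
    snapshots: dict[float, pd.DataFrame] = {}
    founders = tissue.positions.copy()

    # The signal front starts at the amputation plane at t = 0.
    _mark_swept(tissue, 0.0, rec_ev)
    outgrowth[0], xi[0], n_cells[0] = tissue.outgrowth, tissue.xi, tissue.n_cells
    if 0.0 in snap_times:
        snapshots[0.0] = tissue.snapshot()

    for k in range(1, n_steps + 1):
        step(
            tissue,
            config.dt,
            rng,
            g1s_events=g1s_ev,
            division_events=div_ev,
            recruitment_events=rec_ev,
        )
        outgrowth[k] = tissue.outgrowth
        xi[k] = tissue.xi
        n_cells[k] = tissue.n_cells
        t = float(times[k])
        if t in snap_times:
            snapshots[t] = tissue.snapshot()

    events = {}
    if config.record_events:
        events["divisions"] = pd.DataFrame(
            div_ev, columns=["time_h", "position_um", "clone_id"]
        )
        events["g1s_transitions"] = pd.DataFrame(
            g1s_ev, columns=["time_h", "position_um", "clone_id", "recruited"]
        )
        events["recruitments"] = pd.DataFrame(
            rec_ev,
            columns=[
                "time_h",
                "cell_id",
                "position_um",
                "phase_at_recruitment",
                "clock_before",
                "clock_after",
            ],
        )
    return SimulationResult(
        times=times,
        outgrowth=outgrowth,
        xi=xi,
        n_cells=n_cells,
        snapshots=snapshots,
        events=events,
        config=config,
        founder_positions=founders,
    )


def run_replicates(
    config: SimConfig,
    n_replicates: int,
    seed: int | np.random.SeedSequence | None = None,
) -> list[SimulationResult]:
    """Run independent replicate simulations from spawned RNG substreams."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    return [
        run_simulation(config, np.random.default_rng(child))
        for child in ss.spawn(n_replicates)
    ]


def phase_occupancy_map(
    result: SimulationResult,
    bin_width: float = 100.0,
    phases: Sequence[str] = ("G0", "G1", "S", "G2M"),
) -> pd.DataFrame:
    """Per (snapshot time, AP bin) percentage of cells in each phase.

    Percentages are over the cells counted in the bin and sum to 100 across
    the listed phases; empty bins are simply absent from the table.
    """
    if not result.snapshots:
        raise ValueError("result has no snapshots; set config.snapshot_times")
    rows = []
    for t in sorted(result.snapshots):
        snap = result.snapshots[t]
        # bin by cell centers so the cell ending exactly at the amputation
        # plane is counted in the most posterior anterior bin
        centers = (
            snap["position_um"].to_numpy() - snap["length_um"].to_numpy() / 2.0
        )
        bins = np.floor(centers / bin_width) * bin_width
        for b in np.unique(bins):
            sel = snap.loc[bins == b, "phase"]
            n = len(sel)
            row = {
                "time_h": t,
                "bin_start_um": float(b),
                "bin_end_um": float(b) + bin_width,
                "n_cells": n,
            }
            for ph in phases:
                row[f"pct_{ph.lower()}"] = 100.0 * float((sel == ph).sum()) / n
            rows.append(row)
    return pd.DataFrame(rows)


_BAND_QUANTILES = {
    "68": (0.15865, 0.84135),
    "95": (0.02275, 0.97725),
    "99.7": (0.00135, 0.99865),
}


def summarize_replicates(
    results: Sequence[SimulationResult],
) -> dict[str, pd.DataFrame]:
    """Mean and central 68/95/99.7% envelopes of outgrowth and xi over replicates."""
    if len(results) < 2:
        raise ValueError("need at least 2 replicates")
    times = results[0].times
    for r in results[1:]:
        if r.times.shape != times.shape or not np.allclose(r.times, times):
            raise ValueError("replicates are not on a common time grid")
    out = {}
    for name in ("outgrowth", "xi"):
        stack = np.vstack([getattr(r, name) for r in results])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            df = pd.DataFrame({"time_h": times, "mean": np.nanmean(stack, axis=0)})
            for label, (lo, hi) in _BAND_QUANTILES.items():
                df[f"lo{label}"] = np.nanquantile(stack, lo, axis=0)
                df[f"hi{label}"] = np.nanquantile(stack, hi, axis=0)
        out[name] = df
    return out
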
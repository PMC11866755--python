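"""Dynamic Barrier and Well Optimization (DBO).

Two independent feedback controllers regulate the double-well bias of every
lambda coordinate at runtime:

* **Well-position regulation** (40 ps blocks): if a coordinate spent more
  than 70% of a block near one end point (lambda < 0.2 or > 0.8) and the mean
  lambda there deviates from the ideal value 0 or 1 by more than 0.03, the
  well centre is shifted laterally by 0.5 times that deviation, within a
  cumulative +-0.08 adjustment range.  This keeps the average interpolated
  charges at their physical integer values.

* **Barrier regulation** (1 ns blocks): the fraction of frames in transition
  (0.2 < lambda < 0.8) is steered toward 25% with a 5% tolerance by moving
  the central barrier up or down in 1 kJ/mol increments within 1-20 kJ/mol.
  Tautomer coordinates keep two separate barriers, selected by the current
  protonation state of the partner coordinate, because the force felt in the
  tautomerically degenerate (protonated) state is close to zero.

After every adjustment the partition-function correction is re-run and the
following 10 ps of trajectory are tagged with a censoring flag that the
analysis modules honour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DBOConfig", "WellBlockStats", "update_well_position",
           "update_barrier", "censor", "DBOController"]


@dataclass(frozen=True)
class DBOConfig:
    well_block: float = 40.0  # ps
    well_proximity_low: float = 0.2
    well_proximity_high: float = 0.8
    occupancy_threshold: float = 0.70
    mean_tolerance: float = 0.03
    shift_gain: float = 0.5
    max_shift: float = 0.08
    barrier_block: float = 1000.0  # ps
    transition_low: float = 0.2
    transition_high: float = 0.8
    target_fraction: float = 0.25
    fraction_tolerance: float = 0.05
    increment: float = 1.0  # kJ/mol
    barrier_min: float = 1.0  # kJ/mol
    barrier_max: float = 20.0  # kJ/mol
    start_barrier: float = 6.0  # kJ/mol
    censor_duration: float = 10.0  # ps
    adjust_wells: bool = True
    adjust_barrier: bool = True

    def __post_init__(self) -> None:
        if self.barrier_min >= self.barrier_max:
            raise ValueError("barrier range must be ordered")
        for name in ("well_block", "barrier_block", "increment", "censor_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WellBlockStats:
    """Per-block occupancy and mean lambda near each well."""

    occupancy0: float
    mean0: float  # mean lambda over frames with lambda < proximity_low
    occupancy1: float
    mean1: float  # mean lambda over frames with lambda > proximity_high

    @classmethod
    def from_frames(cls, lam: np.ndarray, config: DBOConfig) -> "WellBlockStats":
        lam = np.asarray(lam, dtype=float)
        near0 = lam < config.well_proximity_low
        near1 = lam > config.well_proximity_high
        return cls(
            occupancy0=float(np.mean(near0)),
            mean0=float(np.mean(lam[near0])) if near0.any() else 0.0,
            occupancy1=float(np.mean(near1)),
            mean1=float(np.mean(lam[near1])) if near1.any() else 1.0,
        )


def update_well_position(stats: WellBlockStats, config: DBOConfig):
    """Well-centre shifts from one completed 40 ps block.

    Returns ``(shift0, shift1)``: the lateral displacement of each well
    centre (0 if the occupancy or mean-deviation criteria are not met).  The
    shift is ``-gain * (mean - ideal)``, moving the centre to pull the mean
    back toward the ideal end-point value.
    """
    shift0 = 0.0
    shift1 = 0.0
    if stats.occupancy0 > config.occupancy_threshold:
        dev = stats.mean0 - 0.0
        if abs(dev) > config.mean_tolerance:
            shift0 = -config.shift_gain * dev
    if stats.occupancy1 > config.occupancy_threshold:
        dev = stats.mean1 - 1.0
        if abs(dev) > config.mean_tolerance:
            shift1 = -config.shift_gain * dev
    return shift0, shift1


def update_barrier(transition_fraction: float, barrier: float,
                   config: DBOConfig) -> float:
    """New barrier height after one completed 1 ns block.

    Too many intermediate frames means the barrier is too easy to cross, so
    the barrier is raised; too few and it is lowered, in fixed increments
    within the configured interval.
    """
    f = transition_fraction
    h = barrier
    if f > config.target_fraction + config.fraction_tolerance:
        h += config.increment
    elif f < config.target_fraction - config.fraction_tolerance:
        h -= config.increment
    return float(np.clip(h, config.barrier_min, config.barrier_max))


def censor(trajectory, adjustment_time: float, config: DBOConfig = DBOConfig()):
    """Flag all frames within ``censor_duration`` of an adjustment (inclusive).

    Overlapping windows are unioned; flags are idempotent.  Returns the
    trajectory with its censor mask updated in place.
    """
    t = trajectory.times
    if adjustment_time > t[-1] + 1e-9 or adjustment_time < t[0] - config.censor_duration:
        raise ValueError("adjustment time outside trajectory")
    mask = (t >= adjustment_time - 1e-9) & (t <= adjustment_time + config.censor_duration + 1e-9)
    trajectory.censored |= mask
    return trajectory


class DBOController:
    """Runtime controller plugged into :class:`cphlab.dynamics.Engine`.

    Invoked at the end of every 40 ps well block; barrier statistics are
    accumulated across blocks and acted on every 1 ns.  Block clocks are per
    coordinate and aligned to the simulation start.
    """

    def __init__(self, config: DBOConfig = DBOConfig()):
        self.config = config
        self._trans_counts = None  # in-transition frame counts per (r, i, state)
        self._total_counts = None
        self._block_time = 0.0

    def _ensure(self, R: int, nc: int) -> None:
        if self._trans_counts is None:
            self._trans_counts = np.zeros((R, nc, 2))
            self._total_counts = np.zeros((R, nc, 2))

    def on_block_end(self, engine, block_lam: np.ndarray, time: float) -> None:
        cfg = self.config
        R, nframes, nc = block_lam.shape
        self._ensure(R, nc)
        layout = engine.layout
        changed = set()

        for r in range(R):
            for i in range(nc):
                lam = block_lam[r, :, i]
                if cfg.adjust_wells:
                    stats = WellBlockStats.from_frames(lam, cfg)
                    s0, s1 = update_well_position(stats, cfg)
                    if s0 != 0.0:
                        old = engine.p0[r, i]
                        new = float(np.clip(old + s0, -cfg.max_shift, cfg.max_shift))
                        if new != old:
                            engine.p0[r, i] = new
                            engine.record_adjustment(r, i, "well_p0", old, new,
                                                     time, cfg.censor_duration)
                            changed.add((r, i))
                    if s1 != 0.0:
                        old = engine.p1[r, i]
                        new = float(np.clip(old + s1, 1.0 - cfg.max_shift,
                                            1.0 + cfg.max_shift))
                        if new != old:
                            engine.p1[r, i] = new
                            engine.record_adjustment(r, i, "well_p1", old, new,
                                                     time, cfg.censor_duration)
                            changed.add((r, i))
                # accumulate in-transition statistics per protonation state
                in_trans = (lam > cfg.transition_low) & (lam < cfg.transition_high)
                part = layout.tpartner[i]
                if part >= 0:
                    prot = block_lam[r, :, part] < 0.5
                    self._trans_counts[r, i, 0] += np.sum(in_trans & prot)
                    self._total_counts[r, i, 0] += np.sum(prot)
                    self._trans_counts[r, i, 1] += np.sum(in_trans & ~prot)
                    self._total_counts[r, i, 1] += np.sum(~prot)
                else:
                    self._trans_counts[r, i, 0] += np.sum(in_trans)
                    self._total_counts[r, i, 0] += nframes

        self._block_time += cfg.well_block
        if cfg.adjust_barrier and self._block_time >= cfg.barrier_block - 1e-9:
            for r in range(R):
                for i in range(nc):
                    states = ("prot", "deprot") if layout.tpartner[i] >= 0 else ("prot",)
                    for si, state in enumerate(states):
                        tot = self._total_counts[r, i, si]
                        if tot < 10:  # too few frames in this state to judge
                            continue
                        f = self._trans_counts[r, i, si] / tot
                        old = engine.h[state][r, i]
                        new = update_barrier(f, old, cfg)
                        if new != old:
                            engine.h[state][r, i] = new
                            if layout.tpartner[i] < 0:
                                engine.h["deprot"][r, i] = new
                            engine.record_adjustment(
                                r, i, f"barrier_{state}", old, new,
                                time, cfg.censor_duration)
                            changed.add((r, i))
            self._trans_counts[:] = 0.0
            self._total_counts[:] = 0.0
            self._block_time = 0.0

        if changed:
            engine.apply_partition_correction(sorted(changed))
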
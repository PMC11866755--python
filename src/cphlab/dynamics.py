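"""Propagation of the lambda (and conformational) degrees of freedom.

The lambda coordinates are integrated with velocity Verlet (mass 60 u by
default, 2 fs time step) and thermostatted by stochastic velocity rescaling
(canonical sampling through velocity rescaling, tau = 1 ps) in a group
separate from the conformational coordinates, which follow overdamped
Langevin dynamics.  The partition-function correction is applied before the
first step, and the optional DBO controller adjusts well positions and
barriers on its block schedule, re-running the correction after every change
and censoring the 10 ps following each adjustment.

:func:`velocity_verlet_step` and :func:`csvr_thermostat` are the readable
single-step reference implementations used by the unit tests; production
trajectories come from the compiled kernel in :mod:`cphlab._kernel`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .model import SystemModel, ThermoContext
from .potentials import BiasPotential, correct_well_depths

__all__ = [
    "IntegratorConfig",
    "LambdaTrajectory",
    "velocity_verlet_step",
    "csvr_rescale_factor",
    "csvr_thermostat",
    "kinetic_temperature",
    "simulate",
    "simulate_batch",
]


@dataclass(frozen=True)
class IntegratorConfig:
    """Integrator and thermostat settings."""

    dt: float = 0.002  # ps
    save_interval: float = 0.5  # ps
    thermostat_tau: float = 1.0  # ps
    thermostat_temperature: float = 300.0  # K
    seed: int = 0
    equilibration: float = 50.0  # ps, run with a low barrier and discarded
    equilibration_barrier: float = 2.0  # kJ/mol
    thermostat: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.save_interval / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("save_interval must be an integer multiple of dt")

    @property
    def save_every(self) -> int:
        return int(round(self.save_interval / self.dt))


@dataclass
class LambdaTrajectory:
    """Time series of lambda coordinates for one replica.

    ``lam`` has shape (nframes, ncoord); ``coord_ids`` name the columns as
    ``"<site_id>:p"`` / ``"<site_id>:t"``.  ``censored`` marks frames within
    10 ps of a runtime bias adjustment; analysis routines skip them.
    """

    times: np.ndarray  # ps
    lam: np.ndarray
    coord_ids: list[str]
    censored: np.ndarray
    metadata: dict = field(default_factory=dict)
    vel: np.ndarray | None = None
    conf: np.ndarray | None = None
    conf_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.censored) != len(self.times):
            raise ValueError("censor flags must align with frames")

    def column(self, coord_id: str) -> np.ndarray:
        return self.lam[:, self.coord_ids.index(coord_id)]

    @property
    def n_frames(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Reference single-step implementations


def velocity_verlet_step(x, v, force_fn, mass, dt):
    """One velocity-Verlet step; time-reversible without a thermostat."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    f = np.asarray(force_fn(x), dtype=float)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force")
    v = v + 0.5 * dt * f / mass
    x = x + dt * v
    f = np.asarray(force_fn(x), dtype=float)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force")
    v = v + 0.5 * dt * f / mass
    return x, v


def csvr_rescale_factor(kinetic: float, ndf: int, kt: float, tau: float,
                        dt: float, rng: np.random.Generator) -> float:
    """Exact stochastic velocity-rescaling factor (Bussi-Donadio-Parrinello).

    Relaxes the kinetic energy toward the canonical distribution with time
    constant ``tau``; as tau -> infinity the factor tends to 1.
    """
    if ndf < 1:
        raise ValueError("at least one degree of freedom required")
    if kinetic <= 0.0:
        return 1.0
    c1 = math.exp(-dt / tau)
    r1 = rng.standard_normal()
    s = float(np.sum(rng.standard_normal(ndf - 1) ** 2)) if ndf > 1 else 0.0
    fac = kt / (2.0 * kinetic)
    a2 = (c1 + (1.0 - c1) * fac * (r1 * r1 + s)
          + 2.0 * r1 * math.sqrt(c1 * (1.0 - c1) * fac))
    return math.sqrt(a2)


def csvr_thermostat(velocities, masses, t_target, tau, dt,
                    rng: np.random.Generator, kb: float = 0.0083144621):
    """Rescale a velocity group with the CSVR factor; returns new velocities."""
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    kin = 0.5 * float(np.sum(m * v * v))
    alpha = csvr_rescale_factor(kin, v.size, kb * t_target, tau, dt, rng)
    return v * alpha


def kinetic_temperature(vel, masses, kb: float = 0.0083144621):
    """Instantaneous kinetic temperature of a velocity frame (K)."""
    v = np.asarray(vel, dtype=float)
    kin = 0.5 * np.sum(np.asarray(masses) * v * v, axis=-1)
    return 2.0 * kin / (v.shape[-1] * kb)


# ---------------------------------------------------------------------------
# Batch engine


class _CoordLayout:
    """Flattened coordinate arrays for a SystemModel (kernel layout)."""

    def __init__(self, model: SystemModel):
        self.model = model
        self.coord_ids: list[str] = []
        self.kinds: list[str] = []
        site_to_p: dict[str, int] = {}
        for s in model.sites:
            site_to_p[s.site_id] = len(self.coord_ids)
            self.coord_ids.append(f"{s.site_id}:p")
            self.kinds.append("p")
        tpartner = []
        tchild = []
        for s in model.sites:
            if s.has_tautomer:
                tchild_idx = len(self.coord_ids)
                self.coord_ids.append(f"{s.site_id}:t")
                self.kinds.append("t")
                tpartner.append(site_to_p[s.site_id])
            else:
                pass
        nc = len(self.coord_ids)
        self.nc = nc
        self.tpartner = np.full(nc, -1, dtype=np.int64)
        self.tchild = np.full(nc, -1, dtype=np.int64)
        self.mass = np.empty(nc)
        self.delta_e = np.zeros(nc)
        self.gap = np.zeros(nc)
        k = len(model.sites)
        for i, s in enumerate(model.sites):
            self.mass[i] = s.lambda_mass
            self.delta_e[i] = s.energy_deprot - s.energy_prot
            if s.has_tautomer:
                self.tchild[i] = k
                self.tpartner[k] = i
                self.mass[k] = s.lambda_mass
                g = s.energy_deprot_epsilon - s.energy_deprot
                self.gap[i] = g
                self.gap[k] = g
                k += 1
        self.w = np.zeros((nc, nc))
        wm = model.coupling_matrix()
        ns = len(model.sites)
        self.w[:ns, :ns] = wm
        # conformational coupling slopes (kJ/mol per unit c), delta-branch base
        ncc = len(model.conf_coords)
        self.ncc = ncc
        self.cs = np.zeros((ncc, nc))
        self.conf_h = np.array([c.barrier for c in model.conf_coords])
        self.conf_d = np.array([c.diffusion for c in model.conf_coords])
        kt_ln10 = model.thermo.kt * math.log(10.0)
        for kk, coord in enumerate(model.conf_coords):
            for i, s in enumerate(model.sites):
                if coord.coord_id in s.conf_coupling:
                    s0, s1 = s.conf_coupling[coord.coord_id]
                    self.delta_e[i] += kt_ln10 * s0
                    self.cs[kk, i] = kt_ln10 * (s1 - s0)

    def coord_site(self, i: int) -> str:
        return self.coord_ids[i].split(":")[0]


class Engine:
    """Vectorized lambda-dynamics over a batch of replicas.

    Each replica carries its own bias stack (one :class:`BiasPotential` per
    coordinate, keyed ``(site_id, "p"|"t")``), so replicas at different pH
    values integrate together in one kernel call.
    """

    def __init__(self, model: SystemModel, bias_sets: list[dict],
                 config: IntegratorConfig, dbo=None):
        self.model = model
        self.layout = _CoordLayout(model)
        self.config = config
        self.dbo = dbo
        self.R = len(bias_sets)
        nc = self.layout.nc
        self.biases = bias_sets
        for bs in bias_sets:
            for i in range(nc):
                key = (self.layout.coord_site(i), self.layout.kinds[i])
                if key not in bs:
                    raise ValueError(f"missing bias for coordinate {key}")
        # dual-barrier state for tautomer coordinates: (barrier, depth) per
        # protonation classification of the partner coordinate
        self.h = {"prot": np.empty((self.R, nc)), "deprot": np.empty((self.R, nc))}
        self.d = {"prot": np.zeros((self.R, nc)), "deprot": np.zeros((self.R, nc))}
        self.p0 = np.empty((self.R, nc))
        self.p1 = np.empty((self.R, nc))
        self.slope = np.empty((self.R, nc))
        self.vmm = np.zeros((nc, _kernel.NCOEF))
        self.event_log: list[dict] = []
        self._pending_censor: list[tuple[int, float, float]] = []
        self._sync_from_biases()

    # -- bias bookkeeping --------------------------------------------------
    def _bias(self, r: int, i: int) -> BiasPotential:
        return self.biases[r][(self.layout.coord_site(i), self.layout.kinds[i])]

    def _set_bias(self, r: int, i: int, b: BiasPotential) -> None:
        self.biases[r][(self.layout.coord_site(i), self.layout.kinds[i])] = b

    def _sync_from_biases(self) -> None:
        nc = self.layout.nc
        for r in range(self.R):
            for i in range(nc):
                b = self._bias(r, i)
                self.p0[r, i] = b.dw.p0
                self.p1[r, i] = b.dw.p1
                self.h["prot"][r, i] = b.dw.barrier
                self.h["deprot"][r, i] = b.dw.barrier
                self.d["prot"][r, i] = b.dw.depth_offset
                self.d["deprot"][r, i] = b.dw.depth_offset
                self.slope[r, i] = (b.ph.delta_g_target(b.thermo)
                                    if b.ph is not None else 0.0)
                if b.vmm is not None:
                    coef = np.asarray(b.vmm.coefficients, dtype=float)
                    if len(coef) > _kernel.NCOEF:
                        raise ValueError("V_mm polynomial degree too high for kernel")
                    if r == 0:
                        self.vmm[i, : len(coef)] = coef
        self.wall_off = self._bias(0, 0).dw.wall_offset
        self.wall_k = self._bias(0, 0).dw.wall_stiffness

    def apply_partition_correction(self, pairs=None) -> None:
        """Run the well-depth correction for the given (replica, coord) pairs.

        For tautomer coordinates, both state-selected barriers get their own
        corrected depth offset.  Default: all coordinates of all replicas.
        """
        nc = self.layout.nc
        if pairs is None:
            pairs = [(r, i) for r in range(self.R) for i in range(nc)]
        for r, i in pairs:
            b = self._bias(r, i)
            if self.layout.kinds[i] == "t":
                # the deprotonated state feels the tautomer energy gap; its
                # corrected landscape must reproduce that free-energy
                # difference exactly, the protonated state is degenerate
                gap = self.layout.gap[i]
                for state, tilt, target in (("prot", 0.0, 0.0),
                                            ("deprot", gap, gap)):
                    dw = replace(b.dw, barrier=self.h[state][r, i],
                                 p0=self.p0[r, i], p1=self.p1[r, i],
                                 depth_offset=self.d[state][r, i])
                    trial = BiasPotential(dw=dw, ph=b.ph, vmm=b.vmm,
                                          thermo=b.thermo,
                                          target_offset=b.target_offset)
                    new = correct_well_depths(trial, target=target, tilt=tilt)
                    self.d[state][r, i] = new.depth_offset
                self._set_bias(r, i, replace(
                    b, dw=replace(b.dw, p0=self.p0[r, i], p1=self.p1[r, i],
                                  barrier=self.h["prot"][r, i],
                                  depth_offset=self.d["prot"][r, i])))
            else:
                dw = replace(b.dw, barrier=self.h["prot"][r, i],
                             p0=self.p0[r, i], p1=self.p1[r, i],
                             depth_offset=self.d["prot"][r, i])
                trial = BiasPotential(dw=dw, ph=b.ph, vmm=b.vmm,
                                      thermo=b.thermo,
                                      target_offset=b.target_offset)
                new = correct_well_depths(trial)
                self.d["prot"][r, i] = new.depth_offset
                self.d["deprot"][r, i] = new.depth_offset
                self._set_bias(r, i, replace(b, dw=new))

    # -- integration -------------------------------------------------------
    def _init_state(self, rng: np.random.Generator):
        nc = self.layout.nc
        kt = self.model.thermo.boltzmann_constant * self.config.thermostat_temperature
        lam = np.zeros((self.R, nc))
        # start each coordinate in its more populated well at the run's pH
        for r in range(self.R):
            for i in range(nc):
                b = self._bias(r, i)
                lam[r, i] = b.dw.p1 if b.target_delta_g() < 0 else b.dw.p0
        vel = rng.standard_normal((self.R, nc)) * np.sqrt(kt / self.layout.mass)
        conf = np.zeros((self.R, self.layout.ncc))
        for k, c in enumerate(self.model.conf_coords):
            conf[:, k] = c.value
        return lam, vel, conf

    def _run_chunk(self, lam, vel, conf, nsteps, barrier_override=None):
        cfg = self.config
        nframes = nsteps // cfg.save_every
        nc = self.layout.nc
        out_lam = np.empty((self.R, nframes, nc))
        out_vel = np.empty((self.R, nframes, nc))
        out_conf = np.empty((self.R, nframes, self.layout.ncc))
        hp, hd = self.h["prot"], self.h["deprot"]
        if barrier_override is not None:
            hp = np.full_like(hp, barrier_override)
            hd = np.full_like(hd, barrier_override)
        kt = self.model.thermo.boltzmann_constant * cfg.thermostat_temperature
        _kernel.run_chunk(
            lam, vel, conf, nsteps, cfg.save_every, cfg.dt,
            self.layout.mass, self.layout.delta_e, self.layout.gap,
            self.layout.tpartner, self.layout.tchild, self.layout.w,
            self.vmm, self.slope, self.p0, self.p1, hp, hd,
            self.d["prot"], self.d["deprot"],
            self.wall_off, self.wall_k,
            self.layout.cs, self.layout.conf_h, self.layout.conf_d,
            kt, cfg.thermostat_tau, cfg.thermostat,
            out_lam, out_vel, out_conf)
        if np.any(np.abs(lam) > 5.0):
            bad = np.argwhere(np.abs(lam) > 5.0)[0]
            raise RuntimeError(
                f"divergent lambda on replica {bad[0]}, coordinate "
                f"{self.layout.coord_ids[bad[1]]}: |lambda| > 5"
            )
        return out_lam, out_vel, out_conf

    def run(self, duration: float, rng_seed: int | None = None):
        """Integrate ``duration`` ps (after equilibration); returns trajectories."""
        cfg = self.config
        seed = cfg.seed if rng_seed is None else rng_seed
        rng = np.random.default_rng(seed)
        _kernel.seed(int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)))
        lam, vel, conf = self._init_state(rng)

        self.apply_partition_correction()  # before the first simulation step
        if cfg.equilibration > 0:
            nsteps = int(round(cfg.equilibration / cfg.dt))
            self._run_chunk(lam, vel, conf, nsteps,
                            barrier_override=cfg.equilibration_barrier)

        total_steps = int(round(duration / cfg.dt))
        if self.dbo is not None:
            block_steps = int(round(self.dbo.config.well_block / cfg.dt))
        else:
            block_steps = min(total_steps, int(round(100.0 / cfg.dt)))
        frames_lam, frames_vel, frames_conf, frame_times = [], [], [], []
        t = 0.0
        done = 0
        while done < total_steps:
            n = min(block_steps, total_steps - done)
            ol, ov, oc = self._run_chunk(lam, vel, conf, n)
            nfr = ol.shape[1]
            times = t + cfg.save_interval * np.arange(1, nfr + 1)
            frames_lam.append(ol)
            frames_vel.append(ov)
            frames_conf.append(oc)
            frame_times.append(times)
            t += n * cfg.dt
            done += n
            if self.dbo is not None:
                self.dbo.on_block_end(self, ol, t)

        lam_all = np.concatenate(frames_lam, axis=1)
        vel_all = np.concatenate(frames_vel, axis=1)
        conf_all = np.concatenate(frames_conf, axis=1)
        times = np.concatenate(frame_times)
        censored = np.zeros((self.R, len(times)), dtype=bool)
        for r, t0, t1 in self._pending_censor:
            censored[r] |= (times >= t0 - 1e-9) & (times <= t1 + 1e-9)

        trajs = []
        for r in range(self.R):
            b0 = self._bias(r, 0)
            meta = {
                "pH": b0.ph.pH if b0.ph is not None else None,
                "replica": r,
                "seed": seed,
                "site_ids": [s.site_id for s in self.model.sites],
                "bias_parameters": {
                    f"{k[0]}:{k[1]}": v.to_dict() for k, v in self.biases[r].items()
                },
                "bias_history": [e for e in self.event_log if e["replica"] == r],
            }
            trajs.append(LambdaTrajectory(
                times=times.copy(), lam=lam_all[r], coord_ids=list(self.layout.coord_ids),
                censored=censored[r], metadata=meta, vel=vel_all[r], conf=conf_all[r],
                conf_ids=[c.coord_id for c in self.model.conf_coords]))
        return trajs

    # -- DBO actuation interface -------------------------------------------
    def record_adjustment(self, r: int, i: int, param: str, old: float,
                          new: float, time: float, censor_duration: float) -> None:
        self.event_log.append({
            "time": time, "replica": r, "coordinate": self.layout.coord_ids[i],
            "parameter": param, "old": old, "new": new,
        })
        self._pending_censor.append((r, time, time + censor_duration))


def simulate(model: SystemModel, biases: dict, config: IntegratorConfig,
             duration: float, dbo=None) -> LambdaTrajectory:
    """Run a single-replica lambda-dynamics simulation.

    ``biases`` maps ``(site_id, "p"|"t")`` to a :class:`BiasPotential`.  The
    partition correction is applied before the first step; if a DBO
    controller is given it is invoked on its block schedule.
    """
    eng = Engine(model, [dict(biases)], config, dbo=dbo)
    return eng.run(duration)[0]


def simulate_batch(model: SystemModel, bias_sets: list[dict],
                   config: IntegratorConfig, duration: float,
                   dbo=None) -> list[LambdaTrajectory]:
    """Run many replicas (possibly at different pH) in one vectorized batch."""
    eng = Engine(model, [dict(b) for b in bias_sets], config, dbo=dbo)
    return eng.run(duration)
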
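"""Compiled inner loop of the lambda-dynamics integrator.

All per-step work (force evaluation, velocity-Verlet update, CSVR thermostat,
overdamped conformational Langevin step) lives here so that multi-nanosecond
titration protocols run in seconds.  The Python-level force routine in
:mod:`cphlab.model` / :mod:`cphlab.potentials` is the readable reference; a
regression test asserts that this kernel reproduces its gradients.

Array layout (R replicas, nc lambda coordinates, ncc conformational coords):

* ``lam, vel``: (R, nc) coordinate values and velocities
* ``conf``: (R, ncc)
* per-coordinate constants: ``mass, delta_e, gap, tpartner`` (nc,)
* ``w``: (nc, nc) bilinear coupling (nonzero only between lambda_p coords)
* ``vmm``: (nc, NCOEF) ascending polynomial coefficients of V_mm
* per-(replica, coordinate) bias state: ``slope`` (the V_pH ramp),
  ``p0, p1`` (well positions), ``h_prot, h_deprot`` (barriers; equal for
  protonation coordinates, state-selected for tautomer coordinates),
  ``d_prot, d_deprot`` (well-depth offsets from the partition correction)
* ``cs``: (ncc, nc) dE_deprot/dc conformational coupling slopes
* ``tpartner[i]`` is the protonation-coordinate index for tautomer coordinate
  i, or -1; ``tchild[i]`` is the tautomer-coordinate index for protonation
  coordinate i, or -1.

The thermostat uses numba's module-level RNG; :func:`seed` must be called
once per simulation for reproducible streams.
"""

import numpy as np
from numba import njit

NCOEF = 8


@njit(cache=True)
def seed(s):
    np.random.seed(s)


@njit(cache=True, inline="always")
def _poly_grad(coef, x):
    """Derivative of an ascending-coefficient polynomial at x."""
    g = 0.0
    for k in range(NCOEF - 1, 0, -1):
        g = g * x + k * coef[k]
    return g


@njit(cache=True)
def _forces(lam, conf, f, delta_e, gap, tpartner, tchild, w,
            vmm, slope, p0, p1, h_prot, h_deprot, d_prot, d_deprot,
            wall_off, wall_k, cs, fc, conf_h):
    """Negative gradients on all lambda and conformational coordinates."""
    R, nc = lam.shape
    ncc = conf.shape[1]
    for r in range(R):
        for i in range(nc):
            x = lam[r, i]
            part = tpartner[i]
            if part >= 0:
                # tautomer coordinate: gradient of site energy lp*gap*lt
                g = lam[r, part] * gap[i]
                prot_state = lam[r, part] < 0.5
            else:
                g = delta_e[i]
                child = tchild[i]
                if child >= 0:
                    g += lam[r, child] * gap[i]
                for k in range(ncc):
                    g += cs[k, i] * conf[r, k]
                for j in range(nc):
                    wij = w[i, j]
                    if wij != 0.0:
                        g += wij * lam[r, j]
                prot_state = True
            # double well (state-selected barrier for tautomer coords)
            if prot_state:
                h = h_prot[r, i]
                d = d_prot[r, i]
            else:
                h = h_deprot[r, i]
                d = d_deprot[r, i]
            span = p1[r, i] - p0[r, i]
            u = (x - p0[r, i]) / span
            heff = h - 0.5 * abs(d)
            if heff < 0.1:
                heff = 0.1
            q = 4.0 * u * (1.0 - u)
            dstep = 210.0 * (u * (1.0 - u) * (1.0 - 2.0 * u)) ** 2
            g += (heff * 2.0 * q * (4.0 - 8.0 * u) + d * dstep) / span
            lo = p0[r, i] - wall_off
            hi = p1[r, i] + wall_off
            if x < lo:
                g += -4.0 * wall_k * (lo - x) ** 3
            elif x > hi:
                g += 4.0 * wall_k * (x - hi) ** 3
            # V_pH ramp and V_mm polynomial
            g += slope[r, i]
            g += _poly_grad(vmm[i], x)
            f[r, i] = -g
        for k in range(ncc):
            c = conf[r, k]
            g = 32.0 * conf_h[k] * c * (1.0 - c) * (1.0 - 2.0 * c)
            for i in range(nc):
                if tpartner[i] < 0 and cs[k, i] != 0.0:
                    # shift energy split symmetrically between end states
                    g += cs[k, i] * (lam[r, i] - 0.5)
            fc[r, k] = -g


@njit(cache=True)
def run_chunk(lam, vel, conf, nsteps, save_every, dt,
              mass, delta_e, gap, tpartner, tchild, w,
              vmm, slope, p0, p1, h_prot, h_deprot, d_prot, d_deprot,
              wall_off, wall_k, cs, conf_h, conf_d,
              kt, tau, thermostat_on,
              out_lam, out_vel, out_conf):
    """Advance ``nsteps`` of velocity Verlet, saving every ``save_every`` steps.

    Returns the number of frames written.  ``out_*`` must be preallocated
    with at least nsteps // save_every frames.
    """
    R, nc = lam.shape
    ncc = conf.shape[1]
    f = np.empty((R, nc))
    fc = np.empty((R, ncc))
    _forces(lam, conf, f, delta_e, gap, tpartner, tchild, w,
            vmm, slope, p0, p1, h_prot, h_deprot, d_prot, d_deprot,
            wall_off, wall_k, cs, fc, conf_h)
    c1 = np.exp(-dt / tau)
    beta = 1.0 / kt
    nframes = 0
    for step in range(nsteps):
        for r in range(R):
            for i in range(nc):
                vel[r, i] += 0.5 * dt * f[r, i] / mass[i]
                lam[r, i] += dt * vel[r, i]
            # overdamped Langevin for conformational coordinates
            for k in range(ncc):
                conf[r, k] += (-conf_d[k] * beta * (-fc[r, k]) * dt
                               + np.sqrt(2.0 * conf_d[k] * dt) * np.random.normal())
        _forces(lam, conf, f, delta_e, gap, tpartner, tchild, w,
                vmm, slope, p0, p1, h_prot, h_deprot, d_prot, d_deprot,
                wall_off, wall_k, cs, fc, conf_h)
        for r in range(R):
            for i in range(nc):
                vel[r, i] += 0.5 * dt * f[r, i] / mass[i]
            if thermostat_on:
                # stochastic velocity rescaling (canonical sampling)
                kin = 0.0
                for i in range(nc):
                    kin += 0.5 * mass[i] * vel[r, i] * vel[r, i]
                if kin > 0.0:
                    r1 = np.random.normal()
                    s = 0.0
                    for _ in range(nc - 1):
                        z = np.random.normal()
                        s += z * z
                    fac = kt / (2.0 * kin)
                    a2 = (c1 + (1.0 - c1) * fac * (r1 * r1 + s)
                          + 2.0 * r1 * np.sqrt(c1 * (1.0 - c1) * fac))
                    alpha = np.sqrt(a2)
                    for i in range(nc):
                        vel[r, i] *= alpha
        if (step + 1) % save_every == 0:
            for r in range(R):
                for i in range(nc):
                    out_lam[r, nframes, i] = lam[r, i]
                    out_vel[r, nframes, i] = vel[r, i]
                for k in range(ncc):
                    out_conf[r, nframes, k] = conf[r, k]
            nframes += 1
    return nframes
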
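"""Bias potentials acting on each lambda coordinate and their calibration.

The total bias is V(lambda) = V_mm + V_pH + V_dw:

* ``V_mm`` -- a polynomial equal to minus the model deprotonation free-energy
  profile of the reference compound, making the landscape flat for the
  reference (see :mod:`cphlab.calibration`).
* ``V_pH`` -- a linear ramp ``lambda * kT ln10 (pKa_ref - pH)`` coupling the
  coordinate to the pH bath: the end-state energy difference equals the
  deprotonation free energy at the given pH.
* ``V_dw`` -- a double well concentrating lambda near the physical end states
  0 and 1, with a central barrier controlling transition rates and steep
  confining walls outside the wells.

Because the well shapes are generally asymmetric, the raw double well exerts
an entropic bias on the protonated/deprotonated populations.  The partition
function correction integrates exp(-beta V) over each well and iteratively
refines the deprotonated well-depth offset until the lambda-ensemble free
energy difference matches its target, so that the simulated deprotonation
fraction follows the Henderson-Hasselbalch curve exactly -- including frames
in intermediate lambda states.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .model import LN10, ThermoContext

__all__ = [
    "DoubleWellParams",
    "CalibrationPolynomial",
    "PHPotentialParams",
    "PartitionResult",
    "BiasPotential",
    "v_dw",
    "v_ph",
    "partition_functions",
    "correct_well_depths",
]


@dataclass(frozen=True)
class DoubleWellParams:
    """Parameters of the double-well bias V_dw.

    The interior shape on the normalised coordinate u = (lam-p0)/(p1-p0) is

        V(u) = h_eff * (4u(1-u))**2 + d * T(u),
        T(u) = 70u^3 - 315u^4 + 546u^5 - 420u^6 + 120u^7

    a C-infinity polynomial with exact minima at u=0 (value 0) and u=1
    (value ``depth_offset`` d) and an exact interior maximum at u=1/2 of
    value h_eff + d/2: T' = 210 u^2 (1-u)^2 (1-2u)^2 vanishes at the wells
    and the barrier top, so the double-well topology survives any depth
    offset the partition correction chooses.  h_eff = barrier - |d|/2
    (floored at 0.1) keeps the maximum ``barrier`` above the lower well.
    Quartic walls starting ``wall_offset`` beyond the wells confine the
    coordinate; the smooth polynomial growth outside [0, 1] already rises
    toward them.
    """

    p0: float = 0.0  # protonated well position
    p1: float = 1.0  # deprotonated well position
    barrier: float = 6.0  # kJ/mol, central barrier above the lower well
    depth_offset: float = 0.0  # kJ/mol, applied to the deprotonated well
    wall_offset: float = 0.15  # walls start this far outside the wells
    wall_stiffness: float = 1.0e5  # kJ/mol per unit^4

    def __post_init__(self) -> None:
        if self.p1 <= self.p0:
            raise ValueError("p1 must exceed p0")


def v_dw(lam, params: DoubleWellParams):
    """Double-well bias energy and gradient at ``lam`` (scalar or array)."""
    lam = np.asarray(lam, dtype=float)
    span = params.p1 - params.p0
    u = (lam - params.p0) / span
    d = params.depth_offset
    h_eff = max(params.barrier - 0.5 * abs(d), 0.1)
    q = 4.0 * u * (1.0 - u)
    step = u**3 * (70.0 + u * (-315.0 + u * (546.0 + u * (-420.0 + u * 120.0))))
    dstep = 210.0 * (u * (1.0 - u) * (1.0 - 2.0 * u)) ** 2
    v = h_eff * q * q + d * step
    dv = (h_eff * 2.0 * q * (4.0 - 8.0 * u) + d * dstep) / span

    lo = params.p0 - params.wall_offset
    hi = params.p1 + params.wall_offset
    below = lam < lo
    above = lam > hi
    v = v + params.wall_stiffness * (np.where(below, lo - lam, 0.0) ** 4
                                     + np.where(above, lam - hi, 0.0) ** 4)
    dv = dv + params.wall_stiffness * (-4.0 * np.where(below, lo - lam, 0.0) ** 3
                                       + 4.0 * np.where(above, lam - hi, 0.0) ** 3)
    if np.ndim(lam) == 0:
        return float(v), float(dv)
    return v, dv


@dataclass(frozen=True)
class PHPotentialParams:
    """pH-coupling ramp parameters."""

    pH: float
    pka_ref: float

    def delta_g_target(self, thermo: ThermoContext) -> float:
        """Target deprotonation free energy kT ln10 (pKa_ref - pH), kJ/mol."""
        return thermo.kt * LN10 * (self.pka_ref - self.pH)


def v_ph(lam, params: PHPotentialParams, thermo: ThermoContext):
    """Linear pH ramp: V(1) - V(0) equals the deprotonation free energy."""
    slope = params.delta_g_target(thermo)
    lam = np.asarray(lam, dtype=float)
    v = lam * slope
    dv = np.full_like(lam, slope)
    if np.ndim(lam) == 0:
        return float(v), float(dv)
    return v, dv


@dataclass(frozen=True)
class CalibrationPolynomial:
    """V_mm(lambda) = -DeltaG_MM(lambda) as a fitted polynomial."""

    coefficients: tuple  # ascending degree, kJ/mol
    domain: tuple = (-0.1, 1.1)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def value_grad(self, lam):
        lam = np.asarray(lam, dtype=float)
        c = np.asarray(self.coefficients, dtype=float)
        v = np.polynomial.polynomial.polyval(lam, c)
        dv = np.polynomial.polynomial.polyval(lam, np.polynomial.polynomial.polyder(c))
        if np.ndim(lam) == 0:
            return float(v), float(dv)
        return v, dv


@dataclass(frozen=True)
class PartitionResult:
    """Well partition functions and the deprotonation free energy they imply.

    ``delta_g = G_deprot - G_prot = (1/beta) ln(Z_prot / Z_deprot)``: positive
    when deprotonation is unfavourable, so the equilibrium deprotonated
    fraction is ``Z_deprot / (Z_prot + Z_deprot) = 1 / (1 + exp(beta delta_g))``.
    """

    z_prot: float
    z_deprot: float
    delta_g: float  # kJ/mol
    lambda_barrier: float


@dataclass
class BiasPotential:
    """The complete bias stack for one lambda coordinate.

    ``target_offset`` is an additive correction to the partition-correction
    target free energy; it carries the -kT ln 2 tautomer-degeneracy term for
    the protonation coordinate of tautomeric sites (the protonated chemical
    state occupies two lambda_t wells).
    """

    dw: DoubleWellParams
    ph: PHPotentialParams | None = None
    vmm: CalibrationPolynomial | None = None
    thermo: ThermoContext = None  # type: ignore[assignment]
    target_offset: float = 0.0  # kJ/mol

    def __post_init__(self) -> None:
        if self.thermo is None:
            self.thermo = ThermoContext()

    def value_grad(self, lam):
        v, dv = v_dw(lam, self.dw)
        if self.ph is not None:
            v2, dv2 = v_ph(lam, self.ph, self.thermo)
            v, dv = v + v2, dv + dv2
        if self.vmm is not None:
            v3, dv3 = self.vmm.value_grad(lam)
            v, dv = v + v3, dv + dv3
        return v, dv

    def value(self, lam):
        return self.value_grad(lam)[0]

    def correction_landscape(self, lam):
        """Effective reference landscape used by the partition correction.

        V_mm cancels the reference compound's deprotonation free-energy
        profile by construction, so the landscape the lambda particle
        effectively samples for a calibrated reference is V_dw + V_pH; the
        correction integrates exactly that.
        """
        v, _ = v_dw(lam, self.dw)
        if self.ph is not None:
            v = v + v_ph(lam, self.ph, self.thermo)[0]
        return v

    def target_delta_g(self) -> float:
        """Target lambda-ensemble deprotonation free energy (kJ/mol)."""
        base = self.ph.delta_g_target(self.thermo) if self.ph is not None else 0.0
        return base + self.target_offset

    def to_dict(self) -> dict:
        """Serializable snapshot of all bias parameters (for run metadata)."""
        out = {
            "dw": {
                "p0": self.dw.p0, "p1": self.dw.p1,
                "barrier": self.dw.barrier, "depth_offset": self.dw.depth_offset,
                "wall_offset": self.dw.wall_offset,
                "wall_stiffness": self.dw.wall_stiffness,
            },
            "target_offset": self.target_offset,
        }
        if self.ph is not None:
            out["ph"] = {"pH": self.ph.pH, "pka_ref": self.ph.pka_ref}
        if self.vmm is not None:
            out["vmm"] = {"coefficients": list(self.vmm.coefficients),
                          "domain": list(self.vmm.domain)}
        return out


# ---------------------------------------------------------------------------
# Partition functions and the well-depth correction

#: Frame classification threshold (deprotonated iff lambda >= 0.5); the
#: correction splits its quadrature here so that corrected populations and
#: counted fractions refer to the same two states.
CLASSIFICATION_THRESHOLD = 0.5

#: Quadrature grid resolution (trapezoid) for the well partition functions.
N_QUADRATURE = 2401
#: Integration domain extends this far beyond the wells; wide enough that the
#: Boltzmann weight at the edges (behind the confining walls) is negligible.
QUAD_MARGIN = 0.30


def _quad_grid(dw: DoubleWellParams, n: int = N_QUADRATURE) -> np.ndarray:
    return np.linspace(dw.p0 - QUAD_MARGIN, dw.p1 + QUAD_MARGIN, n)


def partition_functions(vfunc, thermo: ThermoContext,
                        dw: DoubleWellParams | None = None,
                        grid: np.ndarray | None = None,
                        split_at: float | None = None) -> PartitionResult:
    """Well partition functions of a 1-D lambda potential by quadrature.

    ``vfunc`` maps a lambda array to energies (kJ/mol).  The domain is split
    at ``split_at`` if given (the well-depth correction uses the frame
    classification threshold 0.5, so that corrected populations and counted
    fractions agree); otherwise at the interior maximum of V between the two
    wells.  Z_prot integrates exp(-beta V) below the split, Z_deprot above.
    Raises if no interior maximum exists (degenerate single-well potential).
    """
    if grid is None:
        if dw is None:
            raise ValueError("either dw params or an explicit grid is required")
        grid = _quad_grid(dw)
    v = np.asarray(vfunc(grid), dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("potential must be finite on the integration domain")

    if split_at is not None:
        k = int(np.argmin(np.abs(grid - split_at)))
    else:
        # interior argmax between the two wells
        lo = grid[0] if dw is None else dw.p0
        hi = grid[-1] if dw is None else dw.p1
        interior = (grid > lo) & (grid < hi)
        if not np.any(interior):
            raise ValueError("no interior region between wells")
        idx = np.flatnonzero(interior)
        k = idx[np.argmax(v[idx])]
        if k == idx[0] or k == idx[-1]:
            if dw is None:
                raise ValueError(
                    "no interior barrier maximum: degenerate single-well potential")
            # strongly tilted landscape: the minor well lies above the
            # barrier top; split at the designed barrier position instead
            k = int(np.argmin(np.abs(grid - 0.5 * (dw.p0 + dw.p1))))
    lam_b = float(grid[k])

    beta = thermo.beta
    w = np.exp(-beta * (v - v.min()))
    z_p = float(np.trapezoid(w[: k + 1], grid[: k + 1]))
    z_d = float(np.trapezoid(w[k:], grid[k:]))
    if z_p <= 0 or z_d <= 0:
        raise ValueError("non-positive partition function")
    delta_g = (1.0 / beta) * np.log(z_p / z_d)
    return PartitionResult(z_prot=z_p, z_deprot=z_d, delta_g=float(delta_g),
                           lambda_barrier=lam_b)


def correct_well_depths(bias: BiasPotential, target: float | None = None,
                        tol: float = 0.01, d_range: tuple = (-30.0, 30.0),
                        max_iter: int = 100, tilt: float = 0.0) -> DoubleWellParams:
    """Refine the deprotonated well-depth offset to hit the target free energy.

    One-dimensional root find (bracketed Brent) on the depth offset ``d`` such
    that the re-evaluated lambda-ensemble deprotonation free energy
    ``(1/beta) ln(Z_prot/Z_deprot)`` is within ``tol`` (kJ/mol) of ``target``
    (default: the bias's own :meth:`BiasPotential.target_delta_g`).  Invoked
    before the first simulation step and after every runtime adjustment of the
    barrier or well positions.

    ``tilt`` adds a linear energy ``tilt * lambda`` to the probed landscape:
    the deprotonated-state correction of a tautomer coordinate passes the
    tautomer energy gap here (with ``target`` equal to that gap), so that
    the realised well free-energy difference matches the physical one.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if target is None:
        target = bias.target_delta_g()

    def residual(d: float) -> float:
        trial = replace(bias.dw, depth_offset=d)
        probe = BiasPotential(dw=trial, ph=bias.ph, vmm=bias.vmm,
                              thermo=bias.thermo, target_offset=bias.target_offset)
        res = partition_functions(
            lambda g: probe.correction_landscape(g) + tilt * g,
            bias.thermo, dw=trial, split_at=CLASSIFICATION_THRESHOLD)
        return res.delta_g - target

    d0 = bias.dw.depth_offset
    r0 = residual(d0)
    if abs(r0) <= tol:
        return bias.dw
    # delta_g is monotone increasing in d and close to d + const (raising the
    # deprotonated well raises its free energy almost one-to-one), so bracket
    # around the predicted root and widen only if needed.
    d_est = d0 - r0
    half = 3.0
    lo = max(d_range[0], d_est - half)
    hi = min(d_range[1], d_est + half)
    r_lo, r_hi = residual(lo), residual(hi)
    for _ in range(max_iter):
        if r_lo <= 0.0 <= r_hi:
            break
        if r_lo > 0.0:
            if lo <= d_range[0]:
                raise RuntimeError(
                    f"well-depth correction cannot bracket target "
                    f"{target:.3f} kJ/mol in d range {d_range}")
            lo = max(d_range[0], lo - half)
            r_lo = residual(lo)
        else:
            if hi >= d_range[1]:
                raise RuntimeError(
                    f"well-depth correction cannot bracket target "
                    f"{target:.3f} kJ/mol in d range {d_range}")
            hi = min(d_range[1], hi + half)
            r_hi = residual(hi)
    d_star = brentq(residual, lo, hi, xtol=1e-3, maxiter=max_iter)
    return replace(bias.dw, depth_offset=float(d_star))
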
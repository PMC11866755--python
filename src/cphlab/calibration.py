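"""Thermodynamic-integration calibration of the V_mm potential.

The model deprotonation free-energy profile DeltaG_MM(lambda) of an isolated
reference site is estimated by sampling <dH/dlambda> in fixed-lambda windows
and integrating with the trapezoid rule.  Defining
V_mm(lambda) := -DeltaG_MM(lambda) yields a landscape that is flat for the
reference site, so that at pH = pKa_ref the simulated titration recovers the
reference pKa (self-consistency).  For sites whose deprotonation energy is a
simple constant the integrand has zero variance and the profile is exact;
conformation-coupled references require genuine sampling of the orthogonal
coordinate, done here by vectorized Metropolis Monte Carlo.

Calibrations are stored per site type as JSON (grid, profile, polynomial,
provenance) and reused across pH points and replicas.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .model import LN10, SiteModel, SystemModel
from .potentials import CalibrationPolynomial

__all__ = ["TIProfile", "ti_profile", "fit_vmm", "calibration_to_json",
           "calibration_from_json", "DEFAULT_GRID"]

#: 21 equidistant lambda windows slightly beyond the physical end states.
DEFAULT_GRID = np.linspace(-0.1, 1.1, 21)


@dataclass
class TIProfile:
    """Windowed <dH/dlambda> estimates and the integrated free energy."""

    grid: np.ndarray  # lambda values, strictly increasing
    mean_dhdl: np.ndarray  # kJ/mol
    se_dhdl: np.ndarray  # standard errors, kJ/mol
    delta_g: np.ndarray = field(init=False)  # kJ/mol, zero at grid[0]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        dg = np.concatenate((
            [0.0],
            np.cumsum(0.5 * (self.mean_dhdl[1:] + self.mean_dhdl[:-1])
                      * np.diff(self.grid)),
        ))
        self.delta_g = dg


def _sample_conf_mean(model: SystemModel, site: SiteModel, lam: float,
                      n_samples: int, rng: np.random.Generator,
                      n_walkers: int = 64, thin: int = 5, burn: int = 200):
    """Mean and SE of the conformational part of dH/dlambda at fixed lambda.

    Vectorized Metropolis on each coupled conformational coordinate under
    landscape + lambda-scaled coupling energy.
    """
    kt = model.thermo.kt
    kt_ln10 = kt * LN10
    mean = 0.0
    var = 0.0
    for coord in model.conf_coords:
        if coord.coord_id not in site.conf_coupling:
            continue
        s0, s1 = site.conf_coupling[coord.coord_id]
        slope = kt_ln10 * (s1 - s0)  # dE_deprot/dc

        def u(c):
            return (16.0 * coord.barrier * c * c * (1.0 - c) ** 2
                    + (lam - 0.5) * slope * c)

        c = rng.random(n_walkers)
        e = u(c)
        n_sweeps = burn + max(1, n_samples // n_walkers) * thin
        acc_mean = []
        for sweep in range(n_sweeps):
            prop = c + 0.25 * rng.standard_normal(n_walkers)
            ep = u(prop)
            accept = rng.random(n_walkers) < np.exp(-np.clip((ep - e) / kt, -50, 50))
            c = np.where(accept, prop, c)
            e = np.where(accept, ep, e)
            if sweep >= burn and (sweep - burn) % thin == 0:
                acc_mean.append(kt_ln10 * s0 + slope * c.copy())
        samples = np.concatenate(acc_mean)
        mean += float(np.mean(samples))
        # crude SE treating walker-decorrelated draws as independent
        var += float(np.var(samples) / len(samples))
    return mean, np.sqrt(var)


def ti_profile(model: SystemModel, site_id: str, coord: str = "p",
               grid: np.ndarray | None = None, samples_per_window: int = 10_000,
               rng: np.random.Generator | None = None,
               se_warn_threshold: float = 0.5) -> TIProfile:
    """TI profile of an isolated reference site along one lambda coordinate.

    ``coord="p"`` integrates along lambda_p with the tautomer coordinate
    pinned at the delta path (lambda_t = 0); ``coord="t"`` integrates along
    lambda_t with the site protonated (lambda_p = 0), where the landscape is
    tautomerically degenerate and hence flat.
    """
    site = model.site(site_id)
    if any(model.coupling_matrix().ravel()):
        raise ValueError("reference model must be an isolated site (W = 0)")
    if grid is None:
        grid = DEFAULT_GRID.copy()
    if rng is None:
        rng = np.random.default_rng(0)

    means = np.empty(len(grid))
    ses = np.zeros(len(grid))
    for k, lam in enumerate(grid):
        if coord == "p":
            base = site.energy_deprot - site.energy_prot  # delta path
            if site.conf_coupling:
                m, se = _sample_conf_mean(model, site, lam, samples_per_window, rng)
                means[k] = base + m
                ses[k] = se
            else:
                means[k] = base
        elif coord == "t":
            # dH/dlambda_t = lambda_p * (E_eps - E_delta); protonated reference
            means[k] = 0.0
        else:
            raise ValueError("coord must be 'p' or 't'")
    prof = TIProfile(grid=np.asarray(grid, dtype=float), mean_dhdl=means, se_dhdl=ses)
    if np.any(ses > se_warn_threshold):
        import warnings

        warnings.warn("TI window standard error above threshold; "
                      "increase samples_per_window", stacklevel=2)
    return prof


def fit_vmm(profile: TIProfile, degree: int = 5,
            max_residual: float = 0.1) -> CalibrationPolynomial:
    """Least-squares polynomial fit of V_mm(lambda) = -DeltaG_MM(lambda).

    Raises if the maximum fit residual exceeds ``max_residual`` kJ/mol
    (polynomial degree too low for the profile's curvature).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    target = -profile.delta_g
    coef = np.polynomial.polynomial.polyfit(profile.grid, target, degree)
    resid = np.polynomial.polynomial.polyval(profile.grid, coef) - target
    if np.max(np.abs(resid)) > max_residual:
        raise ValueError(
            f"V_mm fit residual {np.max(np.abs(resid)):.3f} kJ/mol exceeds "
            f"{max_residual}; increase the polynomial degree"
        )
    return CalibrationPolynomial(
        coefficients=tuple(float(c) for c in coef),
        domain=(float(profile.grid[0]), float(profile.grid[-1])),
    )


# ---------------------------------------------------------------------------
# Persistence


def _model_hash(model: SystemModel, site_id: str) -> str:
    site = model.site(site_id)
    payload = json.dumps({
        "site": site.site_id, "pka": site.pka_ref, "taut": site.has_tautomer,
        "e_prot": site.energy_prot, "e_deprot": site.energy_deprot,
        "e_eps": site.energy_deprot_epsilon,
        "conf": sorted(site.conf_coupling.items()),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def calibration_to_json(profile: TIProfile, poly: CalibrationPolynomial,
                        model: SystemModel, site_id: str, seed: int) -> str:
    return json.dumps({
        "grid": profile.grid.tolist(),
        "mean_dhdl": profile.mean_dhdl.tolist(),
        "se_dhdl": profile.se_dhdl.tolist(),
        "delta_g": profile.delta_g.tolist(),
        "polynomial": {"coefficients": list(poly.coefficients),
                       "domain": list(poly.domain)},
        "provenance": {"seed": seed, "model_hash": _model_hash(model, site_id),
                       "site_id": site_id},
    }, indent=1)


def calibration_from_json(text: str):
    obj = json.loads(text)
    prof = TIProfile(grid=np.array(obj["grid"]),
                     mean_dhdl=np.array(obj["mean_dhdl"]),
                     se_dhdl=np.array(obj["se_dhdl"]))
    poly = CalibrationPolynomial(
        coefficients=tuple(obj["polynomial"]["coefficients"]),
        domain=tuple(obj["polynomial"]["domain"]))
    return prof, poly, obj["provenance"]
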
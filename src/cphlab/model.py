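"""Extended-Hamiltonian model for titratable sites.

A titratable site is described by two end states (protonated / deprotonated)
whose potential energies are interpolated by an alchemical coordinate
``lambda_p`` treated as a dynamical pseudo-particle.  The convention used
throughout the package is

    lambda_p = 0  ->  protonated
    lambda_p = 1  ->  deprotonated

For tautomeric sites (His-like) a second coordinate ``lambda_t`` selects
between the two chemically distinct deprotonated tautomers:

    H = (1 - lp) * E_prot + lp * [(1 - lt) * E_deprot_delta + lt * E_deprot_eps]

i.e. ``lambda_t = 0`` is the delta tautomer.  The protonated corner is the
single doubly-protonated form, identical for both values of ``lambda_t``.

Pairwise site-site coupling is bilinear, ``W_ij * lp_i * lp_j``, mimicking the
Coulomb interaction of the unit charge differences between end states:
``W > 0`` makes simultaneous deprotonation of two acids unfavourable
(anticooperative titration).

Conformational coordinates are abstract one-dimensional double-well degrees
of freedom that shift a site's deprotonation energy linearly, standing in for
the slow protein motions that couple to protonation in real systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_KJ_PER_MOL_K",
    "LN10",
    "ThermoContext",
    "SiteModel",
    "BufferSite",
    "ConformationalCoordinate",
    "SystemModel",
    "LambdaState",
    "interpolated_site_energy",
    "tautomer_interpolation",
    "total_potential",
    "net_charge",
    "site_charge",
    "buffer_charge",
]

#: Boltzmann constant in kJ mol^-1 K^-1 (value used by the simulation engine).
KB_KJ_PER_MOL_K = 0.0083144621
LN10 = math.log(10.0)


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context: temperature and derived inverse temperature."""

    temperature: float = 300.0  # K
    boltzmann_constant: float = KB_KJ_PER_MOL_K  # kJ/mol/K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        """k_B * T in kJ/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """1 / (k_B * T) in mol/kJ."""
        return 1.0 / self.kt


@dataclass
class SiteModel:
    """A titratable site: end-state energies, reference pKa(s) and charges.

    ``energy_deprot`` (and the tautomer variants) are the *raw* model
    deprotonation energies that the calibration potential V_mm later removes;
    any nonzero value exercises the calibration path the way a real force
    field's (mis)match of the deprotonation free energy would.

    ``conf_coupling`` maps a conformational-coordinate id to a linear pKa
    shift (shift0, shift1): the effective pKa at coordinate value ``c`` is
    ``pka_ref + shift0 + (shift1 - shift0) * c``.  The shift energy
    ``kT ln10 * shift(c)`` is split symmetrically between the end states
    (``-1/2`` on the protonated, ``+1/2`` on the deprotonated one), so the
    pKa shift is exact while neither protonation state is singled out as
    defining the conformational landscape.
    """

    site_id: str
    pka_ref: float
    has_tautomer: bool = False
    pka_micro_delta: float | None = None
    pka_micro_epsilon: float | None = None
    energy_prot: float = 0.0  # kJ/mol
    energy_deprot: float = 0.0  # kJ/mol (delta tautomer for tautomeric sites)
    energy_deprot_epsilon: float | None = None  # kJ/mol, tautomeric sites only
    charge_prot: float = 0.0  # e
    charge_deprot: float = -1.0  # e
    lambda_mass: float = 60.0  # u
    buffer_id: str | None = None
    conf_coupling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(abs(self.charge_prot - self.charge_deprot) - 1.0) > 1e-12:
            raise ValueError("site must release exactly one elementary charge")
        if self.has_tautomer:
            if self.pka_micro_delta is None or self.pka_micro_epsilon is None:
                raise ValueError(
                    f"site {self.site_id!r}: tautomeric sites need both "
                    "microscopic pKa values"
                )
            if self.energy_deprot_epsilon is None:
                raise ValueError(
                    f"site {self.site_id!r}: tautomeric sites need "
                    "energy_deprot_epsilon"
                )
        else:
            if self.energy_deprot_epsilon is not None:
                raise ValueError("energy_deprot_epsilon given on a non-tautomeric site")


@dataclass
class BufferSite:
    """A solvent charge buffer paired with one titratable site.

    The buffer oxygen switches from -0.834 e (deprotonated buffer state) to
    +0.166 e (protonated buffer state).  Its lambda is slaved to the paired
    site's lambda_p so that the summed charge of every (site, buffer) pair is
    exactly constant along any trajectory.
    """

    buffer_id: str
    charge_deprot: float = -0.834  # e
    charge_prot: float = 0.166  # e

    def __post_init__(self) -> None:
        if abs((self.charge_prot - self.charge_deprot) - 1.0) > 1e-12:
            raise ValueError("buffer must absorb exactly +1 e upon protonation")


@dataclass
class ConformationalCoordinate:
    """Abstract slow conformational degree of freedom.

    A symmetric double well with minima at 0 and 1 and central barrier
    ``barrier`` (kJ/mol), advanced by overdamped Langevin dynamics with
    diffusion coefficient ``diffusion`` (units of coordinate^2/ps).  The
    relaxation time between basins scales roughly as
    ``exp(beta*barrier) / diffusion``.
    """

    coord_id: str
    barrier: float = 10.0  # kJ/mol
    diffusion: float = 0.01  # 1/ps (coordinate units squared per ps)
    value: float = 0.0

    def landscape(self, c: float) -> tuple[float, float]:
        """Energy and gradient of the double-well landscape at ``c``."""
        # 16 h c^2 (1-c)^2: minima 0/1 at zero energy, barrier h at c=1/2
        e = 16.0 * self.barrier * c * c * (1.0 - c) ** 2
        g = 32.0 * self.barrier * c * (1.0 - c) * (1.0 - 2.0 * c)
        return e, g


@dataclass
class SystemModel:
    """A collection of titratable sites with couplings and buffers."""

    sites: list[SiteModel]
    thermo: ThermoContext = field(default_factory=ThermoContext)
    pH: float = 7.0
    buffers: list[BufferSite] = field(default_factory=list)
    coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    conf_coords: list[ConformationalCoordinate] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        buf_ids = [b.buffer_id for b in self.buffers]
        if len(set(buf_ids)) != len(buf_ids):
            raise ValueError("duplicate buffer ids")
        referenced = [s.buffer_id for s in self.sites if s.buffer_id is not None]
        if len(set(referenced)) != len(referenced):
            raise ValueError("each buffer may be paired with exactly one site")
        for b in referenced:
            if b not in buf_ids:
                raise ValueError(f"site references unknown buffer {b!r}")
        for (i, j) in self.coupling:
            if i not in ids or j not in ids:
                raise ValueError(f"coupling references unknown sites ({i}, {j})")
            if i == j:
                raise ValueError("coupling matrix has zero diagonal by construction")

    # -- lookups -----------------------------------------------------------
    def site(self, site_id: str) -> SiteModel:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def conf_coord(self, coord_id: str) -> ConformationalCoordinate:
        for c in self.conf_coords:
            if c.coord_id == coord_id:
                return c
        raise KeyError(coord_id)

    def coupling_w(self, i: str, j: str) -> float:
        """Symmetric lookup of the pairwise coupling strength (kJ/mol)."""
        return self.coupling.get((i, j), self.coupling.get((j, i), 0.0))

    def coupling_matrix(self) -> np.ndarray:
        ids = [s.site_id for s in self.sites]
        w = np.zeros((len(ids), len(ids)))
        for a, i in enumerate(ids):
            for b, j in enumerate(ids):
                if a != b:
                    w[a, b] = self.coupling_w(i, j)
        return w


@dataclass
class LambdaState:
    """Instantaneous values of all dynamical coordinates of a SystemModel.

    Arrays are aligned with ``SystemModel.sites`` (protonation coordinates)
    and, for tautomeric sites, ``lambda_t``/``v_t`` hold NaN placeholders at
    non-tautomeric positions.  ``conf`` aligns with ``SystemModel.conf_coords``.
    """

    lambda_p: np.ndarray
    lambda_t: np.ndarray | None = None
    v_p: np.ndarray | None = None
    v_t: np.ndarray | None = None
    conf: np.ndarray | None = None

    @classmethod
    def initial(cls, model: SystemModel, protonated: bool = True) -> "LambdaState":
        n = len(model.sites)
        lp = np.zeros(n) if protonated else np.ones(n)
        lt = np.zeros(n)
        return cls(
            lambda_p=lp,
            lambda_t=lt,
            v_p=np.zeros(n),
            v_t=np.zeros(n),
            conf=np.array([c.value for c in model.conf_coords], dtype=float),
        )


# ---------------------------------------------------------------------------
# Energies


def _conf_shift_energy(site: SiteModel, model: SystemModel | None, conf):
    """Conformational shift energy kT ln10 * shift(c) and its dE/dc slopes."""
    e = 0.0
    slopes: dict[int, float] = {}
    if site.conf_coupling and model is not None and conf is not None:
        kt_ln10 = model.thermo.kt * LN10
        for k, coord in enumerate(model.conf_coords):
            if coord.coord_id in site.conf_coupling:
                s0, s1 = site.conf_coupling[coord.coord_id]
                c = float(conf[k])
                e += kt_ln10 * (s0 + (s1 - s0) * c)
                slopes[k] = kt_ln10 * (s1 - s0)
    return e, slopes


def tautomer_interpolation(lp: float, lt: float, e_prot: float,
                           e_deprot_delta: float, e_deprot_eps: float) -> float:
    """Bilinear tautomer interpolation; the single swappable convention.

    Corners: (lp=0, any lt) -> protonated form; (1, 0) -> delta tautomer;
    (1, 1) -> epsilon tautomer.
    """
    return (1.0 - lp) * e_prot + lp * ((1.0 - lt) * e_deprot_delta + lt * e_deprot_eps)


def interpolated_site_energy(site: SiteModel, lambda_p: float,
                             lambda_t: float | None = None,
                             conf=None, model: SystemModel | None = None) -> float:
    """End-state interpolated energy of a single site (kJ/mol).

    Non-tautomeric: ``(1-lp)*E_prot + lp*E_deprot(c)``.  Tautomeric sites use
    :func:`tautomer_interpolation` and reduce to the two-state form when
    ``lambda_t`` is pinned at 0 or 1.
    """
    if not np.isfinite(lambda_p):
        raise ValueError("lambda_p must be finite")
    shift, _ = _conf_shift_energy(site, model, conf)
    base = (lambda_p - 0.5) * shift
    if not site.has_tautomer:
        return base + (1.0 - lambda_p) * site.energy_prot \
            + lambda_p * site.energy_deprot
    if lambda_t is None:
        raise ValueError(f"site {site.site_id!r} is tautomeric: lambda_t required")
    return base + tautomer_interpolation(lambda_p, lambda_t, site.energy_prot,
                                         site.energy_deprot,
                                         site.energy_deprot_epsilon)


def total_potential(model: SystemModel, state: LambdaState, biases=None):
    """Total potential energy of the extended system and its gradient.

    Sum of interpolated site energies, the bilinear coupling
    ``sum_{i<j} W_ij lp_i lp_j``, one bias potential per lambda coordinate
    (``biases`` maps coordinate key ``(site_id, 'p'|'t')`` to an object with a
    ``value_grad(lam)`` method, e.g. :class:`cphlab.potentials.BiasPotential`),
    and the conformational landscape energies.

    Returns ``(energy, grad)`` where ``grad`` is a dict with arrays
    ``lambda_p``, ``lambda_t`` and ``conf`` (kJ/mol per coordinate unit).
    """
    n = len(model.sites)
    lp = np.asarray(state.lambda_p, dtype=float)
    lt = state.lambda_t
    conf = state.conf
    g_p = np.zeros(n)
    g_t = np.zeros(n)
    g_c = np.zeros(len(model.conf_coords))
    energy = 0.0

    for i, site in enumerate(model.sites):
        shift, slopes = _conf_shift_energy(site, model, conf)
        energy += (lp[i] - 0.5) * shift
        g_p[i] += shift
        for k, s in slopes.items():
            g_c[k] += (lp[i] - 0.5) * s
        if site.has_tautomer:
            if lt is None:
                raise ValueError("tautomeric site requires lambda_t in state")
            lti = float(lt[i])
            energy += tautomer_interpolation(lp[i], lti, site.energy_prot,
                                             site.energy_deprot,
                                             site.energy_deprot_epsilon)
            g_p[i] += (-site.energy_prot + (1.0 - lti) * site.energy_deprot
                       + lti * site.energy_deprot_epsilon)
            g_t[i] += lp[i] * (site.energy_deprot_epsilon - site.energy_deprot)
        else:
            energy += ((1.0 - lp[i]) * site.energy_prot
                       + lp[i] * site.energy_deprot)
            g_p[i] += site.energy_deprot - site.energy_prot

    # pairwise coupling
    w = model.coupling_matrix()
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] != 0.0:
                energy += w[i, j] * lp[i] * lp[j]
                g_p[i] += w[i, j] * lp[j]
                g_p[j] += w[i, j] * lp[i]

    # per-coordinate biases
    if biases:
        for i, site in enumerate(model.sites):
            b = biases.get((site.site_id, "p"))
            if b is not None:
                v, dv = b.value_grad(lp[i])
                energy += v
                g_p[i] += dv
            if site.has_tautomer:
                bt = biases.get((site.site_id, "t"))
                if bt is not None:
                    v, dv = bt.value_grad(float(lt[i]))
                    energy += v
                    g_t[i] += dv

    # conformational landscapes
    for k, coord in enumerate(model.conf_coords):
        if conf is not None:
            e, g = coord.landscape(float(conf[k]))
            energy += e
            g_c[k] += g

    return energy, {"lambda_p": g_p, "lambda_t": g_t, "conf": g_c}


# ---------------------------------------------------------------------------
# Charges


def site_charge(site: SiteModel, lambda_p: float) -> float:
    """Interpolated charge of a site at ``lambda_p`` (e)."""
    return (1.0 - lambda_p) * site.charge_prot + lambda_p * site.charge_deprot


def buffer_charge(buf: BufferSite, lambda_buffer: float) -> float:
    """Interpolated buffer charge; ``lambda_buffer=1`` is the protonated state."""
    return (1.0 - lambda_buffer) * buf.charge_deprot + lambda_buffer * buf.charge_prot


def net_charge(model: SystemModel, state: LambdaState) -> float:
    """Total charge of all sites plus buffers (e).

    Buffer lambdas are slaved to the paired site's lambda_p, so the total is
    exactly constant along any trajectory (charge conservation by
    construction).  Raises if buffering is enabled but a titrating site is
    unpaired.
    """
    total = 0.0
    buffers = {b.buffer_id: b for b in model.buffers}
    for i, site in enumerate(model.sites):
        lp = float(state.lambda_p[i])
        if buffers:
            if site.buffer_id is None:
                raise ValueError(
                    f"site {site.site_id!r} has no paired charge buffer"
                )
            buf = buffers[site.buffer_id]
            # combine the pair's lambda slopes before scaling: the +-1 e
            # slopes cancel exactly, so the total is bitwise constant
            slope = ((site.charge_deprot - site.charge_prot)
                     + (buf.charge_prot - buf.charge_deprot))
            total += site.charge_prot + buf.charge_deprot + lp * slope
        else:
            total += site_charge(site, lp)
    return total
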
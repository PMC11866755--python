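"""Ready-to-run model systems with controlled ground truth.

Each scenario instantiates a fully calibrated toy system whose true
titration behaviour is known by construction, so every analysis path can be
validated by parameter recovery:

* ``single``        -- one Glu-like site (reference pKa 4.40 by default).
* ``tautomer``      -- one dual-lambda His-like site with microscopic
                       tautomer pKa values (6.53 / 6.92 by default).
* ``coupled_pair``  -- two sites with bilinear coupling W (anticooperative
                       for W > 0; W = 0 gives independent titration).
* ``conformation_coupled`` -- one site whose pKa is shifted by ``delta_pka``
                       between the two basins of a slow conformational
                       coordinate.
* ``spread_replica`` -- the same with a conformational relaxation time much
                       longer than the replica length, reproducing the
                       spread-replica titration phenomenology on demand.

The titration protocol follows the standard design: a pH grid extending one
unit beyond the extreme reference pKa values in 0.5-unit steps, several
replicas per pH, each replica seeded independently from
(global seed, scenario tag, pH, replica) and recorded in the metadata so
that reruns are bit-identical.

The raw deprotonation energies of the toy sites are deliberately nonzero
(tens of kJ/mol) so that the V_mm calibration path is genuinely exercised:
titration only recovers the reference pKa because thermodynamic integration
and the fitted calibration polynomial remove them.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import fit_vmm, ti_profile
from .dbo import DBOConfig, DBOController
from .dynamics import Engine, IntegratorConfig, LambdaTrajectory
from .model import (LN10, BufferSite, ConformationalCoordinate, SiteModel,
                    SystemModel, ThermoContext)
from .potentials import BiasPotential, DoubleWellParams, PHPotentialParams
from .titration import TitrationPoint, classify_and_count

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "TitrationDataset",
    "make_scenario",
    "ph_grid",
    "replica_seed",
    "run_titration",
    "direct_boltzmann_oracle",
]

#: Raw (pre-calibration) deprotonation energy of toy sites, kJ/mol.
RAW_DEPROT_ENERGY = 30.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of a synthetic study system."""

    tag: str = "single"
    pka: float = 4.40  # Glu-like single-residue reference
    pka_micro_delta: float = 6.53  # His-like microscopic references
    pka_micro_epsilon: float = 6.92
    pka_second: float = 4.0  # second site of coupled_pair (Asp-like)
    coupling_w: float = 0.0  # kJ/mol
    delta_pka: float = 2.0  # conformational pKa shift between basins
    conf_barrier: float = 6.0  # kJ/mol
    conf_diffusion: float = 0.05  # fast regime; spread_replica uses slow
    n_replicas: int = 10
    duration: float = 2000.0  # ps per replica
    ph_step: float = 0.5
    ph_margin: float = 1.0
    seed: int = 0
    with_buffers: bool = True

    def ground_truth_pkas(self) -> list[float]:
        if self.tag == "single":
            return [self.pka]
        if self.tag == "tautomer":
            macro = -math.log10(10.0 ** -self.pka_micro_delta
                                + 10.0 ** -self.pka_micro_epsilon)
            return [macro, self.pka_micro_epsilon]
        if self.tag == "coupled_pair":
            return [self.pka, self.pka_second]
        if self.tag in ("conformation_coupled", "spread_replica"):
            return [self.pka, self.pka + self.delta_pka]
        raise ValueError(f"unknown scenario tag {self.tag!r}")


def ph_grid(pkas, step: float = 0.5, margin: float = 1.0) -> np.ndarray:
    """Titration pH grid: one unit beyond the extreme pKa values, 0.5 steps."""
    lo = round(min(pkas) - margin, 1)
    hi = round(max(pkas) + margin, 1)
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def replica_seed(global_seed: int, tag: str, ph: float, replica: int) -> int:
    """Stable per-replica seed derived from (seed, scenario, pH, replica)."""
    h = hashlib.sha256(f"{global_seed}|{tag}|{ph:.3f}|{replica}".encode())
    return int.from_bytes(h.digest()[:4], "little") % (2 ** 31)


@dataclass
class Scenario:
    """A calibrated system plus everything needed to titrate it."""

    spec: ScenarioSpec
    model: SystemModel
    vmm: dict  # coordinate key -> CalibrationPolynomial | None
    thermo: ThermoContext

    def bias_set(self, ph: float) -> dict:
        """One calibrated BiasPotential per lambda coordinate at ``ph``.

        The protonation coordinate of a tautomeric site is referenced to the
        delta-path microscopic pKa and carries a -kT ln 2 degeneracy offset
        (the protonated chemical state occupies both lambda_t wells); the
        tautomer coordinate has no pH ramp, its landscape asymmetry being
        physical (the energy gap between tautomers).
        """
        biases = {}
        for s in self.model.sites:
            pka_ref = s.pka_micro_delta if s.has_tautomer else s.pka_ref
            offset = -self.thermo.kt * math.log(2.0) if s.has_tautomer else 0.0
            biases[(s.site_id, "p")] = BiasPotential(
                dw=DoubleWellParams(), ph=PHPotentialParams(pH=ph, pka_ref=pka_ref),
                vmm=self.vmm.get((s.site_id, "p")), thermo=self.thermo,
                target_offset=offset)
            if s.has_tautomer:
                biases[(s.site_id, "t")] = BiasPotential(
                    dw=DoubleWellParams(), ph=None,
                    vmm=self.vmm.get((s.site_id, "t")), thermo=self.thermo)
        return biases

    def corrected_bias_set(self, ph: float) -> dict:
        """Bias set with the partition-function correction already applied.

        This is the stack the engine integrates after its pre-run
        correction; the Boltzmann oracle uses it so that oracle and
        simulation describe the same system.  For a tautomer coordinate the
        correction is state-dependent (the deprotonated state feels the
        tautomer energy gap): the protonated-state stack is stored under
        ``(site, "t")`` and the deprotonated-state one under
        ``(site, "t_deprot")``.
        """
        from .potentials import correct_well_depths

        biases = self.bias_set(ph)
        out = {}
        for (site_id, kind), b in biases.items():
            if kind == "t":
                site = self.model.site(site_id)
                gap = site.energy_deprot_epsilon - site.energy_deprot
                out[(site_id, "t")] = replace(
                    b, dw=correct_well_depths(b, target=0.0))
                out[(site_id, "t_deprot")] = replace(
                    b, dw=correct_well_depths(b, target=gap, tilt=gap))
            else:
                out[(site_id, kind)] = replace(b, dw=correct_well_depths(b))
        return out

    @property
    def ph_values(self) -> np.ndarray:
        return ph_grid(self.spec.ground_truth_pkas(), self.spec.ph_step,
                       self.spec.ph_margin)


def _isolated(site: SiteModel, thermo: ThermoContext,
              conf: list | None = None) -> SystemModel:
    return SystemModel(sites=[replace(site, buffer_id=None)], thermo=thermo,
                       conf_coords=list(conf or []))


def make_scenario(spec: ScenarioSpec,
                  thermo: ThermoContext | None = None,
                  calibration_samples: int = 10_000) -> Scenario:
    """Build and calibrate the system described by ``spec``."""
    thermo = thermo or ThermoContext()
    kt_ln10 = thermo.kt * LN10
    sites: list[SiteModel] = []
    buffers: list[BufferSite] = []
    coupling: dict = {}
    conf: list[ConformationalCoordinate] = []

    def add_site(site: SiteModel) -> None:
        if spec.with_buffers:
            site = replace(site, buffer_id=f"buf-{site.site_id}")
            buffers.append(BufferSite(buffer_id=site.buffer_id))
        sites.append(site)

    if spec.tag == "single":
        add_site(SiteModel(site_id="GLU1", pka_ref=spec.pka,
                           energy_deprot=RAW_DEPROT_ENERGY))
    elif spec.tag == "tautomer":
        gap = kt_ln10 * (spec.pka_micro_epsilon - spec.pka_micro_delta)
        add_site(SiteModel(
            site_id="HIS1", pka_ref=spec.pka_micro_delta, has_tautomer=True,
            pka_micro_delta=spec.pka_micro_delta,
            pka_micro_epsilon=spec.pka_micro_epsilon,
            energy_deprot=RAW_DEPROT_ENERGY,
            energy_deprot_epsilon=RAW_DEPROT_ENERGY + gap,
            charge_prot=1.0, charge_deprot=0.0))
    elif spec.tag == "coupled_pair":
        add_site(SiteModel(site_id="SITE1", pka_ref=spec.pka,
                           energy_deprot=RAW_DEPROT_ENERGY))
        add_site(SiteModel(site_id="SITE2", pka_ref=spec.pka_second,
                           energy_deprot=0.8 * RAW_DEPROT_ENERGY))
        if spec.coupling_w != 0.0:
            coupling[("SITE1", "SITE2")] = spec.coupling_w
    elif spec.tag in ("conformation_coupled", "spread_replica"):
        diffusion = spec.conf_diffusion if spec.tag == "conformation_coupled" \
            else spec.conf_diffusion / 50.0
        conf.append(ConformationalCoordinate(
            coord_id="CC1", barrier=spec.conf_barrier, diffusion=diffusion))
        add_site(SiteModel(site_id="SITE1", pka_ref=spec.pka,
                           energy_deprot=RAW_DEPROT_ENERGY,
                           conf_coupling={"CC1": (0.0, spec.delta_pka)}))
    else:
        raise ValueError(f"unknown scenario tag {spec.tag!r}")

    model = SystemModel(sites=sites, buffers=buffers, coupling=coupling,
                        conf_coords=conf, thermo=thermo)

    # thermodynamic-integration calibration per coordinate
    vmm = {}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCA11B]))
    for s in sites:
        iso = _isolated(s, thermo, conf)
        prof = ti_profile(iso, s.site_id, coord="p", rng=rng,
                          samples_per_window=calibration_samples)
        vmm[(s.site_id, "p")] = fit_vmm(prof, degree=5,
                                        max_residual=1.0 if s.conf_coupling
                                        else 0.1)
        if s.has_tautomer:
            prof_t = ti_profile(iso, s.site_id, coord="t", rng=rng,
                                samples_per_window=calibration_samples)
            vmm[(s.site_id, "t")] = fit_vmm(prof_t, degree=5)
    return Scenario(spec=spec, model=model, vmm=vmm, thermo=thermo)


# ---------------------------------------------------------------------------
# Titration protocol


@dataclass
class TitrationDataset:
    """All per-(pH, replica) counts of a titration, with trajectories."""

    scenario: Scenario
    points: dict  # site_id -> list[TitrationPoint]
    trajectories: list = field(default_factory=list)  # LambdaTrajectory

    def site_points(self, site_id: str) -> list:
        return self.points[site_id]


def run_titration(scenario: Scenario, ph_values=None,
                  n_replicas: int | None = None, duration: float | None = None,
                  config: IntegratorConfig | None = None,
                  dbo: DBOConfig | None = None,
                  keep_trajectories: bool = True) -> TitrationDataset:
    """Run the full titration protocol of a scenario.

    One independently seeded replica per (pH, replica) pair; equilibration,
    partition correction and (optionally) DBO are handled by the engine.
    """
    spec = scenario.spec
    if ph_values is None:
        ph_values = scenario.ph_values
    n_replicas = n_replicas or spec.n_replicas
    duration = duration or spec.duration
    config = config or IntegratorConfig()

    points: dict[str, list[TitrationPoint]] = {
        s.site_id: [] for s in scenario.model.sites}
    trajs: list[LambdaTrajectory] = []
    for ph in ph_values:
        for rep in range(n_replicas):
            seed = replica_seed(spec.seed, spec.tag, float(ph), rep)
            controller = DBOController(dbo) if dbo is not None else None
            eng = Engine(scenario.model, [scenario.bias_set(float(ph))],
                         replace(config, seed=seed), dbo=controller)
            traj = eng.run(duration)[0]
            traj.metadata["replica"] = rep
            traj.metadata["scenario"] = spec.tag
            traj.metadata["ground_truth"] = {
                "pkas": spec.ground_truth_pkas(),
                "coupling_w": spec.coupling_w,
                "delta_pka": spec.delta_pka,
            }
            for s in scenario.model.sites:
                points[s.site_id].append(
                    classify_and_count(traj, s.site_id, replica=rep,
                                       ph=float(ph)))
            if keep_trajectories:
                trajs.append(traj)
    return TitrationDataset(scenario=scenario, points=points,
                            trajectories=trajs)


# ---------------------------------------------------------------------------
# Master oracle


def direct_boltzmann_oracle(scenario: Scenario, ph: float,
                            n_lambda: int = 161, n_conf: int = 81,
                            max_points: int = 20_000_000) -> dict:
    """Exact equilibrium fractions by dense-grid Boltzmann quadrature.

    Integrates exp(-beta U) over *all* continuous coordinates (every lambda
    and every conformational coordinate) of the scenario's calibrated total
    potential at ``ph`` and classifies states exactly as the analysis does
    (deprotonated iff lambda_p >= 0.5; epsilon tautomer iff lambda_t >= 0.5).
    This is the reference the simulator is validated against; it is
    independent of the integrator and of the per-well partition bookkeeping.

    Returns per-site deprotonation probabilities, tautomer microstate
    probabilities, and (for pairs) the 2x2 joint state distribution.
    """
    model = scenario.model
    biases = scenario.corrected_bias_set(ph)
    thermo = scenario.thermo
    layout_keys = []
    axes = []
    for s in model.sites:
        dw = biases[(s.site_id, "p")].dw
        axes.append(np.linspace(dw.p0 - 0.3, dw.p1 + 0.3, n_lambda))
        layout_keys.append((s.site_id, "p"))
        if s.has_tautomer:
            dwt = biases[(s.site_id, "t")].dw
            axes.append(np.linspace(dwt.p0 - 0.3, dwt.p1 + 0.3, n_lambda))
            layout_keys.append((s.site_id, "t"))
    for c in model.conf_coords:
        axes.append(np.linspace(-0.5, 1.5, n_conf))
        layout_keys.append((c.coord_id, "c"))
    npts = int(np.prod([len(a) for a in axes]))
    if npts > max_points:
        raise ValueError(f"state space too large for direct quadrature "
                         f"({npts} grid points)")

    mesh = np.meshgrid(*axes, indexing="ij")
    cols = {k: m.ravel() for k, m in zip(layout_keys, mesh)}
    kt_ln10 = thermo.kt * LN10
    u = np.zeros(npts)
    for s in model.sites:
        lp = cols[(s.site_id, "p")]
        e_d = s.energy_deprot
        if s.conf_coupling:
            for cid, (s0, s1) in s.conf_coupling.items():
                shift = kt_ln10 * (s0 + (s1 - s0) * cols[(cid, "c")])
                u += (lp - 0.5) * shift
        if s.has_tautomer:
            lt = cols[(s.site_id, "t")]
            e_eps = s.energy_deprot_epsilon
            u += ((1.0 - lp) * s.energy_prot
                  + lp * ((1.0 - lt) * e_d + lt * e_eps))
            # state-selected tautomer bias, as integrated by the engine
            v_prot = biases[(s.site_id, "t")].value_grad(lt)[0]
            v_deprot = biases[(s.site_id, "t_deprot")].value_grad(lt)[0]
            u += np.where(lp < 0.5, v_prot, v_deprot)
        else:
            u += (1.0 - lp) * s.energy_prot + lp * e_d
        u += biases[(s.site_id, "p")].value_grad(lp)[0]
    ids = [s.site_id for s in model.sites]
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            w = model.coupling_w(ids[a], ids[b])
            if w != 0.0:
                u += w * cols[(ids[a], "p")] * cols[(ids[b], "p")]
    for c in model.conf_coords:
        cc = cols[(c.coord_id, "c")]
        u += 16.0 * c.barrier * cc * cc * (1.0 - cc) ** 2

    weight = np.exp(-thermo.beta * (u - u.min()))
    total = weight.sum()

    out: dict = {"ph": ph, "sites": {}}
    for s in model.sites:
        deprot = cols[(s.site_id, "p")] >= 0.5
        res = {"x_deprot": float(weight[deprot].sum() / total)}
        if s.has_tautomer:
            eps = cols[(s.site_id, "t")] >= 0.5
            p_prot = float(weight[~deprot].sum() / total)
            p_dd = float(weight[deprot & ~eps].sum() / total)
            p_de = float(weight[deprot & eps].sum() / total)
            res.update(p_prot=p_prot, p_deprot_delta=p_dd, p_deprot_epsilon=p_de,
                       x_micro_delta=p_dd / (p_prot + p_dd),
                       x_micro_epsilon=p_de / (p_prot + p_de))
        out["sites"][s.site_id] = res
    if len(ids) == 2:
        d1 = cols[(ids[0], "p")] >= 0.5
        d2 = cols[(ids[1], "p")] >= 0.5
        out["joint"] = {
            "A1H_A2H": float(weight[~d1 & ~d2].sum() / total),
            "A1H_A2d": float(weight[~d1 & d2].sum() / total),
            "A1d_A2H": float(weight[d1 & ~d2].sum() / total),
            "A1d_A2d": float(weight[d1 & d2].sum() / total),
        }
        out["mean_protons"] = float(
            2.0 * out["joint"]["A1H_A2H"]
            + out["joint"]["A1H_A2d"] + out["joint"]["A1d_A2H"])
    return out
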
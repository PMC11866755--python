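"""Velocity-Verlet integration, CSVR thermostat, and sampling correctness."""

import numpy as np
import pytest
from scipy import stats

from cphlab.dynamics import (Engine, IntegratorConfig, csvr_rescale_factor,
                             csvr_thermostat, kinetic_temperature,
                             velocity_verlet_step)
from cphlab.model import KB_KJ_PER_MOL_K
from cphlab.scenarios import direct_boltzmann_oracle
from cphlab.titration import classify_and_count

KT300 = KB_KJ_PER_MOL_K * 300.0


class TestVelocityVerlet:
    def test_free_particle_advances_linearly(self):
        x, v = np.array([0.0]), np.array([0.3])
        x, v = velocity_verlet_step(x, v, lambda x: np.zeros_like(x), 60.0, 0.002)
        assert x[0] == pytest.approx(0.3 * 0.002)
        assert v[0] == pytest.approx(0.3)

    def test_harmonic_energy_conservation_long_run(self):
        # closed-form oscillator: period 2*pi*sqrt(m/k) >> dt
        k, m, dt = 100.0, 60.0, 0.002
        force = lambda x: -k * x
        x, v = np.array([0.5]), np.array([0.0])
        e0 = 0.5 * k * x[0] ** 2 + 0.5 * m * v[0] ** 2
        drift = 0.0
        for _ in range(1_000_000):
            x, v = velocity_verlet_step(x, v, force, m, dt)
        e1 = 0.5 * k * x[0] ** 2 + 0.5 * m * v[0] ** 2
        assert abs(e1 - e0) / e0 < 1e-4

    def test_time_reversal_retraces_trajectory(self):
        k, m, dt = 50.0, 60.0, 0.002
        force = lambda x: -k * x
        x, v = np.array([0.4]), np.array([0.1])
        x0, v0 = x.copy(), v.copy()
        for _ in range(1000):
            x, v = velocity_verlet_step(x, v, force, m, dt)
        v = -v
        for _ in range(1000):
            x, v = velocity_verlet_step(x, v, force, m, dt)
        assert x[0] == pytest.approx(x0[0], abs=1e-10)
        assert v[0] == pytest.approx(-v0[0], abs=1e-10)

    def test_nonfinite_force_rejected(self):
        with pytest.raises(FloatingPointError):
            velocity_verlet_step(np.array([0.0]), np.array([0.0]),
                                 lambda x: np.array([np.nan]), 60.0, 0.002)


class TestCSVRThermostat:
    def test_infinite_tau_leaves_velocities_unchanged(self, rng):
        f = csvr_rescale_factor(10.0, 5, KT300, tau=1e12, dt=0.002, rng=rng)
        assert f == pytest.approx(1.0, abs=1e-6)

    def test_long_run_kinetic_temperature(self, rng):
        # 10 DOFs relaxed by repeated rescaling reach the 300 K canonical
        # mean; tau = 0.1 ps keeps the kinetic-energy autocorrelation (~
        # tau/dt steps) short enough for a tight mean estimate
        m = np.full(10, 60.0)
        v = rng.standard_normal(10) * np.sqrt(KT300 / 60.0) * 0.2  # cold start
        temps = []
        for step in range(200_000):
            v = csvr_thermostat(v, m, 300.0, tau=0.1, dt=0.002, rng=rng)
            if step > 20_000:
                temps.append(kinetic_temperature(v, m))
        assert np.mean(temps) == pytest.approx(300.0, rel=0.02)

    def test_kinetic_energy_distribution_is_canonical(self, rng):
        # KS test against Gamma(Nf/2, kT), the canonical KE distribution
        ndf = 10
        m = np.full(ndf, 60.0)
        v = rng.standard_normal(ndf) * np.sqrt(KT300 / 60.0)
        kes = []
        for step in range(60_000):
            v = csvr_thermostat(v, m, 300.0, tau=0.05, dt=0.002, rng=rng)
            if step % 300 == 0 and step > 3_000:  # decorrelate samples
                kes.append(0.5 * np.sum(m * v * v))
        d, p = stats.kstest(kes, stats.gamma(a=ndf / 2, scale=KT300).cdf)
        assert p > 0.01

    def test_requires_at_least_one_dof(self, rng):
        with pytest.raises(ValueError):
            csvr_rescale_factor(1.0, 0, KT300, 1.0, 0.002, rng)


@pytest.fixture(scope="module")
def long_single_run(single_scenario):
    eng = Engine(single_scenario.model, [single_scenario.bias_set(4.4)],
                 IntegratorConfig(seed=42))
    return eng.run(20_000.0)[0]


class TestSimulate:
    def test_fraction_at_reference_ph_is_half(self, long_single_run):
        pt = classify_and_count(long_single_run, "GLU1", ph=4.4)
        # ~500 transitions over 20 ns; allow 2 SE of the correlated series
        assert pt.x == pytest.approx(0.5, abs=0.04)

    def test_fraction_one_unit_above_pka(self, single_scenario):
        eng = Engine(single_scenario.model, [single_scenario.bias_set(5.4)],
                     IntegratorConfig(seed=43))
        traj = eng.run(8000.0)[0]
        pt = classify_and_count(traj, "GLU1", ph=5.4)
        assert pt.x == pytest.approx(10.0 / 11.0, abs=0.03)

    def test_fixed_seed_bit_identical(self, single_scenario):
        args = (single_scenario.model, [single_scenario.bias_set(4.4)])
        t1 = Engine(*args, IntegratorConfig(seed=5)).run(200.0)[0]
        t2 = Engine(*args, IntegratorConfig(seed=5)).run(200.0)[0]
        assert np.array_equal(t1.lam, t2.lam)
        assert np.array_equal(t1.vel, t2.vel)

    def test_lambda_histogram_matches_boltzmann_quadrature(
            self, single_scenario, long_single_run):
        # the central sampling-correctness oracle: chi^2 against exp(-beta V)
        biases = single_scenario.corrected_bias_set(4.4)
        b = biases[("GLU1", "p")]
        site = single_scenario.model.sites[0]
        # full landscape felt by lambda: bias stack + raw site energy
        def v_total(g):
            return b.value_grad(g)[0] + g * site.energy_deprot
        edges = np.linspace(-0.2, 1.2, 15)
        lam = long_single_run.lam[:, 0]
        counts, _ = np.histogram(lam, bins=edges)
        grid = np.linspace(-0.3, 1.3, 8001)
        w = np.exp(-single_scenario.thermo.beta * (v_total(grid) - v_total(grid).min()))
        probs = np.array([
            np.trapezoid(w[(grid >= lo) & (grid < hi)],
                         grid[(grid >= lo) & (grid < hi)])
            for lo, hi in zip(edges[:-1], edges[1:])])
        probs /= probs.sum()
        # thin frames to decorrelate before the chi^2 comparison
        thin = lam[::80]
        counts, _ = np.histogram(thin, bins=edges)
        keep = probs > 1e-4
        chi2 = np.sum((counts[keep] - len(thin) * probs[keep]) ** 2
                      / (len(thin) * probs[keep]))
        p = 1.0 - stats.chi2.cdf(chi2, df=keep.sum() - 1)
        assert p > 0.01

    def test_thermostat_tau_does_not_bias_fractions(self, single_scenario):
        xs = {}
        for tau in (0.1, 1.0):
            eng = Engine(single_scenario.model, [single_scenario.bias_set(4.4)],
                         IntegratorConfig(seed=17, thermostat_tau=tau))
            traj = eng.run(6000.0)[0]
            xs[tau] = classify_and_count(traj, "GLU1", ph=4.4).x
        # ~150 transitions each; 2 combined SE of the correlated estimate
        assert abs(xs[0.1] - xs[1.0]) < 0.06

    def test_transition_rate_decreases_with_barrier(self, single_scenario):
        from dataclasses import replace as drep
        rates = []
        for h in (2.0, 6.0, 12.0):
            biases = {
                k: drep(v, dw=drep(v.dw, barrier=h))
                for k, v in single_scenario.bias_set(4.4).items()}
            eng = Engine(single_scenario.model, [biases],
                         IntegratorConfig(seed=23))
            traj = eng.run(4000.0)[0]
            dep = traj.lam[:, 0] >= 0.5
            rates.append(np.sum(dep[1:] != dep[:-1]) / 4.0)  # per ns
        assert rates[0] > rates[1] > rates[2]

    def test_kernel_forces_match_reference_gradient(self, tautomer_scenario, rng):
        # regression: compiled kernel vs the readable python gradient
        from cphlab import _kernel
        from cphlab.dynamics import _CoordLayout
        from cphlab.model import LambdaState, total_potential

        scen = tautomer_scenario
        biases = scen.bias_set(6.4)
        eng = Engine(scen.model, [biases], IntegratorConfig(seed=1))
        lay = eng.layout
        lam = rng.uniform(0.0, 1.0, (1, lay.nc))
        conf = np.zeros((1, lay.ncc))
        f = np.zeros((1, lay.nc))
        fc = np.zeros((1, max(lay.ncc, 1)))[:, :lay.ncc]
        _kernel._forces(lam, conf, f, lay.delta_e, lay.gap, lay.tpartner,
                        lay.tchild, lay.w, eng.vmm, eng.slope, eng.p0, eng.p1,
                        eng.h["prot"], eng.h["deprot"], eng.d["prot"],
                        eng.d["deprot"], eng.wall_off, eng.wall_k, lay.cs,
                        fc, lay.conf_h)
        st = LambdaState(lambda_p=lam[0, :1].copy(),
                         lambda_t=np.array([lam[0, 1]]),
                         conf=np.zeros(0))
        e, g = total_potential(scen.model, st, biases)
        assert -f[0, 0] == pytest.approx(g["lambda_p"][0], rel=1e-10, abs=1e-10)
        assert -f[0, 1] == pytest.approx(g["lambda_t"][0], rel=1e-10, abs=1e-10)

    def test_divergent_lambda_aborts_with_diagnostic(self):
        from cphlab.model import SiteModel, SystemModel
        from cphlab.potentials import BiasPotential, DoubleWellParams

        # a 300 kJ/mol tilt with the walls removed overwhelms the residual
        # polynomial confinement and drives lambda far out of range
        model = SystemModel(sites=[SiteModel(site_id="X", pka_ref=4.4,
                                             energy_deprot=300.0)])
        biases = {("X", "p"): BiasPotential(
            dw=DoubleWellParams(wall_stiffness=0.0, barrier=0.1),
            thermo=model.thermo)}
        eng = Engine(model, [biases],
                     IntegratorConfig(seed=3, equilibration=0.0,
                                      thermostat=False))
        eng.apply_partition_correction = lambda pairs=None: None
        with pytest.raises(RuntimeError, match="divergent"):
            eng.run(2000.0)

    def test_save_interval_must_divide_dt(self):
        with pytest.raises(ValueError):
            IntegratorConfig(dt=0.002, save_interval=0.003)


class TestOracleAgreement:
    def test_simulated_fractions_match_oracle_across_ph(self, single_scenario):
        for ph, seed in ((3.9, 31), (4.9, 33)):
            o = direct_boltzmann_oracle(single_scenario, ph)
            eng = Engine(single_scenario.model, [single_scenario.bias_set(ph)],
                         IntegratorConfig(seed=seed))
            traj = eng.run(6000.0)[0]
            x = classify_and_count(traj, "GLU1", ph=ph).x
            assert x == pytest.approx(o["sites"]["GLU1"]["x_deprot"], abs=0.05)
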
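"""NMI coupling screen, microstate statistics, two-proton macroscopic fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cphlab.coupling import (coupling_screen, entropy, fit_macro_two_site,
                             macro_two_site_curve, microstates_and_coupling_dg,
                             nmi)
from cphlab.model import ThermoContext

TH = ThermoContext()


class TestEntropy:
    def test_constant_series_is_zero(self):
        assert entropy(np.zeros(100)) == 0.0

    def test_balanced_binary_is_ln2(self):
        s = np.array([0, 1] * 500)
        assert entropy(s) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_nine_to_one_split(self):
        s = np.array([0] * 90 + [1] * 10)
        assert entropy(s) == pytest.approx(0.3251, abs=1e-4)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([]))


class TestNMI:
    def test_identical_series(self, rng):
        x = rng.random(1000) < 0.5
        assert nmi(x, x) == pytest.approx(1.0)

    def test_anti_identical_series(self, rng):
        x = rng.random(1000) < 0.5
        assert nmi(x, ~x) == pytest.approx(1.0)

    def test_independent_simulated_pair_is_small(self, pair_scenario_uncoupled):
        # 1e5 frames from two genuinely uncoupled simulated sites
        from cphlab.dynamics import Engine, IntegratorConfig
        scen = pair_scenario_uncoupled
        eng = Engine(scen.model, [scen.bias_set(4.2)],
                     IntegratorConfig(seed=77))
        traj = eng.run(50_000.0)[0]
        x = traj.column("SITE1:p") >= 0.5
        y = traj.column("SITE2:p") >= 0.5
        observed = nmi(x, y)
        assert observed < 0.01
        # shuffling oracle: the finite-sample MI bias floor
        rng = np.random.default_rng(0)
        ys = y.copy()
        rng.shuffle(ys)
        assert abs(observed - nmi(x, ys)) < 0.01

    def test_symmetry_exact(self, rng):
        x = rng.random(500) < 0.3
        y = rng.random(500) < 0.6
        assert nmi(x, y) == nmi(y, x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi(np.zeros(5), np.zeros(6))

    def test_zero_entropy_pair_defined_as_zero(self):
        assert nmi(np.zeros(10), np.zeros(10)) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=2, max_size=60),
           st.lists(st.booleans(), min_size=2, max_size=60))
    def test_bounds_property(self, xs, ys):
        n = min(len(xs), len(ys))
        v = nmi(np.array(xs[:n]), np.array(ys[:n]))
        assert -1e-12 <= v <= 1.0 + 1e-12


class TestCouplingScreen:
    def _series(self, fn, n_rep=3, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        out: dict = {"A": {}, "B": {}}
        for ph in (4.0, 5.0):
            for r in range(n_rep):
                a, b = fn(rng, n)
                out["A"][(ph, r)] = a
                out["B"][(ph, r)] = b
        return out

    def test_uncoupled_pair_not_flagged(self):
        series = self._series(lambda rng, n: (rng.random(n) < 0.5,
                                              rng.random(n) < 0.5))
        stats = coupling_screen(series)
        assert len(stats) == 1 and not stats[0].coupled

    def test_anticorrelated_pair_flagged(self):
        def fn(rng, n):
            a = rng.random(n) < 0.5
            flip = rng.random(n) < 0.05
            return a, ~a ^ flip
        stats = coupling_screen(self._series(fn))
        assert stats[0].coupled

    def test_entropy_gate_suppresses_rare_frame_coincidence(self):
        # both sites almost always protonated; their few deprotonated frames
        # coincide, which drives raw NMI up but not the entropy gate
        def fn(rng, n):
            rare = rng.random(n) < 0.002
            return rare.copy(), rare.copy()
        series = self._series(fn)
        stats = coupling_screen(series)
        assert stats[0].per_ph["mean_nmi"].max() > 0.5  # raw NMI spurious
        assert not stats[0].coupled  # gate catches it

    def test_simulated_anticooperative_pair_flagged(
            self, pair_scenario_anticooperative):
        from cphlab.dynamics import Engine, IntegratorConfig
        scen = pair_scenario_anticooperative
        series: dict = {"SITE1": {}, "SITE2": {}}
        # near the joint midpoint the coupling correlates the two sites
        for r, seed in enumerate((31, 32)):
            eng = Engine(scen.model, [scen.bias_set(4.8)],
                         IntegratorConfig(seed=seed))
            traj = eng.run(4000.0)[0]
            series["SITE1"][(4.8, r)] = traj.column("SITE1:p") >= 0.5
            series["SITE2"][(4.8, r)] = traj.column("SITE2:p") >= 0.5
        stats = coupling_screen(series)
        assert stats[0].coupled


class TestMicrostates:
    def test_fractions_sum_to_one(self, rng):
        x = rng.random(5000) < 0.4
        y = rng.random(5000) < 0.7
        tab = microstates_and_coupling_dg(x, y, TH)
        assert sum(tab.fractions.values()) == pytest.approx(1.0)

    def test_independent_series_have_zero_coupling_dg(self, rng):
        x = rng.random(200_000) < 0.5
        y = rng.random(200_000) < 0.5
        tab = microstates_and_coupling_dg(x, y, TH)
        for dg in tab.coupling_dg.values():
            assert abs(dg) < 0.05

    def test_zero_marginal_reported_missing(self):
        x = np.zeros(100, dtype=bool)
        y = np.tile([True, False], 50)
        tab = microstates_and_coupling_dg(x, y, TH)
        assert np.isnan(tab.coupling_dg["A1d_A2d"])

    def test_windowing(self, rng):
        x = rng.random(9000) < 0.5
        y = rng.random(9000) < 0.5
        tab = microstates_and_coupling_dg(x, y, TH, window_frames=3000)
        assert len(tab.windowed) == 3
        assert tab.window == pytest.approx(1500.0)

    def test_anticooperative_depletes_joint_deprotonation(
            self, pair_scenario_anticooperative, pair_scenario_uncoupled):
        from cphlab.scenarios import direct_boltzmann_oracle
        o_w = direct_boltzmann_oracle(pair_scenario_anticooperative, 4.8)
        o_0 = direct_boltzmann_oracle(pair_scenario_uncoupled, 4.8)
        j_w, j_0 = o_w["joint"], o_0["joint"]
        # with W > 0 the doubly-deprotonated state is depleted relative to
        # the product of marginals; with W = 0 it is not
        def excess(j):
            p1 = j["A1d_A2H"] + j["A1d_A2d"]
            p2 = j["A1H_A2d"] + j["A1d_A2d"]
            return j["A1d_A2d"] / (p1 * p2)
        assert excess(j_w) < 0.8
        assert excess(j_0) == pytest.approx(1.0, abs=0.02)


class TestMacroTwoSite:
    def test_saturation_limits(self):
        assert macro_two_site_curve(-10.0, 2.7, 6.3) == pytest.approx(2.0, abs=1e-3)
        assert macro_two_site_curve(20.0, 2.7, 6.3) == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_recovery(self):
        ph = np.arange(1.0, 8.5, 0.25)
        xx = macro_two_site_curve(ph, 2.7, 6.3)
        fit = fit_macro_two_site(ph, xx)
        assert fit.pka_macro_1 == pytest.approx(2.7, abs=1e-6)
        assert fit.pka_macro_2 == pytest.approx(6.3, abs=1e-6)

    def test_macro_model_beats_per_site_hh_for_strong_coupling(
            self, pair_scenario_anticooperative):
        # per-site H-H fits compose into an independent prediction of <X>;
        # for a strongly coupled pair the macroscopic binding polynomial
        # must fit the mean-protons curve better than that composition
        from cphlab.scenarios import direct_boltzmann_oracle, ph_grid
        from cphlab.titration import TitrationPoint, fit_hh, hh_curve

        phs = ph_grid([4.0, 4.4], margin=2.0)
        oracles = [direct_boltzmann_oracle(pair_scenario_anticooperative,
                                           float(p)) for p in phs]
        xx = np.array([o["mean_protons"] for o in oracles])
        fit = fit_macro_two_site(phs, xx)

        site_pkas = []
        for site in ("SITE1", "SITE2"):
            pts = [TitrationPoint(ph=float(p), replica=0, n_total=100_000,
                                  n_deprot=int(round(
                                      1e5 * o["sites"][site]["x_deprot"])))
                   for p, o in zip(phs, oracles)]
            site_pkas.append(fit_hh(pts).pka)
        indep = sum(1.0 - hh_curve(phs, pk) for pk in site_pkas)
        resid_indep = np.sqrt(np.mean((xx - indep) ** 2))
        assert fit.residual_rms < 0.5 * resid_indep

    def test_bootstrap_ci(self, rng):
        ph = np.repeat(np.arange(2.0, 8.0, 0.5), 4)
        xx = macro_two_site_curve(ph, 3.0, 6.0) + rng.normal(0, 0.02, ph.size)
        reps = np.tile(np.arange(4), 12)
        fit = fit_macro_two_site(ph, xx, replicas=reps, n_boot=200, rng=rng)
        assert fit.ci_1[0] <= 3.0 <= fit.ci_1[1] or abs(fit.pka_macro_1 - 3.0) < 0.1
        assert fit.n_boot == 200

    def test_too_few_ph_values_rejected(self):
        with pytest.raises(ValueError):
            fit_macro_two_site([1.0, 2.0, 3.0, 4.0],
                               [2.0, 1.5, 1.0, 0.5])
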
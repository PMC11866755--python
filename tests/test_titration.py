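"""Titration-curve fitting: H-H, Hill, microscopic pKa, bootstrap."""

import numpy as np
import pytest

from cphlab.dynamics import LambdaTrajectory
from cphlab.titration import (TitrationPoint, bootstrap_ci,
                              classify_and_count, combine_micro_to_macro,
                              fit_hh, fit_hill, fit_micro_pka, hh_curve,
                              hill_curve, replica_spread, titration_table)


def traj_from_series(lam, censored=None, coord_ids=("A:p",)):
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    if lam.shape[0] == 1 and len(coord_ids) == 1:
        lam = lam.T
    n = lam.shape[0]
    return LambdaTrajectory(
        times=0.5 * np.arange(1, n + 1), lam=lam, coord_ids=list(coord_ids),
        censored=np.zeros(n, dtype=bool) if censored is None else censored)


def hh_points(pka=4.4, phs=(3.4, 3.9, 4.4, 4.9, 5.4), reps=1, jitter=None,
              rng=None):
    pts = []
    for ph in phs:
        for r in range(reps):
            x = 1.0 / (1.0 + 10.0 ** (pka - ph))
            if jitter:
                x = float(np.clip(x + rng.normal(0, jitter), 1e-4, 1 - 1e-4))
            n = 10_000
            pts.append(TitrationPoint(ph=ph, replica=r, n_total=n,
                                      n_deprot=int(round(x * n))))
    return pts


class TestClassification:
    def test_threshold_counting(self):
        traj = traj_from_series([0.1, 0.9, 0.6, 0.4])
        pt = classify_and_count(traj, "A", ph=4.4)
        assert pt.x == 0.5
        assert pt.n_total == 4

    def test_all_censored_rejected(self):
        traj = traj_from_series([0.1, 0.9], censored=np.array([True, True]))
        with pytest.raises(ValueError, match="censored"):
            classify_and_count(traj, "A", ph=4.4)

    def test_censored_frames_excluded(self):
        traj = traj_from_series([0.9, 0.9, 0.1, 0.1],
                                censored=np.array([False, True, False, False]))
        pt = classify_and_count(traj, "A", ph=4.4)
        assert pt.n_total == 3
        assert pt.n_deprot == 1

    def test_tautomer_counts_partition_total(self):
        lam = np.array([[0.1, 0.2], [0.9, 0.1], [0.8, 0.9], [0.4, 0.9],
                        [0.6, 0.3]])
        traj = traj_from_series(lam, coord_ids=["H:p", "H:t"])
        pt = classify_and_count(traj, "H", ph=6.4)
        assert pt.n_prot + pt.n_deprot_delta + pt.n_deprot_epsilon == pt.n_total
        assert pt.n_deprot_delta == 2  # frames 2 and 5
        assert pt.n_deprot_epsilon == 1  # frame 3


class TestHendersonHasselbalch:
    def test_noiseless_recovery(self):
        fit = fit_hh(hh_points(pka=4.4))
        assert fit.pka == pytest.approx(4.4, abs=1e-6)

    def test_midpoint_is_half(self):
        assert hh_curve(4.4, 4.4) == pytest.approx(0.5)

    def test_too_few_ph_values_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_hh(hh_points(phs=(4.0, 5.0)))

    def test_degenerate_data_rejected(self):
        pts = [TitrationPoint(ph=p, replica=0, n_total=100, n_deprot=0)
               for p in (3.0, 4.0, 5.0)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_hh(pts)


class TestHill:
    def test_nesting_with_unit_coefficient(self):
        ph = np.linspace(3, 6, 13)
        assert np.allclose(hill_curve(ph, 4.4, 1.0), hh_curve(ph, 4.4))

    def test_noiseless_hill_recovery(self):
        pts = []
        for ph in np.arange(3.0, 6.1, 0.5):
            x = 1.0 / (1.0 + 10.0 ** (0.8 * (4.4 - ph)))
            pts.append(TitrationPoint(ph=float(ph), replica=0, n_total=10_000,
                                      n_deprot=int(round(x * 10_000))))
        fit = fit_hill(pts)
        assert fit.pka == pytest.approx(4.4, abs=1e-3)
        assert fit.hill_n == pytest.approx(0.8, abs=1e-2)

    def test_anticooperative_pair_has_hill_below_one(
            self, pair_scenario_anticooperative):
        # two-site Boltzmann oracle generates the titration curve
        from cphlab.scenarios import direct_boltzmann_oracle, ph_grid
        pts = []
        for ph in ph_grid([4.0, 4.4], margin=1.5):
            o = direct_boltzmann_oracle(pair_scenario_anticooperative, float(ph))
            x = o["sites"]["SITE1"]["x_deprot"]
            pts.append(TitrationPoint(ph=float(ph), replica=0, n_total=10_000,
                                      n_deprot=int(round(x * 10_000))))
        fit = fit_hill(pts)
        assert fit.hill_n < 0.95


class TestMicroscopic:
    def test_macro_from_micro_reference_values(self):
        assert round(combine_micro_to_macro(6.53, 6.92), 2) == 6.38

    def test_single_path_limit(self):
        assert combine_micro_to_macro(5.0, np.inf) == pytest.approx(5.0)

    def test_equal_micro_values_shift_by_log2(self):
        assert combine_micro_to_macro(6.0, 6.0) == pytest.approx(
            6.0 - np.log10(2.0))

    def test_micro_fit_recovers_generating_values(self):
        pkd, pke = 6.53, 6.92
        pts = []
        for ph in np.arange(5.4, 8.0, 0.5):
            # exact three-state populations
            kd = 10.0 ** (ph - pkd)
            ke = 10.0 ** (ph - pke)
            z = 1.0 + kd + ke
            n = 100_000
            npro = int(round(n / z))
            ndd = int(round(n * kd / z))
            pts.append(TitrationPoint(
                ph=float(ph), replica=0, n_total=n,
                n_deprot=n - npro, n_prot=npro, n_deprot_delta=ndd,
                n_deprot_epsilon=n - npro - ndd))
        fd, fe = fit_micro_pka(pts)
        assert fd.pka == pytest.approx(pkd, abs=2e-3)
        assert fe.pka == pytest.approx(pke, abs=2e-3)
        macro = fit_hh(pts)
        assert combine_micro_to_macro(fd.pka, fe.pka) == pytest.approx(
            macro.pka, abs=5e-3)

    def test_missing_tautomer_counts_rejected(self):
        with pytest.raises(ValueError, match="tautomer"):
            fit_micro_pka(hh_points())


class TestBootstrap:
    def test_zero_variance_gives_zero_width(self):
        pts = hh_points(reps=3)
        fit = bootstrap_ci(pts, fit_hh, n_boot=200,
                           rng=np.random.default_rng(0))
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-9)
        assert fit.ci_covers(4.4)

    def test_fixed_seed_reproducible(self, rng):
        pts = hh_points(reps=4, jitter=0.03, rng=np.random.default_rng(9))
        f1 = bootstrap_ci(pts, fit_hh, n_boot=300, rng=np.random.default_rng(5))
        f2 = bootstrap_ci(pts, fit_hh, n_boot=300, rng=np.random.default_rng(5))
        assert (f1.ci_low, f1.ci_high) == (f2.ci_low, f2.ci_high)

    def test_width_shrinks_with_replica_count(self):
        # Monte-Carlo scaling: ~1/sqrt(R)
        widths = {}
        for reps in (4, 16):
            pts = hh_points(reps=reps, jitter=0.05,
                            rng=np.random.default_rng(11))
            fit = bootstrap_ci(pts, fit_hh, n_boot=400,
                               rng=np.random.default_rng(3))
            widths[reps] = fit.ci_high - fit.ci_low
        ratio = widths[4] / widths[16]
        assert 1.3 < ratio < 3.2  # expect ~2

    def test_single_replica_rejected(self):
        with pytest.raises(ValueError, match="2 replicas"):
            bootstrap_ci(hh_points(reps=1), fit_hh, n_boot=10)


class TestTables:
    def test_table_and_spread(self):
        pts = hh_points(reps=3, jitter=0.02, rng=np.random.default_rng(2))
        df = titration_table(pts)
        assert set(df.columns) >= {"pH", "replica", "x"}
        spread = replica_spread(pts)
        assert (spread["n_replicas"] == 3).all()
        assert (spread["x_sd"] >= 0).all()
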
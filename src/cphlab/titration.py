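"""From lambda trajectories to titration curves, pKa values and CIs.

Frames are classified at the lambda_p = 0.5 threshold (deprotonated iff
lambda_p >= 0.5, consistent with lambda = 1 being the fully deprotonated end
state); intermediate frames are *included*, which the partition-function
correction makes statistically sound.  Censored frames are always excluded.

Fits are performed on per-replica deprotonation fractions -- each (pH,
replica) pair contributes one data point -- matching the unit of the
bootstrap: resampling replicas with replacement at every pH, refitting, and
reporting percentile confidence intervals at 5% significance (5000 resamples
by default).

The deprotonation fraction increases with pH (acid convention):
x(pH) = 1 / (1 + 10^(pKa - pH)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TitrationPoint",
    "FitResult",
    "classify_frames",
    "classify_and_count",
    "titration_table",
    "fit_hh",
    "fit_hill",
    "fit_micro_pka",
    "combine_micro_to_macro",
    "bootstrap_ci",
    "replica_spread",
    "hh_curve",
    "hill_curve",
]


@dataclass(frozen=True)
class TitrationPoint:
    """Deprotonation counts for one (pH, replica) trajectory."""

    ph: float
    replica: int
    n_total: int
    n_deprot: int
    # tautomeric sites: protonated / deprotonated-delta / deprotonated-epsilon
    n_prot: int | None = None
    n_deprot_delta: int | None = None
    n_deprot_epsilon: int | None = None

    @property
    def x(self) -> float:
        """Deprotonation fraction N_deprot / N_total."""
        return self.n_deprot / self.n_total

    @property
    def x_micro_delta(self) -> float:
        return self.n_deprot_delta / (self.n_prot + self.n_deprot_delta)

    @property
    def x_micro_epsilon(self) -> float:
        return self.n_deprot_epsilon / (self.n_prot + self.n_deprot_epsilon)


@dataclass
class FitResult:
    """A fitted titration model with bootstrap confidence interval."""

    pka: float
    model: str  # "HH" | "Hill" | "micro-delta" | "micro-epsilon" | "macro2"
    hill_n: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    hill_n_ci: tuple | None = None
    n_boot: int = 0
    n_failures: int = 0
    extra: dict = field(default_factory=dict)

    def ci_covers(self, value: float) -> bool:
        return self.ci_low is not None and self.ci_low <= value <= self.ci_high


def hh_curve(ph, pka):
    """Henderson-Hasselbalch deprotonation fraction."""
    return 1.0 / (1.0 + 10.0 ** (pka - np.asarray(ph, dtype=float)))


def hill_curve(ph, pka, n):
    """Hill-model deprotonation fraction; reduces to H-H at n = 1."""
    return 1.0 / (1.0 + 10.0 ** (n * (pka - np.asarray(ph, dtype=float))))


# ---------------------------------------------------------------------------
# Classification


def classify_frames(trajectory, site_id: str, threshold: float = 0.5):
    """Binary deprotonation series (and tautomer series) of one site.

    Returns (deprot, taut_eps) boolean arrays over non-censored frames;
    ``taut_eps`` is None for non-tautomeric sites (tautomer epsilon iff
    lambda_t >= 0.5).
    """
    keep = ~trajectory.censored
    if not np.any(keep):
        raise ValueError("all frames censored: nothing to classify")
    lp = trajectory.column(f"{site_id}:p")[keep]
    deprot = lp >= threshold
    taut = None
    if f"{site_id}:t" in trajectory.coord_ids:
        taut = trajectory.column(f"{site_id}:t")[keep] >= threshold
    return deprot, taut


def classify_and_count(trajectory, site_id: str, replica: int | None = None,
                       ph: float | None = None) -> TitrationPoint:
    """Count deprotonated (and tautomer) frames of one trajectory.

    Intermediate frames are included (classified at the 0.5 threshold);
    censored frames are excluded.  For tautomeric sites the three counts
    N_prot, N_deprot_delta, N_deprot_epsilon partition N_total exactly.
    """
    deprot, taut = classify_frames(trajectory, site_id)
    meta = trajectory.metadata
    if ph is None:
        ph = meta.get("pH")
    if replica is None:
        replica = meta.get("replica", 0)
    n = int(deprot.size)
    nd = int(np.sum(deprot))
    if taut is None:
        return TitrationPoint(ph=ph, replica=replica, n_total=n, n_deprot=nd)
    n_dd = int(np.sum(deprot & ~taut))
    n_de = int(np.sum(deprot & taut))
    return TitrationPoint(ph=ph, replica=replica, n_total=n, n_deprot=nd,
                          n_prot=n - nd, n_deprot_delta=n_dd, n_deprot_epsilon=n_de)


def titration_table(points: list[TitrationPoint]) -> pd.DataFrame:
    """Tidy per-(pH, replica) table of deprotonation fractions."""
    rows = []
    for p in points:
        row = {"pH": p.ph, "replica": p.replica, "x": p.x,
               "n_total": p.n_total, "n_deprot": p.n_deprot}
        if p.n_prot is not None:
            row.update(x_micro_delta=p.x_micro_delta,
                       x_micro_epsilon=p.x_micro_epsilon)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["pH", "replica"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fits


def _check_points(ph, x):
    ph = np.asarray(ph, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(ph)) < 3:
        raise ValueError("need at least 3 distinct pH values")
    if np.all(x <= 0.0) or np.all(x >= 1.0):
        raise ValueError("degenerate titration data (all fractions 0 or 1)")
    return ph, x


def _pka_init(ph, x) -> float:
    """pH at which the mean fraction crosses 0.5 (linear interpolation)."""
    df = pd.DataFrame({"ph": ph, "x": x}).groupby("ph")["x"].mean()
    phs, xs = df.index.to_numpy(), df.to_numpy()
    above = xs >= 0.5
    if above.all() or not above.any():
        return float(phs[np.argmin(np.abs(xs - 0.5))])
    k = int(np.argmax(above))
    if k == 0:
        return float(phs[0])
    x0, x1 = xs[k - 1], xs[k]
    return float(phs[k - 1] + (0.5 - x0) / (x1 - x0) * (phs[k] - phs[k - 1]))


def _fit_xy(ph, x, model: str) -> FitResult:
    ph, x = _check_points(ph, x)
    p0 = _pka_init(ph, x)
    if model == "Hill":
        popt, _ = curve_fit(hill_curve, ph, x, p0=[p0, 1.0], maxfev=10_000)
        return FitResult(pka=float(popt[0]), hill_n=float(popt[1]), model="Hill")
    popt, _ = curve_fit(hh_curve, ph, x, p0=[p0], maxfev=10_000)
    return FitResult(pka=float(popt[0]), model=model)


def fit_hh(points: list[TitrationPoint]) -> FitResult:
    """Henderson-Hasselbalch fit of per-replica deprotonation fractions."""
    return _fit_xy([p.ph for p in points], [p.x for p in points], "HH")


def fit_hill(points: list[TitrationPoint]) -> FitResult:
    """Hill fit: x = 1/(1 + 10^(n (pKa - pH))); n < 1 is anticooperative."""
    return _fit_xy([p.ph for p in points], [p.x for p in points], "Hill")


def fit_micro_pka(points: list[TitrationPoint]) -> tuple[FitResult, FitResult]:
    """H-H fits of the two microscopic tautomer fractions.

    x_micro_delta = N_deprot_delta / (N_prot + N_deprot_delta), and the
    epsilon analogue; requires tautomer counts on every point.
    """
    if any(p.n_prot is None for p in points):
        raise ValueError("tautomer counts missing: not a tautomeric site?")
    ph = [p.ph for p in points]
    fd = _fit_xy(ph, [p.x_micro_delta for p in points], "micro-delta")
    fe = _fit_xy(ph, [p.x_micro_epsilon for p in points], "micro-epsilon")
    return fd, fe


def combine_micro_to_macro(pka_delta: float, pka_epsilon: float) -> float:
    """Macroscopic pKa from two microscopic tautomer pKa values.

    The macroscopic acid constant is the sum over the two deprotonation
    paths: pKa_macro = -log10(10^-pKa_delta + 10^-pKa_epsilon).
    """
    return float(-np.log10(10.0 ** (-pka_delta) + 10.0 ** (-pka_epsilon)))


# ---------------------------------------------------------------------------
# Bootstrap


_FIT_XS = {
    "HH": ("x", fit_hh),
    "Hill": ("x", fit_hill),
    "micro-delta": ("x_micro_delta", None),
    "micro-epsilon": ("x_micro_epsilon", None),
}


def bootstrap_ci(points: list[TitrationPoint], fit_fn=fit_hh,
                 n_boot: int = 5000, alpha: float = 0.05,
                 rng: np.random.Generator | None = None,
                 model: str | None = None) -> FitResult:
    """Percentile bootstrap CI by resampling replicas within each pH point.

    For each pH the R replica fractions are resampled with replacement and
    the curve refit; repeated ``n_boot`` times.  Fit failures are counted and
    more than 10% of them raise an error.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    by_ph: dict[float, list[TitrationPoint]] = {}
    for p in points:
        by_ph.setdefault(p.ph, []).append(p)
    if any(len(v) < 2 for v in by_ph.values()):
        raise ValueError("bootstrap needs >= 2 replicas per pH point")

    base = fit_fn(points)
    model = model or base.model
    attr = _FIT_XS.get(model, ("x", None))[0]

    phs = sorted(by_ph)
    xcols = {ph: np.array([getattr(p, attr) for p in by_ph[ph]]) for ph in phs}
    ph_arr = np.concatenate([[ph] * len(xcols[ph]) for ph in phs])

    pkas = np.empty(n_boot)
    hills = np.empty(n_boot) if base.hill_n is not None else None
    failures = 0
    kept = 0
    for b in range(n_boot):
        xs = np.concatenate([
            xcols[ph][rng.integers(0, len(xcols[ph]), len(xcols[ph]))]
            for ph in phs
        ])
        try:
            res = _fit_xy(ph_arr, xs, "Hill" if base.hill_n is not None else model)
        except (RuntimeError, ValueError):
            failures += 1
            continue
        pkas[kept] = res.pka
        if hills is not None:
            hills[kept] = res.hill_n
        kept += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"bootstrap fit failure rate too high: "
                           f"{failures}/{n_boot}")
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    lo, hi = np.percentile(pkas[:kept], qs)
    out = FitResult(pka=base.pka, model=model, hill_n=base.hill_n,
                    ci_low=float(lo), ci_high=float(hi),
                    n_boot=n_boot, n_failures=failures)
    if hills is not None:
        nlo, nhi = np.percentile(hills[:kept], qs)
        out.hill_n_ci = (float(nlo), float(nhi))
    return out


def replica_spread(points: list[TitrationPoint]) -> pd.DataFrame:
    """Inter-replica SD of the deprotonation fraction at each pH.

    A large spread at fixed pH (spread-replica titration) diagnoses slow
    coupled dynamics and incomplete convergence.
    """
    df = titration_table(points)
    g = df.groupby("pH")["x"]
    return pd.DataFrame({"x_mean": g.mean(), "x_sd": g.std(ddof=1),
                         "n_replicas": g.size()}).reset_index()
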
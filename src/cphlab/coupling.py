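"""Residue-residue protonation coupling analysis.

Coupled titratable site pairs are screened with Normalized Mutual
Information, NMI = 2 I(X;Y) / (H(X) + H(Y)), computed on the binary
(de)protonation series of each replica.  NMI is symmetric, model-free, lies
in [0, 1], and does not distinguish cooperativity from anticooperativity.
Because NMI can be spuriously high when both series have very low (but
nonzero) entropy, a pair is flagged as coupled only if *both* the mean NMI
and the mean marginal entropy across replicas exceed 0.1 at some pH point.

For a flagged pair the joint protonation microstates (A1H^A2H, A1H^A2-,
A1-^A2H, A1-^A2-) are tabulated -- overall and in sliding windows, whose
inter-replica scatter diagnoses convergence -- together with the coupling
free energy dG = -kT ln[P(A1^A2) / (P(A1) P(A2))] of each observed joint
state (zero under independence; positive when the joint state is depleted
relative to independence).  Finally the two-proton macroscopic titration
model

    <X>(pH) = (10^(pKa1-pH) + 2*10^(pKa1+pKa2-2 pH))
              / (1 + 10^(pKa1-pH) + 10^(pKa1+pKa2-2 pH))

is fitted to the mean number of protons bound, yielding the two macroscopic
pKa values (the inflection points of the curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import ThermoContext
from .titration import _pka_init

__all__ = [
    "entropy",
    "nmi",
    "CouplingStats",
    "coupling_screen",
    "MicrostateTable",
    "microstates_and_coupling_dg",
    "MacroTitrationFit",
    "macro_two_site_curve",
    "fit_macro_two_site",
]

#: Empirical screening threshold on both mean NMI and mean entropy.
COUPLING_THRESHOLD = 0.1


def entropy(series) -> float:
    """Information-theoretic entropy of a discrete series, in nats."""
    s = np.asarray(series)
    if s.size == 0:
        raise ValueError("empty series")
    _, counts = np.unique(s, return_counts=True)
    p = counts / s.size
    return float(-np.sum(p * np.log(p)))


def nmi(x, y) -> float:
    """Normalized mutual information of two aligned binary series.

    2 I(X;Y) / (H(X) + H(Y)) from the empirical 2x2 joint distribution;
    defined as 0 when both marginal entropies vanish.  Equals 1 for
    identical series and for Y = 1 - X (bijections).
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    n = x.size
    hx = entropy(x)
    hy = entropy(y)
    if hx + hy == 0.0:
        return 0.0
    mi = 0.0
    for xv in (False, True):
        px = np.mean(x == xv)
        if px == 0:
            continue
        for yv in (False, True):
            pxy = np.sum((x == xv) & (y == yv)) / n
            py = np.mean(y == yv)
            if pxy > 0:
                mi += pxy * np.log(pxy / (px * py))
    return float(2.0 * mi / (hx + hy))


@dataclass
class CouplingStats:
    """Per-pair NMI screening summary across replicas and pH points."""

    site_x: str
    site_y: str
    per_ph: pd.DataFrame  # columns: pH, mean_nmi, mean_h, n_replicas
    coupled: bool

    def __repr__(self) -> str:  # compact, table printed separately
        return (f"CouplingStats({self.site_x}-{self.site_y}, "
                f"coupled={self.coupled})")


def coupling_screen(series_by_site: dict, threshold: float = COUPLING_THRESHOLD
                    ) -> list[CouplingStats]:
    """Screen all site pairs for protonation coupling.

    ``series_by_site`` maps site_id -> {(pH, replica): binary series}.  A
    pair is coupled iff at any pH both the replica-mean NMI and the
    replica-mean marginal entropy (average of the two sites' entropies)
    exceed ``threshold`` -- the entropy gate suppresses the low-entropy
    false-positive mode of raw NMI.
    """
    out = []
    for sx, sy in combinations(sorted(series_by_site), 2):
        keys = sorted(set(series_by_site[sx]) & set(series_by_site[sy]))
        rows = {}
        for (ph, rep) in keys:
            x = series_by_site[sx][(ph, rep)]
            y = series_by_site[sy][(ph, rep)]
            rows.setdefault(ph, []).append(
                (nmi(x, y), 0.5 * (entropy(x) + entropy(y))))
        per_ph = pd.DataFrame(
            [{"pH": ph, "mean_nmi": np.mean([v[0] for v in vals]),
              "mean_h": np.mean([v[1] for v in vals]),
              "n_replicas": len(vals)} for ph, vals in sorted(rows.items())]
        )
        coupled = bool(np.any((per_ph["mean_nmi"] > threshold)
                              & (per_ph["mean_h"] > threshold)))
        out.append(CouplingStats(site_x=sx, site_y=sy, per_ph=per_ph,
                                 coupled=coupled))
    return out


# ---------------------------------------------------------------------------
# Microstates

_STATES = ["A1H_A2H", "A1H_A2d", "A1d_A2H", "A1d_A2d"]


@dataclass
class MicrostateTable:
    """Joint protonation microstate fractions of a coupled pair."""

    fractions: dict  # state label -> overall fraction (sums to 1)
    windowed: pd.DataFrame  # per-window fractions, one row per window
    coupling_dg: dict  # state label -> kJ/mol, NaN where a marginal vanishes
    window: float  # ps


def microstates_and_coupling_dg(deprot_x, deprot_y, thermo: ThermoContext,
                                window_frames: int = 3000,
                                window_ps: float | None = None,
                                save_interval: float = 0.5) -> MicrostateTable:
    """Microstate fractions, windowed series, and coupling free energies.

    ``deprot_x/y`` are aligned binary deprotonation series; the default
    window of 3000 frames corresponds to 1.5 ns at the 0.5 ps save interval.
    dG_couple(state) = -kT ln[P(joint) / (P(marg_x) P(marg_y))]; states with
    a zero-probability marginal are reported as missing (NaN).
    """
    x = np.asarray(deprot_x).astype(bool)
    y = np.asarray(deprot_y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    if window_ps is not None:
        window_frames = max(1, int(round(window_ps / save_interval)))

    def frac(xs, ys):
        n = xs.size
        return {
            "A1H_A2H": np.sum(~xs & ~ys) / n,
            "A1H_A2d": np.sum(~xs & ys) / n,
            "A1d_A2H": np.sum(xs & ~ys) / n,
            "A1d_A2d": np.sum(xs & ys) / n,
        }

    overall = frac(x, y)
    rows = []
    for k0 in range(0, x.size - window_frames + 1, window_frames):
        f = frac(x[k0: k0 + window_frames], y[k0: k0 + window_frames])
        f["window_start_frame"] = k0
        rows.append(f)
    windowed = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=_STATES + ["window_start_frame"])

    px = {"H": np.mean(~x), "d": np.mean(x)}
    py = {"H": np.mean(~y), "d": np.mean(y)}
    dg = {}
    for state in _STATES:
        sx, sy = state.split("_")
        marg = px[sx[2:]] * py[sy[2:]]
        joint = overall[state]
        if marg == 0.0 or joint == 0.0:
            dg[state] = float("nan")
        else:
            dg[state] = float(-thermo.kt * np.log(joint / marg))
    return MicrostateTable(fractions=overall, windowed=windowed,
                           coupling_dg=dg,
                           window=window_frames * save_interval)


# ---------------------------------------------------------------------------
# Two-proton macroscopic titration


@dataclass
class MacroTitrationFit:
    """Macroscopic two-site titration fit."""

    pka_macro_1: float
    pka_macro_2: float
    ci_1: tuple | None = None
    ci_2: tuple | None = None
    n_boot: int = 0
    residual_rms: float = 0.0
    extra: dict = field(default_factory=dict)


def macro_two_site_curve(ph, pka1, pka2):
    """Mean protons bound <X>(pH) of the two-proton binding polynomial.

    ``pka1`` is the inflection where <X> crosses 0.5 (last proton released)
    and ``pka2`` the one where it crosses 1.5 (first proton released): the
    singly-protonated intermediate dominates for pka2 < pH < pka1, producing
    the <X> = 1 plateau of two well-separated transitions.  With pka1 <
    pka2 the intermediate never dominates and the same formula describes a
    steep concerted two-proton transition.
    """
    ph = np.asarray(ph, dtype=float)
    a = 10.0 ** (pka1 - ph)
    b = 10.0 ** (pka1 + pka2 - 2.0 * ph)
    return (a + 2.0 * b) / (1.0 + a + b)


def fit_macro_two_site(ph, mean_protons, replicas=None, n_boot: int = 0,
                       alpha: float = 0.05,
                       rng: np.random.Generator | None = None) -> MacroTitrationFit:
    """Fit the two-site binding polynomial to mean protons bound vs pH.

    ``ph`` and ``mean_protons`` are per-(pH, replica) observations of the
    average number of protons bound to the pair (in [0, 2]); <X> saturates
    at 2 for pH -> -inf and 0 for pH -> +inf.  Macroscopic pKa values are
    returned ordered pka_macro_1 <= pka_macro_2; if ``replicas`` (replica
    labels aligned with ph) and ``n_boot`` are given, a per-pH replica
    bootstrap CI is attached.
    """
    ph = np.asarray(ph, dtype=float)
    xx = np.asarray(mean_protons, dtype=float)
    if len(np.unique(ph)) < 5:
        raise ValueError("need >= 5 distinct pH values")

    def _fit(ph_v, x_v):
        # initial guesses from the half-saturation crossings: <X> = 1.5
        # (first proton released) and 0.5 (last proton released)
        p_first = _pka_init(ph_v, np.clip(2.0 - x_v, 0, 1))
        p_last = _pka_init(ph_v, np.clip(1.0 - x_v, 0, 1))
        popt, _ = curve_fit(macro_two_site_curve, ph_v, x_v,
                            p0=[p_last, p_first], maxfev=20_000)
        return float(popt[0]), float(popt[1])

    fitted = _fit(ph, xx)
    resid = xx - macro_two_site_curve(ph, *fitted)
    out = MacroTitrationFit(pka_macro_1=float(min(fitted)),
                            pka_macro_2=float(max(fitted)),
                            residual_rms=float(np.sqrt(np.mean(resid ** 2))))
    if n_boot and replicas is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        groups: dict[float, np.ndarray] = {
            p: xx[ph == p] for p in np.unique(ph)
        }
        b1 = np.empty(n_boot)
        b2 = np.empty(n_boot)
        kept = 0
        for _ in range(n_boot):
            ph_b, x_b = [], []
            for p, vals in groups.items():
                pick = vals[rng.integers(0, len(vals), len(vals))]
                ph_b.extend([p] * len(pick))
                x_b.extend(pick)
            try:
                r1, r2 = sorted(_fit(np.array(ph_b), np.array(x_b)))
            except RuntimeError:
                continue
            b1[kept], b2[kept] = r1, r2
            kept += 1
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        out.ci_1 = tuple(float(v) for v in np.percentile(b1[:kept], qs))
        out.ci_2 = tuple(float(v) for v in np.percentile(b2[:kept], qs))
        out.n_boot = n_boot
    return out
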
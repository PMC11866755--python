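"""Partial-least-squares Functional Mode Analysis (FMA).

FMA regresses the protonation coordinate lambda_p on configurational
coordinates to extract the single collective motion most predictive of
protonation: a PLS regression (20 components by default) is trained on the
replicas at the pH closest to the residue's pKa, holding out 20% of the
replicas as a validation set, and the overall regression-coefficient vector
(the ensemble-weighted maximally correlated motion of the FMA literature) is
unit-normalized to give the FMA mode.  Projections of any trajectory onto
the mode, affinely rescaled to the training range [0, 1], form the FMA
trajectory; percentile bins (<=5th, 5-25, 25-50, 50-75, 75-95, >95th) of the
pooled training projections partition all frames, and fitting a
Henderson-Hasselbalch curve within each bin (FMA-binned titration) resolves
the pKa as a function of the conformational sub-ensemble.

Configurations here are plain numeric matrices (toy conformational
coordinates plus optional noise dimensions); rigid-body superposition of
real atomic coordinates is a preprocessing responsibility of the caller.
X is mean-centered but not variance-scaled, preserving the
motion-amplitude interpretation of the mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression

from .titration import FitResult, TitrationPoint, fit_hh

__all__ = [
    "FMAModel",
    "FMABins",
    "fit_fma",
    "project",
    "binned_titration",
    "representative_structures",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass
class FMAModel:
    """A fitted FMA mode with its projection calibration."""

    mode: np.ndarray  # unit-norm direction in configuration space
    mean_x: np.ndarray
    n_components: int
    train_replicas: list
    validation_replicas: list
    explained_variance: float  # R^2 of lambda_p on held-out replicas, >= 0
    pearson_r2: float  # squared Pearson correlation on validation
    proj_offset: float = 0.0  # training-range rescaling: (p - offset) / scale
    proj_scale: float = 1.0
    bin_edges: np.ndarray | None = None  # percentile edges of training proj


def fit_fma(x: np.ndarray, y: np.ndarray, replica_ids,
            n_components: int = 20, validation_fraction: float = 0.2,
            rng: np.random.Generator | None = None,
            percentiles=DEFAULT_PERCENTILES) -> FMAModel:
    """Fit the FMA mode by PLS regression of protonation on configurations.

    ``x``: (n_frames, n_coords) configurations; ``y``: lambda_p per frame;
    ``replica_ids``: replica label per frame (the split unit).  Replicas are
    assigned to validation at random (at least 2).  Explained variance is
    1 - SSE/SST on the held-out replicas, clipped at 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    replica_ids = np.asarray(replica_ids)
    if rng is None:
        rng = np.random.default_rng(0)
    reps = np.unique(replica_ids)
    n_val = max(2, int(round(validation_fraction * len(reps))))
    if len(reps) - n_val < 1:
        raise ValueError("need at least 2 validation and 1 training replica")
    val_reps = rng.choice(reps, size=n_val, replace=False)
    val_mask = np.isin(replica_ids, val_reps)

    x_tr, y_tr = x[~val_mask], y[~val_mask]
    rank = int(np.linalg.matrix_rank(x_tr - x_tr.mean(axis=0)))
    ncomp = min(n_components, rank, x_tr.shape[1], x_tr.shape[0] - 1)
    if ncomp < n_components:
        warnings.warn(
            f"reducing PLS components from {n_components} to {ncomp} "
            "(rank-deficient configurations)", stacklevel=2)

    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(x_tr, y_tr)
    coef = np.asarray(pls.coef_).reshape(-1)
    norm = np.linalg.norm(coef)
    if norm == 0.0:
        raise ValueError("degenerate PLS fit: zero coefficient vector")
    mode = coef / norm
    mean_x = x_tr.mean(axis=0)

    y_pred = pls.predict(x[val_mask]).ravel()
    y_val = y[val_mask]
    sst = float(np.sum((y_val - y_val.mean()) ** 2))
    sse = float(np.sum((y_val - y_pred) ** 2))
    ev = max(0.0, 1.0 - sse / sst) if sst > 0 else 0.0
    if np.std(y_pred) > 0 and np.std(y_val) > 0:
        r2 = float(pearsonr(y_val, y_pred)[0] ** 2)
    else:
        r2 = 0.0

    proj_tr = (x_tr - mean_x) @ mode
    lo, hi = float(proj_tr.min()), float(proj_tr.max())
    scale = hi - lo if hi > lo else 1.0
    model = FMAModel(
        mode=mode, mean_x=mean_x, n_components=ncomp,
        train_replicas=sorted(reps[~np.isin(reps, val_reps)].tolist()),
        validation_replicas=sorted(val_reps.tolist()),
        explained_variance=ev, pearson_r2=r2,
        proj_offset=lo, proj_scale=scale,
    )
    scaled_tr = (proj_tr - lo) / scale
    model.bin_edges = np.percentile(scaled_tr, percentiles)
    return model


def project(x: np.ndarray, model: FMAModel) -> np.ndarray:
    """Scalar FMA projection per frame, rescaled to the training range [0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.mode.size:
        raise ValueError(
            f"configuration dimensionality {x.shape[-1]} != mode "
            f"dimensionality {model.mode.size}")
    return ((x - model.mean_x) @ model.mode - model.proj_offset) / model.proj_scale


@dataclass
class FMABins:
    """FMA-binned titration: per-bin frame counts and pKa fits."""

    edges: np.ndarray  # interior percentile edges on the scaled projection
    bin_labels: list
    counts: np.ndarray  # (n_bins,) frames per bin (non-censored)
    fits: list  # FitResult | None per bin
    reliable: list  # False where any pH has < min_frames frames
    points: dict = field(default_factory=dict)  # bin -> list[TitrationPoint]


def _bin_index(proj: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.searchsorted(edges, proj, side="right")


def binned_titration(model: FMAModel, items, min_frames: int = 100) -> FMABins:
    """Per-bin Henderson-Hasselbalch titration across FMA bins.

    ``items`` is an iterable of ``(projection, deprotonated, ph, replica)``
    tuples per trajectory (extra trailing entries are ignored), where
    ``projection`` (scaled FMA values) and ``deprotonated`` (booleans) are
    aligned non-censored frame arrays.
    Frames are grouped by the model's pooled-training percentile edges; each
    bin's per-(pH, replica) fractions are fitted with H-H.  A bin with fewer
    than ``min_frames`` frames at any pH is marked unreliable.
    """
    edges = model.bin_edges
    if edges is None:
        raise ValueError("model has no bin edges; refit with percentiles")
    nb = len(edges) + 1
    labels = ["<=p5", "p5-p25", "p25-p50", "p50-p75", "p75-p95", ">p95"][:nb]
    counts = np.zeros(nb, dtype=int)
    per_bin_points: dict[int, list[TitrationPoint]] = {b: [] for b in range(nb)}
    ph_bin_counts: dict[int, dict[float, int]] = {b: {} for b in range(nb)}
    all_ph = set()

    for proj, deprot, ph, replica, *_ in items:
        proj = np.asarray(proj, dtype=float)
        deprot = np.asarray(deprot).astype(bool)
        idx = _bin_index(proj, edges)
        all_ph.add(ph)
        for b in range(nb):
            sel = idx == b
            n = int(np.sum(sel))
            counts[b] += n
            ph_bin_counts[b][ph] = ph_bin_counts[b].get(ph, 0) + n
            if n > 0:
                per_bin_points[b].append(TitrationPoint(
                    ph=ph, replica=replica, n_total=n,
                    n_deprot=int(np.sum(deprot[sel]))))

    fits = []
    reliable = []
    for b in range(nb):
        ok = all(ph_bin_counts[b].get(ph, 0) >= min_frames for ph in all_ph)
        reliable.append(ok)
        try:
            fits.append(fit_hh(per_bin_points[b]))
        except (ValueError, RuntimeError):
            fits.append(None)
            reliable[-1] = False
    return FMABins(edges=edges, bin_labels=labels, counts=counts, fits=fits,
                   reliable=reliable, points=per_bin_points)


def representative_structures(x: np.ndarray, proj: np.ndarray,
                              model: FMAModel):
    """Mean configurations of the outermost FMA bins.

    Returns ``(low, high)``: the average configuration vectors of the frames
    at or below the 5th and above the 95th percentile of the training
    projections -- the low/high FMA value structures used to interpret the
    coupling mechanism.
    """
    x = np.asarray(x, dtype=float)
    proj = np.asarray(proj, dtype=float)
    edges = model.bin_edges
    low_sel = proj <= edges[0]
    high_sel = proj > edges[-1]
    if not low_sel.any() or not high_sel.any():
        raise ValueError("empty extreme bin")
    return x[low_sel].mean(axis=0), x[high_sel].mean(axis=0)
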
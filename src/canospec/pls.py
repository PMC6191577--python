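"""Partial least squares regression of traits on 400–1000 nm reflectance.

Adjacent hyperspectral bands are strongly collinear; PLSR projects them
onto a few orthogonal latent variables ("PCs") chosen to covary with the
trait.  Model quality is reported the chemometric way:

* calibration: R²cal, RMSEC and the slope of predicted-vs-observed on the
  training data (for a least-squares fit this slope equals R²cal exactly);
* validation: k-fold cross-validation (default seven folds), with RMSEV and
  R²val = 1 − PRESS/SST computed on the pooled out-of-fold predictions, and
  slope_val from regressing pooled predictions on observations.

The number of components is chosen to minimize pooled RMSEV over
1…max_components, then the model is refit on all data at that size.
Bands are mean-centered only; autoscaling is an explicit opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .spectra import Spectrum

__all__ = [
    "PLSREvaluation",
    "spectra_to_matrix",
    "fit_plsr",
    "cross_validate_plsr",
]

DEFAULT_RANGE = (400.0, 1000.0)


@dataclass
class PLSREvaluation:
    trait_name: str
    n_components: int
    r2_cal: float
    r2_val: float
    rmsec: float
    rmsev: float
    slope_cal: float
    slope_val: float
    n: int
    wavelength_range: tuple[float, float]
    k_folds: int = 7


def spectra_to_matrix(
    spectra: list[Spectrum], wavelength_range: tuple[float, float] = DEFAULT_RANGE
) -> tuple[np.ndarray, np.ndarray]:
    """Stack spectra into a plots × bands matrix restricted to a range."""
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, grid):
            raise ValueError("all spectra must share one wavelength grid")
    sel = (grid >= wavelength_range[0]) & (grid <= wavelength_range[1])
    if not sel.any():
        raise ValueError("wavelength range selects no bands")
    return np.stack([s.reflectance[sel] for s in spectra]), grid[sel]


def _obs_pred_slope(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Slope of the least-squares line of predicted on observed."""
    oc = observed - observed.mean()
    denom = float(oc @ oc)
    if denom == 0:
        raise ValueError("degenerate: observed values are constant")
    return float((oc @ (predicted - predicted.mean())) / denom)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be plots x bands aligned with y")
    if np.ptp(y) == 0:
        raise ValueError("degenerate: constant trait vector")
    return X, y


def fit_plsr(X, y, n_components: int, scale: bool = False):
    """Fit a PLSR model and compute the calibration metric bundle.

    Returns ``(model, metrics)`` where metrics is a dict with keys
    ``r2_cal``, ``rmsec``, ``slope_cal``.  ``scale=True`` switches on band
    autoscaling (unit variance) in addition to mean-centering.
    """
    X, y = _check_xy(X, y)
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    if n_components >= X.shape[0]:
        raise ValueError("n_components must be smaller than the number of plots")
    model = PLSRegression(n_components=n_components, scale=scale)
    model.fit(X, y)
    pred = model.predict(X).ravel()
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    metrics = {
        "r2_cal": 1.0 - sse / sst,
        "rmsec": float(np.sqrt(sse / y.size)),
        "slope_cal": _obs_pred_slope(y, pred),
    }
    return model, metrics


def cross_validate_plsr(
    X,
    y,
    max_components: int = 10,
    k_folds: int = 7,
    seed: int = 0,
    trait_name: str = "",
    wavelength_range: tuple[float, float] = DEFAULT_RANGE,
    scale: bool = False,
) -> PLSREvaluation:
    """Seven-fold (by default) cross-validated PLSR evaluation.

    Plots are partitioned into ``k_folds`` seeded, size-balanced random
    folds.  For each candidate component count, out-of-fold predictions are
    pooled over all folds; the count minimizing RMSEV wins (ties to the
    smaller count).  The returned bundle carries both the pooled validation
    metrics and the calibration metrics of the final refit on all data.
    """
    X, y = _check_xy(X, y)
    n = y.size
    if k_folds > n:
        raise ValueError("more folds than observations")
    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    # every training split must keep more samples than components
    min_train = n - (n // k_folds + (1 if n % k_folds else 0))
    cap = min(max_components, min_train - 1, X.shape[1])
    if cap < 1:
        raise ValueError("too few observations for even one component")

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    press = np.empty(cap)
    pooled = np.empty((cap, n))
    for ncomp in range(1, cap + 1):
        for train, test in splits:
            model = PLSRegression(n_components=ncomp, scale=scale)
            model.fit(X[train], y[train])
            pooled[ncomp - 1, test] = model.predict(X[test]).ravel()
        press[ncomp - 1] = np.sum((y - pooled[ncomp - 1]) ** 2)
    best = int(np.argmin(press)) + 1  # argmin: first minimum = fewest components

    pred_val = pooled[best - 1]
    sst = float(np.sum((y - y.mean()) ** 2))
    rmsev = float(np.sqrt(press[best - 1] / n))
    r2_val = 1.0 - float(press[best - 1]) / sst

    _, cal = fit_plsr(X, y, best, scale=scale)
    return PLSREvaluation(
        trait_name=trait_name,
        n_components=best,
        r2_cal=cal["r2_cal"],
        r2_val=r2_val,
        rmsec=cal["rmsec"],
        rmsev=rmsev,
        slope_cal=cal["slope_cal"],
        slope_val=_obs_pred_slope(y, pred_val),
        n=n,
        wavelength_range=wavelength_range,
        k_folds=k_folds,
    )
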
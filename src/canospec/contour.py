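"""Exhaustive two-band index optimization ("contour maps").

For a trait y and every unordered wavelength pair (λi, λj) within a range,
the map stores the simple-linear-regression coefficient of determination of
y against NDSI(λi, λj) across plots.  For simple regression R² equals the
squared Pearson correlation between predictor and response, which is what
the vectorized inner loop computes; equivalence with the regression module
is exercised in the test suite.  Maps from several sampling dates are
averaged entrywise to find wavelength pairs whose relationship with the
trait is strong *and* stable across growth stages.

Cells are masked (NaN) when the NDSI is undefined for any plot (zero
denominator) or the regression is degenerate; the diagonal (λi = λj, an
identically zero index) is always masked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "ContourMap",
    "BestPair",
    "contour_map_for_trait",
    "mean_contour_map",
    "select_best_pair",
    "ranked_pairs",
    "write_contour_csv",
]


@dataclass
class ContourMap:
    wavelengths: np.ndarray  # nm grid actually used
    r2: np.ndarray           # square, symmetric, NaN = masked, diag masked
    trait_name: str
    n_dates_averaged: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        b = self.wavelengths.size
        if self.r2.shape != (b, b):
            raise ValueError("r2 must be square on the wavelength grid")

    @property
    def n_masked(self) -> int:
        """Masked off-diagonal cells (undefined NDSI or degenerate fit)."""
        off = ~np.eye(len(self.wavelengths), dtype=bool)
        return int(np.isnan(self.r2[off]).sum())


@dataclass(frozen=True)
class BestPair:
    lambda_a: float  # < lambda_b
    lambda_b: float
    mean_r2: float


def contour_map_for_trait(
    spectra: list[Spectrum],
    traits: np.ndarray,
    wavelength_range: tuple[float, float] = (302.0, 1048.0),
    trait_name: str = "",
) -> ContourMap:
    """R² of trait vs NDSI(λi, λj) for every band pair in the range.

    Requires at least 3 aligned observations and a non-constant trait.
    The loop over the first band is vectorized over the second, so a full
    424-band map over dozens of plots takes seconds, not minutes.
    """
    y = np.asarray(traits, dtype=float).ravel()
    if len(spectra) != y.size:
        raise ValueError("spectra and trait vector must be aligned")
    if y.size < 3:
        raise ValueError("need at least 3 aligned observations")
    if np.ptp(y) == 0:
        raise ValueError("degenerate regression: trait vector is constant")

    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, grid):
            raise ValueError("all spectra must share one wavelength grid")
    lo, hi = wavelength_range
    if lo >= hi:
        raise ValueError("empty wavelength range")
    sel = (grid >= lo) & (grid <= hi)
    if sel.sum() < 2:
        raise ValueError("wavelength range selects fewer than 2 bands")
    wl = grid[sel]
    R = np.stack([s.reflectance[sel] for s in spectra])  # n x B

    n, B = R.shape
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    r2 = np.full((B, B), np.nan)
    # upper triangle only, mirrored afterwards: sign flip of the predictor
    # leaves R² unchanged, and a single evaluation per pair keeps the map
    # symmetric to the bit
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(B - 1):
            ri = R[:, i][:, None]
            rest = R[:, i + 1:]
            x = (ri - rest) / (ri + rest)    # n x (B-i-1), NDSI(λi, λj>i)
            bad = ~np.isfinite(x).all(axis=0)
            xc = x - x.mean(axis=0)
            ss_x = np.einsum("ij,ij->j", xc, xc)
            cov = yc @ xc
            row = cov**2 / (ss_x * ss_y)
            row[bad | (ss_x == 0)] = np.nan
            r2[i, i + 1:] = row
            r2[i + 1:, i] = row
    return ContourMap(wl, r2, trait_name=trait_name, n_dates_averaged=1)


def mean_contour_map(maps: list[ContourMap]) -> ContourMap:
    """Entrywise arithmetic mean across sampling dates; masks propagate."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    total = np.zeros_like(first.r2)
    for m in maps:
        if not np.array_equal(m.wavelengths, first.wavelengths):
            raise ValueError("maps must share one wavelength grid")
        if m.trait_name != first.trait_name:
            raise ValueError("maps must describe the same trait")
        total = total + m.r2  # NaN propagates: a cell undefined on any date stays masked
    return ContourMap(
        first.wavelengths, total / len(maps), first.trait_name, n_dates_averaged=len(maps)
    )


def select_best_pair(cmap: ContourMap) -> BestPair:
    """Global off-diagonal maximum; ties break to the lexicographically
    smallest (lambda_a, lambda_b)."""
    r2 = cmap.r2
    if np.all(np.isnan(r2)):
        raise ValueError("fully masked map: no valid wavelength pair")
    best = np.nanmax(r2)
    ii, jj = np.where(r2 == best)
    pairs = sorted(
        {(min(cmap.wavelengths[i], cmap.wavelengths[j]),
          max(cmap.wavelengths[i], cmap.wavelengths[j])) for i, j in zip(ii, jj)}
    )
    a, b = pairs[0]
    return BestPair(float(a), float(b), float(best))


def ranked_pairs(cmap: ContourMap, top: int = 20) -> pd.DataFrame:
    """Top wavelength pairs by mean R², one row per unordered pair."""
    B = len(cmap.wavelengths)
    iu, ju = np.triu_indices(B, k=1)
    vals = cmap.r2[iu, ju]
    ok = np.isfinite(vals)
    order = np.argsort(-vals[ok], kind="stable")[:top]
    ii, jj, vv = iu[ok][order], ju[ok][order], vals[ok][order]
    return pd.DataFrame(
        {
            "lambda_a": cmap.wavelengths[ii],
            "lambda_b": cmap.wavelengths[jj],
            "mean_r2": vv,
            "trait": cmap.trait_name,
        }
    )


def write_contour_csv(cmap: ContourMap, path: str | Path) -> None:
    """Aggregated matrix as CSV with wavelength header row/column."""
    df = pd.DataFrame(cmap.r2, index=cmap.wavelengths, columns=cmap.wavelengths)
    df.index.name = "wavelength_nm"
    df.to_csv(path)
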
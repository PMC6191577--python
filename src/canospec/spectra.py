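"""Hyperspectral plot spectra and two-band normalized-difference indices.

A :class:`Spectrum` holds one plot's reflectance on a fixed wavelength grid
(the field instrument samples 302–1148 nm at 2 nm bandwidth).  All indices
computed here are of the normalized-difference form

    NDSI(a, b) = (R_a - R_b) / (R_a + R_b)

of which NDVI (780, 670 nm) is the classical red/NIR special case.  The
module also carries the fixed 12-index battery built from 19 selected
wavelengths spanning the green peak, red absorption, red edge and NIR
plateau of a vegetation spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "IndexDefinition",
    "INDEX_BATTERY",
    "SELECTED_WAVELENGTHS",
    "default_grid",
    "band_at",
    "ndsi",
    "index_battery",
    "battery_table",
    "read_spectra_csv",
    "write_spectra_csv",
]

#: The 19 wavelengths (nm) from which the fixed index battery is built.
SELECTED_WAVELENGTHS = (
    550, 572, 590, 624, 640, 656, 660, 670, 710, 720,
    730, 740, 760, 774, 780, 800, 820, 850, 952,
)

REFLECTANCE_MAX = 1.5  # tolerates calibration overshoot above 1.0


def default_grid(start: float = 302.0, stop: float = 1148.0, step: float = 2.0) -> np.ndarray:
    """The sensor's wavelength grid in nm (302–1148, 2 nm bandwidth)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class IndexDefinition:
    """A two-band normalized-difference index (R_a − R_b)/(R_a + R_b)."""

    name: str
    lambda_a: float
    lambda_b: float

    def __post_init__(self) -> None:
        if self.lambda_a == self.lambda_b:
            raise ValueError("an NDSI needs two distinct wavelengths")


#: The fixed 12-index battery.  Names follow the lambda_a/lambda_b pattern;
#: the (780, 670) member is the classical NDVI.
INDEX_BATTERY: tuple[IndexDefinition, ...] = tuple(
    IndexDefinition(f"{a}_{b}", a, b)
    for a, b in [
        (590, 550), (624, 572), (710, 640), (760, 550),
        (760, 730), (780, 670), (780, 720), (780, 740),
        (800, 720), (820, 660), (850, 730), (952, 720),
    ]
)


@dataclass
class Spectrum:
    """One plot's reflectance spectrum on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    plot_id: str = ""
    date_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.size != self.reflectance.size:
            raise ValueError("wavelengths and reflectance lengths differ")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two bands")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")
        if self.reflectance.min() < 0 or self.reflectance.max() > REFLECTANCE_MAX:
            raise ValueError(
                f"reflectance outside [0, {REFLECTANCE_MAX}]; got "
                f"[{self.reflectance.min():.3g}, {self.reflectance.max():.3g}]"
            )

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.wavelengths)))


def band_index(wavelengths: np.ndarray, wavelength: float, step: float | None = None) -> int:
    """Index of the band whose center is nearest to ``wavelength``.

    Ties (request exactly halfway between two centers) resolve to the lower
    wavelength.  Requests farther than half the grid step from every band
    center, or outside the grid span, raise ``ValueError``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside grid span [{wl[0]}, {wl[-1]}]"
        )
    if step is None:
        step = float(np.median(np.diff(wl)))
    dist = np.abs(wl - wavelength)
    best = int(np.argmin(dist))  # argmin takes the first (lower) on ties
    if dist[best] > step / 2 + 1e-9:
        raise ValueError(
            f"no band center within half a step ({step / 2} nm) of {wavelength} nm"
        )
    return best


def band_at(spectrum: Spectrum, wavelength: float) -> float:
    """Reflectance of the band nearest ``wavelength`` (ties to the lower band)."""
    return float(spectrum.reflectance[band_index(spectrum.wavelengths, wavelength, spectrum.step)])


def ndsi(spectrum: Spectrum, lambda_a: float, lambda_b: float) -> float:
    """Normalized difference (R_a − R_b)/(R_a + R_b).

    Returns NaN (an explicit undefined-value marker) when the denominator
    vanishes; never a silent zero.
    """
    if lambda_a == lambda_b:
        raise ValueError("an NDSI needs two distinct wavelengths")
    ra = band_at(spectrum, lambda_a)
    rb = band_at(spectrum, lambda_b)
    denom = ra + rb
    if denom == 0.0:
        return float("nan")
    return (ra - rb) / denom


def index_battery(spectrum: Spectrum) -> dict[str, float]:
    """Evaluate the fixed 12-index battery on one spectrum.

    Indices whose bands are missing from the grid, or whose denominator is
    zero, map to NaN rather than being dropped.
    """
    out: dict[str, float] = {}
    for d in INDEX_BATTERY:
        try:
            out[d.name] = ndsi(spectrum, d.lambda_a, d.lambda_b)
        except ValueError:
            out[d.name] = float("nan")
    return out


def battery_table(spectra: Iterable[Spectrum]) -> pd.DataFrame:
    """Index battery for many spectra: one row per (plot_id, date_id)."""
    rows = []
    for s in spectra:
        row: dict[str, object] = {"plot_id": s.plot_id, "date_id": s.date_id}
        row.update(index_battery(s))
        rows.append(row)
    cols = ["plot_id", "date_id"] + [d.name for d in INDEX_BATTERY]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Wide layout: plot_id,date_id,302,304,...,1148 — one row per plot-date.
# Long layout: plot_id,date_id,wavelength,reflectance.


def write_spectra_csv(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in the wide layout (one integer-nm column per band)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].wavelengths
    rows = []
    for s in spectra:
        if not np.array_equal(s.wavelengths, grid):
            raise ValueError("all spectra must share one wavelength grid")
        rows.append([s.plot_id, s.date_id, *s.reflectance])
    cols = ["plot_id", "date_id"] + [_fmt_band(w) for w in grid]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _fmt_band(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else str(w)


def read_spectra_csv(path: str | Path, percent: bool = False) -> list[Spectrum]:
    """Read spectra from wide or long CSV.

    The layout is detected from the header.  With ``percent=True`` the file
    stores reflectance in percent and values are divided by 100 on load.
    """
    df = pd.read_csv(path)
    scale = 0.01 if percent else 1.0
    cols = set(df.columns)
    if {"wavelength", "reflectance"} <= cols:
        out = []
        for (pid, did), grp in df.groupby(["plot_id", "date_id"], sort=False):
            grp = grp.sort_values("wavelength")
            out.append(
                Spectrum(
                    grp["wavelength"].to_numpy(float),
                    grp["reflectance"].to_numpy(float) * scale,
                    plot_id=str(pid),
                    date_id=str(did),
                )
            )
        return out
    band_cols = [c for c in df.columns if c not in ("plot_id", "date_id")]
    grid = np.array([float(c) for c in band_cols])
    order = np.argsort(grid)
    grid = grid[order]
    vals = df[band_cols].to_numpy(float)[:, order] * scale
    return [
        Spectrum(grid, vals[i], plot_id=str(df["plot_id"].iloc[i]), date_id=str(df["date_id"].iloc[i]))
        for i in range(len(df))
    ]
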
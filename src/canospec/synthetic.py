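"""Synthetic wheat-canopy datasets: traits, reflectance spectra, RGB images.

Early-tillering wheat stands have low canopy cover, so both the camera and
the spectrometer see a mixture of plant and bare soil.  The generator
emulates exactly the statistical structure the downstream analysis assumes:

* per-date trait distributions (fresh/dry biomass, N concentration) sampled
  from moment-matched truncated normals, with the N-dilution effect — tissue
  N concentration falling as biomass accumulates across growth stages;
* the exact identity N uptake = dry weight × N concentration / 100;
* canopy closure as a Beer–Lambert curve f = 1 − exp(−k·dry_weight), which
  is near-linear at low cover and saturates toward full closure;
* plot reflectance as a linear two-endmember mixture
  R(λ) = f·R_veg(λ; chl) + (1 − f)·R_soil(λ) + ε, where the chlorophyll
  proxy chl deepens the red (≈670 nm) absorption and shifts the red edge
  with N concentration;
* canopy photographs with an exactly known number of green pixels, so the
  image-analysis stage can be tested against ground truth.

Everything is a deterministic function of the scenario seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .imaging import HSBThresholds, rgb_to_hsb
from .spectra import Spectrum, default_grid

__all__ = [
    "TraitRecord",
    "TraitRange",
    "DateSpec",
    "CanopyScenario",
    "Endmembers",
    "scenario_2014",
    "scenario_2016",
    "generate_traits",
    "fractional_cover",
    "generate_spectrum",
    "generate_spectra",
    "generate_image",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# Trait records and scenario configuration


@dataclass
class TraitRecord:
    """One plot-date observation of the four destructive target variables."""

    plot_id: str
    date_id: str
    bbch: int
    fresh_weight: float  # kg/ha
    dry_weight: float    # kg/ha
    n_conc: float        # % of dry weight
    n_uptake: float      # kg/ha, == dry_weight * n_conc / 100

    def __post_init__(self) -> None:
        if self.dry_weight < 0 or self.fresh_weight < 0:
            raise ValueError("biomass weights must be non-negative")
        if self.n_conc <= 0:
            raise ValueError("n_conc must be positive")
        if self.dry_weight > self.fresh_weight:
            raise ValueError("dry weight cannot exceed fresh weight")

    @classmethod
    def from_biomass(
        cls, plot_id: str, date_id: str, bbch: int,
        fresh_weight: float, dry_weight: float, n_conc: float,
    ) -> "TraitRecord":
        """Build a record with n_uptake derived exactly from the identity."""
        return cls(
            plot_id, date_id, bbch, fresh_weight, dry_weight, n_conc,
            n_uptake=dry_weight * n_conc / 100.0,
        )


@dataclass(frozen=True)
class TraitRange:
    """(min, mean, max) targets for one trait on one date.

    A point mass (lo == mean == hi) is allowed; otherwise the mean must lie
    strictly between the bounds for the truncated normal to be matchable.
    """

    lo: float
    mean: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"infeasible trait range: min {self.lo} > max {self.hi}")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean {self.mean} outside [{self.lo}, {self.hi}]")
        if self.lo < self.hi and not (self.lo < self.mean < self.hi):
            raise ValueError(
                "mean must lie strictly inside (min, max) for a non-degenerate range"
            )

    @property
    def degenerate(self) -> bool:
        return self.lo == self.hi


@dataclass(frozen=True)
class DateSpec:
    """One sampling date: identifier, growth stage, per-trait targets.

    ``n_uptake`` targets, when given, are reference metadata only — uptake is
    always derived from the identity, never sampled or clipped.
    """

    date_id: str
    bbch: int
    fresh_weight: TraitRange
    dry_weight: TraitRange
    n_conc: TraitRange
    n_uptake: TraitRange | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.bbch <= 99):
            raise ValueError("bbch must be a two-digit decimal-scale code")


@dataclass
class CanopyScenario:
    """Full parameterization of one synthetic growing season."""

    name: str
    n_plots: int
    dates: tuple[DateSpec, ...]
    cover_saturation_k: float = 5e-4      # ha/kg, canopy-closure rate
    noise_sd_spectral: float = 0.004      # reflectance units, per band
    noise_sd_trait: float = 0.5           # idiosyncratic share of trait variation, [0,1]
    biomass_n_corr: float = 0.4           # within-date biomass/N%-coupling strength
    image_size: tuple[int, int] = (128, 128)  # (width, height) px
    image_style: Literal["clean", "winter_stressed"] = "clean"
    seed: int = 0
    grid_start: float = 302.0
    grid_stop: float = 1148.0
    grid_step: float = 2.0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValueError("n_plots must be at least 1")
        if not self.dates:
            raise ValueError("a scenario needs at least one sampling date")
        if self.cover_saturation_k <= 0:
            raise ValueError("cover_saturation_k must be positive")
        if not (0.0 <= self.noise_sd_trait <= 1.0):
            raise ValueError("noise_sd_trait is a variance share in [0, 1]")
        if self.noise_sd_spectral < 0:
            raise ValueError("noise_sd_spectral must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return default_grid(self.grid_start, self.grid_stop, self.grid_step)

    # -- JSON round trip (provenance) ------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CanopyScenario":
        d = json.loads(text)
        dates = []
        for ds in d.pop("dates"):
            kw = {}
            for k, v in ds.items():
                if isinstance(v, dict):
                    kw[k] = TraitRange(**v)
                else:
                    kw[k] = v
            dates.append(DateSpec(**kw))
        d["dates"] = tuple(dates)
        d["image_size"] = tuple(d["image_size"])
        return cls(**d)


def scenario_2014(n_plots: int = 64, seed: int = 0, **overrides) -> CanopyScenario:
    """Default four-date season: biomass rising, N% diluting across BBCH 19→30."""
    dates = (
        DateSpec("d1", 19, TraitRange(968, 1913.6, 3704), TraitRange(232, 450.4, 972),
                 TraitRange(2.2, 3.2, 4.9), TraitRange(6.8, 14.4, 29.2)),
        DateSpec("d2", 22, TraitRange(1452, 2952.4, 4812), TraitRange(340, 758.4, 1452),
                 TraitRange(1.9, 2.6, 3.6), TraitRange(8.0, 19.6, 34.8)),
        DateSpec("d3", 25, TraitRange(1900, 5306.4, 10324), TraitRange(472, 1218.8, 2340),
                 TraitRange(1.5, 2.4, 3.3), TraitRange(10.4, 29.2, 58.0)),
        DateSpec("d4", 30, TraitRange(2552, 9186.8, 15454), TraitRange(632, 2206.0, 4304),
                 TraitRange(1.3, 2.0, 3.1), TraitRange(10.0, 44.8, 94.0)),
    )
    return CanopyScenario(name="2014", n_plots=n_plots, dates=dates, seed=seed, **overrides)


def scenario_2016(n_plots: int = 30, seed: int = 0, **overrides) -> CanopyScenario:
    """Two-date verification season: fertilization between dates raises N%.

    Fresh-weight targets are derived from dry weight at a typical ~20 %
    dry-matter fraction (the verification season recorded dry weight only).
    """
    dates = (
        DateSpec("d1", 19, TraitRange(1164, 1927.5, 2866), TraitRange(232.8, 385.5, 573.2),
                 TraitRange(2.6, 3.1, 3.8), TraitRange(8.1, 12.0, 17.0)),
        DateSpec("d2", 22, TraitRange(1826, 2740.5, 4130), TraitRange(365.2, 548.1, 826.0),
                 TraitRange(4.4, 5.0, 5.4), TraitRange(18.1, 27.3, 41.1)),
    )
    return CanopyScenario(name="2016", n_plots=n_plots, dates=dates, seed=seed, **overrides)


SCENARIO_PRESETS = {"2014": scenario_2014, "2016": scenario_2016}


# ---------------------------------------------------------------------------
# Trait sampling


def _matched_truncnorm(r: TraitRange):
    """Truncated normal on [lo, hi] whose mean matches the target.

    The spread is fixed at (hi − lo)/4 and the location solved by root
    finding; the paper-style summaries give only min/mean/max, which pins
    down exactly these two degrees of freedom.
    """
    if r.degenerate:
        return None  # point mass
    sigma = (r.hi - r.lo) / 4.0

    def mean_err(mu: float) -> float:
        a, b = (r.lo - mu) / sigma, (r.hi - mu) / sigma
        return stats.truncnorm.mean(a, b, loc=mu, scale=sigma) - r.mean

    mu = optimize.brentq(mean_err, r.lo - 8 * sigma, r.hi + 8 * sigma, xtol=1e-10)
    a, b = (r.lo - mu) / sigma, (r.hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def _ppf(r: TraitRange, dist, u: np.ndarray) -> np.ndarray:
    if dist is None:
        return np.full_like(u, r.lo)
    return dist.ppf(u)


def _rng_for(scenario: CanopyScenario, stage: int, tag: str = "") -> np.random.Generator:
    crc = zlib.crc32(tag.encode()) if tag else 0
    return np.random.default_rng(np.random.SeedSequence((scenario.seed, stage, crc)))


def generate_traits(scenario: CanopyScenario) -> list[TraitRecord]:
    """Sample one TraitRecord per plot and date.

    Plots carry a latent "vigor" factor shared by both biomass traits and
    loading negatively on N concentration (within-date dilution), with an
    idiosyncratic share controlled by ``noise_sd_trait``.  Marginals are the
    moment-matched truncated normals of each date's targets, so every
    sampled trait respects its configured [min, max].
    """
    rng = _rng_for(scenario, 1)
    tau = scenario.noise_sd_trait
    rho = scenario.biomass_n_corr
    records: list[TraitRecord] = []
    for ds in scenario.dates:
        dists = {
            "fresh": _matched_truncnorm(ds.fresh_weight),
            "dry": _matched_truncnorm(ds.dry_weight),
            "n": _matched_truncnorm(ds.n_conc),
        }
        z = rng.standard_normal(scenario.n_plots)          # plot vigor
        eps = rng.standard_normal((3, scenario.n_plots))   # idiosyncratic
        load = np.sqrt(1.0 - tau**2)
        x_fresh = load * z + tau * eps[0]
        x_dry = load * z + tau * eps[1]
        x_n = -rho * load * z + np.sqrt(1.0 - (rho * load) ** 2) * eps[2]
        u = stats.norm.cdf(np.vstack([x_fresh, x_dry, x_n]))
        fresh = _ppf(ds.fresh_weight, dists["fresh"], u[0])
        dry = _ppf(ds.dry_weight, dists["dry"], u[1])
        nconc = _ppf(ds.n_conc, dists["n"], u[2])
        fresh = np.maximum(fresh, dry)  # destructive samples are weighed wet first
        for i in range(scenario.n_plots):
            records.append(
                TraitRecord.from_biomass(
                    f"p{i + 1:03d}", ds.date_id, ds.bbch,
                    float(fresh[i]), float(dry[i]), float(nconc[i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Canopy closure and spectral mixing


def fractional_cover(dry_weight, k: float):
    """Beer–Lambert canopy closure f = 1 − exp(−k·dry_weight) in [0, 1).

    Near-linear for small biomass, concave, saturating toward full cover —
    the geometry behind the loss of optical sensitivity at high biomass.
    """
    dw = np.asarray(dry_weight, dtype=float)
    if np.any(dw < 0):
        raise ValueError("dry_weight must be non-negative")
    if k <= 0:
        raise ValueError("closure rate k must be positive")
    f = 1.0 - np.exp(-k * dw)
    return float(f) if np.isscalar(dry_weight) else f


def chlorophyll_proxy(n_conc) -> np.ndarray | float:
    """Affine map from N concentration (%) to a [0, 1] chlorophyll proxy."""
    return np.clip((np.asarray(n_conc, dtype=float) - 1.0) / 4.5, 0.0, 1.0)


@dataclass
class Endmembers:
    """Soil and vegetation endmember spectra on a shared wavelength grid.

    Vegetation is parameterized by a chlorophyll proxy in [0, 1] that deepens
    the red absorption trough (~670 nm) and shifts the red-edge inflection to
    longer wavelengths, giving red-edge indices an N signal distinct from
    pure biomass.  Shapes are generic textbook shapes: bright monotone soil,
    green peak / red trough / NIR plateau vegetation.
    """

    wavelengths: np.ndarray
    soil_reflectance: np.ndarray
    nir_plateau: float = 0.48
    red_edge_base_nm: float = 702.0
    red_edge_shift_nm: float = 18.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.soil_reflectance = np.asarray(self.soil_reflectance, dtype=float)
        if self.wavelengths.shape != self.soil_reflectance.shape:
            raise ValueError("soil endmember must live on the wavelength grid")

    @classmethod
    def default(cls, wavelengths: np.ndarray) -> "Endmembers":
        wl = np.asarray(wavelengths, dtype=float)
        soil = 0.08 + 0.22 * (wl - wl[0]) / (wl[-1] - wl[0])
        return cls(wl, soil)

    def vegetation_reflectance(self, chl: float) -> np.ndarray:
        """Vegetation endmember for one chlorophyll-proxy value."""
        chl = float(np.clip(chl, 0.0, 1.0))
        wl = self.wavelengths
        vis = 0.05 + 0.055 * np.exp(-(((wl - 550.0) / 32.0) ** 2))
        red_depth = 0.55 + 0.40 * chl
        vis = vis * (1.0 - red_depth * np.exp(-(((wl - 672.0) / 48.0) ** 2)))
        lam_re = self.red_edge_base_nm + self.red_edge_shift_nm * chl
        s = 1.0 / (1.0 + np.exp(-(wl - lam_re) / 13.0))
        veg = vis * (1.0 - s) + self.nir_plateau * s
        return np.clip(veg, 0.0, 1.0)


def generate_spectrum(
    trait: TraitRecord,
    endmembers: Endmembers,
    scenario: CanopyScenario,
) -> Spectrum:
    """Linear soil–vegetation mixture spectrum for one plot-date.

    R(λ) = f·R_veg(λ; chl(n_conc)) + (1 − f)·R_soil(λ) + ε with f from the
    closure curve and ε i.i.d. Gaussian band noise; clipped to [0, 1].
    The noise stream is keyed on (scenario seed, plot_id, date_id), so the
    whole dataset is reproducible from the scenario alone.
    """
    wl = scenario.wavelengths
    if not np.array_equal(endmembers.wavelengths, wl):
        raise ValueError("endmember grid does not match the scenario's sensor grid")
    f = fractional_cover(trait.dry_weight, scenario.cover_saturation_k)
    veg = endmembers.vegetation_reflectance(chlorophyll_proxy(trait.n_conc))
    refl = f * veg + (1.0 - f) * endmembers.soil_reflectance
    if scenario.noise_sd_spectral > 0:
        rng = _rng_for(scenario, 2, f"{trait.plot_id}:{trait.date_id}")
        refl = refl + rng.normal(0.0, scenario.noise_sd_spectral, size=wl.size)
    return Spectrum(wl, np.clip(refl, 0.0, 1.0), plot_id=trait.plot_id, date_id=trait.date_id)


def generate_spectra(
    traits: list[TraitRecord],
    scenario: CanopyScenario,
    endmembers: Endmembers | None = None,
) -> list[Spectrum]:
    if endmembers is None:
        endmembers = Endmembers.default(scenario.wavelengths)
    return [generate_spectrum(t, endmembers, scenario) for t in traits]


# ---------------------------------------------------------------------------
# Image generation


def _hsv_to_rgb_bytes(h_deg: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized hexcone HSV → RGB, returning uint8 triples."""
    h = (np.asarray(h_deg, dtype=float) % 360.0) / 60.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.rint(np.stack([r, g, b], axis=-1) * 255.0).astype(np.uint8)


def _palette(
    rng: np.random.Generator,
    hue_byte_range: tuple[float, float],
    sat_range: tuple[float, float],
    val_range: tuple[float, float],
    inside: bool,
    thresholds: HSBThresholds,
    size: int = 512,
) -> np.ndarray:
    """Candidate colors in an HSV box, kept only if their byte-scale HSB
    classification matches ``inside`` — generation and segmentation share one
    color convention, so planted counts are exact."""
    h = rng.uniform(*hue_byte_range, size) * 360.0 / 255.0
    s = rng.uniform(*sat_range, size)
    v = rng.uniform(*val_range, size)
    rgb = _hsv_to_rgb_bytes(h, s, v)
    hsb = rgb_to_hsb(rgb)
    t = thresholds
    in_mask = (
        (hsb[:, 0] >= t.hue_lo) & (hsb[:, 0] <= t.hue_hi)
        & (hsb[:, 1] >= t.sat_lo) & (hsb[:, 1] <= t.sat_hi)
        & (hsb[:, 2] >= t.bri_lo) & (hsb[:, 2] <= t.bri_hi)
    )
    keep = rgb[in_mask] if inside else rgb[~in_mask]
    if len(keep) == 0:
        raise RuntimeError("palette box produced no usable colors")
    return keep


def generate_image(
    green_fraction_target: float,
    width: int,
    height: int,
    style: Literal["clean", "winter_stressed"] = "clean",
    seed: int = 0,
    thresholds: HSBThresholds = HSBThresholds(),
) -> tuple[np.ndarray, int]:
    """Synthesize a canopy photograph with an exact green-pixel count.

    Plants exactly ``round(target/100 * width * height)`` pixels whose HSB
    bytes fall inside the green thresholds; all remaining pixels fall
    outside (soil browns, plus yellow/brown stressed-leaf colors in the
    ``winter_stressed`` style that mimics cold-damaged early canopies).
    Pixels are i.i.d. colored with no spatial texture — the green-fraction
    statistic is spatially agnostic.  Returns (image, planted green count).
    """
    if not (0.0 <= green_fraction_target <= 100.0):
        raise ValueError("green_fraction_target must be in [0, 100]")
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be positive")
    rng = np.random.default_rng(seed)
    total = width * height
    n_green = int(round(green_fraction_target / 100.0 * total))

    green_pal = _palette(rng, (55, 112), (0.35, 1.0), (0.30, 1.0), True, thresholds)
    brown_pal = _palette(rng, (8, 38), (0.25, 0.85), (0.15, 0.75), False, thresholds)
    bg_palettes = [brown_pal]
    if style == "winter_stressed":
        # yellow/brown leaf colors: hue just below the green band
        bg_palettes.append(_palette(rng, (22, 42), (0.45, 0.95), (0.35, 0.95), False, thresholds))
    elif style != "clean":
        raise ValueError(f"unknown style {style!r}")

    flat = np.empty((total, 3), dtype=np.uint8)
    order = rng.permutation(total)
    green_ix = order[:n_green]
    bg_ix = order[n_green:]
    flat[green_ix] = green_pal[rng.integers(0, len(green_pal), n_green)]
    if len(bg_ix):
        which = rng.integers(0, len(bg_palettes), len(bg_ix))
        for j, pal in enumerate(bg_palettes):
            sel = bg_ix[which == j]
            flat[sel] = pal[rng.integers(0, len(pal), len(sel))]
    return flat.reshape(height, width, 3), n_green


# ---------------------------------------------------------------------------
# Whole-dataset convenience


def simulate_dataset(scenario: CanopyScenario):
    """Generate the full (traits, spectra, images) bundle for a scenario.

    Images are keyed ``(plot_id, date_id)`` and each carries its ground-truth
    green count; image green targets come from the closure curve applied to
    each plot's dry weight.
    """
    traits = generate_traits(scenario)
    spectra = generate_spectra(traits, scenario)
    w, h = scenario.image_size
    images: dict[tuple[str, str], tuple[np.ndarray, int]] = {}
    for t in traits:
        target = fractional_cover(t.dry_weight, scenario.cover_saturation_k) * 100.0
        img_seed = int(
            np.random.SeedSequence(
                (scenario.seed, 3, zlib.crc32(f"{t.plot_id}:{t.date_id}".encode()))
            ).generate_state(1)[0]
        ) % (2**31)
        images[(t.plot_id, t.date_id)] = generate_image(
            target, w, h, style=scenario.image_style, seed=img_seed
        )
    return traits, spectra, images
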
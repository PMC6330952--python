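"""Synthetic forest scenes with known ground truth.

The generator emulates the statistical structure every pipeline stage
assumes, at the scale of a 1 m-resolution airborne acquisition over an
open pine/oak woodland:

* circular-to-elliptical crowns on a non-vegetated background, placed
  without overlap (minimum center spacing above the sum of radii);
* per-pixel spectra drawn from a per-species multivariate normal and
  multiplied by a radial brightness profile that peaks at the crown apex,
  so near-infrared local maxima sit on tree tops;
* NDVI above the vegetation threshold inside crowns and below it on the
  background, with margin;
* a canopy height model shaped as a cone of the tree's true height over
  each crown;
* a field stem table at the crown apices with Gaussian positional jitter,
  stem diameters back-computed from the crown-radius allometry
  R = a_R·(H·D)^b_R, and the measured crown radius present only for a
  configurable fraction of stems.

Species mean spectra sit at the vertices of a regular simplex in spectral
space, scaled so that every species pair has the same target
Jeffries–Matusita separability under the shared diagonal covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.affinity import rotate, scale
from shapely.geometry import Point

from .core import (
    Affine,
    Crown,
    CrownSet,
    FieldTree,
    FieldTreeSet,
    HyperCube,
    RasterGrid,
)

DEFAULT_SPECIES = ("PIPA", "QULA", "PITA", "QUGE")


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene; defaults give the standard test scene."""

    shape: tuple[int, int] = (100, 120)
    pixel_size: float = 1.0
    n_crowns: int = 25
    radius_range: tuple[float, float] = (2.0, 5.0)
    ellipticity: float = 0.25  # max relative shortening of the minor axis
    species: Sequence[str] = DEFAULT_SPECIES
    n_bands: int = 50
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    jm_target: float = 1.9  # pairwise species separability in [0, 2)
    spectral_noise_sd: float = 0.005  # per-band reflectance sd
    profile_decay: float = 0.6  # apex-to-edge brightness drop (fraction)
    chm_noise_sd: float = 0.3  # m
    stem_jitter_sd: float = 0.5  # m, positional jitter of field stems
    radius_fraction: float = 0.7  # stems with a measured crown radius
    allometry_radius: tuple[float, float] = (0.5, 0.4)  # (a_R, b_R): R = a(HD)^b
    allometry_height: tuple[float, float] = (8.0, 0.9)  # (a_H, b_H): H = aR^b
    plot_grid: tuple[int, int] = (2, 2)  # field plots tiling the scene
    crs: str = "EPSG:32617"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crowns < 0:
            raise ValueError("n_crowns must be >= 0")
        if not 0 < self.jm_target < 2:
            raise ValueError("jm_target must lie in (0, 2)")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("bad radius range")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)

    @property
    def transform(self) -> Affine:
        return Affine.north_up(
            0.0, self.shape[0] * self.pixel_size, self.pixel_size
        )


@dataclass
class SceneTruth:
    """A generated scene plus everything the generator knows about it."""

    cube: HyperCube
    chm: RasterGrid
    crowns: CrownSet
    trees: FieldTreeSet
    apices: list[tuple[int, int]]  # (row, col) apex pixel per crown
    config: SceneConfig = field(repr=False, default=None)


def _vegetation_base(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth leaf-like spectrum: low red, sharp red edge, high NIR plateau."""
    wl = np.asarray(wavelengths)
    green_bump = 0.06 * np.exp(-0.5 * ((wl - 550) / 40.0) ** 2)
    red_edge = 0.45 / (1.0 + np.exp(-(wl - 730) / 12.0))
    return 0.05 + green_bump + red_edge


def _background_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Dry soil/litter: brightness rising gently with wavelength, flat NDVI."""
    wl = np.asarray(wavelengths)
    return 0.18 + 0.12 * (wl - wl[0]) / (wl[-1] - wl[0])


def species_means(config: SceneConfig) -> dict[str, np.ndarray]:
    """Species mean spectra with equal pairwise JM at the configured target.

    The JM target is inverted to a Bhattacharyya distance B and then to a
    mean separation ``delta = sqrt(8·σ²·B)`` valid for the shared diagonal
    covariance; means are placed at base + (delta/√2)·e_k with e_k unit
    vectors on distinct mid-visible bands, which puts every pair exactly
    ``delta`` apart.
    """
    wl = config.wavelengths
    base = _vegetation_base(wl)
    bhatt = -math.log(1.0 - config.jm_target / 2.0)
    delta = math.sqrt(8.0 * config.spectral_noise_sd**2 * bhatt)
    # perturbation bands in the 480-660 nm window, clear of the NDVI bands
    usable = np.where((wl >= 480) & (wl <= 660))[0]
    if len(usable) < len(config.species):
        raise ValueError("not enough bands to separate the configured species")
    picks = usable[np.linspace(0, len(usable) - 1, len(config.species)).astype(int)]
    means = {}
    for name, band in zip(config.species, picks):
        mu = base.copy()
        mu[band] += delta / math.sqrt(2.0)
        means[name] = mu
    return means


def sample_species_pixels(
    config: SceneConfig, species: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n pixel spectra from the species' multivariate normal."""
    mu = species_means(config)[species]
    return rng.normal(mu, config.spectral_noise_sd, size=(n, len(mu)))


def _place_crowns(config: SceneConfig, rng: np.random.Generator):
    """Non-overlapping apex placement by rejection sampling."""
    nrows, ncols = config.shape
    r_lo, r_hi = config.radius_range
    px = config.pixel_size
    placed: list[tuple[int, int, float, float, float]] = []  # row, col, a, b, theta
    attempts = 0
    while len(placed) < config.n_crowns:
        attempts += 1
        if attempts > 200 * max(config.n_crowns, 1):
            raise ValueError("infeasible packing: too many crowns for the extent")
        a = rng.uniform(r_lo, r_hi)
        b = a * (1.0 - config.ellipticity * rng.uniform())
        theta = rng.uniform(0, math.pi)
        margin = int(math.ceil(a / px)) + 1
        if nrows - margin <= margin or ncols - margin <= margin:
            raise ValueError("infeasible packing: crowns larger than the extent")
        row = int(rng.integers(margin, nrows - margin))
        col = int(rng.integers(margin, ncols - margin))
        ok = True
        for prow, pcol, pa, _, _ in placed:
            spacing = math.hypot(row - prow, col - pcol) * px
            if spacing <= a + pa + px:
                ok = False
                break
        if ok:
            placed.append((row, col, a, b, theta))
    return placed


def make_scene(config: Optional[SceneConfig] = None) -> SceneTruth:
    """Generate a full scene: cube, CHM, truth crowns and field stems.

    Deterministic under ``config.seed``. Raises if the requested crowns
    cannot be packed without overlap, and asserts at generation that each
    crown's near-infrared maximum sits on its apex pixel.
    """
    if config is None:
        config = SceneConfig()
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    wl = config.wavelengths
    transform = config.transform
    px = config.pixel_size

    cube_data = rng.normal(
        _background_spectrum(wl)[:, None, None],
        config.spectral_noise_sd,
        size=(config.n_bands, nrows, ncols),
    )
    chm_data = np.clip(rng.normal(0.0, config.chm_noise_sd, (nrows, ncols)), 0, None)

    means = species_means(config)
    a_r, b_r = config.allometry_radius
    a_h, b_h = config.allometry_height
    nir_band = int(np.argmin(np.abs(wl - 810.0)))

    placements = _place_crowns(config, rng)
    rows_grid, cols_grid = np.indices((nrows, ncols))
    crowns: list[Crown] = []
    trees: list[FieldTree] = []
    apices: list[tuple[int, int]] = []
    plot_rows, plot_cols = config.plot_grid

    for k, (row, col, ax_a, ax_b, theta) in enumerate(placements, start=1):
        species = config.species[(k - 1) % len(config.species)]
        # elliptical radial coordinate of every pixel center, apex at (row, col)
        dy = (rows_grid - row) * px
        dx = (cols_grid - col) * px
        u = (dx * math.cos(theta) + dy * math.sin(theta)) / ax_a
        v = (-dx * math.sin(theta) + dy * math.cos(theta)) / ax_b
        rhat = np.sqrt(u**2 + v**2)
        member = rhat <= 1.0
        profile = 1.0 - config.profile_decay * rhat[member]

        n_member = int(member.sum())
        spectra = rng.normal(
            means[species], config.spectral_noise_sd, size=(n_member, config.n_bands)
        )
        cube_data[:, member] = (spectra * profile[:, None]).T

        r_eq = math.sqrt(ax_a * ax_b)
        height = a_h * r_eq**b_h
        chm_data[member] = np.clip(
            height * (1.0 - rhat[member])
            + rng.normal(0.0, config.chm_noise_sd, n_member),
            0.0,
            None,
        )
        # anchor the CHM apex exactly at the true height
        chm_data[row, col] = height

        nir = cube_data[nir_band]
        apex_val = nir[row, col]
        assert apex_val >= nir[member].max() - 1e-12, (
            f"crown {k}: NIR maximum not at apex"
        )

        cx, cy = transform.pixel_center(row, col)
        ellipse = scale(Point(cx, cy).buffer(1.0, quad_segs=64), ax_a, ax_b)
        ellipse = rotate(ellipse, -math.degrees(theta), origin=(cx, cy))
        plot_id = int(row * plot_rows // nrows) * plot_cols + int(
            col * plot_cols // ncols
        )
        crowns.append(
            Crown(
                crown_id=k,
                geometry=ellipse,
                plot_id=plot_id,
                species=species,
                height_m=height,
                radius_m=r_eq,
            )
        )
        apices.append((row, col))

        hd = (r_eq / a_r) ** (1.0 / b_r)
        dbh = hd / height
        measured = rng.uniform() < config.radius_fraction
        trees.append(
            FieldTree(
                stem_id=k,
                x=float(cx + rng.normal(0.0, config.stem_jitter_sd)),
                y=float(cy + rng.normal(0.0, config.stem_jitter_sd)),
                height_m=height,
                dbh_cm=dbh,
                crown_radius_m=r_eq if measured else None,
            )
        )

    bands = [
        RasterGrid(cube_data[i], transform, crs=config.crs)
        for i in range(config.n_bands)
    ]
    return SceneTruth(
        cube=HyperCube(bands, wl),
        chm=RasterGrid(chm_data, transform, crs=config.crs),
        crowns=CrownSet(crowns, crs=config.crs),
        trees=FieldTreeSet(trees, crs=config.crs),
        apices=apices,
        config=config,
    )


def make_allometric_sample(
    a: float,
    b: float,
    noise_sd: float,
    n: int,
    seed: int,
    x_range: tuple[float, float] = (1.0, 100.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) sample with y = a·x^b + Gaussian noise, deterministic under seed."""
    if a <= 0:
        raise ValueError("a must be > 0")
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=n)
    y = a * x**b + rng.normal(0.0, noise_sd, size=n)
    return x, y
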
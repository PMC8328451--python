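"""Synthetic alpine landscapes, snow fields, NDSI scenes and reindeer tracks.

Everything downstream of raw data ingestion can be exercised on the output of
this module: a fractal terrain, a snow-depth field that accumulates in
depressions (negative TPI) and thins along a west-to-east precipitation
gradient, a fine-grid binary snow-free layer (35 cm depth rule), multi-scene
NDSI rasters coherent with the true snow cover, a lichen-cover layer biased
toward wind-blown (snow-free) ridges, and GPS-like tracks whose step choice
prefers snow-free cells with a known log-odds strength ``beta_snowfree``.

All generators are pure functions of ``(cfg.seed, cfg)``: every stage draws
from its own child stream of the config seed, so regenerating any one layer
reproduces it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .grid import Grid
from .terrain import (
    SNOW_FREE_DEPTH_CM,
    aggregate_fraction,
    classify_snow_free_fine,
    tpi,
)
from .tracks import Track

# NDSI endpoints of the monotone snow-cover -> NDSI map: bare alpine ground
# sits slightly negative, full spring snow cover high positive.
NDSI_BARE = -0.15
NDSI_SNOW = 0.85

# child-stream ids, so each layer has an independent but seed-locked RNG
_REFERENCE_ROUGHNESS = 3.0  # exponent at which terrain_relief is calibrated

_STREAM_TERRAIN = 1
_STREAM_SNOW = 2
_STREAM_NDSI = 3
_STREAM_LICHEN = 4
_STREAM_TRACKS = 5


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic landscape and tracking season.

    The defaults emulate a scaled-down tile of an alpine winter range:
    1 m fine cells aggregated 30x to a Landsat-like 30 m grid, mean late-April
    snow depth 131 cm, snow scoured from ridges (positive TPI) into
    depressions, a west->east thinning trend, six NDSI scenes, and animals
    fixed every 3 h whose steps prefer snow-free ground.
    """

    seed: int = 0
    extent: int = 600                # fine cells per side; must divide by coarse_factor
    fine_cell: float = 1.0           # m
    coarse_factor: int = 30          # fine cells per coarse cell side
    terrain_roughness: float = 3.0   # spectral decay exponent (larger = smoother)
    terrain_relief: float = 40.0     # target sd of elevation (m)
    dem_base: float = 1200.0         # m a.s.l., mid-alpine plateau
    snow_base: float = 150.0         # cm, depth baseline at the western edge;
                                     # with the east gradient the domain mean
                                     # lands near the 131 cm late-April norm
    snow_tpi_gain: float = 5.0       # cm of depth per m of (negative) TPI
    snow_east_gradient: float = -100.0  # cm per km eastward (thinning east)
    noise_sd: float = 15.0           # cm, small-scale depth noise
    noise_corr_length: float = 10.0  # m, correlation length of depth noise
    n_scenes: int = 6
    ndsi_noise_sd: float = 0.08
    lichen_noise_sd: float = 10.0    # percentage points
    n_animals: int = 4
    n_steps: int = 500
    step_interval: float = 3.0       # hours between fixes
    beta_snowfree: float = 2.0       # log-odds preference for snow-free cells
    n_candidates: int = 10           # step proposals per move
    step_scale: float = 200.0        # m, sd of isotropic step displacement
    origin_x: float = 0.0
    origin_y: float | None = None    # default: extent * fine_cell (top-left)
    start_time: str = "2015-01-15T00:00:00"
    tpi_window: float = 30.0         # m, analysis TPI window (predictor scale)
    snow_tpi_window: float = 90.0    # m, scale of wind snow redistribution

    def __post_init__(self) -> None:
        if self.extent <= 0 or self.extent % self.coarse_factor:
            raise ValueError(
                f"extent {self.extent} must be a positive multiple of "
                f"coarse_factor {self.coarse_factor}"
            )
        for name in ("noise_sd", "ndsi_noise_sd", "lichen_noise_sd", "step_scale",
                     "terrain_relief", "fine_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_candidates < 2:
            raise ValueError("n_candidates must be >= 2")
        if self.origin_y is None:
            self.origin_y = self.extent * self.fine_cell

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SyntheticBundle:
    """One complete synthetic dataset plus the parameters that generated it."""

    dem: Grid
    tpi: Grid                 # fine-grid TPI used by the snow model
    snow_depth: Grid          # cm, fine
    snow_free_fine: Grid      # binary, fine
    snow_frac_true: Grid      # true snow-free fraction, coarse
    ndsi_scenes: list[Grid]   # coarse
    lichen: Grid              # %, coarse
    tracks: list[Track]
    truth: dict = field(default_factory=dict)


def generate_terrain(cfg: SyntheticConfig) -> Grid:
    """Spatially autocorrelated elevation surface via spectral synthesis.

    White Gaussian noise is shaped in the Fourier domain with a power-law
    amplitude ``(1 + k)**(-roughness/2)`` (k in cycles per domain, DC
    removed), the classic one-parameter fractal-surface recipe:
    ``terrain_roughness`` alone controls how fast spatial autocorrelation
    decays.  The overall gain is a constant calibrated analytically so the
    surface sd equals ``terrain_relief`` at the default roughness; rougher
    settings yield more variance, and in the large-roughness limit every
    nonzero frequency decays, so the surface tends to a constant (variance
    collapses to zero).
    """
    n = cfg.extent
    rng = cfg.rng(_STREAM_TERRAIN)
    noise = rng.standard_normal((n, n))
    fy = np.fft.fftfreq(n)[:, None] * n  # cycles per domain
    fx = np.fft.fftfreq(n)[None, :] * n
    k = np.hypot(fy, fx)
    amp = np.where(k > 0, (1.0 + k) ** (-cfg.terrain_roughness / 2.0), 0.0)
    raw = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    # gain fixed at the reference exponent, independent of cfg roughness
    amp_ref = np.where(k > 0, (1.0 + k) ** (-_REFERENCE_ROUGHNESS / 2.0), 0.0)
    ref_sd = float(np.sqrt((amp_ref**2).mean()))
    surface = raw * (cfg.terrain_relief / ref_sd) if ref_sd > 0 else raw
    return Grid(
        cfg.dem_base + surface,
        origin_x=cfg.origin_x,
        origin_y=cfg.origin_y,
        cell=cfg.fine_cell,
    )


def generate_snow(cfg: SyntheticConfig, dem: Grid) -> tuple[Grid, Grid, Grid]:
    """Snow depth (cm) and the binary snow-free layer on the fine grid.

    Depth = max(0, base + gain * (-TPI) + east_gradient * x_km + noise): snow
    is scoured off ridges (positive TPI) and redistributed into depressions,
    with less snow toward the (continental) east.  Wind redistribution acts at
    a broader scale than the analysis TPI, so the snow model uses TPI at
    ``snow_tpi_window`` (ridges wider than one coarse cell can blow fully
    free); the noise term is spatially correlated over ``noise_corr_length``
    because depth does not vary independently square meter by square meter.
    Returns ``(snow_depth, snow_free_fine, tpi_fine)`` where ``tpi_fine`` is
    the analysis-scale (``tpi_window``) TPI predictor.
    """
    tpi_fine = tpi(dem, window=cfg.tpi_window)
    tpi_snow = tpi(dem, window=cfg.snow_tpi_window)
    x_km = (dem.x_centers()[None, :] - dem.origin_x) / 1000.0
    rng = cfg.rng(_STREAM_SNOW)
    noise = rng.standard_normal(dem.shape)
    if cfg.noise_corr_length > 0:
        sigma = cfg.noise_corr_length / dem.cell
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    depth = (
        cfg.snow_base
        + cfg.snow_tpi_gain * (-tpi_snow.values)
        + cfg.snow_east_gradient * x_km
        + cfg.noise_sd * noise
    )
    depth = np.maximum(depth, 0.0)  # physical non-negativity before thresholding
    depth_grid = dem.like(depth)
    snow_free = classify_snow_free_fine(depth_grid, SNOW_FREE_DEPTH_CM)
    return depth_grid, snow_free, tpi_fine


def ndsi_from_snow_cover(snow_cover_fraction: np.ndarray) -> np.ndarray:
    """Monotone map from snow-COVERED fraction in [0,1] to an NDSI value."""
    return NDSI_BARE + (NDSI_SNOW - NDSI_BARE) * snow_cover_fraction


def generate_ndsi_scenes(cfg: SyntheticConfig, snow_fraction_true: Grid) -> list[Grid]:
    """Noisy NDSI scenes coherent with the true coarse snow-free fraction.

    Each scene is the monotone map of the snow-covered fraction
    (1 - snow-free fraction) plus independent Gaussian scene noise, clipped
    to the NDSI range [-1, 1].
    """
    rng = cfg.rng(_STREAM_NDSI)
    cover = 1.0 - snow_fraction_true.values
    base = ndsi_from_snow_cover(cover)
    scenes = []
    for _ in range(cfg.n_scenes):
        vals = base + cfg.ndsi_noise_sd * rng.standard_normal(base.shape)
        scenes.append(snow_fraction_true.like(np.clip(vals, -1.0, 1.0)))
    return scenes


def generate_lichen(cfg: SyntheticConfig, snow_frac_true: Grid) -> Grid:
    """Lichen cover (%) on the coarse grid, higher on wind-blown ridges.

    Lichen heaths develop where snow is regularly blown off, so expected
    cover rises with the snow-free fraction; noisy, clipped to [0, 100].
    """
    rng = cfg.rng(_STREAM_LICHEN)
    vals = (
        5.0
        + 60.0 * snow_frac_true.values
        + cfg.lichen_noise_sd * rng.standard_normal(snow_frac_true.shape)
    )
    return snow_frac_true.like(np.clip(vals, 0.0, 100.0))


def _reflect(coord: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi) by reflection at both boundaries."""
    span = hi - lo
    z = np.mod(coord - lo, 2.0 * span)
    z = np.where(z >= span, 2.0 * span - z, z)
    # the fold maps exactly-on-upper-edge to hi; nudge inside the half-open cell
    return np.minimum(lo + z, hi - 1e-9)


def simulate_tracks(cfg: SyntheticConfig, snow_free_fine: Grid) -> list[Track]:
    """Discrete-choice movement with a known snow-free preference.

    At each 3-h step an animal draws ``n_candidates`` isotropic Gaussian
    displacement proposals (sd ``step_scale``), reflects any proposal falling
    outside the grid back inside, and picks candidate ``j`` with probability
    proportional to ``exp(beta_snowfree * I[snow-free at j])``.  With
    ``beta_snowfree = 0`` this is an unbiased random walk, so use equals
    availability in expectation; the coefficient is recoverable by the
    downstream selection analysis.
    """
    rng = cfg.rng(_STREAM_TRACKS)
    xmin, ymin, xmax, ymax = snow_free_fine.bounds
    n_a, n_s, n_c = cfg.n_animals, cfg.n_steps, cfg.n_candidates
    x = rng.uniform(xmin, xmax, size=n_a)
    y = rng.uniform(ymin + 1e-9, ymax, size=n_a)
    xs = np.empty((n_s + 1, n_a))
    ys = np.empty((n_s + 1, n_a))
    xs[0], ys[0] = x, y
    for s in range(n_s):
        dx = rng.normal(0.0, cfg.step_scale, size=(n_a, n_c))
        dy = rng.normal(0.0, cfg.step_scale, size=(n_a, n_c))
        cx = _reflect(x[:, None] + dx, xmin, xmax)
        cy = _reflect(y[:, None] + dy, ymin, ymax)
        free = snow_free_fine.sample(cx.ravel(), cy.ravel()).reshape(n_a, n_c)
        w = np.exp(cfg.beta_snowfree * np.nan_to_num(free))
        w /= w.sum(axis=1, keepdims=True)
        pick = (rng.uniform(size=(n_a, 1)) > np.cumsum(w, axis=1)).sum(axis=1)
        pick = np.minimum(pick, n_c - 1)
        x = cx[np.arange(n_a), pick]
        y = cy[np.arange(n_a), pick]
        xs[s + 1], ys[s + 1] = x, y
    t0 = np.datetime64(cfg.start_time)
    times = t0 + (np.arange(n_s + 1) * cfg.step_interval * 3600.0).astype("timedelta64[s]").astype("timedelta64[ns]")
    return [
        Track(f"animal_{a:02d}", times, xs[:, a], ys[:, a]) for a in range(n_a)
    ]


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Run every generator stage and return the full synthetic dataset."""
    dem = generate_terrain(cfg)
    snow_depth, snow_free, tpi_fine = generate_snow(cfg, dem)
    frac_true = aggregate_fraction(snow_free, cfg.coarse_factor)
    scenes = generate_ndsi_scenes(cfg, frac_true)
    lichen = generate_lichen(cfg, frac_true)
    trks = simulate_tracks(cfg, snow_free)
    return SyntheticBundle(
        dem=dem,
        tpi=tpi_fine,
        snow_depth=snow_depth,
        snow_free_fine=snow_free,
        snow_frac_true=frac_true,
        ndsi_scenes=scenes,
        lichen=lichen,
        tracks=trks,
        truth=asdict(cfg),
    )
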
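"""Texture stimuli: irregular grids of equiluminant Gabor annuli.

Stimuli are parameterized by two factors. *Contrast heterogeneity* ``zeta``
is the width of the uniform distribution (centered on 0.5) from which each
annulus's Michelson contrast is drawn; the background always uses the full
range [0, 1] (``zeta = 1``). *Grid coarseness* ``rho`` multiplicatively
scales the average center-to-center distance between neighboring annuli.

Geometry is expressed in degrees of visual angle throughout. Rasters use a
lower-left origin: row index increases with the vertical visual coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import as_rng

#: side length (deg) of the square region feeding the oscillator model; its
#: area matches the 9 x 5 deg^2 rectangular figure of the behavioral task
MODEL_REGION_SIDE = 6.7

#: visual-field position of the model-region center: 7 deg eccentricity on the
#: lower-right diagonal, matching the trained figure location
MODEL_REGION_CENTER = (7.0 / np.sqrt(2.0), -7.0 / np.sqrt(2.0))

#: base center-to-center annulus spacing (deg) at grid coarseness rho = 1
BASE_SPACING = 0.9

DEFAULT_DEG_PER_PIXEL = 1.0 / 20.0  # 20 px/deg: >= 3.5 px per carrier cycle


@dataclass(frozen=True)
class AnnulusParams:
    """Geometry and luminance of a single Gabor annulus."""

    diameter: float = 0.7  # deg
    spatial_frequency: float = 5.7  # cycles/deg
    mean_luminance: float = 60.76  # cd/m^2
    background_luminance: float = 60.76  # cd/m^2

    def __post_init__(self):
        if self.diameter <= 0 or self.spatial_frequency <= 0:
            raise ValueError("diameter and spatial_frequency must be positive")
        if self.mean_luminance <= 0 or self.background_luminance <= 0:
            raise ValueError("luminances must be positive")


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the (zeta, rho) condition grid."""

    zeta: float
    rho: float
    zeta_level: int = 0
    rho_level: int = 0

    def __post_init__(self):
        if not 0.0 < self.zeta <= 1.0:
            raise ValueError("zeta must lie in (0, 1]")
        if self.rho < 1.0:
            raise ValueError("rho must be >= 1")


@dataclass(frozen=True)
class FigureGeometry:
    """Rectangular figure region of the behavioral display."""

    width: float = 9.0
    height: float = 5.0
    eccentricity: float = 7.0
    orientation: str = "vertical"  # {"horizontal", "vertical"}
    quadrant: int = 4  # 1..4, counterclockwise from upper-right

    def __post_init__(self):
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be 'horizontal' or 'vertical'")
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError("quadrant must be 1..4")

    @property
    def bbox_size(self) -> tuple[float, float]:
        """(x-extent, y-extent): the long side is vertical for 'vertical'."""
        if self.orientation == "vertical":
            return (self.height, self.width)
        return (self.width, self.height)


@dataclass
class TexturePatch:
    """A rendered luminance raster plus annulus metadata.

    ``luminance_raster[row, col]`` is in cd/m^2; ``origin`` gives the visual
    coordinates (deg) of the raster's lower-left corner; ``annuli`` holds
    ``(center_x, center_y, contrast)`` per annulus in visual degrees.
    """

    luminance_raster: np.ndarray
    deg_per_pixel: float
    origin: tuple[float, float]
    annuli: list = field(default_factory=list)
    background_luminance: float = 60.76

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Visual coordinates (deg) of pixel centers: (x, y), each 2D."""
        ny, nx = self.luminance_raster.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.deg_per_pixel
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.deg_per_pixel
        return np.meshgrid(x, y)

    def save(self, path_stem: str | Path) -> None:
        """Write a 16-bit grayscale PNG plus a JSON metadata sidecar."""
        from PIL import Image

        path_stem = Path(path_stem)
        raster = self.luminance_raster
        peak = max(raster.max(), 1e-12)
        img = np.round(raster / peak * 65535).astype(np.uint16)
        Image.fromarray(img[::-1]).save(path_stem.with_suffix(".png"))
        meta = {
            "deg_per_pixel": self.deg_per_pixel,
            "origin": list(self.origin),
            "peak_luminance": float(peak),
            "background_luminance": self.background_luminance,
            "annuli": [[float(v) for v in a] for a in self.annuli],
        }
        path_stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def build_condition_grid(n_zeta: int = 5, n_rho: int = 5) -> list[StimulusCondition]:
    """Cartesian grid of conditions: zeta over [0.01, 1], rho over [1, 1.5].

    The default 5 x 5 grid reproduces the behavioral design's 25 conditions
    (zeta in {0.01, 0.2575, 0.505, 0.7525, 1}, rho in {1, 1.125, ..., 1.5});
    other sizes space levels evenly over the same ranges.
    """
    if n_zeta < 2 or n_rho < 2:
        raise ValueError("need at least 2 levels per factor")
    zetas = np.linspace(0.01, 1.0, n_zeta)
    rhos = np.linspace(1.0, 1.5, n_rho)
    return [
        StimulusCondition(zeta=float(z), rho=float(r), zeta_level=i, rho_level=j)
        for i, z in enumerate(zetas)
        for j, r in enumerate(rhos)
    ]


def sample_contrasts(n: int, zeta: float, rng=None) -> np.ndarray:
    """Draw ``n`` contrasts i.i.d. from U[0.5 - zeta/2, 0.5 + zeta/2]."""
    if not 0.0 < zeta <= 1.0:
        raise ValueError("zeta must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    return rng.uniform(0.5 - zeta / 2.0, 0.5 + zeta / 2.0, size=n)


def place_annulus_centers(
    region_width: float,
    region_height: float,
    rho: float,
    annulus: AnnulusParams | None = None,
    rng=None,
    base_spacing: float = BASE_SPACING,
) -> np.ndarray:
    """Jittered regular-grid annulus centers, relative to the region center.

    Centers start on a square grid with spacing ``base_spacing * rho``
    anchored at the region center, then each is displaced in a uniform random
    direction by a radius drawn from U[0, (spacing - diameter)/2]. The jitter
    bound guarantees annuli stay pairwise non-overlapping and keeps the mean
    nearest-neighbor distance proportional to ``rho``.
    """
    annulus = annulus or AnnulusParams()
    rng = as_rng(rng)
    spacing = base_spacing * rho
    if spacing < annulus.diameter:
        raise ValueError("spacing smaller than annulus diameter")
    # grid anchored at region center; only annuli fully inside the region
    half_w = region_width / 2.0 - annulus.diameter / 2.0
    half_h = region_height / 2.0 - annulus.diameter / 2.0
    nx = 2 * int(np.floor(half_w / spacing)) + 1
    ny = 2 * int(np.floor(half_h / spacing)) + 1
    if nx * ny < 4:
        raise ValueError("region too small for at least 4 annuli at this coarseness")
    gx = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    gy = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    xs, ys = np.meshgrid(gx, gy)
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    max_jitter = (spacing - annulus.diameter) / 2.0
    radius = rng.uniform(0.0, max_jitter, size=len(centers))
    angle = rng.uniform(0.0, 2.0 * np.pi, size=len(centers))
    centers = centers + np.column_stack([radius * np.cos(angle), radius * np.sin(angle)])
    return centers


def _profile_phase(annulus: AnnulusParams) -> float:
    """Carrier phase making the annulus profile zero-mean over its support.

    Solves  integral_0^R  w(r) cos(2 pi f r + phi) r dr = 0  for phi, with w
    the annular Gaussian envelope; the area weight r accounts for the 2D
    integral of the radially symmetric profile.
    """
    R = annulus.diameter / 2.0
    r = np.linspace(0.0, R, 2001)
    w = _envelope(r, annulus)
    arg = 2.0 * np.pi * annulus.spatial_frequency * r
    A = np.trapezoid(w * np.cos(arg) * r, r)
    B = np.trapezoid(w * np.sin(arg) * r, r)
    return float(np.arctan2(A, B))


def _envelope(r: np.ndarray, annulus: AnnulusParams) -> np.ndarray:
    """Annular Gaussian envelope peaking at radius diameter/4."""
    r0 = annulus.diameter / 4.0
    sigma_env = annulus.diameter / 8.0
    return np.exp(-((r - r0) ** 2) / (2.0 * sigma_env**2))


def render_patch(
    centers: np.ndarray,
    contrasts: np.ndarray,
    annulus: AnnulusParams | None = None,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
    origin: tuple[float, float] = (0.0, 0.0),
    size: tuple[float, float] = (MODEL_REGION_SIDE, MODEL_REGION_SIDE),
) -> TexturePatch:
    """Rasterize annuli at ``centers`` (visual deg) with the given contrasts.

    Each annulus is L(x) = Lbar * (1 + c * g(|x - center|)) with g a zero-mean
    carrier-times-envelope ring profile normalized to peak magnitude 1 and a
    hard cutoff at radius diameter/2; pixels outside every annulus equal the
    background luminance exactly.
    """
    annulus = annulus or AnnulusParams()
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    contrasts = np.atleast_1d(np.asarray(contrasts, dtype=float))
    if centers.size == 0:
        centers = centers.reshape(0, 2)
    if len(centers) != len(contrasts):
        raise ValueError("centers and contrasts must have equal length")
    if np.any((contrasts < 0) | (contrasts > 1)):
        raise ValueError("contrasts must lie in [0, 1]")
    if deg_per_pixel <= 0:
        raise ValueError("deg_per_pixel must be positive")

    nx = int(round(size[0] / deg_per_pixel))
    ny = int(round(size[1] / deg_per_pixel))
    raster = np.full((ny, nx), annulus.background_luminance, dtype=float)
    phi0 = _profile_phase(annulus)
    R = annulus.diameter / 2.0
    f = annulus.spatial_frequency

    px = origin[0] + (np.arange(nx) + 0.5) * deg_per_pixel
    py = origin[1] + (np.arange(ny) + 0.5) * deg_per_pixel
    for (cx, cy), c in zip(centers, contrasts):
        i0 = max(0, int(np.floor((cx - R - origin[0]) / deg_per_pixel)) - 1)
        i1 = min(nx, int(np.ceil((cx + R - origin[0]) / deg_per_pixel)) + 1)
        j0 = max(0, int(np.floor((cy - R - origin[1]) / deg_per_pixel)) - 1)
        j1 = min(ny, int(np.ceil((cy + R - origin[1]) / deg_per_pixel)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        xx, yy = np.meshgrid(px[i0:i1], py[j0:j1])
        r = np.hypot(xx - cx, yy - cy)
        support = r < R
        if not support.any():
            continue
        g = _envelope(r, annulus) * np.cos(2.0 * np.pi * f * r + phi0)
        g = np.where(support, g, 0.0)
        # recenter on the discrete support for exact equiluminance, then
        # renormalize so contrast c maps to peak modulation c
        g_sup = g[support]
        g_sup = g_sup - g_sup.mean()
        peak = np.max(np.abs(g_sup))
        if peak > 0:
            g_sup = g_sup / peak
        block = raster[j0:j1, i0:i1]
        block[support] = annulus.mean_luminance * (1.0 + c * g_sup)
        raster[j0:j1, i0:i1] = block

    return TexturePatch(
        luminance_raster=raster,
        deg_per_pixel=deg_per_pixel,
        origin=tuple(origin),
        annuli=[(float(cx), float(cy), float(c)) for (cx, cy), c in zip(centers, contrasts)],
        background_luminance=annulus.background_luminance,
    )


def generate_model_patch(
    condition: StimulusCondition,
    rng=None,
    annulus: AnnulusParams | None = None,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
    region_center: tuple[float, float] = MODEL_REGION_CENTER,
    base_spacing: float = BASE_SPACING,
    margin: float = 2.0,
    render: bool = True,
) -> TexturePatch:
    """Render the 6.7 x 6.7 deg model-input patch for one condition.

    Annuli are placed at coarseness ``rho`` and given contrasts drawn at
    heterogeneity ``zeta``; the patch is centered at 7 deg eccentricity.
    The placement region extends ``margin`` degrees beyond the rendered
    raster on every side: the model region is a cutout of a larger figure
    texture, so receptive fields near the patch border pool from the same
    annulus statistics as central ones instead of seeing an artificial empty
    rim. Out-of-raster annuli are kept in the metadata (they drive
    element-level pooling) but clipped from the raster.
    """
    annulus = annulus or AnnulusParams()
    rng = as_rng(rng)
    placed_side = MODEL_REGION_SIDE + 2.0 * margin
    rel = place_annulus_centers(
        placed_side, placed_side, condition.rho, annulus, rng, base_spacing
    )
    centers = rel + np.asarray(region_center)
    contrasts = sample_contrasts(len(centers), condition.zeta, rng)
    origin = (
        region_center[0] - MODEL_REGION_SIDE / 2.0,
        region_center[1] - MODEL_REGION_SIDE / 2.0,
    )
    if not render:
        # annulus metadata only (element-level pooling needs no raster)
        return TexturePatch(
            luminance_raster=np.full((1, 1), annulus.background_luminance),
            deg_per_pixel=deg_per_pixel,
            origin=origin,
            annuli=[(float(x), float(y), float(c)) for (x, y), c in zip(centers, contrasts)],
            background_luminance=annulus.background_luminance,
        )
    return render_patch(centers, contrasts, annulus, deg_per_pixel, origin)


def _sample_figure_rect(figure: FigureGeometry, rng) -> tuple[float, float, float, float]:
    """Sample a figure rectangle (cx, cy, w, h) inside the figure's quadrant."""
    for _ in range(1000):
        long_side = figure.width + rng.uniform(-0.7, 0.7)
        short_side = figure.height + rng.uniform(-0.4, 0.4)
        if figure.orientation == "vertical":
            w, h = short_side, long_side
        else:
            w, h = long_side, short_side
        ecc = figure.eccentricity + rng.uniform(-1.0, 1.0)
        ang = rng.uniform(0.05, np.pi / 2 - 0.05)
        sx = 1.0 if figure.quadrant in (1, 4) else -1.0
        sy = 1.0 if figure.quadrant in (1, 2) else -1.0
        cx, cy = sx * ecc * np.cos(ang), sy * ecc * np.sin(ang)
        if abs(cx) - w / 2.0 > 0 and abs(cy) - h / 2.0 > 0:
            return cx, cy, w, h
    raise ValueError("figure cannot be placed inside a single quadrant")


def generate_full_display(
    condition: StimulusCondition,
    figure: FigureGeometry | None = None,
    rng=None,
    annulus: AnnulusParams | None = None,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
    field_size: tuple[float, float] = (26.6, 20.0),
    base_spacing: float = BASE_SPACING,
) -> TexturePatch:
    """Full-field display: figure at heterogeneity zeta, background at zeta=1.

    The figure's polar angle is randomized within its quadrant under the
    constraint that the rectangle stays entirely inside that quadrant.
    """
    figure = figure or FigureGeometry()
    annulus = annulus or AnnulusParams()
    rng = as_rng(rng)
    cx, cy, w, h = _sample_figure_rect(figure, rng)
    centers = place_annulus_centers(
        field_size[0], field_size[1], condition.rho, annulus, rng, base_spacing
    )
    in_figure = (np.abs(centers[:, 0] - cx) <= w / 2.0) & (
        np.abs(centers[:, 1] - cy) <= h / 2.0
    )
    contrasts = sample_contrasts(len(centers), 1.0, rng)
    if in_figure.any():
        contrasts[in_figure] = sample_contrasts(int(in_figure.sum()), condition.zeta, rng)
    origin = (-field_size[0] / 2.0, -field_size[1] / 2.0)
    patch = render_patch(centers, contrasts, annulus, deg_per_pixel, origin, field_size)
    patch.figure_rect = (cx, cy, w, h)  # type: ignore[attr-defined]
    return patch
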
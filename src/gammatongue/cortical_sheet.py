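"""Retinotopic oscillator sheet: complex-log map, RF sizes, initial coupling.

The sheet places an n x n regular grid of receptive-field (RF) centers over
the model's square region of visual space, maps them to cortical coordinates
with the Schwartz monopole map w = alpha * ln(z + a), assigns each oscillator
an eccentricity-scaled Gaussian RF, and derives the distance-dependent
session-1 coupling matrix K1_ij = gamma * exp(-lambda * d_ij).

Because cortical magnification falls with eccentricity, oscillators that are
equally spaced in the visual field are *not* equally spaced on the cortical
surface: foveal-ward pairs sit further apart (stronger magnification) and are
therefore more strongly coupled than eccentric pairs at the same visual
separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .stimuli import MODEL_REGION_CENTER, MODEL_REGION_SIDE


@dataclass(frozen=True)
class RetinotopyParams:
    """Parameters of the monopole complex-log map (generic human values).

    ``alpha`` is the map scale in centimeters of cortex: the implied foveal
    magnification alpha/a ~ 13 mm/deg and the ~2.2 cm extent of the central
    map both match human V1. ``unit_mm`` converts map coordinates to the
    millimeters in which the coupling decay constant is calibrated.
    """

    a: float = 0.7  # foveal shift, deg
    alpha: float = 0.9  # map scale, cm of cortex
    unit_mm: float = 10.0  # mm per map unit (cm -> mm)

    def __post_init__(self):
        if self.a <= 0 or self.alpha <= 0 or self.unit_mm <= 0:
            raise ValueError("a, alpha and unit_mm must be positive")


@dataclass(frozen=True)
class CouplingConfig:
    """Distance-dependent coupling: maximum strength and exponential decay.

    Defaults were calibrated from macaque V1 recordings relating coherence to
    cortical distance and are treated as given constants.
    """

    gamma: float = 24.63
    lam: float = 0.22

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")


@dataclass
class OscillatorSheet:
    """N = n^2 oscillators with visual RF geometry and cortical positions."""

    n: int
    rf_centers: np.ndarray  # (N, 2) visual deg
    rf_sigma: np.ndarray  # (N,) deg
    cortical_coords: np.ndarray  # (N, 2) cortical mm
    distances: np.ndarray  # (N, N) pairwise cortical distances, mm

    @property
    def N(self) -> int:
        return self.n * self.n

    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            n=self.n,
            rf_centers=self.rf_centers,
            rf_sigma=self.rf_sigma,
            cortical_coords=self.cortical_coords,
            distances=self.distances,
        )

    @classmethod
    def load(cls, path: str | Path) -> "OscillatorSheet":
        with np.load(Path(path)) as z:
            return cls(
                n=int(z["n"]),
                rf_centers=z["rf_centers"],
                rf_sigma=z["rf_sigma"],
                cortical_coords=z["cortical_coords"],
                distances=z["distances"],
            )


@dataclass
class CouplingMatrix:
    """Session-indexed symmetric nonnegative coupling, bounded by gamma."""

    session: int
    K: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if np.any(K < 0):
            raise ValueError("coupling strengths must be non-negative")
        self.K = K


def visual_to_cortical(point, params: RetinotopyParams | None = None) -> np.ndarray:
    """Map visual coordinates (deg) to cortical map coordinates.

    Applies the monopole map w = alpha * ln(z + a) to z = x + iy. The map
    preserves the horizontal meridian (real z maps to real w) and compresses
    the periphery: the local magnification |dw/dz| = alpha / |z + a| decreases
    monotonically with eccentricity.
    """
    params = params or RetinotopyParams()
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    z = pts[:, 0] + 1j * pts[:, 1] + params.a
    if np.any(np.abs(z) < 1e-12):
        raise ValueError("point coincides with the map singularity z = -a")
    w = params.alpha * np.log(z)
    out = np.column_stack([w.real, w.imag])
    return out[0] if np.asarray(point).ndim == 1 else out


def rf_diameter(eccentricity) -> np.ndarray | float:
    """Threshold-linear V1 RF diameter (deg): max(0.172 e - 0.25, 1)."""
    e = np.asarray(eccentricity, dtype=float)
    if np.any(e < 0):
        raise ValueError("eccentricity must be non-negative")
    d = np.maximum(0.172 * e - 0.25, 1.0)
    return float(d) if np.isscalar(eccentricity) or d.ndim == 0 else d


def diameter_to_sigma(diameter) -> np.ndarray | float:
    """Gaussian RF standard deviation from diameter: sigma = diameter / 4.

    Composition of the Gaussian-beam relation FWHM = (sqrt(ln 2)/sqrt(2)) * d
    with sigma = FWHM / (2 sqrt(2 ln 2)), which collapses to exactly d/4.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    s = d / 4.0
    return float(s) if np.isscalar(diameter) or s.ndim == 0 else s


def build_sheet(
    region_center: tuple[float, float] = MODEL_REGION_CENTER,
    region_side: float = MODEL_REGION_SIDE,
    n: int = 20,
    params: RetinotopyParams | None = None,
) -> OscillatorSheet:
    """Construct the oscillator sheet for a square visual region.

    RF centers form an n x n regular grid spanning the region; cortical
    coordinates come from the complex-log map, scaled to millimeters; RF
    sigmas follow the threshold-linear diameter rule evaluated at each RF's
    own eccentricity; distances are Euclidean in cortical mm (the unit of
    the coupling decay calibration).
    """
    params = params or RetinotopyParams()
    if n < 2:
        raise ValueError("n must be >= 2")
    half = region_side / 2.0
    gx = region_center[0] + np.linspace(-half, half, n)
    gy = region_center[1] + np.linspace(-half, half, n)
    xs, ys = np.meshgrid(gx, gy)
    rf_centers = np.column_stack([xs.ravel(), ys.ravel()])
    # reject regions touching the singularity at (-a, 0)
    if np.any(np.hypot(rf_centers[:, 0] + params.a, rf_centers[:, 1]) < 1e-9):
        raise ValueError("region touches the retinotopic map singularity")
    cortical = visual_to_cortical(rf_centers, params) * params.unit_mm
    ecc = np.hypot(rf_centers[:, 0], rf_centers[:, 1])
    sigma = diameter_to_sigma(rf_diameter(ecc))
    diff = cortical[:, None, :] - cortical[None, :, :]
    distances = np.hypot(diff[..., 0], diff[..., 1])
    return OscillatorSheet(
        n=n,
        rf_centers=rf_centers,
        rf_sigma=np.asarray(sigma),
        cortical_coords=cortical,
        distances=distances,
    )


def initial_coupling(
    sheet: OscillatorSheet, config: CouplingConfig | None = None
) -> CouplingMatrix:
    """Session-1 coupling K1_ij = gamma * exp(-lambda * d_ij), zero diagonal."""
    config = config or CouplingConfig()
    K = config.gamma * np.exp(-config.lam * sheet.distances)
    np.fill_diagonal(K, 0.0)  # self-coupling is inert (sin 0 = 0); store 0
    return CouplingMatrix(session=1, K=K)
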
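"""Feedforward drive: RF-weighted local contrast -> intrinsic frequency.

Each oscillator pools the stimulus with an isotropic 2D Gaussian weight
centered on its receptive field (RF) and converts the pooled root-mean-square
(RMS) contrast, expressed in percent, into an intrinsic gamma-band frequency
through the physiologically calibrated linear rule nu = 25 + 0.25 * C
(25-50 Hz over 0-100% contrast).

Two pooling granularities are provided:

* ``weighted_rms_contrast`` — the pixel-level definition: weighted RMS of
  per-pixel luminance deviations from the patch mean. Because most pixels
  under an RF are blank background, this dilutes each annulus's contrast by
  its areal coverage.
* ``element_rms_contrast`` — the texture-element definition used by the model
  by default: each Gabor annulus contributes its own Michelson contrast,
  weighted by the Gaussian RF evaluated at the annulus center. Neural
  assemblies thereby extract the (RMS) average contrast of the annuli inside
  their RFs, so the across-oscillator frequency spread tracks the full
  contrast-heterogeneity range; an RF with no element within its pooling
  radius receives zero contrast and idles at the 25 Hz floor. This is the
  pathway under which the network's synchronization collapses at the
  observed contrast-heterogeneity cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cortical_sheet import OscillatorSheet
from .stimuli import TexturePatch

#: multiplies the dimensionless RMS so the contrast feeding the frequency
#: rule is in percent (a 50% mean stimulus contrast lands mid-range)
CONTRAST_PERCENT_SCALE = 100.0

#: pooling radius in RF standard deviations; beyond it a pixel or element
#: contributes nothing (truncation keeps far elements from dominating empty
#: RFs through weight normalization)
POOLING_RADIUS_SIGMA = 4.0


@dataclass
class ContrastField:
    """Per-oscillator local contrast in percent."""

    C: np.ndarray  # (N,), percent


@dataclass
class FrequencyVector:
    """Per-oscillator intrinsic frequency: nu in Hz, omega = 2 pi nu rad/s."""

    nu: np.ndarray
    omega: np.ndarray


def rf_weights(sheet: OscillatorSheet, patch: TexturePatch) -> np.ndarray:
    """Pixel-level Gaussian weights, shape (N, n_pixels), raster order.

    w_ih = exp(-((x_h - X_i)^2 + (y_h - Y_i)^2) / (2 sigma_i^2)); the weight
    at an RF's own center pixel is ~1 and decays monotonically with distance.
    """
    xx, yy = patch.pixel_coords()
    px, py = xx.ravel(), yy.ravel()
    X = sheet.rf_centers[:, 0][:, None]
    Y = sheet.rf_centers[:, 1][:, None]
    sig = sheet.rf_sigma[:, None]
    x0, y0 = patch.origin
    ny, nx = patch.luminance_raster.shape
    x1 = x0 + nx * patch.deg_per_pixel
    y1 = y0 + ny * patch.deg_per_pixel
    reach = 3.0 * sheet.rf_sigma
    if np.any(
        (sheet.rf_centers[:, 0] - reach < x0)
        | (sheet.rf_centers[:, 0] + reach > x1)
        | (sheet.rf_centers[:, 1] - reach < y0)
        | (sheet.rf_centers[:, 1] + reach > y1)
    ):
        warnings.warn("some receptive fields extend beyond the raster by > 3 sigma")
    d2 = (px[None, :] - X) ** 2 + (py[None, :] - Y) ** 2
    return np.exp(-d2 / (2.0 * sig**2))


def weighted_rms_contrast(patch: TexturePatch, weights: np.ndarray) -> ContrastField:
    """Pixel-level weighted RMS contrast per oscillator, in percent.

    C_i = 100 * sqrt( sum_h w_ih (L_h - Lbar)^2 / Lbar^2 / sum_h w_ih ) with
    Lbar the mean luminance over *all* pixels of the patch. Invariant under a
    common rescaling of all luminances.
    """
    L = patch.luminance_raster.ravel()
    Lbar = L.mean()
    if Lbar <= 0:
        raise ValueError("patch mean luminance must be positive")
    dev2 = ((L - Lbar) / Lbar) ** 2
    C = CONTRAST_PERCENT_SCALE * np.sqrt((weights @ dev2) / weights.sum(axis=1))
    return ContrastField(C=C)


def element_rms_contrast(
    sheet: OscillatorSheet,
    patch: TexturePatch,
    pooling_radius_sigma: float = POOLING_RADIUS_SIGMA,
) -> ContrastField:
    """Element-level pooled contrast per oscillator, in percent.

    Each annulus contributes its Michelson contrast c_a with Gaussian weight
    w_ia = exp(-|center_a - RF_i|^2 / (2 sigma_i^2)), truncated beyond
    ``pooling_radius_sigma`` standard deviations:

        C_i = 100 * sqrt( sum_a w_ia c_a^2 / sum_a w_ia ),

    and C_i = 0 for an RF with no element inside its pooling radius (the
    assembly sees blank background). On sparse (coarse) grids some RFs fall
    in gaps and idle at the frequency floor, which is what makes coarser
    grids harder to synchronize.
    """
    if not patch.annuli:
        return ContrastField(C=np.zeros(sheet.N))
    ann = np.asarray(patch.annuli, dtype=float)  # (A, 3): x, y, contrast
    d2 = (
        (sheet.rf_centers[:, 0][:, None] - ann[None, :, 0]) ** 2
        + (sheet.rf_centers[:, 1][:, None] - ann[None, :, 1]) ** 2
    )
    sig2 = sheet.rf_sigma[:, None] ** 2
    w = np.exp(-d2 / (2.0 * sig2))
    w[d2 > (pooling_radius_sigma**2) * sig2] = 0.0
    wsum = w.sum(axis=1)
    C = np.zeros(sheet.N)
    seen = wsum > 0
    C[seen] = CONTRAST_PERCENT_SCALE * np.sqrt(
        (w[seen] @ ann[:, 2] ** 2) / wsum[seen]
    )
    return ContrastField(C=C)


def contrast_to_frequency(C) -> FrequencyVector:
    """Linear contrast-to-frequency rule: nu = 25 + 0.25 * C (C in percent)."""
    C = np.asarray(getattr(C, "C", C), dtype=float)
    if np.any(C < 0):
        raise ValueError("contrast must be non-negative")
    nu = 25.0 + 0.25 * C
    return FrequencyVector(nu=nu, omega=2.0 * np.pi * nu)


class DrivePipeline:
    """Patch -> intrinsic-frequency pipeline for a fixed sheet.

    ``mode="elements"`` (default) pools annulus contrasts directly; the
    weights are cheap and recomputed per patch since annulus positions vary
    trial to trial. ``mode="pixels"`` applies the pixel-level RMS with the
    Gaussian weight matrix cached once for the fixed raster layout.
    """

    def __init__(
        self,
        sheet: OscillatorSheet,
        template_patch: TexturePatch,
        mode: str = "elements",
    ):
        if mode not in ("elements", "pixels"):
            raise ValueError("mode must be 'elements' or 'pixels'")
        self.sheet = sheet
        self.mode = mode
        self._shape = template_patch.luminance_raster.shape
        if mode == "pixels":
            W = rf_weights(sheet, template_patch)
            self._W = W / W.sum(axis=1, keepdims=True)

    def contrast(self, patch: TexturePatch) -> ContrastField:
        if self.mode == "elements":
            return element_rms_contrast(self.sheet, patch)
        if patch.luminance_raster.shape != self._shape:
            raise ValueError("patch raster does not match the cached layout")
        L = patch.luminance_raster.ravel()
        Lbar = L.mean()
        dev2 = ((L - Lbar) / Lbar) ** 2
        return ContrastField(C=CONTRAST_PERCENT_SCALE * np.sqrt(self._W @ dev2))

    def frequencies(self, patch: TexturePatch) -> FrequencyVector:
        return contrast_to_frequency(self.contrast(patch))
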
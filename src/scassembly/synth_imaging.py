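"""Synthetic data for the imaging and statistics stages.

Two generators with known ground truth:

* :func:`synthesize_axis_pair_stack` renders a superresolution-style
  z-stack of two parallel fluorescent chromosome axes: Gaussian-profile
  ridges offset by ±separation/2 along the normals of a midline polyline,
  blurred by an isotropic in-plane Gaussian PSF, modulated by a Gaussian
  focal envelope across slices, on a constant background with Poisson shot
  noise plus Gaussian read noise. Synapsed axes sit ~150 nm apart;
  unsynapsed (alignment without synapsis) axes ~330-370 nm, which is what
  the axis-separation pipeline must recover.
* :func:`synthesize_tubule_counts` draws per-tubule apoptotic-nucleus
  counts from a two-component Poisson mixture: a low baseline rate in
  healthy tubules and a high "burst" rate in the arrested fraction,
  emulating the overdispersed tubule-level TUNEL counts that are
  dichotomized at >= 5 labelled nuclei.

The z-PSF is not modelled beyond the focal envelope: the measured quantity
is in-plane separation. Default pixel size is 40 nm and default PSF FWHM
120 nm (SIM-scale resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_model import ImageStack, Trace

__all__ = [
    "AxisPairGroundTruth",
    "TubuleCountModel",
    "synthesize_axis_pair_stack",
    "synthesize_tubule_counts",
    "write_stack_tiff",
    "read_stack_tiff",
    "DEFAULT_PIXEL_SIZE_NM",
    "DEFAULT_PSF_FWHM_NM",
]

DEFAULT_PIXEL_SIZE_NM = 40.0
DEFAULT_PSF_FWHM_NM = 120.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AxisPairGroundTruth:
    """Known truth for one synthetic axis-pair image stack.

    ``midline`` is the polyline midway between the two axes, in pixel
    coordinates (x=col, y=row); the rendered axes run at +/-
    ``true_separation_nm``/2 along its normals. ``line_fwhm_nm`` is the
    intrinsic axis thickness before PSF blurring (0 = an infinitely thin
    filament, so the rendered cross-profile is the PSF itself); the
    rendered profile of each axis is Gaussian with
    sigma^2 = sigma_line^2 + sigma_psf^2.
    """

    true_separation_nm: float
    midline: np.ndarray
    amplitude: float = 400.0
    psf_fwhm_nm: float = DEFAULT_PSF_FWHM_NM
    line_fwhm_nm: float = 0.0
    background: float = 20.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    focal_envelope_sd_slices: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_separation_nm < 0:
            raise ValueError("separation must be >= 0")
        if self.psf_fwhm_nm <= 0 or self.line_fwhm_nm < 0:
            raise ValueError("psf_fwhm_nm must be > 0, line_fwhm_nm >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        self.midline = np.asarray(self.midline, dtype=float)
        if self.midline.ndim != 2 or self.midline.shape[1] != 2:
            raise ValueError("midline must be an (N, 2) polyline")

    @property
    def total_sigma_nm(self) -> float:
        s_psf = self.psf_fwhm_nm * FWHM_TO_SIGMA
        s_line = self.line_fwhm_nm * FWHM_TO_SIGMA
        return float(np.hypot(s_psf, s_line))


def _resample_polyline(points: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Densely resample a polyline; returns (points, unit normals)."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate midline")
    s = np.arange(0.0, total + spacing / 2, spacing)
    x = np.interp(s, arclen, points[:, 0])
    y = np.interp(s, arclen, points[:, 1])
    p = np.column_stack([x, y])
    tang = np.gradient(p, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1), 1e-12)[:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return p, normals


def synthesize_axis_pair_stack(
    truth: AxisPairGroundTruth,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    n_slices: int = 9,
    shape: tuple[int, int] | None = None,
) -> tuple[ImageStack, Trace]:
    """Render the two-axis z-stack described by ``truth``.

    Returns the stack and the midline :class:`Trace`. Raises if a ridge
    (plus a 3-sigma margin) leaves the frame.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    if n_slices < 1:
        raise ValueError("need >= 1 slice")
    half_px = truth.true_separation_nm / 2.0 / pixel_size_nm
    sigma_px = truth.total_sigma_nm / pixel_size_nm
    mid, normals = _resample_polyline(truth.midline, spacing=0.25)
    ridges = [mid + half_px * normals, mid - half_px * normals]

    if shape is None:
        allpts = np.vstack(ridges)
        margin = 3.0 * sigma_px + 2.0
        h = int(np.ceil(allpts[:, 1].max() + margin)) + 1
        w = int(np.ceil(allpts[:, 0].max() + margin)) + 1
    else:
        h, w = shape
    margin = 3.0 * sigma_px
    for rp in ridges:
        if (
            (rp[:, 0] < margin - 0.5).any()
            or (rp[:, 1] < margin - 0.5).any()
            or (rp[:, 0] > w - 1 - margin + 0.5).any()
            or (rp[:, 1] > h - 1 - margin + 0.5).any()
        ):
            raise ValueError(
                "axis ridge leaves the frame; enlarge shape or reduce separation"
            )

    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    clean = np.zeros(h * w)
    for rp in ridges:
        d, _ = cKDTree(rp).query(pix, k=1)
        clean += truth.amplitude * np.exp(-(d**2) / (2.0 * sigma_px**2))
    clean = clean.reshape(h, w)

    focus = (n_slices - 1) / 2.0
    env = np.exp(
        -((np.arange(n_slices) - focus) ** 2)
        / (2.0 * truth.focal_envelope_sd_slices**2)
    )
    stack = env[:, None, None] * clean[None, :, :] + truth.background

    rng = np.random.default_rng(truth.seed)
    if truth.poisson_noise:
        stack = rng.poisson(stack).astype(float)
    if truth.read_noise_sd > 0:
        stack = stack + rng.normal(0.0, truth.read_noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)
    return (
        ImageStack(voxels=stack, pixel_size_nm=pixel_size_nm),
        Trace(points=mid[:: max(1, len(mid) // 32)].copy()),
    )


# ----------------------------------------------------------------------
# Tubule apoptosis counts
# ----------------------------------------------------------------------

@dataclass
class TubuleCountModel:
    """Two-component Poisson mixture for per-tubule apoptotic counts.

    With probability ``burst_fraction`` a tubule is "bursting" (meiotic
    arrest, many labelled nuclei, rate ``lambda_high``); otherwise it has
    the healthy baseline rate ``lambda_low``.
    """

    n_tubules: int = 200
    lambda_low: float = 0.2
    burst_fraction: float = 0.05
    lambda_high: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValueError("burst_fraction must be in [0, 1]")
        if self.lambda_low < 0 or self.lambda_high < 0:
            raise ValueError("rates must be >= 0")
        if self.n_tubules < 1:
            raise ValueError("n_tubules must be >= 1")

    def expected_fraction_at_or_above(self, threshold: int = 5) -> float:
        """Closed-form P(count >= threshold) under the mixture."""
        from scipy.stats import poisson

        p_hi = float(poisson.sf(threshold - 1, self.lambda_high))
        p_lo = float(poisson.sf(threshold - 1, self.lambda_low))
        return self.burst_fraction * p_hi + (1.0 - self.burst_fraction) * p_lo


def synthesize_tubule_counts(model: TubuleCountModel) -> np.ndarray:
    """Draw per-tubule integer counts; deterministic under the model seed."""
    rng = np.random.default_rng(model.seed)
    burst = rng.random(model.n_tubules) < model.burst_fraction
    rates = np.where(burst, model.lambda_high, model.lambda_low)
    return rng.poisson(rates)


# ----------------------------------------------------------------------
# TIFF round-trip (16-bit single channel)
# ----------------------------------------------------------------------

def write_stack_tiff(stack: ImageStack, path) -> None:
    """Write the stack as an unsigned 16-bit single-channel TIFF."""
    import tifffile

    data = np.clip(np.round(stack.voxels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        metadata={
            "pixel_size_nm": stack.pixel_size_nm,
            "z_step_um": stack.z_step_um,
        },
    )


def read_stack_tiff(path, pixel_size_nm: float | None = None) -> ImageStack:
    """Read a TIFF written by :func:`write_stack_tiff`."""
    import json

    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None, :, :]
    px = pixel_size_nm or float(meta.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM))
    z = float(meta.get("z_step_um", 0.1))
    return ImageStack(voxels=data.astype(float), pixel_size_nm=px, z_step_um=z)
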
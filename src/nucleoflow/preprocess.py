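"""Background estimation/subtraction and stage-jitter registration.

Two instrumental artefacts are corrected before any quantitative analysis:

* a smooth, inhomogeneous additive background (uneven illumination,
  autofluorescence), estimated by iteratively interpolating the intensity
  from randomly sampled points while progressively excluding bright
  (nucleus) pixels from the sampling mask;
* random stage-positioning errors between frames, which add a spurious
  delta-correlated component to every reconstructed velocity.  Consecutive
  frames are aligned by pure translation; the cumulative trajectory
  ``x_reg`` is decomposed into a smooth migration component ``x_cm``
  (low-order polynomial in time) plus the jitter ``x_noise = x_reg - x_cm``,
  and frames are shifted by ``-x_noise``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import interpolate, ndimage
from skimage.registration import phase_cross_correlation

from .sequence import ImageSequence

__all__ = [
    "RegistrationResult",
    "estimate_background",
    "subtract_background",
    "register",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------


def _interp_scattered(frame: np.ndarray, pts_yx: np.ndarray, coarse: int = 4) -> np.ndarray:
    """Cubic interpolation of frame values at scattered points onto the
    whole image, evaluated on a coarse grid and upsampled (the background
    varies slowly)."""
    h, w = frame.shape
    vals = frame[pts_yx[:, 0], pts_yx[:, 1]]
    gy = np.arange(0, h, coarse)
    gx = np.arange(0, w, coarse)
    mx, my = np.meshgrid(gx, gy)
    grid = interpolate.griddata(
        pts_yx[:, ::-1], vals, (mx, my), method="cubic")
    # outside the convex hull fall back to nearest
    nan = np.isnan(grid)
    if nan.any():
        near = interpolate.griddata(
            pts_yx[:, ::-1], vals, (mx, my), method="nearest")
        grid[nan] = near[nan]
    zoom = (h / grid.shape[0], w / grid.shape[1])
    return ndimage.zoom(grid, zoom, order=1)[:h, :w]


def estimate_background(
    seq: ImageSequence,
    n_iter: int = 10,
    n_sample_frames: int = 10,
    seed: int = 0,
    points_per_px2: float = 1 / 500.0,
    min_coverage: float = 0.05,
) -> np.ndarray:
    """Estimate the static additive background of a recording.

    For each of ``n_sample_frames`` frames equally spaced in time, the
    intensity is cubically interpolated from points drawn at random inside a
    mask that initially covers the whole image; after each interpolation the
    mask is redefined to exclude high-intensity pixels (above the masked
    median + 2 robust standard deviations), which likely belong to nuclei.
    After ``n_iter`` iterations (ten by default) the interpolation is that
    frame's background estimate; the returned background is the average over
    the sampled frames.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = seq.frame_shape
    idx = np.unique(np.linspace(0, seq.n_frames - 1,
                                min(n_sample_frames, seq.n_frames)).astype(int))
    n_pts = max(30, int(h * w * points_per_px2))

    backgrounds = []
    for i in idx:
        frame = seq.frames[i].astype(float)
        mask = np.ones((h, w), bool)
        est = None
        for _ in range(n_iter):
            my, mx = np.nonzero(mask)
            if len(my) < max(n_pts // 3, 16):
                raise RuntimeError(
                    "background mask collapsed below minimum coverage; "
                    "foreground saturates the image")
            take = rng.choice(len(my), size=min(n_pts, len(my)), replace=False)
            pts = np.stack([my[take], mx[take]], axis=1)
            est = _interp_scattered(frame, pts)
            vals = frame[mask]
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            mask = frame <= med + 2 * 1.4826 * mad
            if mask.mean() < min_coverage:
                raise RuntimeError(
                    "background mask collapsed below minimum coverage; "
                    "foreground saturates the image")
        backgrounds.append(est)
    return np.mean(backgrounds, axis=0)


def subtract_background(seq: ImageSequence, background: np.ndarray) -> ImageSequence:
    """Subtract the background from every frame, clipping at zero."""
    if background.shape != seq.frame_shape:
        raise ValueError(
            f"background shape {background.shape} does not match frames {seq.frame_shape}")
    frames = np.clip(seq.frames.astype(float) - background[None], 0.0, None)
    return seq.with_frames(frames)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    """Decomposition of the apparent FOV trajectory.

    All arrays are (T, 2) in (x, y) pixels.  ``x_reg = x_cm + x_noise`` holds
    exactly by construction and ``x_reg[0] = 0``.
    """

    dx_reg: np.ndarray     # per-step content displacement, (T, 2); first row 0
    x_reg: np.ndarray      # cumulative trajectory
    x_cm: np.ndarray       # smooth migration component (polynomial fit)
    x_noise: np.ndarray    # stage jitter component
    registered: ImageSequence


def register(
    seq: ImageSequence,
    poly_degree: int = 20,
    upsample: int = 20,
) -> RegistrationResult:
    """Recover and remove stage-positioning jitter.

    Consecutive frames are aligned by intensity-based phase correlation
    (pure translations, subpixel via Fourier upsampling).  The cumulative
    trajectory is fitted, per coordinate, with a polynomial of degree
    ``poly_degree`` (capped at n_frames/4) on a scaled time axis; the fit is
    the genuine monolayer migration ``x_cm`` and the residual ``x_noise`` is
    subtracted from each frame by bilinear shifting.
    """
    T = seq.n_frames
    if T < 2:
        raise ValueError("registration needs at least 2 frames")
    degree = int(min(poly_degree, max(1, T // 4)))
    if degree < poly_degree:
        log.warning("poly_degree reduced from %d to %d for %d frames",
                    poly_degree, degree, T)

    dx = np.zeros((T, 2))
    for i in range(1, T):
        ref, mov = seq.frames[i - 1], seq.frames[i]
        if ref.std() == 0 or mov.std() == 0:
            log.warning("flat frame pair %d-%d; zero shift assumed", i - 1, i)
            continue
        shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample,
                                              normalization=None)
        # `shift` moves frame i onto frame i-1, so the content displacement
        # of frame i relative to i-1 is -shift; reorder (row, col) -> (x, y)
        dx[i] = [-shift[1], -shift[0]]

    x_reg = np.cumsum(dx, axis=0)
    t = np.arange(T, dtype=float)
    x_cm = np.empty_like(x_reg)
    for c in range(2):
        # fit in a scaled/shifted basis: degree-20 on raw time is singular
        series = np.polynomial.Polynomial.fit(t, x_reg[:, c], degree)
        x_cm[:, c] = series(t)
    x_noise = x_reg - x_cm

    out = np.empty_like(seq.frames, dtype=float)
    for i in range(T):
        if np.allclose(x_noise[i], 0):
            out[i] = seq.frames[i]
        else:
            out[i] = ndimage.shift(seq.frames[i].astype(float),
                                   (-x_noise[i, 1], -x_noise[i, 0]),
                                   order=1, mode="nearest")
    registered = seq.with_frames(out)
    return RegistrationResult(dx, x_reg, x_cm, x_noise, registered)
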
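"""Synthetic monolayer movies with full ground truth.

This module emulates fluorescence time-lapse recordings of confluent
epithelial monolayers with fluorescently tagged nuclei.  Nuclei are rendered
as anti-aliased ellipses with a chromatin-like multiplicative texture and are
advected by a prescribed velocity field; their projected areas respond to the
local divergence of that field through a configurable coupling coefficient
``m`` (the quantity the analysis pipeline is designed to recover):

    A(t + dt) = A(t) * (1 + m * (div v)(x, t) * dt)

so that the single-nucleus area strain rate equals ``m`` times the local
divergence, up to truncation.  Total fluorescence per nucleus is conserved
(intensity scales inversely with area), mimicking a fixed amount of labelled
chromatin.  Optional imperfections reproduce the dominant artefacts of real
recordings: an inhomogeneous additive background, Poisson shot noise, and
random stage-positioning jitter between frames.

Because every rendered frame comes with exact per-nucleus centroids, areas,
velocities and divergences, every downstream stage (registration,
segmentation, tracking, PIV, strain and stiffness estimation) can be tested
quantitatively without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .sequence import ImageSequence

__all__ = [
    "AffineFlow",
    "SinusoidalFlow",
    "SwirlFlow",
    "TextureConfig",
    "NoiseConfig",
    "SynthConfig",
    "GroundTruth",
    "PackingError",
    "generate_movie",
    "inject_jitter",
    "rasterize_ellipses",
]


# ---------------------------------------------------------------------------
# Prescribed velocity fields (positions in µm, time in h, velocities in µm/h)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineFlow:
    """v(x) = v0 + G (x - x_ref); divergence = trace(G) everywhere."""

    v0: tuple[float, float] = (0.0, 0.0)
    grad: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))
    x_ref: tuple[float, float] = (0.0, 0.0)

    def velocity(self, xy: np.ndarray, t_h: float) -> np.ndarray:
        xy = np.atleast_2d(xy)
        g = np.asarray(self.grad, float)
        return np.asarray(self.v0, float) + (xy - np.asarray(self.x_ref, float)) @ g.T

    def divergence(self, xy: np.ndarray, t_h: float) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return np.full(xy.shape[0], self.grad[0][0] + self.grad[1][1], float)


@dataclass(frozen=True)
class SinusoidalFlow:
    """Travelling sinusoidal compression/dilation waves along x and y.

    vx = u0 sin(2*pi*x/wavelength - omega*t + phase_x)
    vy = u0 sin(2*pi*y/wavelength - omega*t + phase_y)

    The divergence spans +-2*pi*u0/wavelength per component; a nonzero
    ``omega_per_h`` makes the pattern drift so that each nucleus samples
    both compression and dilation over the record.
    """

    u0_um_h: float
    wavelength_um: float
    omega_per_h: float = 0.0
    phase_x: float = 0.0
    phase_y: float = 0.0

    def _phases(self, xy: np.ndarray, t_h: float) -> tuple[np.ndarray, np.ndarray]:
        k = 2 * np.pi / self.wavelength_um
        px = k * xy[:, 0] - self.omega_per_h * t_h + self.phase_x
        py = k * xy[:, 1] - self.omega_per_h * t_h + self.phase_y
        return px, py

    def velocity(self, xy: np.ndarray, t_h: float) -> np.ndarray:
        xy = np.atleast_2d(xy)
        px, py = self._phases(xy, t_h)
        return self.u0_um_h * np.stack([np.sin(px), np.sin(py)], axis=1)

    def divergence(self, xy: np.ndarray, t_h: float) -> np.ndarray:
        xy = np.atleast_2d(xy)
        k = 2 * np.pi / self.wavelength_um
        px, py = self._phases(xy, t_h)
        return self.u0_um_h * k * (np.cos(px) + np.cos(py))


@dataclass(frozen=True)
class SwirlFlow:
    """Flocking-like motion: uniform drift plus a rigid swirl (zero divergence)."""

    v0: tuple[float, float] = (0.0, 0.0)
    omega_per_h: float = 0.0
    center_um: tuple[float, float] = (0.0, 0.0)

    def velocity(self, xy: np.ndarray, t_h: float) -> np.ndarray:
        xy = np.atleast_2d(xy)
        rel = xy - np.asarray(self.center_um, float)
        swirl = self.omega_per_h * np.stack([-rel[:, 1], rel[:, 0]], axis=1)
        return np.asarray(self.v0, float) + swirl

    def divergence(self, xy: np.ndarray, t_h: float) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return np.zeros(xy.shape[0])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TextureConfig:
    """Chromatin-like granularity: band-limited multiplicative modulation.

    Each nucleus carries a fixed set of smooth Gaussian granules defined in
    material (nucleus-attached) coordinates, so the texture advects and
    rescales with the nucleus.  ``contrast=0`` disables texturing.
    """

    granule_size_um: float = 2.0
    contrast: float = 0.35
    n_granules: int = 12
    floor: float = 0.25


@dataclass(frozen=True)
class NoiseConfig:
    """Imaging imperfections.

    background_level : additive background, camera counts.
    background_gradient : relative tilt of the background plane across the FOV.
    shot_noise : apply Poisson noise to the expected counts.
    jitter_sigma_px : std of the i.i.d. stage-positioning jitter per frame.
    """

    background_level: float = 120.0
    background_gradient: float = 0.3
    shot_noise: bool = True
    jitter_sigma_px: float = 1.0

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(background_level=0.0, background_gradient=0.0,
                   shot_noise=False, jitter_sigma_px=0.0)


def _default_flow(cfg: "SynthConfig") -> SinusoidalFlow:
    """Sinusoidal compression waves with wavelength equal to the FOV width.

    u0 = 20 µm/h is in the range of RMS speeds of motile MCF10A-like
    monolayers; with a ~330 µm FOV it yields divergences of order 0.4 1/h.
    The phase drifts with a 2 h period, so the peak-to-peak displacement of
    a nucleus (~2 u0/omega ~ 13 µm) stays below the inter-nuclear distance:
    cells oscillate around their cage instead of streaming across the FOV,
    as appropriate for a confluent monolayer near dynamic arrest.
    """
    width_um = cfg.frame_shape[1] * cfg.pixel_size_um
    return SinusoidalFlow(
        u0_um_h=20.0,
        wavelength_um=width_um,
        omega_per_h=2 * np.pi / 2.0,
        phase_y=np.pi / 2,
    )


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for one synthetic recording.

    Defaults emulate a 10x fluorescence recording of a confluent monolayer:
    0.65 µm/px over a 512x512 FOV, one frame every 5 minutes, ~200 nuclei
    covering a fraction ``beta_true`` of the tissue area, nuclear aspect
    ratios with median ~1.4 and spread ~0.5.
    """

    n_nuclei: int = 200
    frame_shape: tuple[int, int] = (512, 512)  # (H, W) px
    pixel_size_um: float = 0.65
    dt_min: float = 5.0
    n_frames: int = 100
    flow: object | None = None  # defaults to _default_flow(self)
    coupling_m: float = 0.5
    beta_true: float = 0.4
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    mean_intensity: float = 400.0
    intensity_spread: float = 0.25
    area_spread: float = 0.15
    ar_median: float = 1.4
    ar_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.beta_true < 1:
            raise ValueError("beta_true must lie in (0, 1)")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        if self.n_nuclei < 1 or self.n_frames < 1:
            raise ValueError("n_nuclei and n_frames must be >= 1")

    def get_flow(self):
        return self.flow if self.flow is not None else _default_flow(self)

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.frame_shape[0] * self.pixel_size_um,
                self.frame_shape[1] * self.pixel_size_um)

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


class PackingError(RuntimeError):
    pass


@dataclass
class GroundTruth:
    """Exact per-frame state of the synthetic monolayer.

    ``table`` columns: frame, label, x_um, y_um (true, jitter-free
    coordinates), area_um2, div_h (divergence at the nucleus center used for
    the update to the next frame), vx_umh, vy_umh, a_um, b_um (ellipse
    semi-axes) and theta (orientation, rad).  ``jitter_px`` is the injected
    stage trajectory in (x, y) pixels.
    """

    table: pd.DataFrame
    jitter_px: np.ndarray
    config: SynthConfig

    def frame(self, i: int) -> pd.DataFrame:
        return self.table[self.table["frame"] == i]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Nucleus initialisation
# ---------------------------------------------------------------------------


def _axes_from_area(area_um2: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Semi-axes (a, b) of an ellipse with given area and aspect ratio p=a/b."""
    b = np.sqrt(area_um2 / (np.pi * p))
    return p * b, b


def _place_nuclei(cfg: SynthConfig, rng: np.random.Generator):
    h, w = cfg.frame_shape
    px = cfg.pixel_size_um
    n = cfg.n_nuclei

    cell_area = (h * w * px**2) / n
    mean_area = cfg.beta_true * cell_area
    areas = mean_area * np.clip(
        rng.normal(1.0, cfg.area_spread, n), 0.5, 1.6)
    # rescale so the mean nuclear area hits beta_true exactly
    areas *= mean_area / areas.mean()
    p = np.clip(rng.normal(cfg.ar_median, cfg.ar_sd, n), 1.05, 3.2)
    theta = rng.uniform(0, np.pi, n)
    a_um, b_um = _axes_from_area(areas, p)
    r_px = np.sqrt(areas / np.pi) / px  # mean radius in px

    nx = max(1, int(round(np.sqrt(n * w / h))))
    ny = int(np.ceil(n / nx))
    sx, sy = w / nx, h / ny
    cells = np.array([(ix, iy) for iy in range(ny) for ix in range(nx)])
    cells = cells[rng.permutation(len(cells))[:n]]
    base = np.stack([(cells[:, 0] + 0.5) * sx, (cells[:, 1] + 0.5) * sy], axis=1)

    min_sep_scale = 0.85
    for _ in range(40):
        jit = rng.uniform(-0.15, 0.15, (n, 2)) * np.array([sx, sy])
        centers_px = base + jit
        if n == 1:
            break
        from scipy.spatial import cKDTree

        tree = cKDTree(centers_px)
        pairs = tree.query_pairs(r=2.2 * r_px.max(), output_type="ndarray")
        if len(pairs) == 0:
            break
        d = np.linalg.norm(centers_px[pairs[:, 0]] - centers_px[pairs[:, 1]], axis=1)
        need = min_sep_scale * (r_px[pairs[:, 0]] + r_px[pairs[:, 1]])
        if np.all(d >= need):
            break
    else:
        achievable = int(0.9 * (h * w) / (np.pi * (min_sep_scale * 2 * r_px.mean()) ** 2 / np.pi))
        raise PackingError(
            f"cannot place {n} non-overlapping nuclei at beta={cfg.beta_true} "
            f"in a {h}x{w} px FOV; approximately {achievable} nuclei are achievable"
        )

    centers_um = centers_px * px
    return centers_um, areas, p, theta, a_um, b_um


def _make_textures(cfg: SynthConfig, rng: np.random.Generator):
    """Granule parameters in normalized material coordinates per nucleus."""
    n, k = cfg.n_nuclei, cfg.texture.n_granules
    # positions inside the unit ellipse (normalized radius < 0.85)
    r = 0.85 * np.sqrt(rng.uniform(0, 1, (n, k)))
    ang = rng.uniform(0, 2 * np.pi, (n, k))
    gx, gy = r * np.cos(ang), r * np.sin(ang)
    sign = rng.choice([-1.0, 1.0], (n, k))
    return gx, gy, sign


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_EDGE_W_PX = 0.6  # half-width of the logistic edge profile


def _render_frame(shape, centers_px, a_px, b_px, theta, intensity,
                  tex_params, tex_cfg: TextureConfig, pixel_size_um: float) -> np.ndarray:
    """Render anti-aliased textured ellipses.

    The intensity profile of each nucleus is ``I * tex * logistic(-d / w)``
    with ``d`` the approximate signed edge distance in px, so the half-max
    contour coincides with the true ellipse boundary independently of
    brightness and texture.
    """
    h, w = shape
    img = np.zeros((h, w), float)
    gx_all, gy_all, sign_all = tex_params
    mean_r_um = None
    for i in range(len(centers_px)):
        cx, cy = centers_px[i]
        a, b = a_px[i], b_px[i]
        ext = max(a, b) + 4.0
        x0, x1 = int(np.floor(cx - ext)), int(np.ceil(cx + ext)) + 1
        y0, y1 = int(np.floor(cy - ext)), int(np.ceil(cy + ext)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        ct, st = np.cos(theta[i]), np.sin(theta[i])
        xr = (ct * dx + st * dy) / a
        yr = (-st * dx + ct * dy) / b
        rho = np.sqrt(xr**2 + yr**2)
        d = (rho - 1.0) * np.sqrt(a * b)
        prof = expit(-d / _EDGE_W_PX)
        if tex_cfg.contrast > 0:
            # granule width in normalized units of the mean radius
            s = tex_cfg.granule_size_um / (np.sqrt(a * b) * pixel_size_um)
            tex = np.zeros_like(rho)
            gx, gy, sg = gx_all[i], gy_all[i], sign_all[i]
            for j in range(len(gx)):
                tex += sg[j] * np.exp(
                    -((xr - gx[j]) ** 2 + (yr - gy[j]) ** 2) / (2 * s**2))
            tex = np.clip(1.0 + tex_cfg.contrast * tex, tex_cfg.floor, None)
        else:
            tex = 1.0
        img[y0:y1, x0:x1] += intensity[i] * tex * prof
    return img


def rasterize_ellipses(shape, centers_px, a_px, b_px, theta) -> np.ndarray:
    """Ground-truth label map: pixel centers inside each true ellipse.

    Pixels claimed by several ellipses go to the one whose normalized radius
    is smallest at that pixel.
    """
    h, w = shape
    labels = np.zeros((h, w), np.uint16)
    best = np.ones((h, w), float)
    for i in range(len(centers_px)):
        cx, cy = centers_px[i]
        a, b = a_px[i], b_px[i]
        ext = max(a, b) + 2.0
        x0, x1 = max(int(cx - ext), 0), min(int(cx + ext) + 2, w)
        y0, y1 = max(int(cy - ext), 0), min(int(cy + ext) + 2, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        ct, st = np.cos(theta[i]), np.sin(theta[i])
        rho = np.sqrt(((ct * dx + st * dy) / a) ** 2 + ((-st * dx + ct * dy) / b) ** 2)
        take = rho < best[y0:y1, x0:x1]
        labels[y0:y1, x0:x1][take] = i + 1
        best[y0:y1, x0:x1][take] = rho[take]
    return labels


# ---------------------------------------------------------------------------
# Movie generation
# ---------------------------------------------------------------------------


def generate_movie(cfg: SynthConfig) -> tuple[ImageSequence, GroundTruth]:
    """Generate a synthetic recording and its exact ground truth.

    Deterministic for a fixed ``cfg.seed``.  Nucleus centers are advected by
    explicit Euler steps of the configured flow; areas follow
    ``A <- A * (1 + m * div * dt)`` with isotropic rescaling of the ellipse
    axes; total per-nucleus fluorescence is conserved.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_shape
    px = cfg.pixel_size_um
    dt_h = cfg.dt_min / 60.0
    flow = cfg.get_flow()

    centers_um, areas, p, theta, a_um, b_um = _place_nuclei(cfg, rng)
    areas0 = areas.copy()
    inten0 = cfg.mean_intensity * np.clip(
        rng.normal(1.0, cfg.intensity_spread, cfg.n_nuclei), 0.4, 1.8)
    tex_params = _make_textures(cfg, rng)

    if cfg.noise.jitter_sigma_px > 0:
        jitter = rng.normal(0.0, cfg.noise.jitter_sigma_px, (cfg.n_frames, 2))
    else:
        jitter = np.zeros((cfg.n_frames, 2))

    yy, xx = np.mgrid[0:h, 0:w]
    bg = cfg.noise.background_level * (
        1.0
        + cfg.noise.background_gradient * (xx / w - 0.5)
        + cfg.noise.background_gradient * (yy / h - 0.5)
    )

    frames = np.empty((cfg.n_frames, h, w))
    rows = []
    for t in range(cfg.n_frames):
        t_h = t * dt_h
        vel = flow.velocity(centers_um, t_h)
        div = flow.divergence(centers_um, t_h)
        a_um, b_um = _axes_from_area(areas, p)
        rows.append(pd.DataFrame({
            "frame": t,
            "label": np.arange(1, cfg.n_nuclei + 1),
            "x_um": centers_um[:, 0],
            "y_um": centers_um[:, 1],
            "area_um2": areas,
            "div_h": div,
            "vx_umh": vel[:, 0],
            "vy_umh": vel[:, 1],
            "a_um": a_um,
            "b_um": b_um,
            "theta": theta,
        }))

        centers_px = centers_um / px + jitter[t]
        inten = inten0 * areas0 / areas  # conserve total fluorescence
        clean = _render_frame((h, w), centers_px, a_um / px, b_um / px,
                              theta, inten, tex_params, cfg.texture, px)
        frame = clean + bg
        if cfg.noise.shot_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        frames[t] = frame

        # advance state
        factor = 1.0 + cfg.coupling_m * div * dt_h
        if np.any(factor <= 0):
            raise RuntimeError("area update factor went non-positive; "
                               "reduce flow amplitude or dt")
        centers_um = centers_um + vel * dt_h
        areas = areas * factor

    seq = ImageSequence(frames, px, cfg.dt_min)
    gt = GroundTruth(pd.concat(rows, ignore_index=True), jitter, cfg)
    return seq, gt


def inject_jitter(seq: ImageSequence, sigma_px: float, seed: int = 0,
                  integer: bool = False) -> tuple[ImageSequence, np.ndarray]:
    """Translate every frame by an i.i.d. zero-mean random displacement.

    Returns the shifted sequence and the jitter trajectory in (x, y) px.
    ``integer=True`` rounds displacements to whole pixels and uses
    nearest-neighbour shifting, so the translations are exactly invertible.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    rng = np.random.default_rng(seed)
    traj = rng.normal(0.0, sigma_px, (seq.n_frames, 2)) if sigma_px > 0 else np.zeros((seq.n_frames, 2))
    if integer:
        traj = np.round(traj)
    if sigma_px == 0:
        return seq.copy(), traj
    order = 0 if integer else 1
    out = np.empty_like(seq.frames, dtype=float)
    for i in range(seq.n_frames):
        # content moves by +traj (x, y) -> shift rows by traj_y, cols by traj_x
        out[i] = ndimage.shift(seq.frames[i].astype(float),
                               (traj[i, 1], traj[i, 0]), order=order, mode="nearest")
    return seq.with_frames(out), traj
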
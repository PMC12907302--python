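"""Visual front-end: grayscale movies, synthetic stimuli, and the
difference-of-Gaussians receptive field.

A :class:`Stimulus` is a stack of grayscale frames (levels in [1, 255])
with a frame rate and a spatial calibration (length per pixel, in one of
the modalities mm / degrees / pixels).  The outer-retina stage is modelled
as a circularly-symmetric spatial difference of Gaussians (centre minus
surround) followed by a causal exponential-cascade temporal filter; the
Gaussian blurs are computed with a fourth-order recursive (Deriche-style)
approximation, O(pixels) regardless of the Gaussian width.

A prosthesis encoder is also provided: the frame is partitioned into one
tile per electrode and each electrode receives the mean gray level of its
tile as an input current.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "Stimulus",
    "ReceptiveFieldSpec",
    "StimulusError",
    "load_stimulus",
    "make_moving_bar",
    "make_full_field",
    "make_grating",
    "recursive_gaussian",
    "gaussian_blur",
    "dog_frame",
    "dog_response",
    "prosthesis_input",
]

GRAY_MIN, GRAY_MAX = 1.0, 255.0


class StimulusError(ValueError):
    pass


@dataclass
class Stimulus:
    """Grayscale frame stack with temporal and spatial calibration."""
    frames: np.ndarray          # (T, H, W), gray levels in [1, 255]
    fps: float
    calibration: float = 1.0    # length units per pixel
    modality: str = "pixels"    # mm | degrees | pixels

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise StimulusError("frames must be a non-empty (T, H, W) stack")
        if self.fps <= 0:
            raise StimulusError("fps must be > 0")
        if self.calibration <= 0:
            raise StimulusError("calibration must be > 0")
        lo, hi = self.frames.min(), self.frames.max()
        if lo < GRAY_MIN or hi > GRAY_MAX:
            raise StimulusError(
                f"gray levels must lie in [{GRAY_MIN:g}, {GRAY_MAX:g}] "
                f"(got [{lo:g}, {hi:g}])")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_at(self, t: float) -> np.ndarray:
        """Zero-order hold: the frame active at time t (s)."""
        k = min(int(np.floor(t * self.fps)), self.n_frames - 1)
        return self.frames[max(k, 0)]


@dataclass
class ReceptiveFieldSpec:
    """Centre-surround spatio-temporal receptive field.

    Spatial part: w_c·G(σ_c) − w_s·G(σ_s) with normalised Gaussians and
    σ_s > σ_c (lateral inhibition).  Temporal part: causal exponential
    cascade of order ``n_rf`` with per-stage time constant ``tau_rf``.
    Widths are in the stimulus' spatial units (converted to pixels via its
    calibration).
    """
    w_c: float = 1.0
    sigma_c: float = 1.0
    w_s: float = 0.5
    sigma_s: float = 3.0
    tau_rf: float = 0.02   # s
    n_rf: int = 1

    def __post_init__(self):
        if not (self.sigma_s > self.sigma_c > 0):
            raise StimulusError("need sigma_s > sigma_c > 0")
        if self.n_rf < 1:
            raise StimulusError("n_rf must be >= 1")
        if self.tau_rf <= 0:
            raise StimulusError("tau_rf must be > 0")


# ---------------------------------------------------------------------------
# I/O and fixtures


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # RGB(A): plain channel mean over the colour channels
        img = img[..., :3].mean(axis=-1)
    return img


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path):
    nums = _NUM_RE.findall(p.stem)
    return (int(nums[-1]) if nums else 0, p.name)


def load_stimulus(path: str | Path, fps: float = 30.0, calibration: float = 1.0,
                  modality: str = "pixels") -> Stimulus:
    """Load a movie or a numbered image stack as a grayscale stimulus.

    ``path`` may be a directory of numbered PNG/TIFF frames or a video
    file; video containers are decoded through imageio and require an
    ffmpeg-capable plugin.  Colour input is converted to grayscale by the
    channel mean; levels are clamped into [1, 255].
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted((p for p in path.iterdir()
                        if p.suffix.lower() in (".png", ".tif", ".tiff", ".bmp",
                                                ".jpg", ".jpeg")),
                       key=_numeric_key)
        if not files:
            raise StimulusError(f"no image frames found in {path}")
        frames = np.stack([_to_gray(iio.imread(f)) for f in files])
    else:
        if not path.exists():
            raise StimulusError(f"no such stimulus file: {path}")
        try:
            data = iio.imread(path, index=None)
        except Exception as exc:
            raise StimulusError(f"cannot read stimulus {path}: {exc}") from exc
        data = np.asarray(data)
        if data.ndim == 2:
            data = data[None]
        if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4)):
            if data.ndim == 3:
                data = data[None]
            frames = np.stack([_to_gray(f) for f in data])
        else:
            frames = data.astype(float)
    if frames.shape[0] == 0:
        raise StimulusError(f"stimulus {path} contains zero frames")
    frames = np.clip(frames, GRAY_MIN, GRAY_MAX)
    return Stimulus(frames, fps=fps, calibration=calibration, modality=modality)


def save_frames(stim: Stimulus, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a stimulus as a numbered 8-bit PNG stack; returns the paths."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(stim.frames):
        p = directory / f"{prefix}_{k:05d}.png"
        iio.imwrite(p, np.round(frame).astype(np.uint8))
        paths.append(p)
    return paths


def make_full_field(level: float, duration: float = 1.0, fps: float = 30.0,
                    size: tuple[int, int] = (32, 32), calibration: float = 1.0,
                    modality: str = "pixels") -> Stimulus:
    """Spatially uniform stimulus at a fixed gray level."""
    if not GRAY_MIN <= level <= GRAY_MAX:
        raise StimulusError("level must lie in [1, 255]")
    n = max(1, round(duration * fps))
    frames = np.full((n, *size), float(level))
    return Stimulus(frames, fps=fps, calibration=calibration, modality=modality)


def make_moving_bar(width: int, speed: float, duration: float = 1.0,
                    fps: float = 30.0, size: tuple[int, int] = (32, 32),
                    bar_level: float = 255.0, bg_level: float = 1.0,
                    x0: float = 0.0, calibration: float = 1.0,
                    modality: str = "pixels") -> Stimulus:
    """Vertical bright bar sweeping rightwards.

    The bar's leading edge sits at x0 + speed·t (pixels; speed in px/s);
    the bar occupies the ``width`` columns behind the edge.
    """
    H, W = size
    if width > W:
        raise StimulusError("bar wider than the frame")
    n = max(1, round(duration * fps))
    frames = np.full((n, H, W), float(bg_level))
    cols = np.arange(W)
    for k in range(n):
        edge = x0 + speed * (k / fps)
        mask = (cols < edge) & (cols >= edge - width)
        frames[k, :, mask] = bar_level
    return Stimulus(frames, fps=fps, calibration=calibration, modality=modality)


def make_grating(spatial_period: float, temporal_freq: float, duration: float = 1.0,
                 fps: float = 30.0, size: tuple[int, int] = (32, 32),
                 contrast: float = 1.0, calibration: float = 1.0,
                 modality: str = "pixels") -> Stimulus:
    """Drifting sinusoidal grating (period in px, drift rate in Hz)."""
    if spatial_period <= 0 or not 0 <= contrast <= 1:
        raise StimulusError("need spatial_period > 0 and contrast in [0, 1]")
    H, W = size
    n = max(1, round(duration * fps))
    x = np.arange(W)
    t = np.arange(n) / fps
    phase = 2 * np.pi * (x[None, :] / spatial_period - temporal_freq * t[:, None])
    rows = 128.0 + 127.0 * contrast * np.sin(phase)  # (T, W)
    frames = np.repeat(rows[:, None, :], H, axis=1)
    frames = np.clip(frames, GRAY_MIN, GRAY_MAX)
    return Stimulus(frames, fps=fps, calibration=calibration, modality=modality)


# ---------------------------------------------------------------------------
# Recursive (Deriche-style) Gaussian filtering

# Fourth-order approximation constants: the Gaussian is approximated by a
# sum of two exponentially damped cosines, yielding an 8-tap recursive
# filter (4 causal + 4 anticausal) whose cost is independent of sigma.
_A0, _A1 = 1.6800, 3.7350
_B0, _B1 = 1.7830, 1.7230
_C0, _C1 = -0.6803, -0.2598
_W0, _W1 = 0.6318, 1.9970


def _deriche_coeffs(sigma: float):
    # z-transform of the sampled causal half of the approximation:
    #   e^{-b k} cos(w k) u[k]  ->  (1 - e^{-b} cos w · z^-1) / D(z)
    #   e^{-b k} sin(w k) u[k]  ->  (e^{-b} sin w · z^-1) / D(z)
    # with D(z) = 1 - 2 e^{-b} cos w · z^-1 + e^{-2b} z^-2; the two damped
    # oscillators combine over the common 4th-order denominator.
    e0, e1 = math.exp(-_B0 / sigma), math.exp(-_B1 / sigma)
    c0, s0 = math.cos(_W0 / sigma), math.sin(_W0 / sigma)
    c1, s1 = math.cos(_W1 / sigma), math.sin(_W1 / sigma)

    num0 = np.array([_A0, -_A0 * e0 * c0 + _A1 * e0 * s0])
    den0 = np.array([1.0, -2 * e0 * c0, e0 ** 2])
    num1 = np.array([_C0, -_C0 * e1 * c1 + _C1 * e1 * s1])
    den1 = np.array([1.0, -2 * e1 * c1, e1 ** 2])

    num_c = np.convolve(num0, den1) + np.convolve(num1, den0)  # 4 taps
    den = np.convolve(den0, den1)                              # 5 taps
    n0, n1, n2, n3 = num_c
    _, d1, d2, d3, d4 = den
    # anticausal numerator (taps on x[i+1] .. x[i+4])
    m1 = n1 - d1 * n0
    m2 = n2 - d2 * n0
    m3 = n3 - d3 * n0
    m4 = -d4 * n0
    num_a = np.array([0.0, m1, m2, m3, m4])
    # normalise to exactly unit DC gain
    dc = (num_c.sum() + num_a.sum()) / den.sum()
    return num_c / dc, num_a / dc, den


def _recursive_pass(x: np.ndarray, sigma: float, axis: int) -> np.ndarray:
    num_c, num_a, den = _deriche_coeffs(sigma)
    pad = int(math.ceil(5 * sigma)) + 5
    xp = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    xp = np.pad(xp, [(0, 0)] * (xp.ndim - 1) + [(pad, pad)], mode="edge")
    y_c = lfilter(num_c, den, xp, axis=-1)
    y_a = lfilter(num_a, den, xp[..., ::-1], axis=-1)[..., ::-1]
    y = (y_c + y_a)[..., pad:-pad]
    return np.moveaxis(y, -1, axis)


def recursive_gaussian(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-blur a 2-D frame with the fourth-order recursive filter.

    Separable: a row pass followed by a column pass; boundaries are
    replicate-padded; the DC gain is exactly one, so a constant image is
    unchanged.  ``sigma`` is in pixels.
    """
    if sigma <= 0:
        raise StimulusError("sigma must be > 0")
    if sigma < 0.5:
        warnings.warn("sigma below 0.5 px: recursive approximation degrades",
                      stacklevel=2)
    frame = np.asarray(frame, dtype=float)
    return _recursive_pass(_recursive_pass(frame, sigma, axis=-1), sigma, axis=-2)


gaussian_blur = recursive_gaussian


def dog_frame(frame: np.ndarray, rf: ReceptiveFieldSpec,
              calibration: float = 1.0) -> np.ndarray:
    """Spatial centre-surround response of one frame.

    ``w_c·G(σ_c)*frame − w_s·G(σ_s)*frame``; σ are divided by the spatial
    calibration (length per pixel) to obtain pixel widths.
    """
    sc = rf.sigma_c / calibration
    ss = rf.sigma_s / calibration
    return rf.w_c * recursive_gaussian(frame, sc) - rf.w_s * recursive_gaussian(frame, ss)


def dog_response(stim: Stimulus, rf: ReceptiveFieldSpec, positions,
                 dt: float | None = None, t_end: float | None = None,
                 gain: float = 1.0) -> np.ndarray:
    """Per-cell drive time series of the receptive-field front end.

    Each frame is filtered spatially (difference of Gaussians), sampled at
    the cell positions (nearest pixel; positions in the stimulus' spatial
    units), zero-order-held between frames on the ``dt`` grid, and passed
    through a causal exponential cascade of order ``n_rf``.  The result is
    an array of shape (n_steps + 1, n_cells) scaled by ``gain``; it feeds a
    cell's external input slot.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise StimulusError("empty position list")
    if dt is None:
        dt = 1.0 / stim.fps
    if t_end is None:
        t_end = stim.duration
    H, W = stim.shape
    px = np.clip(np.round(positions[:, 0] / stim.calibration).astype(int), 0, W - 1)
    py = np.clip(np.round(positions[:, 1] / stim.calibration).astype(int), 0, H - 1)
    if rf.sigma_c / stim.calibration < 0.5:
        warnings.warn("centre width under half a pixel; spatial filtering is "
                      "effectively a point sample", stacklevel=2)

    spatial = np.empty((stim.n_frames, positions.shape[0]))
    for k in range(stim.n_frames):
        filt = dog_frame(stim.frames[k], rf, stim.calibration)
        spatial[k] = filt[py, px]

    n_steps = int(round(t_end / dt))
    drive = np.zeros((n_steps + 1, positions.shape[0]))
    # causal exponential cascade, one exact first-order update per stage
    stages = np.zeros((rf.n_rf, positions.shape[0]))
    alpha = 1.0 - math.exp(-dt / rf.tau_rf)
    for k in range(n_steps + 1):
        frame_idx = min(int(math.floor(k * dt * stim.fps)), stim.n_frames - 1)
        u = spatial[frame_idx]
        for s in range(rf.n_rf):
            stages[s] = stages[s] + alpha * (u - stages[s])
            u = stages[s]
        drive[k] = gain * u
    return drive


def prosthesis_input(stim: Stimulus, nx: int, ny: int, gain: float = 1.0) -> np.ndarray:
    """Per-electrode input currents from tile-averaged pixels.

    The frame is partitioned into ``ny x nx`` tiles (one per electrode of
    the grid, row-major like cell indexing); each electrode's input is the
    mean gray level of its tile times ``gain`` (pA per gray level).
    Returns an array of shape (n_frames, nx*ny).
    """
    H, W = stim.shape
    if nx < 1 or ny < 1:
        raise StimulusError("electrode grid must be at least 1x1")
    if nx > W or ny > H:
        raise StimulusError("more electrodes than pixels along an axis")
    xb = np.floor(np.arange(nx + 1) * W / nx).astype(int)
    yb = np.floor(np.arange(ny + 1) * H / ny).astype(int)
    out = np.empty((stim.n_frames, nx * ny))
    for r in range(ny):
        for c in range(nx):
            tile = stim.frames[:, yb[r]:yb[r + 1], xb[c]:xb[c + 1]]
            out[:, r * nx + c] = tile.mean(axis=(1, 2))
    return gain * out
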
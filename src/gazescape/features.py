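"""Predictor maps for gaze modelling.

Three pixel-level channels drive the fixation models downstream:

* **low-level saliency** — graph-based visual saliency computed from four
  feature channels (intensity, DKL colour opponency, Gabor orientation
  energy, flicker), temporally smoothed and normalized to a per-frame mean
  of 1 so that a value of 1 is the chance level for unguided viewing;
* **centrality** — inverse Euclidean distance to the frame centre,
  capturing the central fixation bias;
* **social ROI** — binary masks of circular head regions.

Geometry helpers convert pixel extents on the presentation display into
degrees of visual angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gabor_kernel
from skimage.transform import resize
from scipy.ndimage import convolve as _ndconvolve


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical presentation geometry used to convert pixels to degrees."""

    screen_px: tuple[int, int]  # (width, height)
    screen_mm: tuple[float, float]
    viewing_distance_mm: float
    video_px: tuple[int, int]

    def __post_init__(self) -> None:
        vals = (*self.screen_px, *self.screen_mm, self.viewing_distance_mm, *self.video_px)
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry values must be positive")
        if self.video_px[0] > self.screen_px[0] or self.video_px[1] > self.screen_px[1]:
            raise ValueError("video does not fit on the screen")


#: The experiment's display: 24" LCD, 516.9 x 323.1 mm at 1920 x 1200 px,
#: viewed from ~50 cm, with 1280 x 720 video clips presented centrally.
DEFAULT_GEOMETRY = DisplayGeometry(
    screen_px=(1920, 1200),
    screen_mm=(516.9, 323.1),
    viewing_distance_mm=500.0,
    video_px=(1280, 720),
)


def visual_angle(extent_px: float, geometry: DisplayGeometry, axis: str = "horizontal") -> float:
    """Visual angle in degrees subtended by ``extent_px`` pixels.

    The pixel extent is converted to millimetres with the screen's
    pixel pitch on the given axis and the full angle is
    ``2 * atan(extent_mm / (2 * distance))``.
    """
    if extent_px < 0:
        raise ValueError("extent_px must be non-negative")
    i = {"horizontal": 0, "vertical": 1}[axis]
    extent_mm = extent_px * (geometry.screen_mm[i] / geometry.screen_px[i])
    return math.degrees(2.0 * math.atan2(extent_mm, 2.0 * geometry.viewing_distance_mm))


@dataclass
class FeatureMapStack:
    """Per-frame scalar maps aligned to video pixel space.

    ``values`` has shape (n_frames, height, width). ``kind`` is one of
    ``saliency``, ``centrality`` or ``roi``.
    """

    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("expected (frames, height, width) array")
        if self.kind not in ("saliency", "centrality", "roi"):
            raise ValueError(f"unknown map kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return self.values.shape[2], self.values.shape[1]


def centrality_map(width_px: int, height_px: int, n_frames: int = 1) -> FeatureMapStack:
    """Inverse-distance-to-centre map, identical across frames.

    ``C(x, y) = 1 / (1 + d((x, y), centre))`` with the centre at
    ``((w-1)/2, (h-1)/2)``; the +1 regularizes the singularity of a pure
    inverse distance at the centre pixel.
    """
    if width_px < 1 or height_px < 1 or n_frames < 1:
        raise ValueError("dimensions must be positive")
    cy = (height_px - 1) / 2.0
    cx = (width_px - 1) / 2.0
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    d = np.hypot(xx - cx, yy - cy)
    frame = 1.0 / (1.0 + d)
    values = np.broadcast_to(frame, (n_frames, height_px, width_px)).copy()
    return FeatureMapStack(values, kind="centrality")


def roi_mask_stack(annotations, width_px: int, height_px: int, n_frames: int) -> FeatureMapStack:
    """Binary head masks from circular ROI annotations.

    ``annotations`` is an iterable/DataFrame of rows (frame, cx, cy, r);
    a pixel is 1 iff its centre lies within distance r of some head centre
    in that frame (union over heads).
    """
    import pandas as pd

    ann = pd.DataFrame(annotations, columns=["frame", "cx", "cy", "r"]) if not hasattr(
        annotations, "columns"
    ) else annotations
    values = np.zeros((n_frames, height_px, width_px), dtype=float)
    if len(ann):
        frames = ann["frame"].to_numpy(dtype=int)
        if frames.min() < 0 or frames.max() >= n_frames:
            raise ValueError("ROI annotation references a frame outside the video")
        if (ann["r"].to_numpy(dtype=float) <= 0).any():
            raise ValueError("ROI radii must be positive")
        yy, xx = np.mgrid[0:height_px, 0:width_px]
        for f, cx, cy, r in zip(frames, ann["cx"], ann["cy"], ann["r"]):
            values[f][(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = 1.0
    return FeatureMapStack(values, kind="roi")


def normalize_mean1(stack: FeatureMapStack | np.ndarray) -> FeatureMapStack:
    """Divide each frame by its mean so every frame has mean exactly 1."""
    values = stack.values if isinstance(stack, FeatureMapStack) else np.asarray(stack, float)
    if values.ndim == 2:
        values = values[None]
    means = values.mean(axis=(1, 2))
    if np.any(~np.isfinite(means)) or np.any(means <= 0):
        raise ValueError("per-frame mean must be positive and finite")
    out = values / means[:, None, None]
    kind = stack.kind if isinstance(stack, FeatureMapStack) else "saliency"
    return FeatureMapStack(out, kind=kind)


def temporal_blur(stack: FeatureMapStack | np.ndarray, sd_frames: float = 2.0) -> FeatureMapStack:
    """Gaussian smoothing of each pixel's time course across frames.

    The kernel is truncated at 4 standard deviations. Near the first and
    last frames the kernel is renormalized over the frames actually
    present, so no mass is invented by padding.
    """
    values = stack.values if isinstance(stack, FeatureMapStack) else np.asarray(stack, float)
    kind = stack.kind if isinstance(stack, FeatureMapStack) else "saliency"
    if sd_frames < 0:
        raise ValueError("sd_frames must be non-negative")
    if sd_frames == 0:
        return FeatureMapStack(values.copy(), kind=kind)
    radius = int(math.ceil(4.0 * sd_frames))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sd_frames) ** 2)
    kernel /= kernel.sum()
    n = values.shape[0]
    out = np.zeros_like(values)
    wsum = np.zeros(n)
    for w, k in zip(kernel, offsets):
        src_lo, src_hi = max(0, -k), min(n, n - k)
        if src_lo >= src_hi:
            continue
        out[src_lo + k : src_hi + k] += w * values[src_lo:src_hi]
        wsum[src_lo + k : src_hi + k] += w
    out /= wsum[:, None, None]
    return FeatureMapStack(out, kind=kind)


# ---------------------------------------------------------------------------
# Graph-based saliency
# ---------------------------------------------------------------------------

# LMS cone responses from linear RGB (Ruderman et al. style transform), used
# to build the DKL opponent axes.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)


def _dkl_channels(frame_rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Red-green (L-M) and blue-yellow (S-(L+M)/2) opponent magnitude maps."""
    lms = frame_rgb @ _RGB2LMS.T
    l, m, s = lms[..., 0], lms[..., 1], lms[..., 2]
    denom = l + m + s + 1e-9
    rg = np.abs(l - m) / denom
    by = np.abs(s - 0.5 * (l + m)) / denom
    return rg, by


def _orientation_channels(lum: np.ndarray, n_orient: int = 4, frequency: float = 0.15):
    """Gabor energy maps of the luminance image at evenly spaced orientations."""
    maps = []
    for i in range(n_orient):
        theta = math.pi * i / n_orient
        kern = gabor_kernel(frequency=frequency, theta=theta)
        # reflective boundaries keep a constant image's energy map constant
        real = _ndconvolve(lum, np.real(kern), mode="reflect")
        imag = _ndconvolve(lum, np.imag(kern), mode="reflect")
        maps.append(np.hypot(real, imag))
    return maps


class _GraphSaliency:
    """Markov-chain activation on a regular image lattice.

    A feature map is down-sampled to a small lattice; a fully connected
    weighted graph is built with edge weight |M(i)-M(j)| * exp(-d^2/2s^2);
    the activation map is the equilibrium distribution of the Markov chain
    obtained by normalizing outgoing weights. A second pass concentrates
    mass with weights A(j) * exp(-d^2/2s^2).
    """

    def __init__(self, lattice_shape: tuple[int, int] = (24, 32), sigma_frac: float = 0.15):
        self.lattice_shape = lattice_shape  # (rows, cols)
        rows, cols = lattice_shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        sigma = sigma_frac * cols
        self._kernel = np.exp(-d2 / (2.0 * sigma * sigma))
        np.fill_diagonal(self._kernel, 0.0)

    @staticmethod
    def _equilibrium(weights: np.ndarray, tol: float = 1e-9, max_iter: int = 2000) -> np.ndarray:
        col_sums = weights.sum(axis=0)
        n = weights.shape[0]
        if not np.all(np.isfinite(col_sums)) or np.all(col_sums <= 0):
            return np.full(n, 1.0 / n)
        col_sums = np.where(col_sums > 0, col_sums, 1.0)
        transition = weights / col_sums  # column-stochastic
        pi = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            nxt = transition @ pi
            s = nxt.sum()
            if s <= 0:
                return np.full(n, 1.0 / n)
            nxt /= s
            if np.abs(nxt - pi).max() < tol:
                return nxt
            pi = nxt
        return pi

    def activation(self, feature_map: np.ndarray) -> np.ndarray:
        small = resize(feature_map, self.lattice_shape, order=1, anti_aliasing=True)
        m = small.ravel()
        if m.max() - m.min() < 1e-12:
            # featureless map: uniform by symmetry; skip the concentration
            # pass, which would otherwise impose lattice-boundary structure
            return np.full(self.lattice_shape, 1.0 / m.size)
        w = np.abs(m[:, None] - m[None, :]) * self._kernel
        act = self._equilibrium(w)
        # mass-concentration pass
        w2 = act[None, :] * self._kernel
        conc = self._equilibrium(w2.T)
        return conc.reshape(self.lattice_shape)


def compute_saliency_stack(
    frames: np.ndarray,
    lattice_shape: tuple[int, int] = (24, 32),
    include_channels: tuple[str, ...] = ("intensity", "color", "orientation", "flicker"),
) -> FeatureMapStack:
    """Graph-based low-level saliency for a video frame stack.

    ``frames`` is (n_frames, h, w) grayscale or (n_frames, h, w, 3) RGB in
    [0, 1]. Four feature channels (intensity, DKL colour, orientation,
    flicker) are turned into activation maps on a coarse lattice via the
    Markov-chain equilibrium construction, combined with equal weights and
    up-sampled to video resolution. The result is *unnormalized*; apply
    :func:`temporal_blur` and :func:`normalize_mean1` downstream.
    """
    frames = np.asarray(frames, dtype=float)
    if not np.all(np.isfinite(frames)):
        raise ValueError("frames contain non-finite pixels")
    if frames.ndim == 3:
        lum = frames
        rgb = None
    elif frames.ndim == 4 and frames.shape[-1] == 3:
        lum = frames.mean(axis=-1)
        rgb = frames
    else:
        raise ValueError("frames must be (n, h, w) or (n, h, w, 3)")
    n, h, w = lum.shape
    if n < 2:
        raise ValueError("need at least 2 frames (flicker requires a predecessor)")

    graph = _GraphSaliency(lattice_shape=lattice_shape)
    out = np.zeros((n, h, w))
    prev_lum = None
    for t in range(n):
        channel_maps: list[np.ndarray] = []
        if "intensity" in include_channels:
            channel_maps.append(lum[t])
        if "color" in include_channels and rgb is not None:
            rg, by = _dkl_channels(rgb[t])
            channel_maps.extend([rg, by])
        if "orientation" in include_channels:
            channel_maps.extend(_orientation_channels(lum[t]))
        if "flicker" in include_channels:
            flick = np.zeros_like(lum[t]) if prev_lum is None else np.abs(lum[t] - prev_lum)
            channel_maps.append(flick)
        prev_lum = lum[t]

        master = np.zeros(graph.lattice_shape)
        for fmap in channel_maps:
            act = graph.activation(fmap)
            master += act / act.sum()
        master /= len(channel_maps)
        out[t] = resize(master, (h, w), order=1)
    return FeatureMapStack(out, kind="saliency", meta={"lattice_shape": lattice_shape})


def saliency_pipeline(frames: np.ndarray, sd_frames: float = 2.0, **kwargs) -> FeatureMapStack:
    """Full saliency chain: graph activation -> temporal blur -> mean-1."""
    return normalize_mean1(temporal_blur(compute_saliency_stack(frames, **kwargs), sd_frames))
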
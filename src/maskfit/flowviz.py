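"""Quantifying mask-seal leakage from high-speed greyscale footage.

A glycerol vapour is injected into a mask sealed onto a model face and
filmed escaping against a dark background. The analysis is deliberately
simple and deterministic:

1. average the first few frames into a background image;
2. average short windows of frames at a regular stride;
3. subtract the background, zero out deviations below a greyscale
   threshold, despeckle, and (for display) scale by local background
   brightness;
4. count the surviving "vapour" pixels per window to obtain a leak time
   series;
5. after the initial filling transient, fit an ordinary least-squares
   line to the counts — the slope grades the severity of the leak, and a
   near-zero slope with a plateau near the filter-window area indicates a
   good seal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter

from .errors import InputError, NumericalError

__all__ = [
    "FrameStack",
    "FlowVizConfig",
    "LeakTimeSeries",
    "LeakSummary",
    "background_image",
    "window_means",
    "deviation_map",
    "vapour_counts",
    "leak_summary",
    "render_overlay",
    "load_frame_dir",
]


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of greyscale frames (values in [0, 255]) at a
    fixed frame rate."""

    frames: np.ndarray
    fps: float

    def __post_init__(self):
        fr = np.asarray(self.frames, dtype=np.float64)
        if fr.ndim != 3:
            raise InputError("frames must be a (n, height, width) array")
        if fr.shape[0] < 1:
            raise InputError("frame stack is empty")
        if self.fps <= 0:
            raise InputError("fps must be positive")
        if fr.min() < 0 or fr.max() > 255:
            raise InputError("greyscale values must lie in [0, 255]")
        if fr.shape[0] < 30:
            warnings.warn(
                f"frame stack has only {fr.shape[0]} frames; "
                "leak statistics need a longer recording",
                stacklevel=2,
            )
        object.__setattr__(self, "frames", fr)

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class FlowVizConfig:
    """Tunable knobs of the leak-analysis pipeline.

    ``background_frames`` frames are averaged into the background;
    windows of ``window`` frames are averaged every ``stride`` frames;
    absolute deviations below ``threshold`` greyscale units count as no
    deviation; displayed deviations are scaled by a brightness factor in
    [1, ``scale_max``]. ``transient_frac`` sets the running-maximum
    fraction that ends the filling transient; ``transient_time`` (s)
    overrides the automatic rule when set.
    """

    background_frames: int = 5
    window: int = 10
    stride: int = 25
    threshold: float = 3.0
    scale_max: float = 2.0
    despeckle_size: int = 3
    transient_frac: float = 0.9
    transient_time: Optional[float] = None
    min_post_transient: int = 5

    def __post_init__(self):
        if self.background_frames < 1 or self.window < 1 or self.stride < 1:
            raise InputError("frame counts must be positive")
        if self.threshold < 0:
            raise InputError("threshold must be non-negative")
        if self.scale_max <= 1:
            raise InputError("scale_max must exceed 1")
        if not 0 < self.transient_frac <= 1:
            raise InputError("transient_frac must lie in (0, 1]")
        if self.window > self.stride:
            warnings.warn(
                "window exceeds stride; analysis windows overlap", stacklevel=2
            )


@dataclass(frozen=True)
class LeakTimeSeries:
    """Vapour pixel count per analysis window against time (s)."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).reshape(-1)
        c = np.asarray(self.counts, dtype=np.int64).reshape(-1)
        if t.size != c.size or t.size == 0:
            raise InputError("times and counts must be equal-length and non-empty")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(c < 0):
            raise InputError("counts must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class LeakSummary:
    """Post-transient least-squares slope (px/s), transient end (s), and
    plateau count of a leak time series."""

    slope: float
    transient_end: float
    plateau_count: float
    n_points: int
    filter_area_reference: Optional[float] = None


def background_image(stack: FrameStack, cfg: FlowVizConfig = FlowVizConfig()) -> np.ndarray:
    """Pixelwise mean of the first ``background_frames`` frames."""
    nb = cfg.background_frames
    if len(stack) < nb:
        raise InputError(
            f"stack has {len(stack)} frames; background needs {nb}"
        )
    return stack.frames[:nb].mean(axis=0)


def window_means(
    stack: FrameStack, cfg: FlowVizConfig = FlowVizConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Mean images over ``window`` frames taken every ``stride`` frames.

    Window ``k`` covers frames ``[k*stride, k*stride + window)`` and is
    stamped at ``k*stride / fps`` seconds. Returns (images, times).
    """
    n = len(stack)
    if n < cfg.window:
        raise InputError(f"stack has {n} frames; a window needs {cfg.window}")
    starts = np.arange(0, n - cfg.window + 1, cfg.stride)
    images = np.stack(
        [stack.frames[s : s + cfg.window].mean(axis=0) for s in starts]
    )
    times = starts / stack.fps
    return images, times


def deviation_map(
    window_image: np.ndarray,
    background: np.ndarray,
    cfg: FlowVizConfig = FlowVizConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded, despeckled, brightness-scaled deviation from background.

    Absolute deviations below ``threshold`` are zeroed; a square median
    filter (``despeckle_size``) removes isolated speckle; surviving values
    are scaled by ``1 + b / b_max`` where ``b`` is the local background
    value (a display aid only — it cannot change mask membership since the
    factor is >= 1). Returns (scaled deviation image, binary vapour mask).
    """
    win = np.asarray(window_image, dtype=np.float64)
    bg = np.asarray(background, dtype=np.float64)
    if win.shape != bg.shape:
        raise InputError(
            f"window shape {win.shape} does not match background {bg.shape}"
        )
    dev = np.abs(win - bg)
    dev[dev < cfg.threshold] = 0.0
    if cfg.despeckle_size > 1:
        dev = median_filter(dev, size=cfg.despeckle_size, mode="constant", cval=0.0)
    b_max = bg.max()
    scale = 1.0 + (cfg.scale_max - 1.0) * (bg / b_max if b_max > 0 else 0.0)
    scaled = dev * scale
    return scaled, scaled > 0


def vapour_counts(
    stack: FrameStack, cfg: FlowVizConfig = FlowVizConfig()
) -> LeakTimeSeries:
    """Vapour pixel count per analysis window: the leak time series."""
    bg = background_image(stack, cfg)
    images, times = window_means(stack, cfg)
    counts = np.empty(len(images), dtype=np.int64)
    for k, img in enumerate(images):
        _, mask = deviation_map(img, bg, cfg)
        counts[k] = int(mask.sum())
    return LeakTimeSeries(times=times, counts=counts)


def leak_summary(
    series: LeakTimeSeries,
    cfg: FlowVizConfig = FlowVizConfig(),
    filter_area_reference: Optional[float] = None,
) -> LeakSummary:
    """Grade a leak time series by its post-transient slope.

    The filling transient ends the first time the count reaches
    ``transient_frac`` of the series maximum (or at ``transient_time`` if
    configured); an ordinary least-squares line is fitted to the counts
    strictly after that point. A near-zero slope with a stable plateau
    indicates a sealed mask; large slopes indicate rapid vapour loss.
    """
    t, c = series.times, series.counts
    if cfg.transient_time is not None:
        t_end = float(cfg.transient_time)
    elif c.max() == 0:
        t_end = float(t[0])
    else:
        t_end = float(t[np.argmax(c >= cfg.transient_frac * c.max())])
    if not (t[0] <= t_end <= t[-1]):
        raise InputError(
            f"transient end {t_end} s lies outside the recording span"
        )
    post = t > t_end
    if post.sum() < cfg.min_post_transient:
        raise NumericalError(
            f"only {int(post.sum())} post-transient points "
            f"(need >= {cfg.min_post_transient}); recording too short"
        )
    slope, _ = np.polyfit(t[post], c[post].astype(float), 1)
    return LeakSummary(
        slope=float(slope),
        transient_end=t_end,
        plateau_count=float(c[post].mean()),
        n_points=int(post.sum()),
        filter_area_reference=filter_area_reference,
    )


def render_overlay(
    stack: FrameStack,
    cfg: FlowVizConfig = FlowVizConfig(),
    out_path=None,
    cmap: str = "inferno",
) -> list:
    """False-colour deviation superimposed on the background image.

    Writes one PNG per analysis window (or an animated GIF if ``out_path``
    ends in ``.gif``) and returns the written paths; with ``out_path``
    None, returns the RGB frames instead. Purely presentational: the
    vapour mask is identical to the one :func:`vapour_counts` counts.
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    bg = background_image(stack, cfg)
    images, _ = window_means(stack, cfg)
    maps = [deviation_map(img, bg, cfg) for img in images]
    vmax = max((m[0].max() for m in maps), default=0.0)
    palette = colormaps[cmap]
    rgb_frames = []
    grey = np.clip(bg / 255.0, 0, 1)
    base_rgb = np.stack([grey] * 3, axis=-1)
    for scaled, mask in maps:
        rgba = palette(scaled / vmax if vmax > 0 else scaled)
        frame = base_rgb.copy()
        frame[mask] = rgba[mask][:, :3]
        rgb_frames.append(np.round(frame * 255).astype(np.uint8))
    if out_path is None:
        return rgb_frames
    out = Path(out_path)
    if out.suffix.lower() == ".gif":
        out.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out, rgb_frames, duration=100, loop=0)
        return [out]
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(rgb_frames):
        p = out / f"overlay_{k:04d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def load_frame_dir(path, fps: float) -> FrameStack:
    """Load a numbered greyscale image sequence (PNG/TIFF) as a FrameStack."""
    import imageio.v3 as iio

    p = Path(path)
    if not p.is_dir():
        raise FileNotFoundError(f"frame directory not found: {p}")
    files = sorted(
        f for f in p.iterdir() if f.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not files:
        raise InputError(f"no PNG/TIFF frames found in {p}")
    frames = []
    for f in files:
        img = np.asarray(iio.imread(f), dtype=np.float64)
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = img[..., :3].mean(axis=-1)
        frames.append(img)
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise InputError(f"frames in {p} have inconsistent dimensions: {shapes}")
    return FrameStack(frames=np.stack(frames), fps=fps)
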
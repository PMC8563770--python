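"""Parametric synthetic data with known ground truth.

None of the facial scans behind the sizing workflow can be redistributed,
so every downstream module is exercised against generated data instead:

* :func:`synth_face` — a parametric facial mesh whose nasal cross-section,
  cut perpendicular to the ridge, is an exact Gaussian of chosen ``A`` and
  ``sigma``, on a shallow curved base with exact landmark placement;
* :func:`synth_cohort` — tables of (eye-to-chin, A, sigma) records drawn
  from independent normal distributions, emulating a scanned cohort;
* :func:`synth_leak_video` — greyscale high-speed footage of a bright
  vapour disc of known pixel area growing (or saturating) on a static
  background.

All generators are deterministic under their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import brentq

from .errors import InputError
from .facial_params import FacialParameters
from .flowviz import FrameStack
from .mesh_core import LandmarkSet

__all__ = [
    "FaceSpec",
    "CohortSpec",
    "LeakVideoSpec",
    "synth_face",
    "synth_cohort",
    "synth_leak_video",
]

# Cohort defaults. The eye-to-chin moments are chosen so that FWHM-based
# size brackets land at midpoints near 97.3 / 104.9 / 112.4 mm, matching
# the published nine-design catalogue; sigma and A moments likewise mirror
# the catalogue's per-cell means.
COHORT_EYE_TO_CHIN_MU = 104.85
COHORT_EYE_TO_CHIN_SD = 6.37
COHORT_SIGMA_MU = 10.1
COHORT_SIGMA_SD = 0.72
COHORT_A_MU = 23.3
COHORT_A_SD = 1.2


@dataclass(frozen=True)
class FaceSpec:
    """Ground-truth parameters for one synthetic face.

    Lengths in mm, ``ridge_angle`` in degrees, ``noise_sd`` the standard
    deviation of i.i.d. vertex noise applied along vertex normals.
    """

    eye_to_chin: float = 104.9
    A: float = 24.4
    sigma: float = 10.2
    ridge_angle: float = 25.0
    face_width: float = 140.0
    mesh_resolution: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("eye_to_chin", "A", "sigma", "face_width", "mesh_resolution"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not 0.0 <= self.ridge_angle < 60.0:
            raise InputError("ridge_angle must lie in [0, 60) degrees")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if self.mesh_resolution > self.sigma / 8.0:
            raise InputError(
                f"mesh_resolution {self.mesh_resolution} mm too coarse to "
                f"resolve sigma = {self.sigma} mm (need >= 8 vertices per sigma)"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Moments of the independent normal draws for a synthetic cohort."""

    n: int = 10_000
    eye_to_chin_mu: float = COHORT_EYE_TO_CHIN_MU
    eye_to_chin_sd: float = COHORT_EYE_TO_CHIN_SD
    sigma_mu: float = COHORT_SIGMA_MU
    sigma_sd: float = COHORT_SIGMA_SD
    A_mu: float = COHORT_A_MU
    A_sd: float = COHORT_A_SD
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise InputError("cohort size n must be >= 1")
        for name in ("eye_to_chin_sd", "sigma_sd", "A_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LeakVideoSpec:
    """Parameters of a synthetic vapour-escape recording.

    The plume is a bright disc whose pixel area grows at
    ``plume_area_rate`` px/s after ``injection_time``; with
    ``plateau_area`` set the area saturates there (a sealed mask filling
    its fixed filter window). Intensities are greyscale units in [0, 255];
    the disc sits ``plume_intensity`` above the background so it clears
    the deviation threshold.
    """

    width: int = 160
    height: int = 120
    fps: float = 250.0
    duration: float = 6.0
    injection_time: float = 1.0
    plume_area_rate: float = 0.0
    plateau_area: Optional[float] = None
    noise_sd: float = 0.0
    background_level: float = 20.0
    plume_intensity: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 8 or self.height < 8:
            raise InputError("frame dimensions too small")
        if self.fps <= 0 or self.duration <= 0:
            raise InputError("fps and duration must be positive")
        if not 0.0 <= self.injection_time < self.duration:
            raise InputError("injection_time must lie within the recording")
        if self.plume_area_rate < 0 or (
            self.plateau_area is not None and self.plateau_area < 0
        ):
            raise InputError("plume rates and areas must be non-negative")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# faces


def _grid_faces(nrow: int, ncol: int) -> np.ndarray:
    """Two triangles per grid cell, consistent winding."""
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    return np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([b, d, c], axis=1)]
    )


def synth_face(spec: FaceSpec) -> tuple[trimesh.Trimesh, LandmarkSet, FacialParameters]:
    """Generate a parametric facial mesh with exact known parameters.

    The base surface is a shallow cylindrical cap (curved along the
    vertical axis, radius ~420 mm) standing in for the facial plane, with
    the eye landmarks on the eyeline and the chin landmark placed so the
    midsagittal eye-to-chin distance is exact. The nose is an additive
    ridge: at every station ``s`` along the bridge->tip axis (inclined at
    ``ridge_angle`` to the facial plane) the surface is displaced, along
    the in-plane height direction of the perpendicular section, by
    ``A * exp(-x^2 / (2 sigma^2))`` times a smooth envelope that equals 1
    exactly at mid-ridge. A section cut perpendicular to the ridge at
    station 0.5 therefore recovers the Gaussian parameters exactly (up to
    mesh resolution): the base contributes only a straight line that the
    chord baseline removes.

    Returns the mesh, the exact landmarks (from which
    :func:`~maskfit.mesh_core.orient_face` derives the canonical frame),
    and the ground-truth :class:`FacialParameters`.
    """
    rng = np.random.default_rng(spec.seed)
    res = spec.mesh_resolution
    theta = np.radians(spec.ridge_angle)
    r_base = 420.0  # vertical radius of the facial cap, mm

    def z_base(y):
        return -np.square(y) / (2.0 * r_base)

    # chin: on the base surface at the exact midsagittal distance
    target = spec.eye_to_chin

    def gap(y):
        return np.hypot(y, z_base(y)) - target

    y_chin = brentq(gap, -target, -1e-6)
    chin = np.array([0.0, y_chin, z_base(y_chin)])

    eye_half = min(35.0, 0.35 * spec.face_width)
    left_eye = np.array([-eye_half, 0.0, 0.0])
    right_eye = np.array([eye_half, 0.0, 0.0])

    # The canonical anatomical frame is fixed by the landmarks: its y-axis
    # opposes the chin vector (which has a z-component, since the chin sits
    # on the curved base), so express the ridge inclination relative to
    # those axes — the extracted ridge angle is then exactly `theta`.
    ey_canon = -chin / np.linalg.norm(chin)
    ez_canon = np.cross(np.array([1.0, 0.0, 0.0]), ey_canon)

    # nasal ridge axis: from a bridge point on the base, inclined at theta
    # to the canonical facial plane
    y_bridge = -0.12 * spec.eye_to_chin
    bridge = np.array([0.0, y_bridge, z_base(y_bridge)])
    ridge_len = 0.38 * spec.eye_to_chin
    d = -np.cos(theta) * ey_canon + np.sin(theta) * ez_canon
    tip = bridge + ridge_len * d
    # height direction of a section perpendicular to the ridge
    m = np.sin(theta) * ey_canon + np.cos(theta) * ez_canon

    # grid
    half_w = spec.face_width / 2.0
    xs = np.arange(-half_w, half_w + res / 2, res)
    ys = np.arange(30.0, y_chin - 20.0, -res)
    gx, gy = np.meshgrid(xs, ys)
    gz = z_base(gy)
    base = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    s = (base - bridge) @ d  # ridge-axis coordinate of each base vertex
    envelope = np.exp(-np.square(s - ridge_len / 2.0) / (2.0 * (ridge_len / 3.0) ** 2))
    g = spec.A * np.exp(-np.square(base[:, 0]) / (2.0 * spec.sigma**2)) * envelope
    verts = base + g[:, None] * m

    faces = _grid_faces(len(ys), len(xs))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if spec.noise_sd > 0:
        normals = np.asarray(mesh.vertex_normals, dtype=float)
        verts = verts + normals * rng.normal(0.0, spec.noise_sd, size=len(verts))[:, None]
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    landmarks = LandmarkSet(
        left_eye=left_eye, right_eye=right_eye, chin=chin,
        nose_tip=tip, nose_bridge=bridge,
    )
    truth = FacialParameters(
        eye_to_chin=spec.eye_to_chin, A=spec.A, sigma=spec.sigma,
        ridge_angle=spec.ridge_angle, fit_rmse=0.0,
    )
    return mesh, landmarks, truth


# ---------------------------------------------------------------------------
# cohorts


def synth_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table with columns
    ``subject_id, eye_to_chin_mm, A_mm, sigma_mm``.

    Each parameter is an independent normal draw clipped at three standard
    deviations from its mean (keeps all values positive at the default
    moments and bounds pathological tails).
    """
    rng = np.random.default_rng(spec.seed)

    def draw(mu, sd):
        vals = rng.normal(mu, sd, size=spec.n)
        return np.clip(vals, mu - 3 * sd, mu + 3 * sd)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(spec.n)],
            "eye_to_chin_mm": draw(spec.eye_to_chin_mu, spec.eye_to_chin_sd),
            "A_mm": draw(spec.A_mu, spec.A_sd),
            "sigma_mm": draw(spec.sigma_mu, spec.sigma_sd),
        }
    )


# ---------------------------------------------------------------------------
# leak videos


def synth_leak_video(spec: LeakVideoSpec) -> tuple[FrameStack, pd.DataFrame]:
    """Render a synthetic vapour-escape recording.

    Returns the frame stack and a ground-truth table with one row per
    frame: ``time_s`` and ``area_px``, the number of pixels actually drawn
    for the disc in that frame.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.fps))
    h, w = spec.height, spec.width
    # static background with a mild horizontal brightness gradient, so the
    # brightness-scaling stage sees non-uniform background values
    col = np.linspace(0.0, 10.0, w)
    background = np.clip(spec.background_level + col[None, :], 0, 255)
    background = np.repeat(background, h, axis=0).reshape(h, w)

    cy, cx = 0.45 * h, 0.5 * w
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    max_radius = min(cy, h - cy, cx, w - cx) - 1.0

    times = np.arange(n_frames) / spec.fps
    frames = np.empty((n_frames, h, w), dtype=np.float64)
    areas = np.zeros(n_frames, dtype=np.int64)
    for k, t in enumerate(times):
        frame = background.copy()
        area = 0.0
        if t >= spec.injection_time:
            area = spec.plume_area_rate * (t - spec.injection_time)
            if spec.plateau_area is not None:
                area = min(area, spec.plateau_area)
        if area > 0:
            radius = np.sqrt(area / np.pi)
            if radius > max_radius:
                raise InputError(
                    f"plume radius {radius:.1f} px exceeds the frame at t={t:.2f} s"
                )
            disc = r2 <= radius**2
            frame[disc] += spec.plume_intensity
            areas[k] = int(disc.sum())
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[k] = np.clip(frame, 0, 255)

    truth = pd.DataFrame({"time_s": times, "area_px": areas})
    return FrameStack(frames=frames, fps=spec.fps), truth
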
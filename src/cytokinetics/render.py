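"""Rendering of synthetic multi-channel time-lapse movies.

A cell's division site is rendered as:

* **GFP / ring channels** — the constricting ring seen edge-on: two 2-D
  Gaussian puncta separated by the ring diameter d(t) along the neck axis,
  with total integrated signal equal to the driving intensity trace;
* **spindle channel** — a line segment along the mother–bud axis that
  elongates through anaphase and splits into two shrinking halves at the true
  breakage frame.

Photon (Poisson) noise and Gaussian read noise are applied on top of a
constant background.  Movies are written as one multi-page TIFF per channel
with a JSON sidecar holding pixel size, frame interval and channel names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from pydantic import BaseModel, Field

__all__ = ["SceneConfig", "Movie", "render_movie", "write_movie", "read_movie",
           "spindle_length_series"]


class SceneConfig(BaseModel):
    """Geometry, optics and noise of the rendered scene."""

    shape: tuple[int, int] = (64, 64)          # (rows, cols), px
    pixel_size: float = Field(default=0.1, gt=0)   # μm/px
    frame_interval: float = Field(default=1.0, gt=0)  # min
    psf_sigma: float = Field(default=0.15, gt=0)   # μm
    neck_center: tuple[float, float] = (32.0, 32.0)  # (x, y), px
    axis: tuple[float, float] = (1.0, 0.0)     # mother–bud axis (unit vector)
    background: float = Field(default=100.0, ge=0)  # counts/px
    gain: float = Field(default=50.0, gt=0)    # photons per intensity unit
    read_noise_sd: float = Field(default=2.0, ge=0)
    t_start: float = -45.0                     # min, clock time of frame 0
    seed: int = 0

    @property
    def axis_unit(self) -> np.ndarray:
        v = np.asarray(self.axis, dtype=float)
        return v / np.linalg.norm(v)

    @property
    def neck_axis_unit(self) -> np.ndarray:
        """Ring puncta separate along the neck axis, normal to the mother–bud axis."""
        ux, uy = self.axis_unit
        return np.array([-uy, ux])


@dataclass
class Movie:
    channels: dict[str, np.ndarray]  # name -> (T, H, W)
    pixel_size: float                # μm/px
    frame_interval: float            # min
    t_start: float = -45.0           # min

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def times(self) -> np.ndarray:
        return self.t_start + self.frame_interval * np.arange(self.n_frames)


def _gauss2d(shape: tuple[int, int], x0: float, y0: float, sigma_px: float,
             flux: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    amp = flux / (2.0 * np.pi * sigma_px ** 2)
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma_px ** 2))


def _draw_segment(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray,
                  sigma_px: float, flux: float, step: float = 0.25) -> np.ndarray:
    """Line segment as a dense chain of PSF-sized Gaussians with total ``flux``."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / step)), 1) + 1
    ts = np.linspace(0.0, 1.0, n)
    img = np.zeros(shape)
    for t in ts:
        p = p0 + t * (p1 - p0)
        img += _gauss2d(shape, p[0], p[1], sigma_px, flux / n)
    return img


def spindle_length_series(times: np.ndarray, breakage_time: float,
                          short_len: float = 1.2, long_len: float = 4.6,
                          elongation_min: float = 20.0,
                          decay_min: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Spindle length (μm) and half-length after breakage, per frame.

    Before anaphase the spindle is ``short_len``; it elongates linearly over
    ``elongation_min`` minutes to ``long_len`` and breaks at ``breakage_time``,
    after which each half shrinks to nothing over ``decay_min`` minutes.
    """
    t = np.asarray(times, dtype=float)
    frac = np.clip((t - (breakage_time - elongation_min)) / elongation_min, 0.0, 1.0)
    length = short_len + (long_len - short_len) * frac
    length[t >= breakage_time] = long_len
    half0 = 0.3 * long_len
    half = np.clip(half0 * (1.0 - (t - breakage_time) / decay_min), 0.0, half0)
    half[t < breakage_time] = 0.0
    return length, half


def render_movie(scene: SceneConfig,
                 gfp_trace: np.ndarray,
                 diameter: Optional[np.ndarray] = None,
                 ring_trace: Optional[np.ndarray] = None,
                 breakage_time: float = 0.0,
                 asymmetry: float = 0.0,
                 spindle_flux: float = 120.0,
                 noise: bool = True) -> Movie:
    """Render one cell: GFP channel, optional ring-marker channel, spindle.

    ``diameter`` drives the separation of the two ring puncta (μm); when it is
    None or zero, the signal collapses to a single punctum at the neck.
    ``asymmetry`` in [0, 1] moves the constriction midpoint toward one side by
    ``asymmetry * (d0 - d(t))/2``, emulating one-sided furrow ingression.
    """
    gfp_trace = np.asarray(gfp_trace, dtype=float)
    n = gfp_trace.size
    shape = tuple(scene.shape)
    sigma_px = scene.psf_sigma / scene.pixel_size
    center = np.asarray(scene.neck_center, dtype=float)
    n_axis = scene.neck_axis_unit
    mb_axis = scene.axis_unit
    times = scene.t_start + scene.frame_interval * np.arange(n)
    rng = np.random.default_rng(scene.seed)

    d = np.zeros(n) if diameter is None else np.asarray(diameter, dtype=float)
    d0 = float(np.nanmax(d)) if np.any(np.isfinite(d)) else 0.0

    def ring_frame(intensity: float, diam_um: float) -> np.ndarray:
        half_px = 0.5 * diam_um / scene.pixel_size
        shift_px = asymmetry * 0.5 * (d0 - diam_um) / scene.pixel_size
        mid = center + shift_px * n_axis
        p1 = mid - half_px * n_axis
        p2 = mid + half_px * n_axis
        for p in (p1, p2):
            if not (0 <= p[0] < shape[1] and 0 <= p[1] < shape[0]):
                raise ValueError("ring diameter exceeds the field of view")
        return (_gauss2d(shape, p1[0], p1[1], sigma_px, intensity / 2.0)
                + _gauss2d(shape, p2[0], p2[1], sigma_px, intensity / 2.0))

    channels: dict[str, np.ndarray] = {}
    gfp = np.empty((n, *shape))
    for k in range(n):
        gfp[k] = ring_frame(gfp_trace[k], float(d[k]) if np.isfinite(d[k]) else 0.0)
    channels["GFP"] = gfp
    if ring_trace is not None:
        ring_trace = np.asarray(ring_trace, dtype=float)
        rf = np.empty((n, *shape))
        for k in range(n):
            rf[k] = ring_frame(ring_trace[k], float(d[k]) if np.isfinite(d[k]) else 0.0)
        channels["ring"] = rf

    length, half = spindle_length_series(times, breakage_time)
    sp = np.zeros((n, *shape))
    for k in range(n):
        half_len_px = 0.5 * length[k] / scene.pixel_size
        pole_m = center - half_len_px * mb_axis
        pole_d = center + half_len_px * mb_axis
        if times[k] < breakage_time:
            sp[k] = _draw_segment(shape, pole_m, pole_d, sigma_px,
                                  spindle_flux * length[k])
        elif half[k] > 0:
            h_px = half[k] / scene.pixel_size
            sp[k] = (_draw_segment(shape, pole_m, pole_m + h_px * mb_axis,
                                   sigma_px, spindle_flux * half[k])
                     + _draw_segment(shape, pole_d, pole_d - h_px * mb_axis,
                                     sigma_px, spindle_flux * half[k]))
    channels["spindle"] = sp

    for name, stack in channels.items():
        img = scene.gain * stack + scene.background
        if noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
            if scene.read_noise_sd > 0:
                img = img + rng.normal(0.0, scene.read_noise_sd, img.shape)
        channels[name] = img
    return Movie(channels=channels, pixel_size=scene.pixel_size,
                 frame_interval=scene.frame_interval, t_start=scene.t_start)


def write_movie(movie: Movie, directory: str | Path, stem: str,
                extra: dict | None = None) -> Path:
    """One multi-page TIFF per channel plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_min": movie.frame_interval,
        "t_start_min": movie.t_start,
        "channels": {},
        **(extra or {}),
    }
    for name, stack in movie.channels.items():
        fname = f"{stem}_{name}.tif"
        tifffile.imwrite(directory / fname, stack.astype(np.float32))
        meta["channels"][name] = fname
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_movie(sidecar: str | Path) -> Movie:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    channels = {name: tifffile.imread(sidecar.parent / fname).astype(float)
                for name, fname in meta["channels"].items()}
    return Movie(channels=channels, pixel_size=meta["pixel_size_um"],
                 frame_interval=meta["frame_interval_min"],
                 t_start=meta["t_start_min"])
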
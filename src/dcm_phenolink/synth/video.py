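"""Synthetic beating-monolayer videos and EHT post-deflection traces.

Frames are a static random texture warped by a time-varying global
translation whose magnitude follows a periodic contraction pulse (raised
cosine). The per-frame displacement vector is stored as ground truth, from
which the true inter-frame speed trace follows directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = ["VideoSpec", "BeatingVideo", "generate_beating_video", "pulse_train", "generate_deflection_trace"]


@dataclass(frozen=True)
class VideoSpec:
    frame_size_px: tuple[int, int] = (96, 96)
    n_frames: int = 750
    frame_rate_hz: float = 75.0
    pacing_hz: float = 0.5
    peak_displacement_px: float = 6.0
    pulse_width_s: float = 0.4
    direction_deg: float = 0.0
    texture_scale_px: float = 3.0
    texture_amplitude: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.texture_amplitude <= 0:
            raise ValueError("texture_amplitude must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.pulse_width_s * self.pacing_hz >= 1.0:
            raise ValueError("pulse must be shorter than the pacing period")


@dataclass
class BeatingVideo:
    frames: np.ndarray  # (n_frames, ny, nx)
    frame_rate_hz: float
    truth: dict = field(default_factory=dict)


def pulse_train(t: np.ndarray, pacing_hz: float, width_s: float) -> np.ndarray:
    """Raised-cosine contraction pulses of unit peak at each pacing time."""
    t = np.asarray(t, dtype=float)
    phase = np.mod(t, 1.0 / pacing_hz)
    return np.where(phase < width_s, 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / width_s)), 0.0)


def generate_beating_video(spec: VideoSpec) -> BeatingVideo:
    """Render a textured video with known per-frame displacement.

    Ground truth stored in ``truth``: per-frame displacement vectors (px),
    the true inter-frame mean speed trace (px/s), and a flag when any
    inter-frame displacement exceeds the conventional search radius of the
    block matcher (8 px), in which case integer block matching saturates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.frame_size_px
    texture = gaussian_filter(rng.standard_normal((ny, nx)), spec.texture_scale_px, mode="wrap")
    texture = spec.texture_amplitude * (texture - texture.min()) / max(float(np.ptp(texture)), 1e-12)

    t = np.arange(spec.n_frames) / spec.frame_rate_hz
    mag = spec.peak_displacement_px * pulse_train(t, spec.pacing_hz, spec.pulse_width_s)
    theta = np.deg2rad(spec.direction_deg)
    disp = np.stack([mag * np.sin(theta), mag * np.cos(theta)], axis=1)  # (dy, dx)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    frames = np.empty((spec.n_frames, ny, nx))
    for i in range(spec.n_frames):
        dy, dx = disp[i]
        if dy == 0.0 and dx == 0.0:
            frames[i] = texture
        else:
            # sample the texture at the displaced location (content moves by +d)
            frames[i] = map_coordinates(texture, [yy - dy, xx - dx], order=3, mode="wrap")
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)

    step = np.linalg.norm(np.diff(disp, axis=0), axis=1)
    truth = {
        "displacement_px": disp,
        "speed_px_per_s": step * spec.frame_rate_hz,
        "exceeds_search_radius": bool(np.any(step > 8.0)),
        "spec": spec,
    }
    return BeatingVideo(frames=frames, frame_rate_hz=spec.frame_rate_hz, truth=truth)


def generate_deflection_trace(
    duration_s: float = 20.0,
    sample_rate_hz: float = 75.0,
    pacing_hz: float = 0.5,
    peak_deflection_m: float = 1.0e-4,
    pulse_width_s: float = 0.5,
    drift_m_per_s: float = 0.0,
    noise_sd_m: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthetic EHT post-deflection trace (time_s, deflection_m, truth)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    d = peak_deflection_m * pulse_train(t, pacing_hz, pulse_width_s) + drift_m_per_s * t
    if noise_sd_m > 0:
        d = d + rng.normal(0.0, noise_sd_m, size=n)
    truth = {
        "peak_deflection_m": peak_deflection_m,
        "n_beats": int(np.floor(duration_s * pacing_hz)),
    }
    return t, d, truth
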
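"""Monolayer contractility via block matching and EHT force from post deflection.

Two independent readouts of contractile function:

1. **Block-matching motion analysis** of high-speed videos of beating
   monolayers: each frame is tiled into blocks and the integer displacement
   maximizing normalized cross-correlation (NCC) within a search radius is
   assigned per block; the mean speed trace over textured blocks yields
   beat rate and peak contraction/relaxation velocities.
2. **Cantilever post deflection** of engineered heart tissues (EHTs): the
   tissue bends two elastic silicone posts; for a tip load on a cylindrical
   cantilever the force producing tip deflection ``d`` is

       F = 3 * pi * d * E * r**4 / (4 * L**3)

   with elastic modulus ``E``, post radius ``r`` and post length ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "MotionField",
    "EHTGeometry",
    "block_match_motion",
    "motion_beat_metrics",
    "deflection_to_force",
    "eht_force_per_beat",
]


@dataclass
class MotionField:
    """Per-frame-pair grid of displacement vectors from block matching."""

    vectors: np.ndarray  # (n_pairs, nby, nbx, 2) as (dy, dx), px
    scores: np.ndarray  # (n_pairs, nby, nbx) best NCC per block
    valid: np.ndarray  # (n_pairs, nby, nbx) bool
    frame_rate_hz: float
    block_px: int
    search_px: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.vectors[self.valid]) > self.search_px):
            raise ValueError("displacement exceeds search radius")

    @property
    def saturated(self) -> np.ndarray:
        """Valid blocks whose match sits on the search boundary.

        A saturated vector means the true displacement may exceed the
        search radius; its magnitude is a lower bound only.
        """
        at_bound = np.abs(self.vectors).max(axis=3) >= self.search_px
        return at_bound & self.valid


@dataclass(frozen=True)
class EHTGeometry:
    """Elastic properties of the silicone posts (SI units)."""

    elastic_modulus_Pa: float = 1.7e6
    post_radius_m: float = 5.0e-4
    post_length_m: float = 1.0e-2

    def validate(self) -> None:
        if min(self.elastic_modulus_Pa, self.post_radius_m, self.post_length_m) <= 0:
            raise ValueError("all geometry parameters must be strictly positive")


def _block_sums(a: np.ndarray, block: int) -> np.ndarray:
    nby, nbx = a.shape[0] // block, a.shape[1] // block
    return a[: nby * block, : nbx * block].reshape(nby, block, nbx, block).sum(axis=(1, 3))


def _integral(a: np.ndarray) -> np.ndarray:
    """Zero-padded 2D integral image: window sums by inclusion-exclusion."""
    out = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=out[1:, 1:])
    return out


def _window_sums(cum: np.ndarray, rows: np.ndarray, cols: np.ndarray, block: int) -> np.ndarray:
    """Sums of block windows with origins at rows x cols (clipped in-bounds)."""
    r = np.clip(rows, 0, cum.shape[0] - 1 - block)[:, None]
    c = np.clip(cols, 0, cum.shape[1] - 1 - block)[None, :]
    return cum[r + block, c + block] - cum[r, c + block] - cum[r + block, c] + cum[r, c]


def block_match_motion(
    frames: np.ndarray,
    block_px: int = 16,
    search_px: int = 8,
    frame_rate_hz: float = 75.0,
    min_variance: float = 1e-6,
) -> MotionField:
    """Integer-displacement block matching between consecutive frames.

    For each ``block_px`` block of frame ``t`` the displacement in
    ``[-search_px, search_px]^2`` maximizing the NCC against frame ``t+1``
    is selected. Candidate shifts are scanned in order of increasing
    magnitude (ties then raster order on (dy, dx)) and only a strictly
    better score displaces the incumbent, so ties resolve to the smallest
    displacement. Blocks whose reference variance falls below
    ``min_variance``, or for which no candidate window lies inside the
    frame, are marked invalid.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("frames must be a (n_frames, ny, nx) stack with n_frames >= 2")
    n_frames, ny, nx = frames.shape
    nby, nbx = ny // block_px, nx // block_px
    if nby == 0 or nbx == 0:
        raise ValueError("frame smaller than one block")
    n = float(block_px * block_px)

    shifts = [
        (dy, dx)
        for dy in range(-search_px, search_px + 1)
        for dx in range(-search_px, search_px + 1)
    ]
    shifts.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))

    n_pairs = n_frames - 1
    vectors = np.zeros((n_pairs, nby, nbx, 2))
    best_scores = np.full((n_pairs, nby, nbx), -np.inf)
    valid = np.zeros((n_pairs, nby, nbx), dtype=bool)

    H, W = nby * block_px, nbx * block_px
    pad = search_px
    by = np.arange(nby) * block_px
    bx = np.arange(nbx) * block_px
    # per shift, which blocks have their candidate window fully in frame
    inbounds = {}
    for dy, dx in shifts:
        ok_r = (by + dy >= 0) & (by + dy + block_px <= ny)
        ok_c = (bx + dx >= 0) & (bx + dx + block_px <= nx)
        inbounds[(dy, dx)] = np.logical_and.outer(ok_r, ok_c)

    for p in range(n_pairs):
        ref = frames[p, :H, :W]
        sx = _block_sums(ref, block_px)
        sxx = _block_sums(ref * ref, block_px)
        var_ref = sxx - sx * sx / n
        textured = var_ref / n >= min_variance

        tgt_pad = np.zeros((ny + 2 * pad, nx + 2 * pad))
        tgt_pad[pad : pad + ny, pad : pad + nx] = frames[p + 1]
        cum_t = _integral(frames[p + 1])
        cum_t2 = _integral(frames[p + 1] ** 2)

        for dy, dx in shifts:
            tgt = tgt_pad[pad + dy : pad + dy + H, pad + dx : pad + dx + W]
            sy = _window_sums(cum_t, by + dy, bx + dx, block_px)
            syy = _window_sums(cum_t2, by + dy, bx + dx, block_px)
            sxy = _block_sums(ref * tgt, block_px)
            var_tgt = syy - sy * sy / n
            denom = np.sqrt(np.maximum(var_ref, 0.0) * np.maximum(var_tgt, 0.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                ncc = (sxy - sx * sy / n) / denom
            ncc = np.where((denom > 0) & inbounds[(dy, dx)] & textured, ncc, -np.inf)
            better = ncc > best_scores[p]
            best_scores[p][better] = ncc[better]
            vectors[p][better] = (dy, dx)
        valid[p] = np.isfinite(best_scores[p])

    return MotionField(
        vectors=vectors,
        scores=best_scores,
        valid=valid,
        frame_rate_hz=frame_rate_hz,
        block_px=block_px,
        search_px=search_px,
    )


@dataclass
class BeatMetrics:
    speed_trace: np.ndarray  # per frame pair, units/s
    time_s: np.ndarray
    beat_rate_hz: float
    n_beats: int
    peak_contraction_velocity: float
    peak_relaxation_velocity: float
    details: dict = field(default_factory=dict)


def motion_beat_metrics(
    field: MotionField,
    pixel_size_um: float = 1.0,
    smooth_window: int = 5,
    peak_rel_height: float = 0.3,
) -> BeatMetrics:
    """Beat rate and peak velocities from a motion field.

    The speed trace is the mean displacement magnitude over valid blocks per
    frame pair times the frame rate (um/s given the pixel size). A
    contraction cycle appears as a pair of speed peaks — contraction then
    relaxation — so detected peaks are paired in order; peak velocities are
    the maxima over the respective phase. A short moving average (default 5
    pairs) suppresses integer-displacement quantization before peak
    detection.
    """
    mags = np.linalg.norm(field.vectors, axis=3)
    mags = np.where(field.valid, mags, np.nan)
    with np.errstate(invalid="ignore"):
        mean_mag = np.nanmean(mags.reshape(mags.shape[0], -1), axis=1)
    mean_mag = np.nan_to_num(mean_mag)
    speed = mean_mag * pixel_size_um * field.frame_rate_hz
    t = (np.arange(len(speed)) + 0.5) / field.frame_rate_hz

    if smooth_window > 2 and len(speed) >= smooth_window:
        # quadratic Savitzky-Golay: averages the integer-displacement
        # quantization noise without flattening the velocity peaks
        smooth = savgol_filter(speed, smooth_window, polyorder=2)
    else:
        smooth = speed

    if smooth.max() <= 0:
        return BeatMetrics(speed, t, 0.0, 0, 0.0, 0.0)

    min_dist = max(1, int(0.05 * field.frame_rate_hz))
    peaks, _ = find_peaks(smooth, height=peak_rel_height * smooth.max(), distance=min_dist)
    n_beats = len(peaks) // 2
    if n_beats == 0:
        return BeatMetrics(speed, t, 0.0, 0, float(smooth.max()), 0.0)
    contraction = peaks[0 : 2 * n_beats : 2]
    relaxation = peaks[1 : 2 * n_beats : 2]
    duration = len(speed) / field.frame_rate_hz
    return BeatMetrics(
        speed_trace=speed,
        time_s=t,
        beat_rate_hz=n_beats / duration,
        n_beats=n_beats,
        peak_contraction_velocity=float(smooth[contraction].max()),
        peak_relaxation_velocity=float(smooth[relaxation].max()),
        details={"contraction_peak_idx": contraction, "relaxation_peak_idx": relaxation},
    )


def deflection_to_force(d, geom: EHTGeometry = EHTGeometry()):
    """Tip force (N) on a cylindrical cantilever post deflected by ``d`` metres.

    F = 3*pi*d*E*r^4 / (4*L^3); exactly linear in d and quartic in r.
    """
    geom.validate()
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("deflection must be nonnegative")
    out = (
        3.0
        * np.pi
        * d
        * geom.elastic_modulus_Pa
        * geom.post_radius_m**4
        / (4.0 * geom.post_length_m**3)
    )
    return float(out) if out.ndim == 0 else out


def eht_force_per_beat(
    time_s: np.ndarray,
    deflection_m: np.ndarray,
    geom: EHTGeometry = EHTGeometry(),
    peak_rel_prominence: float = 0.3,
) -> dict:
    """Per-contraction-cycle force from a post-deflection trace.

    Peaks are contraction maxima; the per-cycle rest position is the local
    minimum between the preceding peak (or trace start) and the current
    peak, so slow baseline drift is tracked cycle by cycle. The maximum
    deflection from rest converts to force via :func:`deflection_to_force`.
    Returns a dict with ``per_beat_force_N``, ``mean_force_N``, ``n_beats``.
    """
    time_s = np.asarray(time_s, dtype=float)
    d = np.asarray(deflection_m, dtype=float)
    if time_s.shape != d.shape or d.ndim != 1:
        raise ValueError("time_s and deflection_m must be 1D of equal length")
    span = float(d.max() - d.min())
    if span <= 0:
        return {"per_beat_force_N": [], "mean_force_N": None, "n_beats": 0}
    peaks, _ = find_peaks(d, prominence=peak_rel_prominence * span)
    if len(peaks) == 0:
        return {"per_beat_force_N": [], "mean_force_N": None, "n_beats": 0}
    # rest = local minimum in the stretch just before each contraction
    # (a quarter of the beat interval): tracking rest per cycle keeps the
    # amplitude honest under slow baseline drift
    interval = float(np.median(np.diff(peaks))) if len(peaks) >= 2 else float(len(d))
    w = max(2, int(round(0.25 * interval)))
    forces = []
    deflections = []
    prev = 0
    for pk in peaks:
        lo = max(prev, pk - w)
        rest = float(d[lo:pk].min()) if pk > lo else float(d[pk])
        amp = max(float(d[pk]) - rest, 0.0)
        deflections.append(amp)
        forces.append(deflection_to_force(amp, geom))
        prev = pk
    return {
        "per_beat_force_N": forces,
        "per_beat_deflection_m": deflections,
        "mean_force_N": float(np.mean(forces)),
        "n_beats": len(forces),
        "peak_times_s": time_s[peaks].tolist(),
    }
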
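"""Calcium-transient kinetics from paced ratiometric (Fura-2) traces.

Cells loaded with Fura-2 and field-stimulated at a fixed pacing rate produce
a F340/F380 ratio trace with one transient per stimulus. This module
segments the trace into per-beat windows and extracts, per transient:

- baseline ratio (mean of the dimmest pre-upstroke samples),
- amplitude (peak minus baseline),
- time to peak,
- decay kinetics: monoexponential tau plus model-free t50/t90 recovery times.

Per-cell summaries are medians across beats, which tolerate occasional
corrupt beats without explicit outlier rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import medfilt

__all__ = [
    "CalciumTrace",
    "TransientMetrics",
    "compute_ratio",
    "segment_transients",
    "transient_metrics",
    "aggregate_cell",
]

#: A pre-upstroke segment must cover at least this fraction of the window
#: to serve as the baseline region; otherwise the trailing (diastolic)
#: quarter of the window is used.
BASELINE_MIN_PRE_FRACTION = 0.15

#: The decay fit starts at this fraction of the half-recovery time after
#: the peak (~the 80%-amplitude point of a monoexponential): the first
#: samples after the maximum still carry upstroke shape and would bias the
#: fitted tau.
FIT_START_T50_FRACTION = 1.0 / 3.0



@dataclass
class CalciumTrace:
    """A paced ratiometric trace (uniformly sampled within 1% jitter)."""

    time_s: np.ndarray
    ratio: np.ndarray
    pacing_hz: float | None = None
    stimulus_times_s: list[float] | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time_s.shape != self.ratio.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and ratio must be 1D arrays of equal length")
        if len(self.time_s) >= 3:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time_s must be strictly ascending")
            if (dt.max() - dt.min()) > 0.01 * dt.mean():
                raise ValueError("sampling must be uniform within 1% jitter")
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("ratio contains non-finite values")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time_s)))


@dataclass
class TransientMetrics:
    baseline_ratio: float
    amplitude: float
    time_to_peak_s: float
    tau_decay_s: float | None
    t50_decay_s: float | None
    t90_decay_s: float | None
    fit_r2: float | None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.tau_decay_s is not None and self.tau_decay_s <= 0:
            raise ValueError("tau_decay_s must be positive when reported")
        if (
            self.t50_decay_s is not None
            and self.t90_decay_s is not None
            and self.t50_decay_s > self.t90_decay_s + 1e-12
        ):
            raise ValueError("t50 must not exceed t90")


def compute_ratio(
    f340: np.ndarray,
    f380: np.ndarray,
    time_s: np.ndarray | None = None,
    bg340: float = 0.0,
    bg380: float = 0.0,
    pacing_hz: float | None = None,
) -> CalciumTrace:
    """Background-corrected excitation ratio (F340 - bg)/(F380 - bg)."""
    f340 = np.asarray(f340, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f340.shape != f380.shape:
        raise ValueError("f340 and f380 must have the same length")
    denom = f380 - bg380
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise ValueError(
            f"background-corrected F380 is nonpositive at sample {bad[0]}; "
            "check bg380 or the channel assignment"
        )
    if time_s is None:
        time_s = np.arange(len(f340), dtype=float)
    return CalciumTrace(time_s=time_s, ratio=(f340 - bg340) / denom, pacing_hz=pacing_hz)


def _detect_upstrokes(trace: CalciumTrace) -> np.ndarray:
    """Fallback beat anchors when stimulus times are absent: threshold crossings.

    The smoothed trace is scanned for upward crossings of the midpoint
    between its 10th and 90th percentiles, separated by at least half a
    pacing period (or 0.5 s when pacing is unknown).
    """
    r = medfilt(trace.ratio, 3)
    lo, hi = np.percentile(r, [10, 90])
    noise = np.std(np.diff(r)) / np.sqrt(2)
    floor = 0.01 * max(np.median(np.abs(r)), 1e-12)
    if hi - lo < max(6 * noise, floor):
        return np.array([])  # flat trace: no beats distinguishable from noise
    thr = 0.5 * (lo + hi)
    above = r > thr
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    if crossings.size == 0:
        return np.array([])
    min_gap = 0.5 / trace.pacing_hz if trace.pacing_hz else 0.5
    kept = [crossings[0]]
    for c in crossings[1:]:
        if trace.time_s[c] - trace.time_s[kept[-1]] >= min_gap:
            kept.append(c)
    return trace.time_s[np.array(kept)]


def segment_transients(trace: CalciumTrace) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a paced trace into one-pacing-period windows.

    Windows anchor at the provided stimulus times; absent those, at detected
    upstrokes. A trailing window that does not fit inside the recording is
    dropped. Returns a list of ``(time_s, ratio)`` pairs with time measured
    from the window start.
    """
    if trace.stimulus_times_s is not None:
        anchors = np.asarray(trace.stimulus_times_s, dtype=float)
    elif trace.pacing_hz is not None or len(trace.time_s):
        anchors = _detect_upstrokes(trace)
        if anchors.size and trace.pacing_hz:
            # back the anchor off by a few samples so the window keeps a
            # pre-upstroke baseline segment
            anchors = np.maximum(anchors - 3.0 / trace.sample_rate_hz, trace.time_s[0])
    else:
        anchors = np.array([])
    if trace.pacing_hz is not None:
        period = 1.0 / trace.pacing_hz
    elif anchors.size >= 2:
        period = float(np.median(np.diff(anchors)))
    else:
        period = None
    if anchors.size == 0 or period is None:
        if anchors.size == 0:
            warnings.warn("no beats detectable in trace", stacklevel=2)
        return []
    windows = []
    # a window is complete when it is short of the recording end by less
    # than one sample period
    t_end = trace.time_s[-1] + 1.0 / trace.sample_rate_hz
    for t0 in anchors:
        if t0 + period > t_end + 1e-9:
            break
        sel = (trace.time_s >= t0 - 1e-9) & (trace.time_s < t0 + period - 1e-9)
        if np.count_nonzero(sel) < 4:
            continue
        windows.append((trace.time_s[sel] - t0, trace.ratio[sel]))
    return windows


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First downward crossing time of ``level`` by linear interpolation."""
    below = y <= level
    idx = np.nonzero(below)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - level) * (t1 - t0) / (y0 - y1))


def transient_metrics(window: tuple[np.ndarray, np.ndarray]) -> TransientMetrics:
    """Kinetic metrics of a single beat window.

    Peak location is found on a lightly smoothed copy (3-sample moving
    median); the amplitude is read from the raw samples averaged over a
    +/-2-sample neighbourhood of the peak, which suppresses the upward bias
    of a raw max under noise without distorting the waveform. The decay tau
    comes from a least-squares monoexponential fit of the raw decay from the
    peak to 90% recovery; t50/t90 are interpolated recovery times and are
    reported even when the fit fails.
    """
    t, y = window
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise ValueError("window too short")
    smooth = medfilt(y, 3)
    i_peak = int(np.argmax(smooth))

    # Diastolic baseline region: the pre-upstroke segment when the window
    # carries one, else the trailing quarter of the window
    # (stimulus-anchored windows start on the upstroke, and the transient
    # has largely recovered before the next stimulus). The median is
    # unbiased under symmetric noise, unlike a low-percentile statistic;
    # the residual decay still present in a trailing region is corrected
    # iteratively below once tau is known.
    n_pre = max(i_peak - int(0.05 * len(y)), 0)
    if n_pre >= int(BASELINE_MIN_PRE_FRACTION * len(y)):
        quiescent_idx = np.arange(n_pre)
        tail_region = False
    else:
        quiescent_idx = np.arange(int(0.75 * len(y)), len(y))
        tail_region = True
    baseline = float(np.median(y[quiescent_idx]))

    # peak value: parabolic vertex through the smoothed samples around the
    # detected maximum — unbiased for a smooth extremum and far less
    # sensitive to single noise excursions than a raw max
    lo = max(0, i_peak - 2)
    hi = min(len(y), i_peak + 3)
    if hi - lo >= 3:
        coef = np.polyfit(t[lo:hi] - t[i_peak], smooth[lo:hi], 2)
        peak_val = float(coef[2] - coef[1] ** 2 / (4 * coef[0])) if coef[0] < 0 else float(y[i_peak])
    else:
        peak_val = float(y[i_peak])
    time_to_peak = float(t[i_peak] - t[0])

    tau = None
    r2 = None
    t50 = None
    t90 = None
    amplitude = max(peak_val - baseline, 0.0)
    if amplitude > 0 and i_peak < len(t) - 3:
        td = t[i_peak:] - t[i_peak]
        yd = y[i_peak:]
        for _ in range(3):  # refine baseline against its own decay tail
            amplitude = max(peak_val - baseline, 0.0)
            t50 = _interp_crossing(td, smooth[i_peak:], baseline + 0.5 * amplitude)
            t90 = _interp_crossing(td, smooth[i_peak:], baseline + 0.1 * amplitude)
            if t50 is None or t50 <= 0:
                break
            # fit the decay from the noise-robust ~80%-amplitude point
            # (t50/3 for a monoexponential; the first samples after the
            # maximum still carry upstroke shape) down to 90% recovery
            fit_start = int(np.searchsorted(td, t50 * FIT_START_T50_FRACTION))
            fit_end = len(td) if t90 is None else max(fit_start + 4, int(np.searchsorted(td, t90)) + 1)
            td_fit, yd_fit = td[fit_start:fit_end], yd[fit_start:fit_end]
            if len(td_fit) < 4:
                td_fit, yd_fit = td[:fit_end], yd[:fit_end]
            # rate initialized from the half-recovery time and bounded
            # within a factor of 8 of it; the asymptote is pinned to the
            # measured baseline: a free offset is nearly collinear with a
            # slow rate over a finite decay segment
            k0 = np.log(2.0) / t50
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    b_fix = baseline
                    popt, _ = curve_fit(
                        lambda tt, c, k: b_fix + c * np.exp(-k * tt),
                        td_fit,
                        yd_fit,
                        p0=(max(amplitude, 1e-6), k0),
                        bounds=([0.0, k0 / 8.0], [np.inf, k0 * 8.0]),
                        maxfev=2000,
                    )
            except (RuntimeError, ValueError):
                tau = None
                r2 = None
                break
            tau = float(1.0 / popt[1])
            resid = yd_fit - (b_fix + popt[0] * np.exp(-popt[1] * td_fit))
            ss_tot = float(np.sum((yd_fit - yd_fit.mean()) ** 2))
            r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else None
            if not tail_region:
                break
            tail_t = t[quiescent_idx] - t[i_peak]
            residual_tail = float(np.median(popt[0] * np.exp(-tail_t / tau)))
            new_baseline = float(np.median(y[quiescent_idx])) - residual_tail
            if abs(new_baseline - baseline) < 1e-6:
                baseline = new_baseline
                break
            baseline = new_baseline
        amplitude = max(peak_val - baseline, 0.0)
    if t50 is not None and t90 is not None and t50 > t90:
        t50, t90 = t90, t50  # pathological noise ordering; keep the invariant
    return TransientMetrics(
        baseline_ratio=baseline,
        amplitude=amplitude,
        time_to_peak_s=time_to_peak,
        tau_decay_s=tau,
        t50_decay_s=t50,
        t90_decay_s=t90,
        fit_r2=r2,
    )


def aggregate_cell(metrics: list[TransientMetrics]) -> dict:
    """Per-cell summary: median across beats per metric, with beat count.

    Raises ``ValueError`` for an empty beat list (the cell is excluded
    upstream with a logged reason). Beats whose decay fit failed contribute
    to amplitude statistics but not to tau.
    """
    if not metrics:
        raise ValueError("no analyzable beats; cell excluded")

    out: dict = {"n_beats": len(metrics)}
    for name in ("baseline_ratio", "amplitude", "time_to_peak_s", "tau_decay_s", "t50_decay_s", "t90_decay_s"):
        vals = np.array([v for v in (getattr(m, name) for m in metrics) if v is not None], dtype=float)
        out[name] = float(np.median(vals)) if vals.size else None
        out[name + "_sd"] = float(np.std(vals)) if vals.size else None
        out[name + "_n"] = int(vals.size)
    return out
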
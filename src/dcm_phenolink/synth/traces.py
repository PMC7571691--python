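"""Synthetic paced ratiometric calcium transients.

Each beat is modelled as a saturating rise multiplied by a monoexponential
decay,

    g(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay),  t >= 0,

normalized to unit peak so that the requested amplitude is exactly the peak
excess over baseline. The peak occurs at t* = tau_rise*ln(1 + tau_decay/tau_rise)
(zero of g'), which gives the closed-form normalization used below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dcm_phenolink.calcium import CalciumTrace

__all__ = ["TraceSpec", "generate_calcium_trace", "transient_shape", "transient_peak_time"]


@dataclass(frozen=True)
class TraceSpec:
    duration_s: float = 10.0
    sample_rate_hz: float = 50.0
    pacing_hz: float = 0.5
    baseline_ratio: float = 1.0
    amplitude: float = 0.5
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.4
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0 or self.pacing_hz <= 0:
            raise ValueError("duration, sample rate and pacing must be positive")
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise ValueError("time constants must be positive")
        period = 1.0 / self.pacing_hz
        if period <= self.tau_rise_s + self.tau_decay_s:
            raise ValueError(
                f"pacing period {period:.3g} s must exceed tau_rise + tau_decay = "
                f"{self.tau_rise_s + self.tau_decay_s:.3g} s; transients would overlap"
            )
        if self.sample_rate_hz < 20 * self.pacing_hz:
            raise ValueError("sample_rate_hz must be at least 20x pacing_hz")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be nonnegative")


def transient_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of the un-normalized rise*decay product."""
    return tau_rise * np.log1p(tau_decay / tau_rise)


def transient_shape(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak transient waveform; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0, -np.expm1(-np.maximum(t, 0) / tau_rise) * np.exp(-np.maximum(t, 0) / tau_decay), 0.0)
    t_peak = transient_peak_time(tau_rise, tau_decay)
    g_peak = -np.expm1(-t_peak / tau_rise) * np.exp(-t_peak / tau_decay)
    return g / g_peak


def generate_calcium_trace(spec: TraceSpec) -> CalciumTrace:
    """Simulate a paced F340/F380 ratio trace with per-beat ground truth.

    Stimuli fire at multiples of the pacing period starting at t = 0; the
    trace is the baseline plus one unit-peak transient scaled by
    ``amplitude`` per stimulus, plus white Gaussian noise. Ground-truth
    per-beat parameters are stored on the returned trace.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    period = 1.0 / spec.pacing_hz
    n_beats = int(np.floor(spec.duration_s * spec.pacing_hz))
    stim = np.arange(n_beats) * period

    ratio = np.full(n, spec.baseline_ratio)
    for t0 in stim:
        ratio = ratio + spec.amplitude * transient_shape(t - t0, spec.tau_rise_s, spec.tau_decay_s)
    if spec.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, spec.noise_sd, size=n)

    truth = {
        "baseline_ratio": spec.baseline_ratio,
        "amplitude": spec.amplitude,
        "tau_rise_s": spec.tau_rise_s,
        "tau_decay_s": spec.tau_decay_s,
        "time_to_peak_s": float(transient_peak_time(spec.tau_rise_s, spec.tau_decay_s)),
        "n_beats": n_beats,
        "spec": spec,
    }
    return CalciumTrace(
        time_s=t,
        ratio=ratio,
        pacing_hz=spec.pacing_hz,
        stimulus_times_s=stim.tolist(),
        truth=truth,
    )
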
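"""Derived-variable formulas operating on trial-level measurements.

Covers the bespoke quantities computed from balance, gait and dynamometer
trials before any statistics: sway ratios (Romberg, somatosensory), the
symmetry angle for inter-limb asymmetry, MAD% gait variability, gait speed
reserve, rate of torque development (RTD) from filtered torque-time traces,
muscle-quality indices and flexor/extensor strength ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt


@dataclass
class TorqueTrace:
    """Uniformly sampled torque signal (Nm) from an isometric contraction.

    ``baseline_window`` is the leading number of samples treated as rest when
    estimating the pre-contraction baseline torque.
    """

    samples: np.ndarray
    rate: float  # Hz
    baseline_window: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.baseline_window is None:
            # default rest window: first 500 ms of the trace
            self.baseline_window = max(1, int(round(0.5 * self.rate)))

    def __len__(self) -> int:
        return len(self.samples)


def symmetry_angle(left: float, right: float) -> float:
    """Inter-limb symmetry angle as a percentage, |45deg - atan(L/R)| / 90 * 100.

    0 means perfect symmetry; 50 is the boundary (one side zero).  The
    magnitude (absolute value) is returned, so the measure is order-invariant.
    A zero right side is handled as the arctan limit of 90deg.
    """
    if left < 0 or right < 0:
        raise ValueError("symmetry angle requires non-negative inputs")
    if left == 0 and right == 0:
        raise ValueError("symmetry angle undefined when both sides are zero")
    angle = 90.0 if right == 0 else np.degrees(np.arctan(left / right))
    return abs(45.0 - angle) / 90.0 * 100.0


def romberg_ratio(ec_sway: float, eo_sway: float) -> float:
    """Eyes-closed / eyes-open sway velocity: visual contribution to balance."""
    if eo_sway <= 0:
        raise ValueError("eyes-open sway velocity must be positive")
    return ec_sway / eo_sway


def somatosensory_ratio(foam_sway: float, firm_sway: float) -> float:
    """Foam / firm surface sway velocity: somatosensory contribution."""
    if firm_sway <= 0:
        raise ValueError("firm-surface sway velocity must be positive")
    return foam_sway / firm_sway


def mad_percent(series) -> float:
    """Median absolute deviation of repeated trials as % of the median.

    The raw MAD (no 1.4826 consistency constant) divided by |median| times
    100; the gait-variability measure applied to the five steps per variable.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 trials")
    med = np.median(s)
    if med == 0:
        raise ValueError("median is zero; MAD% undefined")
    return float(np.median(np.abs(s - med)) / abs(med) * 100.0)


def gait_speed_reserve(mgs: float, ugs: float) -> float:
    """Maximal / usual gait speed: capacity to increase walking speed."""
    if ugs <= 0:
        raise ValueError("usual gait speed must be positive")
    return mgs / ugs


def butterworth_lowpass(t: TorqueTrace, cutoff: float = 150.0, order: int = 2) -> TorqueTrace:
    """Zero-phase (forward-backward) low-pass Butterworth filtering.

    Default 150 Hz cut-off at order 2, the configuration used for torque
    signals before RTD analysis.  Bidirectional filtering avoids phase lag
    that would bias onset timing.
    """
    if cutoff >= t.rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(order, cutoff, fs=t.rate)
    return replace(t, samples=filtfilt(b, a, t.samples))


def detect_onset(t: TorqueTrace, delta: float = 4.0) -> int:
    """First sample index where torque reaches ``delta`` Nm above baseline.

    Baseline is the mean over the trace's leading ``baseline_window`` samples.
    The search starts after the baseline window; a trace already above
    threshold there returns the first post-window sample.
    """
    base = float(np.mean(t.samples[: t.baseline_window]))
    threshold = base + delta
    idx = np.nonzero(t.samples[t.baseline_window:] >= threshold)[0]
    if idx.size == 0:
        raise ValueError(f"torque never reaches baseline + {delta} Nm")
    return int(idx[0] + t.baseline_window)


def rtd(
    t: TorqueTrace,
    windows: tuple[tuple[float, float], ...] = ((0, 50), (0, 100), (0, 200)),
    delta: float = 4.0,
    method: str = "endpoint",
) -> list[float]:
    """Rate of torque development (Nm/s) over early windows from onset.

    For each (0, w) window in milliseconds: the slope delta-torque /
    delta-time between onset and onset + w.  ``method="leastsq"`` fits a
    least-squares line over the window instead of using the endpoints.
    """
    onset = detect_onset(t, delta=delta)
    out = []
    for start, stop in windows:
        i0 = onset + int(round(start / 1000.0 * t.rate))
        i1 = onset + int(round(stop / 1000.0 * t.rate))
        if i1 >= len(t):
            raise ValueError(
                f"trace too short after onset for the (0, {stop:g}) ms window"
            )
        if method == "endpoint":
            out.append((t.samples[i1] - t.samples[i0]) / ((stop - start) / 1000.0))
        elif method == "leastsq":
            tt = np.arange(i0, i1 + 1) / t.rate
            out.append(float(np.polyfit(tt, t.samples[i0 : i1 + 1], 1)[0]))
        else:
            raise ValueError(f"unknown RTD method {method!r}")
    return out


def muscle_quality(torques, lean_mass: float) -> float:
    """Muscle quality: summed peak torque per kilogram of lean tissue (Nm/kg).

    Callers compose the printed indices: single-torque variants pass one
    torque, combined extension+flexion variants pass both; the dominant limb
    is the one with the higher measured torque, and the composite index is
    the mean of the dominant and non-dominant values.
    """
    if lean_mass <= 0:
        raise ValueError("lean mass must be positive")
    return float(np.sum(np.asarray(torques, dtype=float)) / lean_mass)


def strength_ratio(flexor_pt: float, extensor_pt: float) -> float:
    """Flexor / extensor peak-torque quotient (also dorsi/plantar-flexion)."""
    if extensor_pt <= 0:
        raise ValueError("extensor peak torque must be positive")
    return flexor_pt / extensor_pt
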
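"""Trial segmentation, filtering, and kinematic magnitude series.

The processing chain mirrors standard offline wearable-accelerometry
practice: crop each trial to its task-performance window, low-pass the
axis signals at 8 Hz (6th-order Butterworth) to remove high-frequency
noise, high-pass at 0.25 Hz (6th-order Butterworth) to isolate movement
from gravity and slow postural adjustment, then derive velocity and
displacement by trapezoidal integration (re-applying the 0.25 Hz
high-pass after each integration to suppress drift) and jerk by central
differencing.  Per-sample magnitudes are the Euclidean norm across axes.

Both filters are applied forward–backward (zero phase), which doubles
the effective order; this keeps temporal features undistorted at the
cost of a steeper-than-nominal transition band.

Units follow the g-input convention: acceleration in g, velocity in
g·s, displacement in g·s², jerk in g/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .types import SensorChannel, SensorTrial

__all__ = [
    "LOWPASS_HZ",
    "HIGHPASS_HZ",
    "FILTER_ORDER",
    "KinematicSeries",
    "segment_trial",
    "bandfilter",
    "highpass",
    "derive_kinematics",
    "min_filter_length",
]

LOWPASS_HZ = 8.0
HIGHPASS_HZ = 0.25
FILTER_ORDER = 6


from functools import lru_cache


@lru_cache(maxsize=32)
def _lp_sos(fs: float, cutoff: float = LOWPASS_HZ, order: int = FILTER_ORDER):
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


@lru_cache(maxsize=32)
def _hp_sos(fs: float, cutoff: float = HIGHPASS_HZ, order: int = FILTER_ORDER):
    return signal.butter(order, cutoff, btype="high", fs=fs, output="sos")


def min_filter_length(order: int = FILTER_ORDER) -> int:
    """Shortest input the zero-phase cascade accepts (3 × (order + 1))."""
    return 3 * (order + 1)


def _check_length(n: int) -> None:
    if n <= min_filter_length():
        raise ValueError(
            f"window of {n} samples is too short to filter "
            f"(need > {min_filter_length()})"
        )


def _zerophase(sos, x: np.ndarray) -> np.ndarray:
    """Symmetrized forward–backward filtering.

    A single ``sosfiltfilt`` pass is only approximately invariant under
    time reversal because its edge conditioning is one-sided relative to
    the long transient of the 0.25 Hz stage.  Averaging the
    forward–backward and backward–forward passes makes the operator
    exactly time-reversal symmetric (and keeps zero phase); padding is
    widened toward the transient length of the slowest stage.
    """
    n = x.shape[0]
    padlen = int(min(n - 2, 300))
    a = signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)
    b = signal.sosfiltfilt(sos, x[::-1], axis=0, padlen=padlen)[::-1]
    return 0.5 * (a + b)


def segment_trial(trial: SensorTrial) -> SensorTrial:
    """Crop all channels to the ``[start_marker, end_marker)`` window.

    Returns a new trial whose markers span the full cropped window.
    """
    trial.validate()
    start, end = trial.start_marker, trial.end_marker
    _check_length(end - start)
    channels = {
        name: SensorChannel(ch.placement, ch.samples[start:end], ch.fs)
        for name, ch in trial.channels.items()
    }
    return replace(
        trial, channels=channels, start_marker=0, end_marker=end - start
    )


def bandfilter(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 8 Hz low-pass then 0.25 Hz high-pass Butterworth cascade.

    Accepts a 1-D series or an (n_samples, n_axes) array; filters along
    axis 0.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * LOWPASS_HZ:
        raise ValueError(f"fs={fs} Hz violates Nyquist for the 8 Hz low-pass")
    _check_length(x.shape[0])
    y = _zerophase(_lp_sos(fs), x)
    return _zerophase(_hp_sos(fs), y)


def highpass(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.25 Hz high-pass only (used after each integration)."""
    return _zerophase(_hp_sos(fs), np.asarray(x, dtype=float))


@dataclass
class KinematicSeries:
    """Magnitude time series for one sensor placement.

    All four series share one length; magnitudes are nonnegative by
    construction.
    """

    displacement: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    jerk: np.ndarray
    fs: float
    placement: str

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "disp": self.displacement,
            "vel": self.velocity,
            "acc": self.acceleration,
            "jerk": self.jerk,
        }


def _cumtrapz(x: np.ndarray, fs: float) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(x, dx=1.0 / fs, axis=0, initial=0.0)


def derive_kinematics(
    channel: SensorChannel, *, prefiltered: bool = True
) -> KinematicSeries:
    """Derive displacement/velocity/acceleration/jerk magnitude series.

    ``prefiltered=False`` applies the band-pass cascade first; otherwise
    the channel samples are assumed to already be band-filtered.
    """
    acc = np.asarray(channel.samples, dtype=float)
    fs = channel.fs
    if not prefiltered:
        acc = bandfilter(acc, fs)
    vel = highpass(_cumtrapz(acc, fs), fs)
    disp = highpass(_cumtrapz(vel, fs), fs)
    jerk = np.gradient(acc, 1.0 / fs, axis=0)
    norm = lambda a: np.linalg.norm(a, axis=1)  # noqa: E731
    return KinematicSeries(
        displacement=norm(disp),
        velocity=norm(vel),
        acceleration=norm(acc),
        jerk=norm(jerk),
        fs=fs,
        placement=channel.placement,
    )
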
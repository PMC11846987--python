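"""Per-axis signal conditioning from raw mG accelerometry to displacement.

The chain applied to every axis of every sensor, in order:

1. outlier replacement — samples beyond ``k`` standard deviations from the
   trace mean (mean and SD computed once over the whole trace) are replaced
   by linear interpolation between the nearest retained neighbours;
2. gravity zeroing — subtraction of the whole-session mean;
3. unit conversion mG → m·s⁻² (standard gravity, 9.80665 m·s⁻² per 1000 mG);
4. band-pass Butterworth filter (default 2nd order, 0.5–11 Hz), zero-phase
   (forward–backward) by default;
5. cumulative-trapezoid integration to velocity, and again to displacement.

Double integration of band-limited noise produces low-frequency drift that
would otherwise dominate displacement-derived metrics, so by default each
integration is followed by the same high-pass corner (0.5 Hz) and mean
removal (``drift_correction``).  Setting ``zero_phase=False`` and
``drift_correction=False`` gives a strict single-pass variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    LengthError,
    UnitError,
)
from .signals import AxisTrace, SensorRecording

#: standard gravity, m·s⁻² per g
STANDARD_GRAVITY = 9.80665

#: unit produced by integrating each unit once
_INTEGRATED_UNIT = {"m_s2": "m_s", "m_s": "m"}


@dataclass
class PreprocessConfig:
    """Tunable parameters of the conditioning chain.

    ``norm_mode`` selects how the three axes are combined into the global
    magnitude trace: ``"as_printed"`` is the sum of per-axis absolute values,
    ``"euclidean"`` the L2 norm (see :func:`esokin.kinematics.global_magnitude`).
    """

    outlier_k: float = 3.0
    band_low_hz: float = 0.5
    band_high_hz: float = 11.0
    filter_order: int = 2
    zero_phase: bool = True
    drift_correction: bool = True
    norm_mode: str = "as_printed"

    def validate(self, rate: float) -> None:
        if not (0.0 < self.band_low_hz < self.band_high_hz < rate / 2.0):
            raise ConfigurationError(
                f"need 0 < band_low_hz < band_high_hz < rate/2; got "
                f"({self.band_low_hz}, {self.band_high_hz}) at {rate} Hz"
            )
        if self.outlier_k <= 0:
            raise ConfigurationError("outlier_k must be > 0")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if self.norm_mode not in ("as_printed", "euclidean"):
            raise ConfigurationError(f"unknown norm_mode {self.norm_mode!r}")


@dataclass
class ProcessedSignals:
    """Filtered acceleration, velocity and displacement for one sensor."""

    acc_x: AxisTrace
    acc_y: AxisTrace
    acc_z: AxisTrace
    vel_x: AxisTrace
    vel_y: AxisTrace
    vel_z: AxisTrace
    disp_x: AxisTrace
    disp_y: AxisTrace
    disp_z: AxisTrace
    acc_global: AxisTrace
    disp_global: AxisTrace
    fraction_unchanged: float = 1.0

    @property
    def rate(self) -> float:
        return self.acc_x.rate

    def __len__(self) -> int:
        return len(self.acc_x)


def replace_outliers(trace: AxisTrace, k: float = 3.0) -> tuple[AxisTrace, float]:
    """Replace samples beyond ``k`` SDs of the trace mean by interpolation.

    Mean and SD are computed once over the full trace (population SD).  A
    flagged sample is replaced by linear interpolation between the nearest
    retained neighbours; flagged samples at the edges take the nearest
    retained value.  Returns the cleaned trace and the fraction replaced.
    Constant traces (SD = 0) have no outliers because the comparison is
    strict.
    """
    x = trace.samples
    if x.size < 2:
        raise LengthError("outlier replacement needs at least 2 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x))  # single pass over the full trace
    mask = np.abs(x - mean) > k * sd
    n_out = int(mask.sum())
    if n_out == 0:
        return trace.replace(samples=x.copy()), 0.0
    if n_out == x.size:
        raise DegenerateInputError("every sample flagged as an outlier")
    good = np.flatnonzero(~mask)
    cleaned = x.copy()
    # np.interp holds the boundary values flat, which implements the
    # nearest-valid-value rule for leading/trailing outliers.
    cleaned[mask] = np.interp(np.flatnonzero(mask), good, x[good])
    return trace.replace(samples=cleaned), n_out / x.size


def remove_mean(trace: AxisTrace) -> AxisTrace:
    """Zero the trace by subtracting its whole-session mean (gravity removal)."""
    return trace.replace(samples=trace.samples - np.mean(trace.samples))


def convert_mg_to_ms2(trace: AxisTrace) -> AxisTrace:
    """Convert a trace recorded in mG to m·s⁻²."""
    if trace.units != "mG":
        raise UnitError(f"expected units mG, got {trace.units!r}")
    return trace.replace(samples=trace.samples * (STANDARD_GRAVITY / 1000.0),
                         units="m_s2")


def _sos_bandpass(low: float, high: float, order: int, rate: float):
    return sps.butter(order, [low, high], btype="bandpass", fs=rate,
                      output="sos")


def _apply_sos(sos, x: np.ndarray, zero_phase: bool,
               rate: float | None = None, low_hz: float | None = None
               ) -> np.ndarray:
    if zero_phase:
        min_pad = 3 * (2 * sos.shape[0] + 1)
        if x.size <= min_pad:
            raise LengthError(
                f"trace of {x.size} samples is shorter than the zero-phase "
                f"filter warm-up length ({min_pad + 1})"
            )
        # pad long enough to absorb the slowest (high-pass corner) edge
        # transient; scipy's default pad covers only the section count
        padlen = min_pad
        if rate and low_hz:
            padlen = min(x.size - 1, max(min_pad, int(3.0 * rate / low_hz)))
        return sps.sosfiltfilt(sos, x, padlen=padlen)
    if x.size <= 2 * sos.shape[0] + 1:
        raise LengthError("trace shorter than the filter warm-up length")
    return sps.sosfilt(sos, x)


def bandpass_filter(trace: AxisTrace, config: PreprocessConfig | None = None) -> AxisTrace:
    """Butterworth band-pass (default 2nd order, 0.5–11 Hz) on one trace.

    With ``zero_phase`` the filter runs forward and backward (no lag, squared
    magnitude response); otherwise a single causal pass.
    """
    config = config or PreprocessConfig()
    config.validate(trace.rate)
    sos = _sos_bandpass(config.band_low_hz, config.band_high_hz,
                        config.filter_order, trace.rate)
    return trace.replace(samples=_apply_sos(
        sos, trace.samples, config.zero_phase,
        rate=trace.rate, low_hz=config.band_low_hz))


def integrate_trapezoid(
    trace: AxisTrace,
    drift_correction: bool = True,
    *,
    highpass_hz: float = 0.5,
    filter_order: int = 2,
    zero_phase: bool = True,
) -> AxisTrace:
    """Cumulative-trapezoid integration of one trace (initial value 0).

    Units are demoted one derivative (m·s⁻² → m·s⁻¹ → m).  With
    ``drift_correction`` the integral is high-pass filtered at
    ``highpass_hz`` and mean-removed before return, suppressing the
    random-walk drift that integration of noise produces.
    """
    if trace.units not in _INTEGRATED_UNIT:
        raise UnitError(f"cannot integrate units {trace.units!r}")
    y = cumulative_trapezoid(trace.samples, dx=1.0 / trace.rate, initial=0.0)
    if drift_correction:
        sos = sps.butter(filter_order, highpass_hz, btype="highpass",
                         fs=trace.rate, output="sos")
        y = _apply_sos(sos, y, zero_phase, rate=trace.rate, low_hz=highpass_hz)
        y = y - np.mean(y)
    return trace.replace(samples=y, units=_INTEGRATED_UNIT[trace.units])


def preprocess_axis(trace: AxisTrace, config: PreprocessConfig) -> tuple[
        AxisTrace, AxisTrace, AxisTrace, float]:
    """Full chain on one axis: returns (acceleration, velocity, displacement,
    fraction_replaced)."""
    cleaned, frac = replace_outliers(trace, config.outlier_k)
    zeroed = remove_mean(cleaned)
    ms2 = convert_mg_to_ms2(zeroed)
    acc = bandpass_filter(ms2, config)
    vel = integrate_trapezoid(
        acc, config.drift_correction, highpass_hz=config.band_low_hz,
        filter_order=config.filter_order, zero_phase=config.zero_phase)
    disp = integrate_trapezoid(
        vel, config.drift_correction, highpass_hz=config.band_low_hz,
        filter_order=config.filter_order, zero_phase=config.zero_phase)
    return acc, vel, disp, frac


def preprocess_sensor(
    recording: SensorRecording,
    config: PreprocessConfig | None = None,
) -> ProcessedSignals:
    """Run the conditioning chain on all three axes of one sensor.

    ``fraction_unchanged`` is the mean over axes of the proportion of samples
    *not* replaced by the outlier stage.
    """
    # imported here to keep the module dependency one-directional at import
    from .kinematics import global_magnitude

    config = config or PreprocessConfig()
    config.validate(recording.rate)
    for t in recording.traces:
        if t.units != "mG":
            raise UnitError(
                f"{recording.placement}.{t.axis}: expected raw mG input, "
                f"got {t.units!r}")

    out: dict[str, AxisTrace] = {}
    fractions = []
    for trace in recording.traces:
        acc, vel, disp, frac = preprocess_axis(trace, config)
        out[f"acc_{trace.axis}"] = acc
        out[f"vel_{trace.axis}"] = vel
        out[f"disp_{trace.axis}"] = disp
        fractions.append(frac)

    acc_global = global_magnitude(out["acc_x"], out["acc_y"], out["acc_z"],
                                  config.norm_mode)
    disp_global = global_magnitude(out["disp_x"], out["disp_y"], out["disp_z"],
                                   config.norm_mode)
    return ProcessedSignals(
        **out,
        acc_global=acc_global,
        disp_global=disp_global,
        fraction_unchanged=float(1.0 - np.mean(fractions)),
    )
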
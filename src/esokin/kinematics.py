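"""Per-session kinematic metrics.

From the processed hand/forearm/arm signals a session is summarized by:

* RMS of the global acceleration magnitude of each segment (m·s⁻²);
* hand:forearm and forearm:arm RMS ratios — how much more one segment
  accelerates than the next proximal one;
* the summed count of sign changes of the three hand velocity components —
  an index of repetitive direction change;
* cumulative distance: the sum of absolute frame-to-frame changes of the
  global hand displacement magnitude (m);
* a 95% confidence ellipse of the hand's x–y displacement point cloud,
  reported in cm: semi-axes a ≥ b, area A = πab, and the long:short axis
  ratio a/b (1 for a circular footprint).

The global magnitude combines the three axes per frame.  The published form
is the sum of per-axis absolute values (√x² + √y² + √z²); an L2
(``euclidean``) option is provided because the L1 form is unusual.  The L1
default is kept for fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .errors import (
    DegenerateGeometryError,
    DegenerateInputError,
    LengthError,
)
from .preprocess import PreprocessConfig, ProcessedSignals
from .signals import AxisTrace


@dataclass
class EllipseFit:
    """Confidence ellipse of a 2D point cloud (cm units).

    Axes come from the eigen-decomposition of the sample covariance, scaled
    by the χ²(2) quantile at the coverage level: a Gaussian cloud falls
    inside the ellipse with probability ``coverage``.
    """

    a: float                      # long semi-axis, cm
    b: float                      # short semi-axis, cm
    area_cm2: float               # π·a·b
    long_short_ratio: float       # a/b ≥ 1
    center: tuple[float, float]   # (x̄, ȳ), cm
    orientation_rad: float        # angle of the long axis
    coverage: float = 0.95


@dataclass
class KinematicSummary:
    """The scalar metric suite of one session."""

    hand_rms: float
    forearm_rms: float
    arm_rms: float
    hand_forearm_ratio: float
    forearm_arm_ratio: float
    zero_crossings: int
    cumulative_distance_m: float
    ellipse: EllipseFit | None
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        """Flatten to one metrics-table row (fixed schema, see signals)."""
        e = self.ellipse
        return {
            "hand_rms": self.hand_rms,
            "forearm_rms": self.forearm_rms,
            "arm_rms": self.arm_rms,
            "hand_forearm_ratio": self.hand_forearm_ratio,
            "forearm_arm_ratio": self.forearm_arm_ratio,
            "zero_crossings": self.zero_crossings,
            "cumulative_distance_m": self.cumulative_distance_m,
            "ellipse_a_cm": e.a if e else np.nan,
            "ellipse_b_cm": e.b if e else np.nan,
            "ellipse_area_cm2": e.area_cm2 if e else np.nan,
            "long_short_ratio": e.long_short_ratio if e else np.nan,
        }


def _as_array(trace) -> np.ndarray:
    return trace.samples if isinstance(trace, AxisTrace) else np.asarray(trace, float)


def global_magnitude(x, y, z, norm_mode: str = "as_printed"):
    """Combine three axis traces into one nonnegative magnitude trace.

    ``as_printed``: per-frame |x| + |y| + |z|.  ``euclidean``:
    √(x² + y² + z²).  The L1 form dominates the L2 form frame-wise.
    """
    ax, ay, az = _as_array(x), _as_array(y), _as_array(z)
    if not (ax.shape == ay.shape == az.shape):
        raise LengthError("axis traces must have equal length")
    if norm_mode == "as_printed":
        mag = np.abs(ax) + np.abs(ay) + np.abs(az)
    elif norm_mode == "euclidean":
        mag = np.sqrt(ax**2 + ay**2 + az**2)
    else:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    if isinstance(x, AxisTrace):
        return x.replace(samples=mag, axis="global")
    return mag


def rms(trace) -> float:
    """Root mean square of a trace: √(mean of squared samples)."""
    x = _as_array(trace)
    if x.size == 0:
        raise LengthError("RMS of an empty trace")
    return float(np.sqrt(np.mean(x**2)))


def segment_ratios(hand_rms: float, forearm_rms: float, arm_rms: float
                   ) -> tuple[float, float]:
    """(hand:forearm, forearm:arm) RMS acceleration ratios."""
    if forearm_rms <= 0 or arm_rms <= 0:
        raise DegenerateInputError("segment ratio with a zero-RMS denominator")
    return hand_rms / forearm_rms, forearm_rms / arm_rms


def count_zero_crossings(vx, vy, vz, deadband: float = 0.0) -> int:
    """Summed sign changes of three velocity traces.

    A crossing is a pair of consecutive *effective* samples whose signs
    multiply negative; samples with |v| ≤ deadband count as zero, and exact
    zeros carry the previous sign forward (so a touch of zero without a
    sign change is not a crossing).
    """
    total = 0
    for v in (vx, vy, vz):
        x = _as_array(v)
        s = np.sign(np.where(np.abs(x) <= deadband, 0.0, x))
        nz = s[s != 0.0]
        if nz.size >= 2:
            total += int(np.sum(nz[1:] * nz[:-1] < 0))
    return total


def cumulative_distance(disp_global) -> float:
    """Sum of absolute frame-to-frame changes of the displacement magnitude."""
    d = _as_array(disp_global)
    if d.size < 2:
        raise LengthError("cumulative distance needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(d))))


def fit_confidence_ellipse(points: np.ndarray, coverage: float = 0.95
                           ) -> EllipseFit:
    """Fit a coverage ellipse to a 2D point cloud (cm).

    The sample covariance is eigen-decomposed; semi-axes are
    a = √(q·λ₁), b = √(q·λ₂) with λ₁ ≥ λ₂ and q the χ²(2) quantile at the
    coverage level (q ≈ 5.9915 at 0.95).  This is the population-coverage
    ellipse of the cloud, not a standard-error ellipse of its mean.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("ellipse fit needs at least 3 points")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")

    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)       # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam2 <= 0 or lam2 <= 1e-12 * max(lam1, 1.0):
        raise DegenerateGeometryError(
            "points are collinear or coincident; ellipse is degenerate")
    q = float(spstats.chi2.ppf(coverage, df=2))
    a, b = float(np.sqrt(q * lam1)), float(np.sqrt(q * lam2))
    vec = evecs[:, 1]
    center = pts.mean(axis=0)
    return EllipseFit(
        a=a,
        b=b,
        area_cm2=float(np.pi * a * b),
        long_short_ratio=a / b,
        center=(float(center[0]), float(center[1])),
        orientation_rad=float(np.arctan2(vec[1], vec[0])),
        coverage=coverage,
    )


def summarize_session(
    hand: ProcessedSignals,
    forearm: ProcessedSignals,
    arm: ProcessedSignals,
    config: PreprocessConfig | None = None,
    deadband: float = 0.0,
) -> KinematicSummary:
    """Assemble the full metric suite from three processed sensors.

    RMS values come from each segment's global acceleration; direction
    changes from the hand velocity components; distance from the hand's
    global displacement; the ellipse from the hand's x–y displacement in cm.
    A degenerate (e.g. motionless) point cloud yields ``ellipse=None`` with
    a ``"degenerate-ellipse"`` flag instead of an exception, so near-zero
    sessions still produce a row.
    """
    if not (len(hand) == len(forearm) == len(arm)):
        raise LengthError("the three sensors must have equal trace lengths")
    if not (hand.rate == forearm.rate == arm.rate):
        raise LengthError("the three sensors must share the sampling rate")

    flags: list[str] = []
    hand_rms_v = rms(hand.acc_global)
    forearm_rms_v = rms(forearm.acc_global)
    arm_rms_v = rms(arm.acc_global)
    try:
        r_hf, r_fa = segment_ratios(hand_rms_v, forearm_rms_v, arm_rms_v)
    except DegenerateInputError:
        r_hf = r_fa = float("nan")  # motionless segment: ratios undefined
        flags.append("degenerate-rms")

    zc = count_zero_crossings(hand.vel_x, hand.vel_y, hand.vel_z, deadband)
    cd = cumulative_distance(hand.disp_global)

    pts_cm = np.column_stack([hand.disp_x.samples, hand.disp_y.samples]) * 100.0
    try:
        ellipse = fit_confidence_ellipse(pts_cm)
    except DegenerateGeometryError:
        ellipse = None
        flags.append("degenerate-ellipse")

    return KinematicSummary(
        hand_rms=hand_rms_v,
        forearm_rms=forearm_rms_v,
        arm_rms=arm_rms_v,
        hand_forearm_ratio=r_hf,
        forearm_arm_ratio=r_fa,
        zero_crossings=zc,
        cumulative_distance_m=cd,
        ellipse=ellipse,
        flags=flags,
    )
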
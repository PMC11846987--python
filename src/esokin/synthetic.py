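"""Genre-conditioned synthetic accelerometer sessions with analytic truth.

The generator emulates the study conditions: a 10-minute, 500 Hz recording
from three tri-axial sensors (hand, forearm, arm) in mG, containing a static
gravity offset, ballistic mouse movements, white measurement noise, and rare
spike artefacts.

Movement model
--------------
Hand motion is a sequence of *out-and-back flicks* from a home position on
the mousepad plane: each event picks a target from an anisotropic Gaussian
(the spatial covariance controls how oblong the footprint is), moves to it
with a fifth-order minimum-jerk profile and returns the same way.  This is
the standard ballistic-reach primitive; it is band-limited well inside the
0.5–11 Hz analysis band and, because the hand returns to home, the planned
path length (twice the sum of target distances) is recoverable from the
high-pass-filtered displacement without a drift ambiguity.  A small vertical
(z) residual of 5% of each flick amplitude emulates hand roll; forearm and
arm acceleration are attenuated copies of the hand signal.

Event timing is a Poisson stream thinned so flicks never overlap; the
ground truth records the events actually placed.  Randomness is split into
independent substreams (events / noise / artefacts / metadata) so that, for
a fixed seed, toggling artefacts does not perturb the planned path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .preprocess import STANDARD_GRAVITY
from .signals import AxisTrace, Session, SensorRecording

#: spike magnitude in units of the clean per-axis signal SD
SPIKE_FACTOR = 12.0

#: vertical residual as a fraction of flick amplitude
Z_RESIDUAL = 0.05

#: genre-conditioned probabilities of choosing (400, 1000, 1600) DPI,
#: shaped after the cohort's reported preferences (FPS favours low DPI,
#: MOBA high DPI)
DPI_CHOICE_P = {
    "FPS": (0.40, 0.33, 0.27),
    "MOBA": (0.125, 0.125, 0.75),
    "Adventure": (0.33, 0.33, 0.34),
}
DPI_LEVELS = (400, 1000, 1600)


@dataclass
class SyntheticSpec:
    """Full parameterization of one synthetic session."""

    genre: str
    rate_hz: float = 500.0
    duration_s: float = 600.0
    event_rate_hz: float = 1.0            # mean flick events per second
    amp_mean_cm: float = 3.0              # log-normal flick amplitude, mean
    amp_sd_cm: float = 1.0                # log-normal flick amplitude, SD
    spatial_cov_cm2: np.ndarray = field(
        default_factory=lambda: np.eye(2) * 4.0)  # target covariance (shape)
    move_dur_s: tuple[float, float] = (0.25, 0.40)  # one-way stroke duration
    noise_sd_mg: float = 1.5              # white sensor noise per axis
    gravity_mg: tuple[float, float, float] = (60.0, -40.0, 995.0)
    outlier_rate: float = 0.01            # per-sample spike probability
    segment_attenuation: tuple[float, float] = (0.6, 0.4)  # forearm, arm
    seed: int = 0

    def validate(self) -> None:
        cov = np.asarray(self.spatial_cov_cm2, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ConfigurationError("spatial_cov_cm2 must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ConfigurationError("spatial_cov_cm2 must be positive definite")
        if not (0.0 <= self.outlier_rate < 0.05):
            raise ConfigurationError("outlier_rate must be in [0, 0.05)")
        fa, ar = self.segment_attenuation
        if not (0.0 < fa <= 1.0 and 0.0 < ar <= 1.0):
            raise ConfigurationError("attenuation factors must be in (0, 1]")
        if self.event_rate_hz < 0 or self.amp_mean_cm <= 0 or self.amp_sd_cm < 0:
            raise ConfigurationError("event rate and amplitude must be valid")
        lo, hi = self.move_dur_s
        if not (0.0 < lo <= hi):
            raise ConfigurationError("move_dur_s must be an increasing range")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigurationError("rate and duration must be positive")


@dataclass
class GroundTruth:
    """Generative quantities a perfect pipeline would recover."""

    true_path_length_m: float      # sum of planned movement amplitudes
    true_spatial_cov_cm2: np.ndarray
    n_events: int
    event_times_s: list[float]
    attenuation: tuple[float, float]
    outliers_injected: int


def min_jerk_profile(distance_cm: float, duration_s: float, rate_hz: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fifth-order minimum-jerk point-to-point profile.

    Returns (displacement, velocity, acceleration) sampled on
    ``[0, duration]`` inclusive.  Boundary velocity and acceleration are
    exactly zero; peak velocity is (15/8)·distance/duration.
    """
    if distance_cm <= 0 or duration_s <= 0 or rate_hz <= 0:
        raise ValueError("distance, duration and rate must be positive")
    n = int(round(duration_s * rate_hz)) + 1
    tau = np.linspace(0.0, 1.0, n)
    d, T = distance_cm, duration_s
    disp = d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = (d / T) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    acc = (d / T**2) * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return disp, vel, acc


def genre_preset(genre: str, seed: int = 0, duration_s: float = 600.0
                 ) -> SyntheticSpec:
    """Default generator settings per game genre.

    The presets encode the qualitative regimes of the three genres: FPS has
    the largest, fastest flicks over a strongly oblong footprint; MOBA the
    highest flick rate inside a compact near-circular footprint; Adventure
    sparse, slow movements over an oblong footprint.  They are set for this
    regime ordering, not to reproduce any particular cohort's means.
    """
    common = dict(rate_hz=500.0, duration_s=duration_s, noise_sd_mg=1.5,
                  gravity_mg=(60.0, -40.0, 995.0), outlier_rate=0.01,
                  seed=seed)
    if genre == "FPS":
        return SyntheticSpec(
            genre="FPS", event_rate_hz=0.9, amp_mean_cm=4.0, amp_sd_cm=1.4,
            spatial_cov_cm2=np.diag([9.0, 2.25]), move_dur_s=(0.25, 0.40),
            segment_attenuation=(0.55, 0.35), **common)
    if genre == "MOBA":
        return SyntheticSpec(
            genre="MOBA", event_rate_hz=1.5, amp_mean_cm=1.8, amp_sd_cm=0.6,
            spatial_cov_cm2=np.diag([4.0, 3.3]), move_dur_s=(0.20, 0.30),
            segment_attenuation=(0.75, 0.55), **common)
    if genre == "Adventure":
        return SyntheticSpec(
            genre="Adventure", event_rate_hz=0.5, amp_mean_cm=3.5,
            amp_sd_cm=1.2, spatial_cov_cm2=np.diag([7.5, 2.5]),
            move_dur_s=(0.30, 0.50), segment_attenuation=(0.65, 0.45),
            **common)
    raise ConfigurationError(f"unknown genre {genre!r}")


def _plan_events(spec: SyntheticSpec, rng: np.random.Generator):
    """Poisson-stream flick plan, thinned to forbid overlapping flicks.

    Returns (start_times, stroke_durations, 2D targets in cm).
    """
    lo, hi = spec.move_dur_s
    # log-normal amplitude with the requested mean/SD on the cm scale
    sigma2 = np.log1p((spec.amp_sd_cm / spec.amp_mean_cm) ** 2)
    mu = np.log(spec.amp_mean_cm) - sigma2 / 2.0
    cov = np.asarray(spec.spatial_cov_cm2, dtype=float)
    rms_g = np.sqrt(np.trace(cov))

    starts, durs, targets = [], [], []
    t = 0.0
    while spec.event_rate_hz > 0:
        t = t + rng.exponential(1.0 / spec.event_rate_hz)
        d = rng.uniform(lo, hi)
        if t + 2 * d >= spec.duration_s:
            break
        amp = float(np.exp(rng.normal(mu, np.sqrt(sigma2))))
        g = rng.multivariate_normal(np.zeros(2), cov)
        target = amp * g / rms_g  # covariance sets shape, amplitude sets scale
        starts.append(t)
        durs.append(d)
        targets.append(target)
        t = t + 2 * d
    return (np.array(starts), np.array(durs),
            np.array(targets).reshape(-1, 2))


def simulate_session(spec: SyntheticSpec, participant_id: str = "sim"
                     ) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Deterministic for a fixed ``spec.seed``; the event plan, sensor noise,
    spike artefacts and DPI choice use independent substreams.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_events, rng_noise, rng_spikes, rng_meta = (
        np.random.default_rng(c) for c in ss.spawn(4))

    n = int(round(spec.duration_s * spec.rate_hz))
    starts, durs, targets = _plan_events(spec, rng_events)

    # analytic hand acceleration (cm/s^2) on the sample grid
    acc = np.zeros((3, n))
    z_signs = rng_events.choice([-1.0, 1.0], size=len(starts))
    for t0, d, tgt, zs in zip(starts, durs, targets, z_signs):
        amp = float(np.hypot(*tgt))
        direction = np.array([tgt[0], tgt[1], zs * Z_RESIDUAL * amp])
        i0 = int(round(t0 * spec.rate_hz))
        m = int(round(d * spec.rate_hz)) + 1
        tau = np.linspace(0.0, 1.0, m)
        prof = (60 * tau - 180 * tau**2 + 120 * tau**3) / d**2
        for stroke_sign, offset in ((1.0, 0), (-1.0, m - 1)):
            sl = slice(i0 + offset, min(i0 + offset + m, n))
            k = sl.stop - sl.start
            acc[:, sl] += stroke_sign * np.outer(direction / amp, prof[:k]) * amp

    hand_ms2 = acc / 100.0  # cm/s^2 -> m/s^2
    att_f, att_a = spec.segment_attenuation
    gravity = np.asarray(spec.gravity_mg, dtype=float)

    recordings = {}
    outliers_injected = 0
    for placement, scale in (("hand", 1.0), ("forearm", att_f), ("arm", att_a)):
        sig_mg = scale * hand_ms2 * (1000.0 / STANDARD_GRAVITY)
        sig_mg = sig_mg + gravity[:, None]
        sig_mg = sig_mg + rng_noise.normal(0.0, spec.noise_sd_mg, size=(3, n))
        if spec.outlier_rate > 0:
            for k in range(3):
                mask = rng_spikes.random(n) < spec.outlier_rate
                n_spk = int(mask.sum())
                if n_spk:
                    sd = float(np.std(sig_mg[k]))
                    signs = rng_spikes.choice([-1.0, 1.0], size=n_spk)
                    sig_mg[k, mask] += signs * SPIKE_FACTOR * sd
                    outliers_injected += n_spk
        traces = {
            a: AxisTrace(sig_mg[k], axis=a, units="mG", rate=spec.rate_hz)
            for k, a in enumerate("xyz")
        }
        recordings[placement] = SensorRecording(placement=placement, **traces)

    dpi = int(rng_meta.choice(DPI_LEVELS, p=DPI_CHOICE_P.get(
        spec.genre, (1 / 3, 1 / 3, 1 / 3))))
    session = Session(participant_id=participant_id, genre=spec.genre,
                      dpi=dpi, **recordings)
    truth = GroundTruth(
        true_path_length_m=float(
            2.0 * np.sum(np.hypot(targets[:, 0], targets[:, 1])) / 100.0),
        true_spatial_cov_cm2=np.asarray(spec.spatial_cov_cm2, dtype=float),
        n_events=len(starts),
        event_times_s=[float(t) for t in starts],
        attenuation=spec.segment_attenuation,
        outliers_injected=outliers_injected,
    )
    return session, truth
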
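"""Data model and file I/O for tri-axial accelerometer recordings.

A *session* is one participant playing one game for up to ten minutes while
three tri-axial accelerometers (hand, forearm, arm) record at 500 Hz in mG.
The on-disk exchange format is a plain CSV dialect:

* a header block of ``#key=value`` lines carrying ``rate_hz``, ``units``,
  ``participant_id``, ``genre`` and ``dpi``;
* a column-header row ``t,hand_x,hand_y,hand_z,forearm_x,forearm_y,
  forearm_z,arm_x,arm_y,arm_z``;
* comma-separated data rows with ``.`` as decimal separator, UTF-8.

The time column is stored for readability but is *derived* metadata: samples
are assumed uniformly spaced at ``1/rate_hz`` and time stamps deviating from
that grid by more than 1 µs are rejected, because uniform spacing underlies
the numerical integration downstream.
"""

from __future__ import annotations

import dataclasses
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, RateError

AXES = ("x", "y", "z")
PLACEMENTS = ("hand", "forearm", "arm")
GENRES = ("FPS", "MOBA", "Adventure")
DPI_LEVELS = (400, 1000, 1600)
VALID_UNITS = ("mG", "m_s2", "m_s", "m")

#: column order of the recording CSV dialect
CSV_COLUMNS = ["t"] + [f"{p}_{a}" for p in PLACEMENTS for a in AXES]

#: fixed column order of the per-session metrics table
METRICS_COLUMNS = [
    "participant_id",
    "genre",
    "dpi",
    "hand_rms",
    "forearm_rms",
    "arm_rms",
    "hand_forearm_ratio",
    "forearm_arm_ratio",
    "zero_crossings",
    "cumulative_distance_m",
    "ellipse_a_cm",
    "ellipse_b_cm",
    "ellipse_area_cm2",
    "long_short_ratio",
]

_TIME_JITTER_S = 1e-6


@dataclass
class AxisTrace:
    """One axis of one sensor: a uniformly sampled real-valued signal."""

    samples: np.ndarray
    axis: str = "x"
    units: str = "mG"
    rate: float = 500.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate

    def replace(self, **kwargs) -> "AxisTrace":
        """Return a copy with selected fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass
class SensorRecording:
    """Tri-axial trace of one limb segment."""

    placement: str
    x: AxisTrace
    y: AxisTrace
    z: AxisTrace

    @property
    def traces(self) -> tuple[AxisTrace, AxisTrace, AxisTrace]:
        return (self.x, self.y, self.z)

    @property
    def rate(self) -> float:
        return self.x.rate


@dataclass
class Session:
    """One participant's three sensor recordings plus study metadata."""

    participant_id: str
    genre: str
    dpi: int | None
    hand: SensorRecording
    forearm: SensorRecording
    arm: SensorRecording

    @property
    def recordings(self) -> tuple[SensorRecording, SensorRecording, SensorRecording]:
        return (self.hand, self.forearm, self.arm)

    @property
    def rate(self) -> float:
        return self.hand.rate

    @property
    def n_samples(self) -> int:
        return len(self.hand.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


def validate_session(session: Session) -> list[str]:
    """Check every session invariant; return a report of violations.

    The report is empty iff the session is valid.  Each entry names the
    violated invariant and where it was found, e.g.
    ``"hand.x: all samples finite"``.
    """
    report: list[str] = []
    if session.genre not in GENRES:
        report.append(f"genre: genre in {GENRES} (got {session.genre!r})")
    if session.dpi is not None and session.dpi not in DPI_LEVELS:
        report.append(f"dpi: dpi in {DPI_LEVELS} (got {session.dpi!r})")

    ref = session.hand.x
    for rec in session.recordings:
        for trace in rec.traces:
            loc = f"{rec.placement}.{trace.axis}"
            if trace.rate <= 0:
                report.append(f"{loc}: rate > 0")
            if len(trace) < 2:
                report.append(f"{loc}: length >= 2")
            if not np.all(np.isfinite(trace.samples)):
                report.append(f"{loc}: all samples finite")
            if trace.units not in VALID_UNITS:
                report.append(f"{loc}: units in {VALID_UNITS}")
            if len(trace) != len(ref):
                report.append(f"{loc}: equal length across traces")
            if trace.rate != ref.rate:
                report.append(f"{loc}: equal rate across traces")
            if trace.units != ref.units:
                report.append(f"{loc}: equal units across traces")
    if session.duration_s > 600.0 + 1.0 / max(session.rate, 1e-9):
        report.append("session: duration_s <= 600")
    return report


def _parse_header_block(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line[1:].strip()
        if "=" not in body:
            raise FormatError(f"malformed header line: {line!r}")
        key, value = body.split("=", 1)
        meta[key.strip()] = value.strip()
    return meta


def read_session(
    path: str | Path,
    metadata: dict | None = None,
    max_duration_s: float = 600.0,
) -> Session:
    """Read a recording CSV file into a validated :class:`Session`.

    ``metadata`` may override ``participant_id``, ``genre`` and ``dpi`` from
    the file header.  Recordings longer than ``max_duration_s`` are
    truncated; shorter ones are accepted with a warning (participants played
    *up to* ten minutes).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    header_lines = [ln for ln in lines if ln.startswith("#")]
    meta = _parse_header_block(header_lines)
    if metadata:
        meta.update({k: v for k, v in metadata.items() if v is not None})

    try:
        rate = float(meta["rate_hz"])
    except KeyError:
        raise FormatError(f"{path}: header missing rate_hz") from None
    if rate <= 0:
        raise RateError(f"{path}: rate_hz must be positive, got {rate}")
    units = meta.get("units", "mG")
    if units not in VALID_UNITS:
        raise FormatError(f"{path}: unknown units tag {units!r}")

    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body))
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[CSV_COLUMNS]

    bad = df.index[~np.isfinite(df.to_numpy(dtype=float)).all(axis=1)]
    if len(bad):
        raise ParseError(f"{path}: non-finite value in data row {int(bad[0])}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 data rows, got {len(df)}")

    t = df["t"].to_numpy(dtype=float)
    expected = t[0] + np.arange(len(t)) / rate
    if np.max(np.abs(t - expected)) > _TIME_JITTER_S:
        raise RateError(
            f"{path}: time stamps deviate from the uniform 1/{rate} Hz grid "
            f"by more than {_TIME_JITTER_S} s"
        )

    n_max = int(round(max_duration_s * rate))
    if len(df) > n_max:
        df = df.iloc[:n_max]
    elif len(df) < n_max:
        warnings.warn(
            f"{path}: recording is {len(df) / rate:.1f} s, shorter than "
            f"{max_duration_s:.0f} s; accepted without padding",
            stacklevel=2,
        )

    recordings = {}
    for placement in PLACEMENTS:
        traces = {
            a: AxisTrace(df[f"{placement}_{a}"].to_numpy(dtype=float), axis=a,
                         units=units, rate=rate)
            for a in AXES
        }
        recordings[placement] = SensorRecording(placement=placement, **traces)

    dpi_raw = meta.get("dpi", "")
    dpi = int(dpi_raw) if str(dpi_raw).strip() not in ("", "None") else None
    session = Session(
        participant_id=str(meta.get("participant_id", path.stem)),
        genre=str(meta.get("genre", "")),
        dpi=dpi,
        **recordings,
    )
    problems = validate_session(session)
    if problems:
        raise FormatError(f"{path}: invalid session: {'; '.join(problems)}")
    return session


def write_session(session: Session, path: str | Path) -> None:
    """Write a session in the recording CSV dialect (lossless round-trip)."""
    path = Path(path)
    units = session.hand.x.units
    rate = session.rate
    n = session.n_samples
    cols = {"t": np.arange(n) / rate}
    for rec in session.recordings:
        for trace in rec.traces:
            cols[f"{rec.placement}_{trace.axis}"] = trace.samples
    df = pd.DataFrame(cols, columns=CSV_COLUMNS)

    header = (
        f"#rate_hz={rate:g}\n"
        f"#units={units}\n"
        f"#participant_id={session.participant_id}\n"
        f"#genre={session.genre}\n"
        f"#dpi={'' if session.dpi is None else session.dpi}\n"
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")


def write_metrics_table(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write per-session metric rows as CSV in the fixed column order."""
    df = pd.DataFrame(list(rows))
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metrics table missing column(s) {missing}")
    df = df[METRICS_COLUMNS]
    df.to_csv(path, index=False)
    return df


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a cohort report (plain dict of JSON-safe values) to disk."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_default),
        encoding="utf-8",
    )
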
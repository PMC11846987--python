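"""Orchestration: sessions → per-session metrics table → cohort report.

``run_session`` takes one recording through preprocessing and the metric
suite; ``run_cohort`` collects the per-session rows, then runs the genre
comparison ladder on every metric (assumption checks, log transform with a
bootstrap CI of each group's log-mean, one-way ANOVA with η² and Fisher LSD
follow-ups), the genre × DPI contingency analysis with Šidák-corrected
pairwise follow-ups, and a one-sample t test of the ellipse long:short
ratio against 1 per genre.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import groupstats as gs
from .errors import ConfigurationError, DegenerateInputError, EsokinError
from .kinematics import KinematicSummary, summarize_session
from .preprocess import PreprocessConfig, preprocess_sensor
from .signals import (
    GENRES,
    Session,
    read_session,
    write_metrics_table,
    write_report,
)

logger = logging.getLogger("esokin")

#: metrics compared across genres, in report order
COMPARED_METRICS = [
    "hand_rms",
    "hand_forearm_ratio",
    "forearm_arm_ratio",
    "zero_crossings",
    "cumulative_distance_m",
    "ellipse_area_cm2",
]


@dataclass
class CohortReport:
    """Everything one cohort run produces."""

    metrics_table: list[dict]
    comparisons: list[gs.GroupComparison]
    assumption_checks: dict
    bootstrap_cis: dict
    dpi_analysis: gs.ContingencyResult | None
    shape_tests: dict
    config_echo: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "metrics_table": self.metrics_table,
            "comparisons": [dataclasses.asdict(c) for c in self.comparisons],
            "assumption_checks": self.assumption_checks,
            "bootstrap_cis": self.bootstrap_cis,
            "dpi_analysis": (dataclasses.asdict(self.dpi_analysis)
                             if self.dpi_analysis else None),
            "shape_tests": {g: dataclasses.asdict(r)
                            for g, r in self.shape_tests.items()},
            "config_echo": self.config_echo,
            "seed": self.seed,
        }


def summarize_one(session: Session, config: PreprocessConfig | None = None,
                  deadband: float = 0.0) -> tuple[KinematicSummary, dict]:
    """Preprocess all three sensors of a session and compute its metrics.

    Returns the summary plus a metrics-table row dict (metadata + metrics).
    """
    config = config or PreprocessConfig()
    t0 = time.perf_counter()
    processed = {rec.placement: preprocess_sensor(rec, config)
                 for rec in session.recordings}
    summary = summarize_session(processed["hand"], processed["forearm"],
                                processed["arm"], config, deadband=deadband)
    logger.info(
        "session %s: %.2f s, fraction_unchanged=%.4f%s",
        session.participant_id, time.perf_counter() - t0,
        float(np.mean([p.fraction_unchanged for p in processed.values()])),
        f", flags={summary.flags}" if summary.flags else "",
    )
    row = {
        "participant_id": session.participant_id,
        "genre": session.genre,
        "dpi": session.dpi,
        **summary.as_row(),
    }
    return summary, row


def run_session(session_path: str | Path,
                config: PreprocessConfig | None = None,
                deadband: float = 0.0) -> dict:
    """Read one recording file and return its metrics-table row."""
    try:
        session = read_session(session_path)
        _, row = summarize_one(session, config, deadband)
        return row
    except EsokinError as exc:
        logger.error("session %s failed: %s: %s", session_path,
                     type(exc).__name__, exc)
        raise


def run_cohort(
    sessions: list[Session],
    config: PreprocessConfig | None = None,
    seed: int = 0,
    deadband: float = 0.0,
    bootstrap_n: int = 1000,
    coverage: float = 0.95,
    out_dir: str | Path | None = None,
) -> CohortReport:
    """Full cohort analysis over already-loaded sessions.

    Requires at least two genres with three or more sessions each (checked
    before any computation).  Sessions without DPI metadata are excluded
    from the contingency analysis only.  All randomness (the bootstrap)
    derives from ``seed``.
    """
    config = config or PreprocessConfig()
    genres_present = sorted({s.genre for s in sessions},
                            key=lambda g: GENRES.index(g) if g in GENRES else 99)
    counts = {g: sum(1 for s in sessions if s.genre == g)
              for g in genres_present}
    if len(genres_present) < 2 or any(c < 3 for c in counts.values()):
        raise ConfigurationError(
            f"cohort analysis needs >= 2 genres with >= 3 sessions each; "
            f"got {counts}")

    rows = [summarize_one(s, config, deadband)[1] for s in sessions]

    comparisons: list[gs.GroupComparison] = []
    assumption_checks: dict = {}
    bootstrap_cis: dict = {}
    rng_seed = np.random.SeedSequence(seed)
    metric_seeds = rng_seed.generate_state(len(COMPARED_METRICS) * 3)
    for im, metric in enumerate(COMPARED_METRICS):
        groups = [
            [r[metric] for r in rows if r["genre"] == g
             and np.isfinite(r[metric])]
            for g in genres_present
        ]
        assumption_checks[metric] = gs.check_assumptions(groups)
        logged, cis = [], {}
        for ig, (g, vals) in enumerate(zip(genres_present, groups)):
            sub_seed = int(metric_seeds[im * 3 + ig % 3]) % (2**31)
            lv, ci = gs.log_bootstrap(vals, B=bootstrap_n, level=coverage,
                                      seed=sub_seed + ig)
            logged.append(lv)
            cis[g] = ci
        bootstrap_cis[metric] = cis
        anova = gs.one_way_anova(logged, variable=metric)
        anova.posthoc = gs.lsd_posthoc(logged, anova, labels=genres_present)
        comparisons.append(anova)

    with_dpi = [s for s in sessions if s.dpi is not None]
    dpi_analysis = None
    if len({s.genre for s in with_dpi}) >= 2:
        dpi_analysis = gs.dpi_contingency_analysis(
            [s.genre for s in with_dpi], [s.dpi for s in with_dpi],
            genre_labels=genres_present)

    shape_tests: dict[str, gs.OneSampleResult] = {}
    for g in genres_present:
        ratios = [r["long_short_ratio"] for r in rows
                  if r["genre"] == g and np.isfinite(r["long_short_ratio"])]
        if len(ratios) >= 2:
            try:
                shape_tests[g] = gs.one_sample_t(ratios, mu0=1.0)
            except DegenerateInputError:
                pass

    report = CohortReport(
        metrics_table=rows,
        comparisons=comparisons,
        assumption_checks=assumption_checks,
        bootstrap_cis=bootstrap_cis,
        dpi_analysis=dpi_analysis,
        shape_tests=shape_tests,
        config_echo={
            "preprocess": dataclasses.asdict(config),
            "deadband": deadband,
            "bootstrap_n": bootstrap_n,
            "coverage": coverage,
        },
        seed=seed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_metrics_table(rows, out_dir / "metrics.csv")
        write_report(report.to_dict(), out_dir / "cohort_report.json")
    return report


def validate_report_schema(report: dict) -> list[str]:
    """Structural validation of a serialized cohort report.

    Returns a list of problems (empty when valid): required keys, one
    metrics row per session-derived entry, and exactly one comparison per
    compared metric.
    """
    problems: list[str] = []
    required = {"metrics_table", "comparisons", "assumption_checks",
                "bootstrap_cis", "dpi_analysis", "shape_tests",
                "config_echo", "seed"}
    missing = required - set(report)
    if missing:
        problems.append(f"missing keys: {sorted(missing)}")
        return problems
    if not isinstance(report["metrics_table"], list):
        problems.append("metrics_table must be a list")
    seen = [c.get("variable") for c in report["comparisons"]]
    for metric in COMPARED_METRICS:
        if seen.count(metric) != 1:
            problems.append(
                f"metric {metric!r} appears {seen.count(metric)} times in "
                f"comparisons (expected exactly once)")
    for c in report["comparisons"]:
        for key in ("F", "df1", "df2", "p", "eta2", "posthoc"):
            if key not in c:
                problems.append(f"comparison {c.get('variable')}: missing {key}")
    if not isinstance(report["seed"], int):
        problems.append("seed must be an integer")
    return problems
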
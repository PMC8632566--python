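"""Synthetic smartphone-voice cohorts.

Generates participant rosters, daily self-reports and per-call acoustic
feature tables with the statistical structure a naturalistic
voice-monitoring study of bipolar disorder exhibits:

* three diagnostic groups — patients (BD), unaffected first-degree
  relatives (UR) and healthy controls (HC) — with a group-level mean shift
  on a subset of features (UR intermediate between BD and HC);
* a stable per-participant feature offset (the vocal "fingerprint") that
  dominates between-person variation;
* daily latent affective states for BD participants (mood band, activity
  deviation, insomnia) that shift that day's call features and drive the
  self-reported mood/activity/sleep values;
* heavy class imbalance (mania on only a few percent of labeled days),
  uneven follow-up length, and days with calls but no self-report.

Every feature value decomposes as::

    value = group shift + fingerprint + state shift (BD only) + N(0, noise_sd)

The generator is fully deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

GROUPS = ("BD", "UR", "HC")

#: the 9-point self-reported mood scale (depressed .. manic)
MOOD_SCALE = (-3.0, -2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)
#: the 7-point self-reported activity scale (0 = normal)
ACTIVITY_SCALE = (-3, -2, -1, 0, 1, 2, 3)

#: mood values consistent with each latent mood state
_MOOD_VALUES = {
    "mania": (1.0, 2.0, 3.0),
    "depression": (-3.0, -2.0, -1.0),
    "euthymia": (-0.5, 0.0, 0.5),
}
_ACTIVITY_VALUES = {
    "increased": (1, 2, 3),
    "decreased": (-3, -2, -1),
    "neutral": (0,),
}

STATE_NAMES = (
    "mania",
    "depression",
    "increased_activity",
    "decreased_activity",
    "insomnia",
)

#: daily state probabilities emulating the observed class imbalance
#: (mania on ~3% of labeled days, depression ~12%, insomnia ~19%,
#: increased activity ~29%, decreased activity ~23%)
DEFAULT_STATE_PREVALENCE = {
    "mania": 0.03,
    "depression": 0.12,
    "increased_activity": 0.29,
    "decreased_activity": 0.23,
    "insomnia": 0.19,
}

ROSTER_COLUMNS = ["participant_id", "group"]
REPORT_COLUMNS = ["participant_id", "date", "mood", "activity", "bedtime", "wakeup"]


def feature_columns(n_features: int) -> list[str]:
    """Names of the acoustic feature columns: ``f0001`` .. ``fNNNN``."""
    return [f"f{i + 1:04d}" for i in range(n_features)]


@dataclasses.dataclass
class SyntheticConfig:
    """Cohort-generation parameters.

    Defaults mirror the scale of the emulated study: 121 BD / 21 UR / 38 HC
    participants, follow-up between a handful of days and nearly a year
    (mean about 155 days), and roughly four calls per monitored day, which
    yields on the order of 1e5 call entries.  The feature dimension defaults
    to 64 (configurable up to the full 6552-dimensional acoustic set).
    """

    n_bd: int = 121
    n_ur: int = 21
    n_hc: int = 38
    days_per_participant: tuple[int, int] = (10, 300)
    calls_per_day: float = 4.0
    n_features: int = 64
    fingerprint_sd: float = 1.0
    group_effect: float = 1.0
    state_effect: float = 0.5
    noise_sd: float = 1.0
    #: fraction of features carrying the group / state shifts
    affected_fraction: float = 0.25
    #: UR shift as a multiple of the BD shift (intermediate by hypothesis)
    ur_scale: float = 0.5
    state_prevalence: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_STATE_PREVALENCE)
    )
    missing_report_prob: float = 0.4
    start_date: str = "2019-01-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        for name in ("n_bd", "n_ur", "n_hc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.days_per_participant
        if not (0 < lo <= hi):
            raise ValueError("days_per_participant must satisfy 0 < min <= max")
        if self.calls_per_day < 0:
            raise ValueError("calls_per_day must be >= 0")
        for name in ("fingerprint_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be in (0, 1]")
        if not 0.0 <= self.missing_report_prob <= 1.0:
            raise ValueError("missing_report_prob must be in [0, 1]")
        unknown = set(self.state_prevalence) - set(STATE_NAMES)
        if unknown:
            raise ValueError(f"unknown state(s) in state_prevalence: {sorted(unknown)}")
        for state, p in self.state_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"state_prevalence[{state!r}] must be in [0, 1]")
        prev = self.state_prevalence
        if prev.get("mania", 0.0) + prev.get("depression", 0.0) > 1.0:
            raise ValueError(
                "mutually exclusive mood states: mania + depression prevalence > 1"
            )
        if prev.get("increased_activity", 0.0) + prev.get("decreased_activity", 0.0) > 1.0:
            raise ValueError(
                "mutually exclusive activity states: prevalence sums > 1"
            )


@dataclasses.dataclass
class Participant:
    """One rostered participant with their latent feature-space offset."""

    participant_id: str
    group: str
    fingerprint: np.ndarray


class Cohort(NamedTuple):
    roster: pd.DataFrame
    reports: pd.DataFrame
    entries: pd.DataFrame


def _direction(rng: np.random.Generator, n_features: int, fraction: float) -> np.ndarray:
    """A sparse signed direction vector for a mean-shift effect."""
    n_affected = max(1, int(round(fraction * n_features)))
    v = np.zeros(n_features)
    idx = rng.choice(n_features, size=n_affected, replace=False)
    v[idx] = rng.choice([-1.0, 1.0], size=n_affected)
    return v


def _fmt_clock(minutes: np.ndarray) -> list[str]:
    return [f"{int(m) // 60:02d}:{int(m) % 60:02d}" for m in minutes]


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort: roster, daily self-reports and call features.

    Self-reports are produced for BD participants only (they are the group
    using the daily monitoring system); a fraction ``missing_report_prob``
    of their days have calls but no report.  A BD day's latent mood state,
    activity deviation and insomnia status drive both the self-report
    values and that day's additive feature shifts, so labels derived
    downstream from the reports round-trip the generating state.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features
    prev = {s: config.state_prevalence.get(s, 0.0) for s in STATE_NAMES}

    group_dir = _direction(rng, n_feat, config.affected_fraction)
    state_dirs = {
        s: _direction(rng, n_feat, config.affected_fraction) for s in STATE_NAMES
    }
    group_shift = {
        "BD": config.group_effect * group_dir,
        "UR": config.ur_scale * config.group_effect * group_dir,
        "HC": np.zeros(n_feat),
    }

    roster_rows: list[tuple[str, str]] = []
    report_frames: list[pd.DataFrame] = []
    entry_frames: list[pd.DataFrame] = []
    start = pd.Timestamp(config.start_date)
    counts = (("BD", config.n_bd), ("UR", config.n_ur), ("HC", config.n_hc))
    pid_width = max(3, len(str(config.n_bd + config.n_ur + config.n_hc)))

    serial = 0
    for group, n_members in counts:
        for _ in range(n_members):
            serial += 1
            pid = f"P{serial:0{pid_width}d}"
            roster_rows.append((pid, group))
            fingerprint = rng.normal(0.0, config.fingerprint_sd, n_feat)

            lo, hi = config.days_per_participant
            n_days = int(rng.integers(lo, hi + 1))
            dates = pd.date_range(start, periods=n_days, freq="D")

            # latent daily states (non-BD participants stay in no state)
            day_shift = np.tile(group_shift[group] + fingerprint, (n_days, 1))
            if group == "BD":
                p_m, p_d = prev["mania"], prev["depression"]
                mood_state = rng.choice(
                    ["mania", "depression", "euthymia"],
                    size=n_days,
                    p=[p_m, p_d, 1.0 - p_m - p_d],
                )
                p_i, p_dec = prev["increased_activity"], prev["decreased_activity"]
                activity_state = rng.choice(
                    ["increased", "decreased", "neutral"],
                    size=n_days,
                    p=[p_i, p_dec, 1.0 - p_i - p_dec],
                )
                insomnia = rng.random(n_days) < prev["insomnia"]

                for s, mask in (
                    ("mania", mood_state == "mania"),
                    ("depression", mood_state == "depression"),
                    ("increased_activity", activity_state == "increased"),
                    ("decreased_activity", activity_state == "decreased"),
                    ("insomnia", insomnia),
                ):
                    day_shift[mask] += config.state_effect * state_dirs[s]

                # self-report values consistent with the day's state
                mood = np.array(
                    [rng.choice(_MOOD_VALUES[s]) for s in mood_state]
                )
                activity = np.array(
                    [int(rng.choice(_ACTIVITY_VALUES[s])) for s in activity_state]
                )
                sleep = np.where(
                    insomnia,
                    rng.integers(240, 360, n_days),
                    rng.integers(380, 541, n_days),
                )
                bed = (21 * 60 + 15 * rng.integers(0, 16, n_days)) % 1440
                wake = (bed + sleep) % 1440
                kept = rng.random(n_days) >= config.missing_report_prob
                if kept.any():
                    report_frames.append(
                        pd.DataFrame(
                            {
                                "participant_id": pid,
                                "date": dates[kept].strftime("%Y-%m-%d"),
                                "mood": mood[kept],
                                "activity": activity[kept],
                                "bedtime": _fmt_clock(bed[kept]),
                                "wakeup": _fmt_clock(wake[kept]),
                            }
                        )
                    )

            # calls per day ~ Poisson(calls_per_day), truncated at 0 by nature
            n_calls = rng.poisson(config.calls_per_day, n_days)
            total = int(n_calls.sum())
            if total == 0:
                continue
            day_idx = np.repeat(np.arange(n_days), n_calls)
            seconds = rng.integers(8 * 3600, 22 * 3600, total)
            timestamps = dates[day_idx] + pd.to_timedelta(seconds, unit="s")
            features = day_shift[day_idx] + rng.normal(
                0.0, config.noise_sd, (total, n_feat)
            )
            frame = pd.DataFrame(features, columns=feature_columns(n_feat))
            frame.insert(0, "timestamp", timestamps.strftime("%Y-%m-%dT%H:%M:%S"))
            frame.insert(0, "participant_id", pid)
            entry_frames.append(frame)

    roster = pd.DataFrame(roster_rows, columns=ROSTER_COLUMNS)
    reports = (
        pd.concat(report_frames, ignore_index=True)
        if report_frames
        else pd.DataFrame(columns=REPORT_COLUMNS)
    )
    entries = (
        pd.concat(entry_frames, ignore_index=True)
        if entry_frames
        else pd.DataFrame(columns=["participant_id", "timestamp"] + feature_columns(n_feat))
    )
    return Cohort(roster=roster, reports=reports, entries=entries)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write ``roster.csv``, ``reports.csv`` and ``features.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": directory / "roster.csv",
        "reports": directory / "reports.csv",
        "features": directory / "features.csv",
    }
    cohort.roster.to_csv(paths["roster"], index=False)
    cohort.reports.to_csv(paths["reports"], index=False)
    cohort.entries.to_csv(paths["features"], index=False)
    return paths


def _require_columns(frame: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"{name}: malformed header, missing column(s) {missing}")


def read_cohort(directory: str | Path) -> Cohort:
    """Read and validate a cohort directory written by :func:`write_cohort`.

    Raises ``ValueError`` on malformed headers, unknown group labels
    (naming the offending row) and duplicate (participant, date)
    self-reports.
    """
    directory = Path(directory)
    roster = pd.read_csv(directory / "roster.csv", comment="#")
    reports = pd.read_csv(
        directory / "reports.csv",
        comment="#",
        dtype={"date": str, "bedtime": str, "wakeup": str},
    )
    entries = pd.read_csv(directory / "features.csv", comment="#", dtype={"timestamp": str})

    _require_columns(roster, ROSTER_COLUMNS, "roster.csv")
    _require_columns(reports, REPORT_COLUMNS, "reports.csv")
    if "participant_id" not in entries.columns or "timestamp" not in entries.columns:
        raise ValueError("features.csv: malformed header")

    bad = ~roster["group"].isin(GROUPS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"roster.csv row {row}: unknown group label "
            f"{roster['group'].iloc[row]!r} for participant "
            f"{roster['participant_id'].iloc[row]!r}"
        )

    dup = reports.duplicated(subset=["participant_id", "date"])
    if dup.any():
        row = reports.loc[dup].iloc[0]
        raise ValueError(
            "reports.csv: duplicate self-report for participant "
            f"{row['participant_id']!r} on {row['date']!r}"
        )

    known = set(roster["participant_id"])
    orphans = set(entries["participant_id"]) - known
    if orphans:
        raise ValueError(f"features.csv: unrostered participant(s) {sorted(orphans)}")
    return Cohort(roster=roster, reports=reports, entries=entries)
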
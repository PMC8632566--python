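"""Affective-state labels from daily self-reports, joined to call features.

Daily self-reports carry mood on a 9-point scale (−3 .. 3, depressed to
manic), activity on a 7-point scale (−3 .. 3, 0 = normal) and sleep
duration derived from bedtime / wake-up clock times.  The label
definitions are:

* euthymia: mood in {−0.5, 0, 0.5}; depression: mood < −0.5;
  mania: mood > 0.5;
* increased activity: score > 0; decreased: score < 0; neutral: 0;
* insomnia: total sleep < 360 minutes (strict);
* broad mania: mood > 0.5 AND activity > 0 AND sleep < 360 min.

Call-level feature rows are joined to the report of the same calendar day;
all calls on a day inherit that day's single label, and days with calls
but no report are excluded from state contrasts.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .synthetic import GROUPS, MOOD_SCALE, ACTIVITY_SCALE

logger = logging.getLogger(__name__)

_MOOD_SET = {round(m, 1) for m in MOOD_SCALE}
_ACTIVITY_SET = set(ACTIVITY_SCALE)

INSOMNIA_THRESHOLD_MIN = 360

#: the six state contrasts (positive class named first)
STATE_CONTRASTS = (
    "mania_vs_euthymia",
    "depression_vs_euthymia",
    "increased_vs_neutral_activity",
    "decreased_vs_neutral_activity",
    "insomnia_vs_normal_sleep",
    "broad_mania_vs_rest",
)

GROUP_CONTRASTS = ("BD_vs_HC", "BD_vs_UR", "UR_vs_HC")


def classify_mood(mood: float) -> str:
    """Mood band for a 9-point mood score.

    Scores are validated against the discrete scale after rounding to one
    decimal, avoiding float-equality pitfalls at the ±0.5 boundaries.
    """
    m = round(float(mood), 1)
    if m not in _MOOD_SET:
        raise ValueError(f"mood score {mood!r} is not on the 9-point scale")
    if -0.5 <= m <= 0.5:
        return "euthymia"
    return "depression" if m < -0.5 else "mania"


def classify_activity(activity: float) -> str:
    """Activity band for a 7-point activity score (0 = normal)."""
    a = int(activity)
    if a != activity or a not in _ACTIVITY_SET:
        raise ValueError(f"activity score {activity!r} is not on the 7-point scale")
    if a == 0:
        return "neutral"
    return "increased" if a > 0 else "decreased"


def _parse_clock(value: str) -> int:
    try:
        hh, mm = str(value).split(":")
        hh, mm = int(hh), int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"unparseable clock time {value!r}") from exc
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise ValueError(f"clock time {value!r} out of range")
    return hh * 60 + mm


def sleep_minutes(bedtime: str, wakeup: str) -> int:
    """Minutes from bedtime to the next occurrence of wake-up.

    Wraps across midnight; ``bedtime == wakeup`` yields 0, not 1440
    (conservative toward a genuinely reported zero-sleep day; logged).
    """
    b, w = _parse_clock(bedtime), _parse_clock(wakeup)
    if b == w:
        logger.debug("bedtime == wakeup (%s): sleep duration taken as 0 min", bedtime)
        return 0
    return (w - b) % 1440


def classify_insomnia(minutes: float) -> bool:
    """True iff total sleep is strictly below 360 minutes."""
    if minutes < 0:
        raise ValueError("sleep minutes must be >= 0")
    return minutes < INSOMNIA_THRESHOLD_MIN


def classify_broad_mania(mood: float, activity: float, minutes: float) -> bool:
    """Broader mania: increased mood AND increased activity AND short sleep."""
    return (
        classify_mood(mood) == "mania"
        and classify_activity(activity) == "increased"
        and classify_insomnia(minutes)
    )


def label_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Per-day state labels for a self-report table.

    Returns one row per (participant, date) with columns ``mood_state``,
    ``activity_state``, ``insomnia``, ``broad_mania`` and ``sleep_minutes``.
    """
    out = reports[["participant_id", "date"]].copy()
    out["mood_state"] = [classify_mood(m) for m in reports["mood"]]
    out["activity_state"] = [classify_activity(a) for a in reports["activity"]]
    out["sleep_minutes"] = [
        sleep_minutes(b, w) for b, w in zip(reports["bedtime"], reports["wakeup"])
    ]
    out["insomnia"] = [classify_insomnia(m) for m in out["sleep_minutes"]]
    out["broad_mania"] = (
        (out["mood_state"] == "mania")
        & (out["activity_state"] == "increased")
        & out["insomnia"]
    )
    return out


@dataclasses.dataclass
class LabeledDataset:
    """Day-joined feature rows with binary labels for one contrast."""

    frame: pd.DataFrame  # participant_id, date, label, f0001..fNNNN
    contrast_name: str
    positive_class: str

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("f")]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def participants(self) -> np.ndarray:
        return self.frame["participant_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def with_labels(self, participant_labels: pd.Series) -> "LabeledDataset":
        """A copy with each participant's rows relabeled (permutation support)."""
        frame = self.frame.copy()
        frame["label"] = frame["participant_id"].map(participant_labels).astype(int)
        return LabeledDataset(frame, self.contrast_name, self.positive_class)


def _entry_days(entries: pd.DataFrame) -> pd.Series:
    """Local calendar date of each call timestamp (ISO string)."""
    return pd.to_datetime(entries["timestamp"]).dt.strftime("%Y-%m-%d")


def build_group_dataset(
    roster: pd.DataFrame,
    entries: pd.DataFrame,
    contrast: tuple[str, str] | str,
) -> LabeledDataset:
    """Diagnostic-group contrast: every call of the two groups, positive
    class = membership of the first-named group.  No self-report join."""
    if isinstance(contrast, str):
        parts = contrast.split("_vs_")
        if len(parts) != 2:
            raise ValueError(f"unknown group contrast {contrast!r}")
        contrast = (parts[0], parts[1])
    pos, neg = contrast
    for g in (pos, neg):
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
    if pos == neg:
        raise ValueError("contrast groups must be distinct")

    group_of = roster.set_index("participant_id")["group"]
    for g in (pos, neg):
        if not (group_of == g).any():
            raise ValueError(f"group {g!r} has no rostered participants")

    groups = entries["participant_id"].map(group_of)
    mask = groups.isin([pos, neg])
    frame = entries.loc[mask].copy()
    frame.insert(1, "date", _entry_days(frame))
    frame.insert(2, "label", (groups[mask] == pos).astype(int))
    frame = frame.drop(columns=["timestamp"]).reset_index(drop=True)
    return LabeledDataset(frame, f"{pos}_vs_{neg}", positive_class=pos)


def _contrast_masks(labels: pd.DataFrame, contrast: str) -> tuple[pd.Series, pd.Series]:
    mood, act = labels["mood_state"], labels["activity_state"]
    if contrast == "mania_vs_euthymia":
        return mood == "mania", mood == "euthymia"
    if contrast == "depression_vs_euthymia":
        return mood == "depression", mood == "euthymia"
    if contrast == "increased_vs_neutral_activity":
        return act == "increased", act == "neutral"
    if contrast == "decreased_vs_neutral_activity":
        return act == "decreased", act == "neutral"
    if contrast == "insomnia_vs_normal_sleep":
        return labels["insomnia"], ~labels["insomnia"]
    if contrast == "broad_mania_vs_rest":
        # negative class = all labeled days not meeting the conjunction
        return labels["broad_mania"], ~labels["broad_mania"]
    raise ValueError(f"unknown state contrast {contrast!r}")


def build_state_dataset(
    reports: pd.DataFrame,
    entries: pd.DataFrame,
    contrast: str,
) -> LabeledDataset:
    """Affective-state contrast within patients.

    A call contributes one row iff its calendar day has a self-report and
    the day's label falls in one of the contrast's two classes.
    """
    if contrast not in STATE_CONTRASTS:
        raise ValueError(
            f"unknown state contrast {contrast!r}; expected one of {STATE_CONTRASTS}"
        )
    labels = label_reports(reports)
    pos, neg = _contrast_masks(labels, contrast)
    labels = labels.assign(label=np.select([pos, neg], [1, 0], default=-1))
    labels = labels.loc[labels["label"] >= 0, ["participant_id", "date", "label"]]

    frame = entries.copy()
    frame["date"] = _entry_days(frame)
    frame = frame.merge(labels, on=["participant_id", "date"], how="inner")
    feature_cols = [c for c in entries.columns if c.startswith("f")]
    frame = frame[["participant_id", "date", "label"] + feature_cols].reset_index(
        drop=True
    )
    return LabeledDataset(frame, contrast, positive_class=contrast.split("_vs_")[0])
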
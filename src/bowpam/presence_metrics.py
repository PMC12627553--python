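"""Detection performance and acoustic-presence summaries.

Performance is tallied at file level (one 10-min recording per unit) or at
hour level, where each file contributes to the full clock hour in which it
starts; an hour is positive when at least one of its files is positive, and
hours with no recorded files are missing, not negative (duty-cycled
recorders must not inflate specificity).  Presence rolls up further to
hours-per-day, and song annotations are tabulated with songs numbered in
order of first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

SAMPLE_DAYS_OF_MONTH = (5, 10, 15, 20, 25)


@dataclass(frozen=True)
class PerformanceSummary:
    """Confusion counts with derived sensitivity and false-positive rate.

    Rates are ``None`` (flagged undefined) when their denominator is zero,
    never silently NaN.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    level: str = "file"

    @property
    def n_units(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else None

    @property
    def fp_rate(self) -> Optional[float]:
        d = self.fp + self.tn
        return self.fp / d if d > 0 else None

    def rounded(self, ndigits: int = 2) -> Tuple[Optional[float], Optional[float]]:
        """Display rounding used in performance tables (2 dp)."""
        s, f = self.sensitivity, self.fp_rate
        return (None if s is None else round(s, ndigits),
                None if f is None else round(f, ndigits))


def confusion_summary(predicted: Sequence[int], truth: Sequence[int],
                      level: str = "file") -> PerformanceSummary:
    """Confusion counts over aligned unit-level decisions.

    For hour-level summaries, roll both predictions and truth up with
    :func:`hourly_rollup` first and pass the aligned per-hour flags here.
    """
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth length mismatch")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    return PerformanceSummary(tp=tp, tn=tn, fp=fp, fn=fn, level=level)


def hourly_rollup(records: pd.DataFrame,
                  columns: Sequence[str] = ("predicted", "truth")) -> pd.DataFrame:
    """Per-hour flags: an hour is positive iff >= 1 positive file starts in it.

    Only hours containing at least one record appear in the result (missing
    hours stay missing).  Returns a DataFrame indexed by the hour timestamp
    with one boolean-as-int column per requested input column.
    """
    if "start_time" not in records.columns:
        raise ValueError("records need a start_time column")
    hours = pd.to_datetime(records["start_time"]).dt.floor("h")
    present = [c for c in columns if c in records.columns]
    grouped = records[present].astype(int).groupby(hours).max()
    grouped.index.name = "hour"
    return grouped


@dataclass
class PresenceSeries:
    """Daily acoustic presence derived from hourly flags."""

    daily: pd.DataFrame          # columns: presence_hours, recorded_hours
    total_presence_hours: int
    days_with_presence: int


def daily_presence(hourly_flags: pd.Series) -> PresenceSeries:
    """Positive hours per day plus season totals.

    ``hourly_flags`` is the per-hour 0/1 series from :func:`hourly_rollup`
    (index: hour timestamps).  Recorded hours per day count the hours that
    exist in the series at all, keeping duty-cycle gaps out of denominators.
    """
    flags = hourly_flags.astype(int)
    days = flags.index.floor("d")
    daily = pd.DataFrame({
        "presence_hours": flags.groupby(days).sum(),
        "recorded_hours": flags.groupby(days).size(),
    })
    daily.index.name = "date"
    return PresenceSeries(
        daily=daily,
        total_presence_hours=int(flags.sum()),
        days_with_presence=int((daily["presence_hours"] > 0).sum()),
    )


def select_sample_days(start, end) -> List[pd.Timestamp]:
    """The 5th, 10th, 15th, 20th and 25th of each month within [start, end]."""
    days = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    return [d for d in days if d.day in SAMPLE_DAYS_OF_MONTH]


@dataclass
class SongTally:
    """Song-occurrence tabulation with first-occurrence numbering."""

    numbering: Dict[str, int]            # reviewer label -> song number
    songs_per_day: pd.Series             # unique songs per date
    songs_per_month: pd.Series           # unique songs per calendar month
    active_days: pd.Series               # distinct active days per song number


def song_tally(annotations: pd.DataFrame) -> SongTally:
    """Tabulate song occurrence from (date, song_label) annotations.

    Songs are renumbered 1..K in order of their first appearance date
    (ties broken by row order), then counted per day, per month, and per
    song as the number of distinct days each song was recorded.
    """
    ann = annotations.copy()
    ann["date"] = pd.to_datetime(ann["date"]).dt.normalize()
    ann = ann.reset_index(drop=True)

    first_seen = (ann.reset_index()
                  .groupby("song_label", sort=False)
                  .agg(date=("date", "min"), order=("index", "min"))
                  .sort_values(["date", "order"]))
    numbering = {label: i + 1 for i, label in enumerate(first_seen.index)}
    ann["song"] = ann["song_label"].map(numbering)

    songs_per_day = ann.groupby("date")["song"].nunique()
    songs_per_month = ann.groupby(ann["date"].dt.to_period("M"))["song"].nunique()
    active_days = ann.groupby("song")["date"].nunique().sort_index()
    return SongTally(numbering=numbering, songs_per_day=songs_per_day,
                     songs_per_month=songs_per_month, active_days=active_days)
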
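"""Thresholding and the partial false-positive-control review workflow.

Model probabilities become binary detections at a fixed 0.5 threshold
(ties count as negative).  Because bowhead whales call almost exclusively
in winter, positive detections falling between March 1st and the first
reviewer-confirmed detection of the following autumn are flagged for manual
review; a reviewer can only reject a detection (flip 1 -> 0), never create
one, so sensitivity is invariant under review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DETECTION_THRESHOLD = 0.5
DETECTION_COLUMNS = ["clip_id", "start_time", "probability", "predicted",
                     "review_status"]


@dataclass(frozen=True)
class ReviewWindow:
    """Seasonal review window per deployment year.

    Each season-year starts at ``season_start`` (month, day) and the review
    window runs from there until the first reviewer-confirmed detection at
    or after ``autumn_search_from``; with no confirmed autumn detection the
    window extends to the end of the records.  The autumn anchor is a
    parameter because field protocols anchor it differently (September vs
    November); the default is September 1.
    """

    season_start: Tuple[int, int] = (3, 1)
    autumn_search_from: Tuple[int, int] = (9, 1)


def threshold_scores(probabilities: Sequence[float],
                     threshold: float = DETECTION_THRESHOLD) -> np.ndarray:
    """Binary decisions: p > threshold -> 1, p < threshold -> 0, tie -> 0."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p > threshold).astype(int)


def make_detections(clip_ids: Sequence[str], start_times,
                    probabilities: Sequence[float],
                    truth: Optional[Sequence[int]] = None,
                    threshold: float = DETECTION_THRESHOLD) -> pd.DataFrame:
    """Assemble the detection table, one row per clip."""
    df = pd.DataFrame({
        "clip_id": list(clip_ids),
        "start_time": pd.to_datetime(list(start_times)),
        "probability": np.asarray(probabilities, dtype=float),
    })
    df["predicted"] = threshold_scores(df["probability"].to_numpy(), threshold)
    df["review_status"] = "auto"
    if truth is not None:
        df["truth"] = np.asarray(truth, dtype=int)
    return df


def _season_year(ts: pd.Timestamp, season_start: Tuple[int, int]) -> int:
    m, d = season_start
    return ts.year if (ts.month, ts.day) >= (m, d) else ts.year - 1


def flag_review_window(records: pd.DataFrame,
                       window: ReviewWindow = ReviewWindow()) -> pd.DataFrame:
    """Positive detections inside the season's review window.

    Window end per season-year is the first already-confirmed detection at
    or after the autumn anchor (inclusive); detections after it need no
    review.  Returns the flagged subset of ``records``.
    """
    if len(records) == 0:
        return records.iloc[0:0]
    times = pd.to_datetime(records["start_time"])
    season = times.map(lambda ts: _season_year(ts, window.season_start))
    flagged = np.zeros(len(records), dtype=bool)
    for year in season.unique():
        in_season = (season == year).to_numpy()
        start = pd.Timestamp(year=year, month=window.season_start[0],
                             day=window.season_start[1])
        anchor = pd.Timestamp(year=year, month=window.autumn_search_from[0],
                              day=window.autumn_search_from[1])
        confirmed = (in_season
                     & (records["review_status"] == "confirmed").to_numpy()
                     & (records["predicted"] == 1).to_numpy()
                     & (times >= anchor).to_numpy())
        end = times[confirmed].min() if confirmed.any() else times[in_season].max()
        flagged |= (in_season
                    & (records["predicted"] == 1).to_numpy()
                    & (times >= start).to_numpy()
                    & (times <= end).to_numpy())
    return records[flagged]


def apply_review(records: pd.DataFrame,
                 decisions: Dict[str, str],
                 flagged_ids: Iterable[str]) -> pd.DataFrame:
    """Apply reviewer decisions (``confirm`` | ``reject``) to flagged clips.

    Rejected detections become predicted 0 with status ``rejected``;
    confirmed ones keep predicted 1.  Decisions for unflagged clips are an
    error, and applying the same decisions twice is a no-op.
    """
    flagged_ids = set(flagged_ids)
    unknown = set(decisions) - flagged_ids
    if unknown:
        raise ValueError(f"decisions reference unflagged clips: {sorted(unknown)}")
    bad = {d for d in decisions.values() if d not in ("confirm", "reject")}
    if bad:
        raise ValueError(f"unknown decisions: {sorted(bad)}")
    out = records.copy()
    for clip_id, decision in decisions.items():
        sel = out["clip_id"] == clip_id
        if decision == "reject":
            out.loc[sel, "predicted"] = 0
            out.loc[sel, "review_status"] = "rejected"
        else:
            out.loc[sel, "review_status"] = "confirmed"
    return out
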
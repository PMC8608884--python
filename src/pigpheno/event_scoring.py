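"""Scoring of novel-object-recognition sessions and baited ball-pit trials.

Novel-object sessions are scored from manually annotated contact intervals
labeled ``novel`` / ``familiar``; the summary reports cumulative seconds per
object, each object's percentage of total contact time, and the standard
discrimination index (novel - familiar) / (novel + familiar).

Ball-pit trials are scored from instant ``retrieval`` events: the latency to
the first retrieval is measured from trial start, subsequent latencies are
successive differences, and the trial's mean latency is the mean of the
available latencies.  Trials are capped at 300 s and hold at most six
retrievals (six buried rewards).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import EventLog, ValidationError

logger = logging.getLogger(__name__)

CONTACT_LABELS = ("novel", "familiar")
TRIAL_CAP_S = 300.0  # the assay lasts under 5 minutes
MAX_RETRIEVALS = 6


@dataclass
class ContactSummary:
    familiar_seconds: float
    novel_seconds: float
    familiar_pct: float  # NaN when total contact time is zero
    novel_pct: float
    n_bouts: dict[str, int] = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def total_seconds(self) -> float:
        return self.familiar_seconds + self.novel_seconds


@dataclass
class RetrievalTrial:
    retrieval_times: np.ndarray  # seconds from trial start, ordered
    latencies: np.ndarray  # first from trial start, then successive diffs
    mean_latency: float

    @property
    def n_retrieved(self) -> int:
        return len(self.retrieval_times)


def _merge_intervals(intervals: np.ndarray) -> tuple[np.ndarray, bool]:
    """Union of [start, end] intervals; returns (merged, had_overlap)."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2), False
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    ivs = intervals[order]
    merged = [ivs[0].copy()]
    overlap = False
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            overlap = overlap or s < merged[-1][1]
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.array(merged), overlap


def contact_summary(log: EventLog) -> ContactSummary:
    """Cumulative contact seconds and percentages per object.

    Overlapping same-label intervals are merged with a warning (annotator
    overlap, not double contact).  Overlaps *across* labels are both counted.
    Zero total contact leaves the percentages NaN and flags the summary.
    """
    df = log.data
    unknown = set(df["label"]) - set(CONTACT_LABELS)
    if unknown:
        raise ValidationError(f"contact labels must be in {CONTACT_LABELS}, got {sorted(unknown)}")
    if df["end"].isna().any():
        raise ValidationError("contact events must be intervals (end required)")
    seconds: dict[str, float] = {}
    n_bouts: dict[str, int] = {}
    flags: list[str] = []
    for label in CONTACT_LABELS:
        ivs = df.loc[df["label"] == label, ["start", "end"]].to_numpy(float)
        n_bouts[label] = len(ivs)
        merged, overlapped = _merge_intervals(ivs)
        if overlapped:
            logger.warning("overlapping %r intervals merged", label)
            flags.append(f"merged-overlap:{label}")
        seconds[label] = float((merged[:, 1] - merged[:, 0]).sum()) if len(merged) else 0.0
    total = seconds["novel"] + seconds["familiar"]
    if total > 0:
        novel_pct = 100.0 * seconds["novel"] / total
        familiar_pct = 100.0 * seconds["familiar"] / total
    else:
        novel_pct = familiar_pct = float("nan")
        flags.append("zero-total-contact")
    return ContactSummary(
        familiar_seconds=seconds["familiar"],
        novel_seconds=seconds["novel"],
        familiar_pct=familiar_pct,
        novel_pct=novel_pct,
        n_bouts=n_bouts,
        flags=flags,
    )


def discrimination_index(summary: ContactSummary) -> float:
    """(novel - familiar) / (novel + familiar) contact time, in [-1, 1].

    NaN when no contact occurred at all.
    """
    total = summary.total_seconds
    if total == 0:
        return float("nan")
    return (summary.novel_seconds - summary.familiar_seconds) / total


def retrieval_trial(log: EventLog, trial_start: float = 0.0) -> RetrievalTrial:
    """Latencies between successful reward retrievals in one ball-pit trial.

    Events must be instants labeled ``retrieval``; at most six, all at or
    after ``trial_start`` and within the 300 s trial cap.
    """
    df = log.data[log.data["label"] == "retrieval"]
    if df["end"].notna().any():
        raise ValidationError("retrieval events must be instants (no end)")
    times = np.sort(df["start"].to_numpy(float))
    if len(times) > MAX_RETRIEVALS:
        raise ValidationError(f"more than {MAX_RETRIEVALS} retrievals in one trial")
    if len(times) and times[0] < trial_start:
        raise ValidationError("retrieval before trial start")
    if len(times) and times[-1] - trial_start > TRIAL_CAP_S:
        raise ValidationError(f"retrieval after the {TRIAL_CAP_S:.0f} s trial cap")
    rel = times - trial_start
    if len(np.unique(times)) != len(times):
        raise ValidationError("retrieval times must be strictly increasing")
    latencies = np.diff(np.concatenate(([0.0], rel)))
    mean = float(latencies.mean()) if len(latencies) else float("nan")
    return RetrievalTrial(retrieval_times=rel, latencies=latencies, mean_latency=mean)
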
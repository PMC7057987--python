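"""Streaming retention monitoring.

Frames arrive in order at a fixed interval (500 ms by default).  Each frame
is scored by the classifier; the first run of ``M`` consecutive scores at or
above the operating cutoff marks the capsule's entry into the descending
duodenum (DSD).  Because the capsule does not return to the stomach once it
has truly entered the DSD, a later run of ``K`` consecutive sub-cutoff
scores means the mark was premature: it is revoked and the search resumes
from the end of the contradicting run, with every revision kept in the
mark's correction history.  If no entry has been marked by the warning
limit (2 h by default) a gastric-retention warning is raised.

Deviation of the CNN mark from a reference (endoscopist) mark is counted
exclusively — ``max(|i_cnn - i_ref| - 1, 0)`` intervening frames — and
binned at the +/-1 min and +/-3 min edges; a deviation beyond +/-8 min is a
monitoring failure.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import percent

__all__ = [
    "MonitorConfig",
    "EntryMark",
    "WarningStatus",
    "Direction",
    "DeviationBin",
    "DeviationReport",
    "score_stream",
    "mark_entry",
    "correct_mark",
    "monitor_stream",
    "check_warning",
    "deviation",
    "deviation_summary",
]


@dataclass(frozen=True)
class MonitorConfig:
    """Operating parameters of the streaming monitor.

    ``cutoff`` normally comes from the Youden procedure on a validation
    set.  ``m_confirm`` consecutive positive frames mark entry (1 = the
    first DSD frame marks, revisable); ``k_correct`` consecutive negative
    frames after a mark revoke it.  ``warning_limit_s`` defaults to the
    2-hour gastric-retention limit.
    """

    cutoff: float = 0.5
    m_confirm: int = 1
    k_correct: int = 3
    warning_limit_s: float = 7200.0
    interval_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.m_confirm < 1 or self.k_correct < 1:
            raise ValueError("m_confirm and k_correct must be >= 1")
        if self.warning_limit_s < 0 or self.interval_ms <= 0:
            raise ValueError("warning limit must be >= 0 and interval > 0")


@dataclass
class EntryMark:
    """A (possibly corrected) DSD-entry mark.

    ``history`` holds ``(old_index, new_index, reason)`` tuples in stream
    order; ``new_index`` is ``None`` while a revocation has not yet been
    replaced by a new mark.
    """

    index: int | None
    interval_ms: float = 500.0
    run_length: int = 1
    history: list = field(default_factory=list)

    @property
    def time_s(self) -> float | None:
        if self.index is None:
            return None
        return self.index * self.interval_ms / 1000.0


@dataclass(frozen=True)
class WarningStatus:
    raised: bool
    frame_index: int | None = None
    time_s: float | None = None


class Direction(enum.Enum):
    AHEAD = "ahead"
    DELAYED = "delayed"
    EXACT = "exact"


class DeviationBin(enum.Enum):
    LT_1MIN = "<1min"
    BETWEEN_1_3MIN = "1-3min"
    GE_3MIN = ">=3min"


@dataclass(frozen=True)
class DeviationReport:
    frames: int
    direction: Direction
    time_s: float
    bin: DeviationBin
    failure: bool


# ---------------------------------------------------------------------------
# scoring and marking
# ---------------------------------------------------------------------------


def score_stream(classifier, stream, batch_size: int = 256) -> np.ndarray:
    """Score every frame of a stream in order.

    ``classifier`` is anything with a ``predict_score(frames) -> scores``
    method (a trained results object or a raw network); ``stream`` is a
    ``FrameStream`` or an ``(n, H, W)`` array of raw 8-bit frames, which
    are normalized before scoring.
    """
    frames = getattr(stream, "frames", stream)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise ValueError("empty stream")
    out = np.empty(len(frames), dtype=float)
    for lo in range(0, len(frames), batch_size):
        out[lo : lo + batch_size] = classifier.predict_score(frames[lo : lo + batch_size])
    return out


def _first_run_at_or_above(scores: np.ndarray, cutoff: float, m: int, start: int) -> int | None:
    run = 0
    for i in range(start, len(scores)):
        run = run + 1 if scores[i] >= cutoff else 0
        if run >= m:
            return i - m + 1
    return None


def mark_entry(scores, cfg: MonitorConfig) -> EntryMark:
    """First index starting a run of >= M scores at/above the cutoff.

    Returns a mark with ``index=None`` when no qualifying run exists —
    absence is a valid outcome, feeding :func:`check_warning`.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("empty score series")
    idx = _first_run_at_or_above(s, cfg.cutoff, cfg.m_confirm, 0)
    return EntryMark(index=idx, interval_ms=cfg.interval_ms, run_length=cfg.m_confirm)


def correct_mark(mark: EntryMark, scores, cfg: MonitorConfig) -> EntryMark:
    """Apply the retrospective correction rule over the full score series.

    Starting from the existing mark, any run of >= K consecutive sub-cutoff
    scores after the marked index revokes the mark ("confirmed repeatedly"
    to be stomach); the entry search resumes from the end of that run.
    Repeats until the series is exhausted.  Each revision is appended to the
    correction history.
    """
    s = np.asarray(scores, dtype=float).ravel()
    out = EntryMark(
        index=mark.index,
        interval_ms=mark.interval_ms,
        run_length=mark.run_length,
        history=list(mark.history),
    )
    while out.index is not None:
        # look for K consecutive negatives after the marked frame
        run = 0
        violation_end = None
        for i in range(out.index + 1, len(s)):
            run = run + 1 if s[i] < cfg.cutoff else 0
            if run >= cfg.k_correct:
                violation_end = i
                break
        if violation_end is None:
            break
        new_idx = _first_run_at_or_above(s, cfg.cutoff, cfg.m_confirm, violation_end + 1)
        out.history.append(
            (out.index, new_idx, f"{cfg.k_correct} consecutive stomach frames after mark")
        )
        out.index = new_idx
    return out


def monitor_stream(scores, cfg: MonitorConfig) -> EntryMark:
    """Mark entry and apply all corrections: the full streaming decision."""
    return correct_mark(mark_entry(scores, cfg), scores, cfg)


def check_warning(scores, cfg: MonitorConfig) -> WarningStatus:
    """Gastric-retention warning if no mark exists by the time limit.

    Elapsed stream time after observing ``n`` frames is ``n * interval``;
    the warning is attributed to the first frame index at which the limit
    is crossed, ``ceil(limit / interval)``.
    """
    s = np.asarray(scores, dtype=float).ravel()
    mark = monitor_stream(s, cfg) if s.size else EntryMark(None, cfg.interval_ms)
    interval_s = cfg.interval_ms / 1000.0
    elapsed_s = s.size * interval_s
    if mark.index is None and elapsed_s >= cfg.warning_limit_s:
        frame = math.ceil(cfg.warning_limit_s / interval_s)
        return WarningStatus(raised=True, frame_index=frame, time_s=frame * interval_s)
    return WarningStatus(raised=False)


# ---------------------------------------------------------------------------
# deviation
# ---------------------------------------------------------------------------

_BIN_1MIN_S = 60.0
_BIN_3MIN_S = 180.0
_FAILURE_S = 480.0


def _bin_for(time_s: float) -> DeviationBin:
    if time_s < _BIN_1MIN_S:
        return DeviationBin.LT_1MIN
    if time_s < _BIN_3MIN_S:
        return DeviationBin.BETWEEN_1_3MIN
    return DeviationBin.GE_3MIN


def deviation(cnn_index: int, reference_index: int, interval_ms: float = 500.0) -> DeviationReport:
    """Deviation of the CNN mark from the reference mark.

    Frames are counted exclusively — ``max(|delta| - 1, 0)`` frames lie
    strictly between the two marks — and converted to seconds at the frame
    interval.  The mark is DELAYED when the CNN index is later than the
    reference, AHEAD when earlier.
    """
    if cnn_index < 0 or reference_index < 0:
        raise ValueError("indices must be nonnegative")
    delta = cnn_index - reference_index
    frames = max(abs(delta) - 1, 0)
    if delta > 0:
        direction = Direction.DELAYED
    elif delta < 0:
        direction = Direction.AHEAD
    else:
        direction = Direction.EXACT
    time_s = frames * interval_ms / 1000.0
    return DeviationReport(
        frames=frames,
        direction=direction,
        time_s=time_s,
        bin=_bin_for(time_s),
        failure=time_s > _FAILURE_S,
    )


def deviation_summary(reports) -> dict:
    """Bin counts/percentages and the failure / within-8-min rates."""
    reports = list(reports)
    if not reports:
        raise ValueError("empty report list")
    n = len(reports)
    counts = {b: 0 for b in DeviationBin}
    failures = 0
    for r in reports:
        counts[r.bin] += 1
        failures += int(r.failure)
    return {
        "n": n,
        "counts": {b.value: counts[b] for b in DeviationBin},
        "percent": {b.value: percent(counts[b] / n) for b in DeviationBin},
        "failures": failures,
        "failure_rate_percent": percent(failures / n),
        "within_8min_percent": percent(1.0 - failures / n),
    }
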
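"""Timeline marker codec.

In the timeline method of trial introspection, participants recreate a
dual-task trial by placing four markers (one per event: S1, S2, R1, R2) on a
horizontal line that represents the whole trial interval, from frame onset
("start") to frame offset ("end").  The codec here is the linear map between
trial time in milliseconds and marker position in pixels, plus the derived
introspective reaction times (iRT1, iRT2).

Conventions
-----------
* Pixel 0 is the left ("start") end of the line and corresponds to frame
  onset (t = 0 ms); ``timeline_px`` corresponds to ``trial_duration_ms``.
* The timeline represents the full frame interval, including the foreperiod
  before S1 and the endperiod after the last response.
* Marker positions are continuous; they are not snapped to tick marks.
* Negative iRTs are legal output (a reversed marker pair) and are passed
  downstream unchanged; exclusion decisions are made on objective RTs only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimelineReport",
    "IntrospectiveRTs",
    "decode",
    "encode",
    "compute_irts",
    "add_irt_columns",
]


@dataclass(frozen=True)
class TimelineReport:
    """The four marker positions of one trial recreation plus geometry.

    Attributes
    ----------
    iS1_px, iS2_px, iR1_px, iR2_px
        Marker positions in pixels, each in ``[0, timeline_px]``.
    timeline_px
        Length of the timeline in pixels.
    trial_duration_ms
        Duration the timeline represents: foreperiod + last event +
        endperiod, in milliseconds.
    """

    iS1_px: float
    iS2_px: float
    iR1_px: float
    iR2_px: float
    timeline_px: float
    trial_duration_ms: float

    def __post_init__(self) -> None:
        if not self.timeline_px > 0:
            raise ValueError("timeline_px must be positive")
        if not self.trial_duration_ms > 0:
            raise ValueError("trial_duration_ms must be positive")
        for name in ("iS1_px", "iS2_px", "iR1_px", "iR2_px"):
            v = getattr(self, name)
            if not (0 <= v <= self.timeline_px):
                raise ValueError(
                    f"{name}={v} outside the timeline [0, {self.timeline_px}]"
                )


@dataclass(frozen=True)
class IntrospectiveRTs:
    """Reported reaction times decoded from a timeline recreation (ms)."""

    iRT1: float
    iRT2: float


def decode(marker_px, timeline_px, trial_duration_ms):
    """Convert a marker position (pixels) to trial time (ms).

    Linear map of ``[0, timeline_px]`` onto ``[0, trial_duration_ms]``.
    Accepts scalars or arrays.  Raises ``ValueError`` if a marker lies
    outside the timeline.
    """
    marker_px = np.asarray(marker_px, dtype=float)
    if np.any(np.asarray(timeline_px) <= 0):
        raise ValueError("timeline_px must be positive")
    if np.any(marker_px < 0) or np.any(marker_px > timeline_px):
        raise ValueError("marker position outside [0, timeline_px]")
    out = marker_px / timeline_px * trial_duration_ms
    return float(out) if out.ndim == 0 else out


def encode(t_ms, timeline_px, trial_duration_ms, clip: bool = False):
    """Convert a trial time (ms) to a marker position (pixels).

    Exact inverse of :func:`decode`.  With ``clip=True`` times outside the
    represented interval are clamped to the line ends instead of raising;
    the simulator uses this for noisy marker times.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    if np.any(np.asarray(trial_duration_ms) <= 0):
        raise ValueError("trial_duration_ms must be positive")
    if clip:
        t_ms = np.clip(t_ms, 0.0, trial_duration_ms)
    elif np.any(t_ms < 0) or np.any(t_ms > trial_duration_ms):
        raise ValueError("time outside [0, trial_duration_ms]")
    out = t_ms / trial_duration_ms * timeline_px
    return float(out) if out.ndim == 0 else out


def compute_irts(report: TimelineReport) -> IntrospectiveRTs:
    """Decode iRT1 and iRT2 from a timeline recreation.

    iRT1 is the decoded distance from the S1 marker to the R1 marker, iRT2
    from the S2 marker to the R2 marker.  A marker pair in reversed order
    yields a negative iRT, which is returned as-is.
    """
    ms = {
        k: decode(getattr(report, k), report.timeline_px, report.trial_duration_ms)
        for k in ("iS1_px", "iS2_px", "iR1_px", "iR2_px")
    }
    return IntrospectiveRTs(
        iRT1=ms["iR1_px"] - ms["iS1_px"],
        iRT2=ms["iR2_px"] - ms["iS2_px"],
    )


def add_irt_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Append decoded ``iRT1``/``iRT2`` columns to a tidy trial table.

    Requires the marker columns ``iS1_px, iS2_px, iR1_px, iR2_px`` plus
    ``timeline_px`` and ``trial_duration_ms``.
    """
    out = trials.copy()
    scale = out["trial_duration_ms"] / out["timeline_px"]
    out["iRT1"] = (out["iR1_px"] - out["iS1_px"]) * scale
    out["iRT2"] = (out["iR2_px"] - out["iS2_px"]) * scale
    return out
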
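"""Single-trial introspective-accuracy statistic.

A trial's temporal structure (four events S1, S2, R1, R2) is summarised by a
single angle: plot the point (S1, R1) against the point (R2, S2) in pixel
coordinates on the trial's timeline, draw the line through them, and take
the arctangent of its slope::

    rad = atan( (S2 - R1) / (R2 - S1) )

Applied to the participant's marker positions this gives ``rad_intro``;
applied to the true event times (encoded to pixels on the same timeline)
it gives ``rad_obj``.  Their absolute difference

    delta_rad = |rad_obj - rad_intro|

is the per-trial measure of introspective *in*accuracy: 0 when the reported
structure is exactly parallel to the objective one, growing as events are
reported in a different order or with a different spacing.

The sign of the radian tracks the order of the two central events: S2
before R1 (short-SOA structure, S1-S2-R1-R2) gives a negative radian, R1
before S2 (long-SOA structure) a positive one.  The covariate
``central_gap`` is the absolute time |t_S2 - t_R1| between those two
central events.

Edge cases: a vertical line (R2 and S1 markers coincide, numerator nonzero)
is mapped to ±π/2; a report whose line is undefined (all four markers
coincide, or both line points identical) is *degenerate* and returns NaN —
degenerate trials are removed before modelling, not errored on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrialEvents
from .timeline import encode

__all__ = [
    "RadianSummary",
    "radian_of_report",
    "radian_of_trial",
    "delta_rad",
    "central_gap",
    "add_radian_columns",
]


@dataclass(frozen=True)
class RadianSummary:
    """Radian summary of one trial."""

    rad_obj: float
    rad_intro: float
    delta_rad: float
    central_gap_ms: float
    degenerate: bool


def radian_of_report(iS1_px, iR1_px, iR2_px, iS2_px):
    """Radian of the line through (iS1, iR1) and (iR2, iS2).

    Accepts scalars or arrays; returns NaN for degenerate reports (both
    line points identical, which includes all four markers coinciding).
    A vertical line with nonzero numerator returns sign(numerator)·π/2.
    """
    iS1 = np.asarray(iS1_px, dtype=float)
    iR1 = np.asarray(iR1_px, dtype=float)
    iR2 = np.asarray(iR2_px, dtype=float)
    iS2 = np.asarray(iS2_px, dtype=float)
    num = iS2 - iR1
    den = iR2 - iS1
    with np.errstate(divide="ignore", invalid="ignore"):
        rad = np.arctan(num / den)
    vertical = (den == 0) & (num != 0)
    rad = np.where(vertical, np.sign(num) * np.pi / 2.0, rad)
    degenerate = (den == 0) & (num == 0)
    rad = np.where(degenerate, np.nan, rad)
    return float(rad) if rad.ndim == 0 else rad


def radian_of_trial(events: TrialEvents, timeline_px: float, trial_duration_ms: float):
    """Objective radian: encode the true event times to pixels on the
    trial's own timeline and apply :func:`radian_of_report` to them, so the
    objective and introspective slopes share one geometry."""
    px = encode(
        np.array([events.t_S1, events.t_R1, events.t_R2, events.t_S2]),
        timeline_px,
        trial_duration_ms,
    )
    return radian_of_report(px[0], px[1], px[2], px[3])


def delta_rad(rad_obj, rad_intro):
    """Absolute radian difference — the introspective-inaccuracy measure."""
    out = np.abs(np.asarray(rad_obj, dtype=float) - np.asarray(rad_intro, dtype=float))
    return float(out) if out.ndim == 0 else out


def central_gap(events: TrialEvents) -> float:
    """Absolute time (ms) between the trial's two central events, S2 and R1."""
    return float(abs(events.t_S2 - events.t_R1))


def add_radian_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Append ``rad_obj``, ``rad_intro``, ``delta_rad``, ``central_gap`` and
    ``degenerate`` columns to a tidy trial table (vectorised)."""
    out = trials.copy()
    scale = out["timeline_px"] / out["trial_duration_ms"]
    obj_px = {e: out[f"t_{e}"] * scale for e in ("S1", "R1", "R2", "S2")}
    out["rad_obj"] = radian_of_report(
        obj_px["S1"].to_numpy(),
        obj_px["R1"].to_numpy(),
        obj_px["R2"].to_numpy(),
        obj_px["S2"].to_numpy(),
    )
    out["rad_intro"] = radian_of_report(
        out["iS1_px"].to_numpy(),
        out["iR1_px"].to_numpy(),
        out["iR2_px"].to_numpy(),
        out["iS2_px"].to_numpy(),
    )
    out["degenerate"] = np.isnan(out["rad_intro"]) | np.isnan(out["rad_obj"])
    out["delta_rad"] = delta_rad(out["rad_obj"].to_numpy(), out["rad_intro"].to_numpy())
    out["central_gap"] = (out["t_S2"] - out["t_R1"]).abs()
    return out
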
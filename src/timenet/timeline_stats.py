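"""Descriptive per-timeline statistics.

These summaries -- occupancy, state entropy, mean interaction lifetime and
lag autocorrelation -- are repo-defined conveniences for inspecting
individual interaction timelines; the precise formulas are this package's
choices (documented below and in the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .information import entropy
from .network import Timeline

__all__ = ["TimelineSummary", "summarize_timeline", "mean_lifetime", "autocorrelation"]


@dataclass(frozen=True)
class TimelineSummary:
    mean: float  # mean count; occupancy for binary timelines
    entropy: float  # plug-in Shannon entropy of states, bits
    mean_lifetime: float  # mean length (frames) of maximal nonzero runs; nan if none
    autocorrelation: float  # Pearson r between X[:-lag] and X[lag:]; nan if undefined
    lag: int
    autocorrelation_defined: bool


def mean_lifetime(x: Timeline | np.ndarray) -> float:
    """Mean length of maximal runs of consecutive frames with value > 0.

    For binary timelines, mean lifetime times the number of runs equals the
    total number of occupied frames.  NaN when the timeline is all zero.
    """
    vals = x.values if isinstance(x, Timeline) else np.asarray(x)
    present = np.concatenate([[0], (vals > 0).astype(int), [0]])
    starts = np.flatnonzero(np.diff(present) == 1)
    ends = np.flatnonzero(np.diff(present) == -1)
    if starts.size == 0:
        return float("nan")
    return float(np.mean(ends - starts))


def autocorrelation(x: Timeline | np.ndarray, lag: int) -> tuple[float, bool]:
    """Pearson correlation between a timeline and its lag-shifted copy.

    Returns (value, defined).  Undefined -- flagged, value NaN -- when either
    overlapping segment is constant, e.g. for constant timelines.
    """
    vals = x.values if isinstance(x, Timeline) else np.asarray(x)
    if not 0 < lag < vals.size:
        raise ValueError(f"lag must be in (0, {vals.size})")
    a = vals[:-lag].astype(float)
    b = vals[lag:].astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), False
    r = float(np.corrcoef(a, b)[0, 1])
    return r, True


def summarize_timeline(x: Timeline | np.ndarray, lag: int = 1) -> TimelineSummary:
    """Mean, entropy, mean lifetime and lag autocorrelation of a timeline."""
    vals = x.values if isinstance(x, Timeline) else np.asarray(x)
    ac, defined = autocorrelation(vals, lag)
    return TimelineSummary(
        mean=float(np.mean(vals)),
        entropy=entropy(vals),
        mean_lifetime=mean_lifetime(vals),
        autocorrelation=ac,
        lag=lag,
        autocorrelation_defined=defined,
    )
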
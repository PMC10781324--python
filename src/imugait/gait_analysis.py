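"""Temporal gait-parameter estimation from lower-limb angular velocity.

The estimator works on the y-component of the gyroscope and its signal
vector magnitude (resultant).  Both are low-pass filtered; toe-off and
heel-strike events both appear as peaks in gyro-y, and are told apart by
their position relative to the instants where the resultant rises through
a threshold: the swing phase drives the resultant high, so the upward
crossing marks the start of swing and the peak nearest it is the toe-off,
while the peak at the far boundary of the swing interval is the heel
strike.  Heel strikes and toe-offs then split each stride into stance
(heel strike -> next toe-off) and swing (toe-off -> next heel strike).

"Gait duration" follows the single-foot convention: half the stride
duration, i.e. an estimate of the step duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_core import ImuSeries


@dataclass
class FilterSpec:
    """Butterworth low-pass settings.

    A 5 Hz cutoff suppresses reconstruction noise while keeping the gait
    band (stride frequencies ~1 Hz and their first harmonics) intact; the
    reference event-detection literature used 12 Hz.  Zero-phase
    (forward-backward) application avoids biasing event times.
    """

    cutoff: float = 5.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def lowpass(x, sample_rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth low-pass; zero-phase (filtfilt) by default."""
    x = np.asarray(x, dtype=float)
    nyquist = sample_rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyquist} Hz")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=sample_rate, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


@dataclass
class GaitEvents:
    """Alternating toe-off / heel-strike timestamps (seconds) for one walk."""

    toe_offs: np.ndarray
    heel_strikes: np.ndarray

    def __post_init__(self) -> None:
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        for name, arr in (("toe_offs", self.toe_offs), ("heel_strikes", self.heel_strikes)):
            if len(arr) > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def __len__(self) -> int:
        return len(self.toe_offs) + len(self.heel_strikes)

    def merged(self) -> tuple[np.ndarray, list[str]]:
        """All events in chronological order with their labels."""
        times = np.concatenate([self.toe_offs, self.heel_strikes])
        labels = ["TO"] * len(self.toe_offs) + ["HS"] * len(self.heel_strikes)
        order = np.argsort(times, kind="stable")
        return times[order], [labels[i] for i in order]

    def alternates(self) -> bool:
        _, labels = self.merged()
        return all(a != b for a, b in zip(labels, labels[1:]))


def detect_gait_events(
    gyro_y,
    resultant,
    sample_rate: float,
    threshold: float = 50.0,
    invert_y: bool = True,
    prominence_frac: float = 0.2,
) -> GaitEvents:
    """Classify gyro-y peaks into toe-offs and heel strikes.

    Both inputs must already be low-pass filtered.  Candidate events are
    prominence-selected peaks of the (optionally inverted) gyro-y; within
    each cycle delimited by upward threshold crossings of the resultant,
    the peak nearest the crossing is labelled toe-off and the remaining
    peaks heel strikes.  Alternation is enforced by dropping the
    lower-prominence member of any same-label adjacent pair.  Returns
    empty events when no full cycle is present.
    """
    y = np.asarray(gyro_y, dtype=float)
    r = np.asarray(resultant, dtype=float)
    if y.shape != r.shape:
        raise ValueError("gyro_y and resultant must have equal lengths")
    if invert_y:
        y = -y
    empty = GaitEvents(np.empty(0), np.empty(0))
    if len(y) < 3 or not np.any(np.abs(y) > 0):
        return empty
    prominence = prominence_frac * np.max(np.abs(y))
    peaks, props = sps.find_peaks(y, prominence=prominence)
    crossings = np.flatnonzero((r[:-1] < threshold) & (r[1:] >= threshold)) + 1
    if len(peaks) < 2 or len(crossings) < 1:
        return empty
    prominences = props["prominences"]
    # cycles run from each upward crossing to the next; within a cycle the
    # peak nearest the crossing is the toe-off and the peak at the far
    # boundary the heel strike (peaks in between are discarded)
    events = []  # (sample index, label, prominence)
    bounds = np.append(crossings, len(y))
    lo = 0
    for j, c in enumerate(crossings):
        hi = bounds[j + 1]
        in_cycle = np.flatnonzero((peaks >= lo) & (peaks < hi))
        lo = hi
        if len(in_cycle) == 0:
            continue
        nearest = in_cycle[np.argmin(np.abs(peaks[in_cycle] - c))]
        events.append((int(peaks[nearest]), "TO", float(prominences[nearest])))
        last = in_cycle[-1]
        if last != nearest:
            events.append((int(peaks[last]), "HS", float(prominences[last])))
    events.sort()
    # enforce alternation: drop the lower-prominence peak of same-label pairs
    kept: list[tuple[int, str, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    tos = np.array([e[0] for e in kept if e[1] == "TO"], dtype=float) / sample_rate
    hss = np.array([e[0] for e in kept if e[1] == "HS"], dtype=float) / sample_rate
    return GaitEvents(tos, hss)


def detect_events_from_series(
    series: ImuSeries,
    filter_spec: FilterSpec = FilterSpec(),
    threshold: float = 50.0,
    invert_y: bool | None = None,
    prominence_frac: float = 0.2,
) -> GaitEvents:
    """Filter gyro-y and the gyroscope resultant of a series, then detect
    events.  ``invert_y`` defaults to True for shoe-site signals."""
    if invert_y is None:
        invert_y = series.site == "shoe"
    y = lowpass(series.channel("gy"), series.sample_rate, filter_spec)
    r = lowpass(series.gyro_resultant(), series.sample_rate, filter_spec)
    events = detect_gait_events(y, r, series.sample_rate, threshold, invert_y,
                                prominence_frac)
    return GaitEvents(events.toe_offs + series.start_time,
                      events.heel_strikes + series.start_time)


@dataclass
class GaitParameters:
    """Mean temporal gait parameters in seconds."""

    mean_stride_s: float
    mean_gait_s: float
    mean_stance_s: float
    mean_swing_s: float
    n_strides: int

    ROW_LABELS = (
        "mean stride duration [s]",
        "mean gait duration [s]",
        "mean stance duration [s]",
        "mean swing duration [s]",
    )

    def as_rows(self) -> list[tuple[str, float]]:
        return list(
            zip(
                self.ROW_LABELS,
                (self.mean_stride_s, self.mean_gait_s, self.mean_stance_s, self.mean_swing_s),
            )
        )


def compute_gait_parameters(events: GaitEvents) -> GaitParameters:
    """Stride = successive heel strikes; gait = half stride (single-foot
    step estimate); stance = heel strike to next toe-off; swing = toe-off
    to next heel strike.  Means pool all complete cycles."""
    hs = events.heel_strikes
    to = events.toe_offs
    if len(hs) < 2:
        raise ValueError("need at least 2 heel strikes to compute gait parameters")
    strides = np.diff(hs)
    mean_stride = float(np.mean(strides))
    stances = []
    for h in hs:
        nxt = to[to > h]
        if len(nxt):
            stances.append(nxt[0] - h)
    swings = []
    for t in to:
        nxt = hs[hs > t]
        if len(nxt):
            swings.append(nxt[0] - t)
    return GaitParameters(
        mean_stride_s=mean_stride,
        mean_gait_s=mean_stride / 2.0,
        mean_stance_s=float(np.mean(stances)) if stances else float("nan"),
        mean_swing_s=float(np.mean(swings)) if swings else float("nan"),
        n_strides=len(strides),
    )


@dataclass
class GaitComparison:
    """Absolute reference-vs-test differences in milliseconds."""

    stride_ms: float
    gait_ms: float
    stance_ms: float
    swing_ms: float

    def as_rows(self) -> list[tuple[str, float]]:
        return list(
            zip(
                GaitParameters.ROW_LABELS,
                (self.stride_ms, self.gait_ms, self.stance_ms, self.swing_ms),
            )
        )


def compare_gait_parameters(reference: GaitParameters, test: GaitParameters) -> GaitComparison:
    """|reference - test| per parameter, in milliseconds."""
    return GaitComparison(
        stride_ms=abs(reference.mean_stride_s - test.mean_stride_s) * 1000.0,
        gait_ms=abs(reference.mean_gait_s - test.mean_gait_s) * 1000.0,
        stance_ms=abs(reference.mean_stance_s - test.mean_stance_s) * 1000.0,
        swing_ms=abs(reference.mean_swing_s - test.mean_swing_s) * 1000.0,
    )
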
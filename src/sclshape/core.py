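"""Core containers shared across the pipeline.

A session recording holds one participant's full skin-conductance trace
(microsiemens, nominally 40 Hz) together with event markers that delimit,
per imagery scene, a pre-script baseline, a guided (script playback) window
and a self-produced imagery window. Downstream stages work on per-window
:class:`Segment` / :class:`NormalizedSegment` views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedEventsError

# Phase labels
BASELINE = "baseline"
GUIDED = "guided"
SELF = "self"
PHASES = (BASELINE, GUIDED, SELF)
MODALITIES = (GUIDED, SELF)

# Expertise tiers: recreational-to-national vs. international level
TIERS_1_3 = "tiers1_3"
TIER_4 = "tier4"
TIERS = (TIERS_1_3, TIER_4)

# Six analysis scenes plus the squat test scene (used only for the power check)
ANALYSIS_SCENES = (
    "training_session",
    "home_venue",
    "successful_competition",
    "fitness_activity",
    "slow_start",
    "championship_start",
)
TEST_SCENE = "squats"
ALL_SCENES = ANALYSIS_SCENES + (TEST_SCENE,)

FEATURE_NAMES = ("nSCL_mean", "nSCL_var", "nSCL_slope", "nSCL_nfsc")

#: Column schema of the long-format feature table (one row per
#: person x scene x modality) emitted by :func:`sclshape.features.feature_table`.
FEATURE_COLUMNS = ("person", "tier", "scene", "phase") + FEATURE_NAMES


@dataclass(frozen=True)
class Event:
    """One marker window: ``scene`` x ``phase`` spanning [start, end) seconds."""

    scene: str
    phase: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise MalformedEventsError(
                f"event {self.scene}/{self.phase}: end {self.end} <= start {self.start}"
            )


@dataclass
class Recording:
    """One participant's full SCL session.

    Attributes
    ----------
    person : str
        Participant identifier.
    tier : str
        Expertise tier label, ``"tiers1_3"`` or ``"tier4"``.
    t : ndarray
        Sample times in seconds, strictly increasing.
    scl : ndarray
        Skin conductance in microsiemens, same length as ``t``.
    events : list of Event
        Scene/phase windows; must lie inside the recording span and,
        within a scene, be ordered baseline -> guided -> self.
    fs : float
        Nominal sampling rate in Hz.
    """

    person: str
    tier: str
    t: np.ndarray
    scl: np.ndarray
    events: list[Event] = field(default_factory=list)
    fs: float = 40.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.scl = np.asarray(self.scl, dtype=float)
        if self.t.shape != self.scl.shape:
            raise ValueError("t and scl must have the same shape")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise MalformedEventsError(f"recording {self.person}: times not strictly increasing")

    @property
    def scenes(self) -> list[str]:
        seen: list[str] = []
        for ev in self.events:
            if ev.scene not in seen:
                seen.append(ev.scene)
        return seen

    def window(self, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (t, scl) samples with start <= t < end."""
        m = (self.t >= start) & (self.t < end)
        return self.t[m], self.scl[m]


@dataclass
class Segment:
    """A scene x phase window of raw SCL for one participant."""

    person: str
    tier: str
    scene: str
    phase: str
    t: np.ndarray
    scl: np.ndarray
    n_removed: int = 0  # samples dropped by IQR cleaning

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.scl = np.asarray(self.scl, dtype=float)

    @property
    def duration(self) -> float:
        if self.t.size == 0:
            return 0.0
        return float(self.t[-1] - self.t[0])

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.person, self.scene, self.phase)


@dataclass
class NormalizedSegment(Segment):
    """A cleaned segment with nSCL (percent change from the pre-script baseline).

    ``nscl[i] = 100 * (scl[i] - baseline) / baseline``; the raw microsiemens
    samples are kept alongside because fluctuation counting applies its
    amplitude threshold on the raw scale.
    """

    baseline: float = float("nan")
    nscl: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.nscl is not None:
            self.nscl = np.asarray(self.nscl, dtype=float)
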
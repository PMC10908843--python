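"""Raw SCL cleaning and baseline normalization.

Cleaning uses the 1.5 IQR rule: points outside
[Q1 - 1.5*(Q3 - Q1), Q3 + 1.5*(Q3 - Q1)] are removed (one pass, quartiles by
linear interpolation, computed on the input). Cleaning is applied per
scene x phase segment, because the slow tonic drift would otherwise let a
whole-session fence remove valid samples.

Normalization expresses each script window as percent change (nSCL) from the
mean of the cleaned 5 s window immediately preceding script onset:
nSCL_t = 100 * (x_t - b) / b.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import BASELINE, GUIDED, PHASES, Event, NormalizedSegment, Recording, Segment
from .errors import (
    DegenerateSegmentError,
    InvalidBaselineError,
    MalformedEventsError,
    MissingBaselineError,
    TooShortError,
)


def iqr_fence(samples: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """Lower/upper Tukey fence at ``k`` IQR, quartiles by linear interpolation."""
    q1, q3 = np.percentile(samples, [25.0, 75.0])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def iqr_clean(samples: np.ndarray, k: float = 1.5) -> tuple[np.ndarray, np.ndarray, int]:
    """Remove points outside the 1.5 IQR fence.

    Parameters
    ----------
    samples : array of conductance values (uS), length >= 4.
    k : fence multiplier (1.5 by convention).

    Returns
    -------
    (cleaned, keep_mask, n_removed). The mask lets callers retain the
    original time stamps of surviving points (no interpolation is done).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise TooShortError(f"iqr_clean needs >= 4 samples, got {x.size}")
    lo, hi = iqr_fence(x, k)
    keep = (x >= lo) & (x <= hi)
    if not keep.any():
        raise DegenerateSegmentError("IQR cleaning removed every sample")
    return x[keep], keep, int(x.size - keep.sum())


def segment_session(recording: Recording) -> tuple[list[Segment], list[str]]:
    """Cut a recording into raw per-scene baseline/guided/self segments.

    Returns (segments, warnings). Scenes missing a marker for some phase are
    reported in the warnings list and the missing segment skipped. Overlapping
    or out-of-order markers raise :class:`MalformedEventsError`.
    """
    if not recording.events:
        raise MalformedEventsError(f"recording {recording.person} has no event markers")
    t_lo, t_hi = recording.t[0], recording.t[-1] + 1.0 / recording.fs
    prev_end = -np.inf
    for ev in recording.events:
        if ev.start < prev_end - 1e-9:
            raise MalformedEventsError(
                f"{recording.person}: marker {ev.scene}/{ev.phase} overlaps the previous one"
            )
        if ev.start < t_lo - 1e-9 or ev.end > t_hi + 1e-9:
            raise MalformedEventsError(
                f"{recording.person}: marker {ev.scene}/{ev.phase} outside recording span"
            )
        prev_end = ev.end

    by_scene: dict[str, dict[str, Event]] = {}
    for ev in recording.events:
        if ev.phase not in PHASES:
            raise MalformedEventsError(f"unknown phase label {ev.phase!r}")
        by_scene.setdefault(ev.scene, {})[ev.phase] = ev

    segments: list[Segment] = []
    notes: list[str] = []
    for scene, phases in by_scene.items():
        for phase in PHASES:
            if phase not in phases:
                notes.append(f"{recording.person}/{scene}: missing {phase} marker, skipped")
                continue
            ev = phases[phase]
            tt, xx = recording.window(ev.start, ev.end)
            segments.append(
                Segment(person=recording.person, tier=recording.tier,
                        scene=scene, phase=phase, t=tt, scl=xx)
            )
    return segments, notes


def clean_segment(seg: Segment, k: float = 1.5) -> Segment:
    """Apply the IQR fence to one segment, keeping surviving time stamps."""
    cleaned, keep, n_removed = iqr_clean(seg.scl, k)
    return Segment(person=seg.person, tier=seg.tier, scene=seg.scene, phase=seg.phase,
                   t=seg.t[keep], scl=cleaned, n_removed=n_removed)


def baseline_mean(recording: Recording, scene: str, baseline_dur: float = 5.0,
                  clean: bool = True) -> float:
    """Mean cleaned conductance in the ``baseline_dur`` window before script onset.

    The window ends at the guided (script) marker's start. Raises
    :class:`MissingBaselineError` if no samples survive, and
    :class:`InvalidBaselineError` if the mean is non-positive.
    """
    onset = None
    for ev in recording.events:
        if ev.scene == scene and ev.phase == GUIDED:
            onset = ev.start
            break
    if onset is None:
        raise MissingBaselineError(f"{recording.person}/{scene}: no guided marker")
    tt, xx = recording.window(onset - baseline_dur, onset)
    if xx.size == 0:
        raise MissingBaselineError(f"{recording.person}/{scene}: empty baseline window")
    if clean and xx.size >= 4:
        xx, _, _ = iqr_clean(xx)
    b = float(np.mean(xx))
    if b <= 0:
        raise InvalidBaselineError(f"{recording.person}/{scene}: baseline {b} <= 0")
    return b


def normalize(segment: Segment, b: float) -> NormalizedSegment:
    """Express a segment as percent change from baseline ``b`` (uS).

    Raw samples are retained alongside nSCL so fluctuation counting can apply
    its microsiemens threshold on the original scale.
    """
    if b <= 0:
        raise InvalidBaselineError(f"baseline must be positive, got {b}")
    nscl = 100.0 * (segment.scl - b) / b
    return NormalizedSegment(
        person=segment.person, tier=segment.tier, scene=segment.scene,
        phase=segment.phase, t=segment.t, scl=segment.scl,
        n_removed=segment.n_removed, baseline=float(b), nscl=nscl,
    )


def preprocess_recording(
    recording: Recording, k: float = 1.5, baseline_dur: float = 5.0
) -> tuple[list[NormalizedSegment], list[str]]:
    """Segment, clean and normalize one recording.

    Returns the guided/self normalized segments (all scenes, including the
    test scene; downstream analyses select the six analysis scenes) and a
    list of warnings about skipped segments.
    """
    segments, notes = segment_session(recording)
    out: list[NormalizedSegment] = []
    baselines: dict[str, float] = {}
    for seg in segments:
        if seg.phase == BASELINE:
            continue
        try:
            cleaned = clean_segment(seg, k)
        except (TooShortError, DegenerateSegmentError) as exc:
            notes.append(f"{seg.person}/{seg.scene}/{seg.phase}: {exc}")
            continue
        if seg.scene not in baselines:
            try:
                baselines[seg.scene] = baseline_mean(recording, seg.scene, baseline_dur)
            except (MissingBaselineError, InvalidBaselineError) as exc:
                notes.append(str(exc))
                baselines[seg.scene] = float("nan")
        b = baselines[seg.scene]
        if not np.isfinite(b):
            continue
        out.append(normalize(cleaned, b))
    return out, notes


def preprocess_cohort(
    recordings: list[Recording], k: float = 1.5, baseline_dur: float = 5.0,
    warn: bool = False,
) -> tuple[list[NormalizedSegment], list[str]]:
    """Preprocess every recording; optionally surface warnings via ``warnings``."""
    all_segments: list[NormalizedSegment] = []
    all_notes: list[str] = []
    for rec in recordings:
        segs, notes = preprocess_recording(rec, k, baseline_dur)
        all_segments.extend(segs)
        all_notes.extend(notes)
    if warn:
        for note in all_notes:
            warnings.warn(note, stacklevel=2)
    return all_segments, all_notes
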
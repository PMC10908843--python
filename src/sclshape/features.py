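"""The four nSCL indices per (person, scene, modality).

nSCL_mean   mean percent change from the pre-script baseline
nSCL_var    sample (n-1) variance of nSCL, percent^2
nSCL_slope  ordinary-least-squares slope of nSCL on time, percent/s
nSCL_nfsc   skin-conductance fluctuations per minute

A fluctuation is a local maximum whose trough-to-peak rise is at least
0.02 uS with a mean rise slope below 2 uS/s (steeper rises are treated as
artifacts). Counting operates on the cleaned raw microsiemens series --
the amplitude threshold is meaningless on the percent scale -- after a 0.5 s
moving-average smoothing that suppresses quantization micro-peaks; the
count is normalized to events per minute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .core import (
    ANALYSIS_SCENES,
    FEATURE_COLUMNS,
    MODALITIES,
    NormalizedSegment,
    Segment,
)
from .errors import DuplicateRecordError, TooShortError


def compute_basic_features(seg: NormalizedSegment) -> tuple[float, float, float]:
    """(mean, sample variance, OLS slope) of a normalized segment's nSCL."""
    y = np.asarray(seg.nscl, dtype=float)
    if y.size < 3:
        raise TooShortError(f"{seg.key}: need >= 3 samples, got {y.size}")
    t = np.asarray(seg.t, dtype=float)
    slope = float(np.polyfit(t - t[0], y, 1)[0])
    return float(y.mean()), float(y.var(ddof=1)), slope


def count_fluctuations(
    seg: Segment,
    fs: float,
    min_amp: float = 0.02,
    max_rise_slope: float = 2.0,
    smooth_window: float = 0.5,
) -> float:
    """Fluctuations per minute in a raw-scale (uS) segment.

    Parameters
    ----------
    seg : segment whose ``scl`` is in microsiemens.
    fs : nominal sampling rate, Hz.
    min_amp : minimum trough-to-peak rise, uS (default 0.02).
    max_rise_slope : artifact cutoff on the mean rise slope, uS/s (default 2).
    smooth_window : moving-average width in seconds applied before peak
        finding (default 0.5 s).
    """
    if seg.duration < 5.0:
        raise TooShortError(f"{seg.key}: segment of {seg.duration:.2f}s < 5s")
    x = np.asarray(seg.scl, dtype=float)
    t = np.asarray(seg.t, dtype=float)
    win = max(int(round(smooth_window * fs)), 1)
    smooth = uniform_filter1d(x, size=win, mode="nearest") if win > 1 else x
    peaks, _ = find_peaks(smooth)
    count = 0
    prev_peak = 0
    for pk in peaks:
        trough_rel = int(np.argmin(smooth[prev_peak : pk + 1]))
        trough = prev_peak + trough_rel
        rise = smooth[pk] - smooth[trough]
        dt = t[pk] - t[trough]
        if rise >= min_amp and dt > 0 and rise / dt < max_rise_slope:
            count += 1
        prev_peak = pk
    duration = seg.duration + 1.0 / fs  # inclusive sample span
    return count / (duration / 60.0)


def feature_table(
    segments: list[NormalizedSegment],
    fs: float = 40.0,
    scenes: tuple[str, ...] = ANALYSIS_SCENES,
    min_amp: float = 0.02,
    max_rise_slope: float = 2.0,
    smooth_window: float = 0.5,
    nfsc_on_raw: bool = True,
) -> pd.DataFrame:
    """One feature row per (person, scene, modality) over the given scenes.

    With the default cohort (30 persons x 6 analysis scenes) this yields 180
    guided and 180 self-produced records. Duplicate (person, scene, phase)
    segments raise :class:`DuplicateRecordError`.
    """
    rows = []
    seen: set[tuple[str, str, str]] = set()
    for seg in segments:
        if seg.phase not in MODALITIES or seg.scene not in scenes:
            continue
        if seg.key in seen:
            raise DuplicateRecordError(f"duplicate segment {seg.key}")
        seen.add(seg.key)
        mean, var, slope = compute_basic_features(seg)
        target = seg if nfsc_on_raw else _as_percent_segment(seg)
        amp = min_amp if nfsc_on_raw else 100.0 * min_amp / seg.baseline
        slope_cut = max_rise_slope if nfsc_on_raw else 100.0 * max_rise_slope / seg.baseline
        nfsc = count_fluctuations(target, fs, amp, slope_cut, smooth_window)
        rows.append({
            "person": seg.person, "tier": seg.tier, "scene": seg.scene,
            "phase": seg.phase, "nSCL_mean": mean, "nSCL_var": var,
            "nSCL_slope": slope, "nSCL_nfsc": nfsc,
        })
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    return df.sort_values(["person", "scene", "phase"], ignore_index=True)


def _as_percent_segment(seg: NormalizedSegment) -> Segment:
    # Counting on the normalized scale: thresholds are rescaled by the caller.
    return Segment(person=seg.person, tier=seg.tier, scene=seg.scene,
                   phase=seg.phase, t=seg.t, scl=seg.nscl)
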
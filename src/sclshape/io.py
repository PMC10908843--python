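"""File formats: long-format recordings CSV, TSV tables and matrices.

The canonical exchange format for recordings is a long CSV with columns
``person_id,tier,scene,phase,t,scl_uS`` -- device-agnostic, diff-able and
exactly what the simulator writes. Event markers are implicit: each
contiguous (person, scene, phase) block spans one marker window.

All tabular outputs are TSV; writers prepend a ``# config_hash=...`` comment
line when given one, so every artifact declares the configuration that
produced it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PHASES, Event, Recording
from .errors import ParseError
from .similarity import SimilarityMatrix

RECORDING_COLUMNS = ["person_id", "tier", "scene", "phase", "t", "scl_uS"]


def write_recordings(recordings: list[Recording], path) -> None:
    """Write a cohort to the long-format CSV."""
    frames = []
    for rec in recordings:
        scene_of = np.empty(rec.t.size, dtype=object)
        phase_of = np.empty(rec.t.size, dtype=object)
        for ev in rec.events:
            m = (rec.t >= ev.start) & (rec.t < ev.end)
            scene_of[m] = ev.scene
            phase_of[m] = ev.phase
        keep = scene_of != None  # noqa: E711 - object array comparison
        frames.append(pd.DataFrame({
            "person_id": rec.person, "tier": rec.tier, "scene": scene_of[keep],
            "phase": phase_of[keep], "t": rec.t[keep], "scl_uS": rec.scl[keep],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_recordings(path) -> list[Recording]:
    """Read and validate a long-format recordings CSV.

    Raises :class:`ParseError` naming the offending row for missing columns,
    non-monotone time within a person, negative conductance, or unknown
    phase labels.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty input file") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")

    neg = df.index[df["scl_uS"] <= 0]
    if len(neg):
        raise ParseError(f"{path}: non-positive conductance at data row {neg[0] + 2}")
    bad_phase = df.index[~df["phase"].isin(PHASES)]
    if len(bad_phase):
        raise ParseError(
            f"{path}: unknown phase {df.loc[bad_phase[0], 'phase']!r} "
            f"at data row {bad_phase[0] + 2}"
        )

    recordings = []
    for person, grp in df.groupby("person_id", sort=True):
        t = grp["t"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = grp.index[int(np.argmax(dt <= 0)) + 1] + 2
            raise ParseError(f"{path}: non-monotone time for {person} at data row {row}")
        fs = 1.0 / np.median(dt) if t.size > 1 else 40.0
        events = []
        block = (grp["scene"].ne(grp["scene"].shift())
                 | grp["phase"].ne(grp["phase"].shift())).cumsum()
        for _, sub in grp.groupby(block):
            t0, t1 = float(sub["t"].iloc[0]), float(sub["t"].iloc[-1])
            events.append(Event(str(sub["scene"].iloc[0]), str(sub["phase"].iloc[0]),
                                t0, t1 + 1.0 / fs))
        tiers = grp["tier"].unique()
        if len(tiers) != 1:
            raise ParseError(f"{path}: conflicting tier labels for {person}")
        recordings.append(Recording(person=str(person), tier=str(tiers[0]), t=t,
                                    scl=grp["scl_uS"].to_numpy(dtype=float),
                                    events=events, fs=float(round(fs, 6))))
    return recordings


def write_table(df: pd.DataFrame, path, config_hash: str = "") -> None:
    """TSV table writer with an optional config-hash header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_hash:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_similarity(matrix: SimilarityMatrix, path, config_hash: str = "") -> None:
    """Similarity matrix as TSV with person ids as header row/column."""
    df = pd.DataFrame(matrix.sim, index=matrix.persons, columns=matrix.persons)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_hash:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, sep="\t", index_label="person")
    path.write_text(buf.getvalue())


def read_similarity(path, condition: str = "") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    sim = df.to_numpy(dtype=float)
    return SimilarityMatrix(persons=[str(p) for p in df.columns], condition=condition,
                            sim=sim, dist=np.full_like(sim, np.nan))


def similarity_edges(matrix: SimilarityMatrix, threshold: float = 60.0) -> pd.DataFrame:
    """Edge list of pairs whose similarity meets the display threshold."""
    rows = []
    n = len(matrix.persons)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.sim[i, j] >= threshold:
                rows.append({"person_a": matrix.persons[i],
                             "person_b": matrix.persons[j],
                             "similarity": matrix.sim[i, j]})
    return pd.DataFrame(rows, columns=["person_a", "person_b", "similarity"])


SEGMENT_COLUMNS = ["person", "tier", "scene", "phase", "t", "nscl", "scl_raw", "baseline"]


def write_segments(segments, path, config_hash: str = "") -> None:
    """Tidy per-sample nSCL segment CSV (one row per retained sample)."""
    frames = []
    for seg in segments:
        frames.append(pd.DataFrame({
            "person": seg.person, "tier": seg.tier, "scene": seg.scene,
            "phase": seg.phase, "t": seg.t, "nscl": seg.nscl,
            "scl_raw": seg.scl, "baseline": seg.baseline,
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=SEGMENT_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_hash:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False, float_format="%.6f")
    path.write_text(buf.getvalue())


def read_segments(path):
    """Read the tidy segment CSV back into NormalizedSegment objects."""
    from .core import NormalizedSegment

    df = pd.read_csv(path, comment="#")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    for (person, scene, phase), grp in df.groupby(["person", "scene", "phase"], sort=True):
        out.append(NormalizedSegment(
            person=str(person), tier=str(grp["tier"].iloc[0]), scene=str(scene),
            phase=str(phase), t=grp["t"].to_numpy(float),
            scl=grp["scl_raw"].to_numpy(float),
            baseline=float(grp["baseline"].iloc[0]),
            nscl=grp["nscl"].to_numpy(float)))
    return out
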
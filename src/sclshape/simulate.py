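"""Synthetic electrodermal-activity (EDA) session generator.

Produces seeded, ground-truth-annotated multi-participant skin-conductance
sessions with the statistical structure the downstream analysis assumes:

* a slow tonic level per person (2-15 uS) with a per-segment linear drift,
  drawn from modality- and tier-specific normal distributions (negative on
  average: habituation),
* superimposed phasic skin-conductance responses (SCRs) as peak-normalized
  biexponential (Bateman) kernels, event times Poisson per segment,
  amplitudes lognormal (well above the 0.02 uS counting threshold),
* white measurement noise, and a small positive conductance floor.

Instructional-modality effects (self-produced imagery: steeper negative
drift, more heterogeneous drift -> lower mean nSCL and higher variance;
higher SCR rate -> more fluctuations) and expertise-tier effects (tier 4:
steeper but more consistent drift, fewer SCRs -> lower variance, fewer
fluctuations, mutually more similar signal shapes) are injected purely as
parameter shifts, so the full pipeline can be validated by recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ALL_SCENES,
    ANALYSIS_SCENES,
    BASELINE,
    GUIDED,
    SELF,
    TEST_SCENE,
    TIER_4,
    TIERS_1_3,
    Event,
    Recording,
)
from .errors import InvalidParameterError

ParamMap = dict[tuple[str, str], tuple[float, float]]
RateMap = dict[tuple[str, str], float]

#: Per-(phase, tier) tonic drift: (mean, sd) across segments, expressed in
#: percent of the person's tonic base per second. Drift is specified on the
#: normalized scale (and converted to uS/s per person) because the modality
#: and tier effects are characterized on nSCL: guided ~ -0.024 %/s for
#: tiers 1-3 vs. -0.068 %/s for tier 4, self-produced ~ -0.044 and
#: -0.054 %/s. Tier 4 drifts are steeper but less dispersed; self-produced
#: drift is more dispersed than its slope sd alone would suggest so that
#: within-window nSCL variance is higher in self-produced imagery.
DRIFT_DEFAULTS: ParamMap = {
    (BASELINE, TIERS_1_3): (0.0, 0.0),
    (BASELINE, TIER_4): (0.0, 0.0),
    (GUIDED, TIERS_1_3): (-0.024, 0.112),
    (GUIDED, TIER_4): (-0.068, 0.046),
    (SELF, TIERS_1_3): (-0.044, 0.091),
    (SELF, TIER_4): (-0.054, 0.053),
}

#: Per-(phase, tier) SCR event rate, events per minute. Self-produced imagery
#: roughly doubles the rate; tier 4 fluctuates less in either modality.
SCR_RATE_DEFAULTS: RateMap = {
    (BASELINE, TIERS_1_3): 1.2,
    (BASELINE, TIER_4): 0.8,
    (GUIDED, TIERS_1_3): 1.5,
    (GUIDED, TIER_4): 0.9,
    (SELF, TIERS_1_3): 3.3,
    (SELF, TIER_4): 2.3,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: 30 participants (30% tier 4),
    seven scenes (six analysis scenes + the squat test scene), 40 Hz
    sampling, 5 s pre-script baseline, 45 s guided script, 60 s
    self-produced imagery.
    """

    n_participants: int = 30
    tier4_fraction: float = 0.3
    n_scenes: int = 7
    fs: float = 40.0
    baseline_dur: float = 5.0
    guided_dur: float = 45.0
    self_dur: float = 60.0
    tonic_base_range: tuple[float, float] = (2.0, 15.0)
    drift: ParamMap = field(default_factory=lambda: dict(DRIFT_DEFAULTS))
    scr_rate: RateMap = field(default_factory=lambda: dict(SCR_RATE_DEFAULTS))
    scr_amp: tuple[float, float] = (math.log(0.12), 0.5)  # lognormal (mu, sigma), uS
    max_rise_drift: float = 0.10  # cap on positive tonic drift, %/s of base
    tau_rise: float = 0.7
    tau_decay: float = 3.0
    noise_sd: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidParameterError("n_participants must be >= 1")
        if not 0.0 <= self.tier4_fraction <= 1.0:
            raise InvalidParameterError("tier4_fraction must be in [0, 1]")
        if not 1 <= self.n_scenes <= len(ALL_SCENES):
            raise InvalidParameterError(f"n_scenes must be in [1, {len(ALL_SCENES)}]")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        for name in ("baseline_dur", "guided_dur", "self_dur"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not self.tau_decay > self.tau_rise > 0:
            raise InvalidParameterError("need tau_decay > tau_rise > 0")
        if any(r < 0 for r in self.scr_rate.values()):
            raise InvalidParameterError("scr_rate values must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        lo, hi = self.tonic_base_range
        if not 0 < lo <= hi:
            raise InvalidParameterError("tonic_base_range must satisfy 0 < lo <= hi")

    @property
    def scenes(self) -> tuple[str, ...]:
        """Scene labels: up to six analysis scenes, then the test scene."""
        if self.n_scenes <= len(ANALYSIS_SCENES):
            return ANALYSIS_SCENES[: self.n_scenes]
        return ANALYSIS_SCENES + (TEST_SCENE,)

    def phase_durations(self) -> dict[str, float]:
        return {BASELINE: self.baseline_dur, GUIDED: self.guided_dur, SELF: self.self_dur}


def null_modality_config(base: SimConfig | None = None, **kwargs) -> SimConfig:
    """A configuration with no modality effect: self-produced drift and SCR
    rate are set equal to the guided values per tier. Used for type-I-error
    (null) studies of the paired modality comparisons."""
    cfg = base if base is not None else SimConfig(**kwargs)
    drift = dict(cfg.drift)
    rate = dict(cfg.scr_rate)
    for tier in (TIERS_1_3, TIER_4):
        drift[(SELF, tier)] = drift[(GUIDED, tier)]
        rate[(SELF, tier)] = rate[(GUIDED, tier)]
    return replace(cfg, drift=drift, scr_rate=rate)


def scr_kernel(
    t: np.ndarray | float, amp: float, tau_rise: float, tau_decay: float
) -> np.ndarray | float:
    """Peak-normalized biexponential (Bateman) SCR kernel.

    k(t) = amp * (exp(-t/tau_decay) - exp(-t/tau_rise)) / peak, so the kernel
    is 0 at t = 0, rises to a single interior maximum exactly equal to
    ``amp`` at t* = tau_rise*tau_decay/(tau_decay - tau_rise) *
    ln(tau_decay/tau_rise), and decays exponentially back toward 0.
    """
    if not tau_decay > tau_rise > 0:
        raise InvalidParameterError("need tau_decay > tau_rise > 0")
    if amp <= 0:
        raise InvalidParameterError("amp must be positive")
    t_arr = np.asarray(t, dtype=float)
    t_star = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise)
    out = np.where(
        t_arr >= 0,
        amp * (np.exp(-np.maximum(t_arr, 0.0) / tau_decay)
               - np.exp(-np.maximum(t_arr, 0.0) / tau_rise)) / peak,
        0.0,
    )
    if np.isscalar(t) or (isinstance(t, np.ndarray) and t.ndim == 0):
        return float(out)
    return out


@dataclass
class GroundTruth:
    """Generator-side truth for every simulated segment.

    ``segments``: person, tier, scene, phase, start, end, drift (uS/s).
    ``events``: person, scene, phase, time (s, inside its segment), amp (uS).
    """

    segments: pd.DataFrame
    events: pd.DataFrame

    def to_tsv(self, segments_path, events_path) -> None:
        self.segments.to_csv(segments_path, sep="\t", index=False)
        self.events.to_csv(events_path, sep="\t", index=False)


def _tier_labels(cfg: SimConfig) -> list[str]:
    n4 = int(round(cfg.n_participants * cfg.tier4_fraction))
    return [TIERS_1_3] * (cfg.n_participants - n4) + [TIER_4] * n4


def simulate_session(config: SimConfig) -> tuple[list[Recording], GroundTruth]:
    """Generate the full cohort: one Recording per participant plus truth.

    Each recording concatenates, per scene, contiguous baseline -> guided ->
    self-produced windows. The signal is tonic base + piecewise-linear drift
    + sum of SCR kernels + white noise, floored at 0.05 uS. Deterministic for
    a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    durs = config.phase_durations()
    scene_dur = sum(durs.values())
    scenes = config.scenes
    total_dur = scene_dur * len(scenes)
    n_total = int(round(total_dur * fs))
    t = np.arange(n_total) / fs
    tiers = _tier_labels(config)

    recordings: list[Recording] = []
    seg_rows: list[dict] = []
    ev_rows: list[dict] = []
    for p in range(config.n_participants):
        person = f"P{p + 1:02d}"
        tier = tiers[p]
        base = rng.uniform(*config.tonic_base_range)
        signal = np.zeros(n_total)
        events: list[Event] = []
        level = base
        cursor = 0.0
        for scene in scenes:
            for phase in (BASELINE, GUIDED, SELF):
                dur = durs[phase]
                start, end = cursor, cursor + dur
                i0, i1 = int(round(start * fs)), int(round(end * fs))
                mu, sd = config.drift[(phase, tier)]
                pct_drift = rng.normal(mu, sd) if sd > 0 else mu
                # Sustained steep tonic rises are not physiological (habituation
                # dominates); cap the positive tail so ramps cannot mimic SCRs.
                pct_drift = min(pct_drift, config.max_rise_drift)
                drift = pct_drift * base / 100.0  # percent of tonic base -> uS/s
                local_t = t[i0:i1] - start
                signal[i0:i1] = level + drift * local_t
                level = level + drift * dur

                rate = config.scr_rate[(phase, tier)]
                n_ev = rng.poisson(rate * dur / 60.0)
                ev_t = np.sort(rng.uniform(start, end, size=n_ev))
                ev_a = rng.lognormal(config.scr_amp[0], config.scr_amp[1], size=n_ev)
                for te, amp in zip(ev_t, ev_a):
                    j0 = int(np.ceil(te * fs))
                    if j0 < n_total:
                        signal[j0:] += scr_kernel(
                            t[j0:] - te, amp, config.tau_rise, config.tau_decay
                        )
                    ev_rows.append(
                        {"person": person, "scene": scene, "phase": phase,
                         "time": float(te), "amp": float(amp)}
                    )
                seg_rows.append(
                    {"person": person, "tier": tier, "scene": scene, "phase": phase,
                     "start": start, "end": end, "drift": float(drift)}
                )
                events.append(Event(scene, phase, start, end))
                cursor = end
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=n_total)
        signal = np.maximum(signal, 0.05)
        recordings.append(
            Recording(person=person, tier=tier, t=t.copy(), scl=signal,
                      events=events, fs=fs)
        )

    truth = GroundTruth(
        segments=pd.DataFrame(seg_rows),
        events=pd.DataFrame(
            ev_rows, columns=["person", "scene", "phase", "time", "amp"]
        ),
    )
    return recordings, truth


def _default_templates(length: int) -> np.ndarray:
    """Three smooth, mutually dissimilar shape templates on [0, 1]."""
    x = np.linspace(0.0, 1.0, length)
    ramp = -x + 0.25 * np.sin(2 * np.pi * x)
    bumps = np.exp(-((x - 0.3) / 0.08) ** 2) + 0.8 * np.exp(-((x - 0.7) / 0.10) ** 2)
    wave = np.sin(3 * np.pi * x) + 0.5 * x
    tpl = np.stack([ramp, bumps, wave])
    tpl -= tpl.mean(axis=1, keepdims=True)
    tpl /= tpl.std(axis=1, keepdims=True)
    return tpl


def simulate_shape_groups(
    n_per_group: int = 15,
    n_groups: int = 2,
    length: int = 240,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Series drawn from ``n_groups`` distinct shape templates plus noise.

    Each series gets a random positive amplitude and offset (removed by
    z-normalization downstream), so only shape carries group identity.
    Returns (series array of shape (n_groups*n_per_group, length), labels).
    """
    if not 1 <= n_groups <= 3:
        raise InvalidParameterError("n_groups must be 1..3")
    rng = np.random.default_rng(seed)
    templates = _default_templates(length)[:n_groups]
    series, labels = [], []
    for g in range(n_groups):
        for _ in range(n_per_group):
            amp = rng.uniform(0.5, 2.0)
            off = rng.uniform(-1.0, 1.0)
            series.append(amp * templates[g] + off + rng.normal(0, noise_sd, length))
            labels.append(g)
    return np.asarray(series), np.asarray(labels)
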
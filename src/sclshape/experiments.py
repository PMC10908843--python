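"""Seeded simulation studies validating the pipeline end to end.

These are the package's own calibration/recovery experiments: they generate
cohorts with the simulator's configured effects (or their null versions),
push them through the full preprocessing -> feature -> test chain, and
measure how reliably the configured structure is recovered. Both the test
suite and ``scripts/acceptance.py`` run them.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .clustering import cluster_conditions, compare_k, consensus, kshape
from .core import GUIDED, SELF, TIER_4
from .features import feature_table
from .preprocess import preprocess_cohort
from .similarity import condition_series, group_similarity, modality_similarity
from .simulate import SimConfig, null_modality_config, simulate_session, simulate_shape_groups
from .stats import wilcoxon_signed_rank

RECOVERY_FEATURES = ("nSCL_mean", "nSCL_var", "nSCL_nfsc", "nSCL_slope")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _paired(records, feature):
    wide = records.pivot_table(index=["person", "scene"], columns="phase",
                               values=feature, aggfunc="first")
    wide = wide.dropna(subset=[GUIDED, SELF])
    return wide[GUIDED].to_numpy(), wide[SELF].to_numpy()


def modality_recovery_study(
    n_replicates: int = 100,
    seed: int = 0,
    null_modality: bool = False,
    alpha: float = 0.05,
    features: tuple[str, ...] = RECOVERY_FEATURES,
) -> dict[str, dict[str, float]]:
    """Replicate the paired guided-vs-self Wilcoxon tests over seeded cohorts.

    Each replicate simulates the default 30-person, six-scene cohort (40 Hz),
    runs cleaning/normalization/feature extraction, and tests each feature.
    With ``null_modality=True`` the self-produced drift and SCR rate are set
    equal to the guided ones, so rejections estimate the type-I error.

    Returns per feature: rejection rate at ``alpha`` and the fraction of
    replicates whose median paired difference has the configured direction
    (self lower for nSCL_mean; self higher for nSCL_var and nSCL_nfsc).
    """
    seeds = _child_seeds(seed, n_replicates)
    reject = {f: 0 for f in features}
    direction = {f: 0 for f in features}
    for s in seeds:
        cfg = SimConfig(n_scenes=6, seed=int(s))
        if null_modality:
            cfg = null_modality_config(cfg)
        recordings, _ = simulate_session(cfg)
        segments, _ = preprocess_cohort(recordings)
        feats = feature_table(segments, fs=cfg.fs)
        for f in features:
            guided, self_ = _paired(feats, f)
            rep = wilcoxon_signed_rank(guided, self_, feature=f)
            if rep.p < alpha:
                reject[f] += 1
            med = np.median(self_ - guided)
            expected_sign = -1.0 if f in ("nSCL_mean", "nSCL_slope") else 1.0
            if med * expected_sign > 0:
                direction[f] += 1
    n = float(n_replicates)
    return {f: {"rejection_rate": reject[f] / n, "direction_rate": direction[f] / n}
            for f in features}


def tier_similarity_study(seed: int = 0) -> dict[str, dict[str, float]]:
    """Scene-averaged DTW similarity within tiers, per modality, one cohort."""
    cfg = SimConfig(n_scenes=6, seed=seed)
    recordings, _ = simulate_session(cfg)
    tiers = {rec.person: rec.tier for rec in recordings}
    segments, _ = preprocess_cohort(recordings)
    mats = modality_similarity(segments, fs_in=cfg.fs)
    return {mod: {k: float(v) for k, v in group_similarity(mat, tiers).items()}
            for mod, mat in mats.items()}


def shape_recovery_study(
    seed: int = 0, n_per_group: int = 15, noise_sd: float = 0.05
) -> dict[str, float]:
    """k-Shape on two shape-template groups: adjusted Rand index at k=2 and
    the mean-silhouette ordering across k = 2, 3, 4."""
    X, labels = simulate_shape_groups(n_per_group=n_per_group, n_groups=2,
                                      noise_sd=noise_sd, seed=seed)
    pred, _, _, _, _ = kshape(X, k=2, seed=seed, n_init=10)
    ari = adjusted_rand_score(labels, pred)
    conditions = {("templates", "guided"): {f"S{i:02d}": X[i] for i in range(len(X))}}
    sil = compare_k(conditions, ks=(2, 3, 4), seed=seed, n_init=10)
    return {"ari_k2": float(ari), "silhouette_k2": sil[2],
            "silhouette_k3": sil[3], "silhouette_k4": sil[4]}


def consensus_enrichment_study(
    seed: int = 0, k: int = 2, n_init: int = 10, threshold: int = 10
) -> dict[str, float]:
    """12-condition consensus on a simulated cohort: are connectivity-graph
    edges enriched for tier-4 pairs relative to random pairing?"""
    cfg = SimConfig(n_scenes=6, seed=seed)
    recordings, _ = simulate_session(cfg)
    tiers = {rec.person: rec.tier for rec in recordings}
    segments, _ = preprocess_cohort(recordings)
    conditions = condition_series(segments, fs_in=cfg.fs)
    results = cluster_conditions(conditions, k=k, seed=seed, n_init=n_init)
    graph = consensus(results, threshold=threshold, tiers=tiers)
    edges = graph.edges
    n4 = sum(1 for t in tiers.values() if t == TIER_4)
    n = len(tiers)
    expected = (n4 * (n4 - 1) / 2) / (n * (n - 1) / 2)
    if edges:
        both4 = sum(1 for a, b, _ in edges
                    if tiers[a] == TIER_4 and tiers[b] == TIER_4)
        observed = both4 / len(edges)
    else:
        observed = float("nan")
    mean_sil = float(np.mean([r.sil_mean for r in results if r.sil_mean is not None]))
    return {"n_edges": float(len(edges)), "tier4_edge_fraction": observed,
            "random_tier4_fraction": expected, "n_conditions": float(len(results)),
            "mean_silhouette_k2": mean_sil}
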
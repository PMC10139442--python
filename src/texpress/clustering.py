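"""Expression-profile clustering of interspecific DEGs.

Profiles are per-gene Z-scored mean TPM over the four species x stage
conditions; k-means (Lloyd's algorithm, k-means++ seeding, best of several
restarts) is run for each k and the number of clusters is chosen by the gap
statistic with the one-standard-error rule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Condition order of profile vectors.
CONDITIONS = (("A", "L4"), ("A", "YA"), ("B", "L4"), ("B", "YA"))


@dataclass
class GapResult:
    k_values: List[int]
    log_w: List[float]
    e_log_w: List[float]
    gap: List[float]
    se: List[float]
    k_chosen: int


def select_clusterable_genes(
    tpm: pd.DataFrame, deg_results: Sequence
) -> Set[str]:
    """DEGs in >= 1 stage with TPM mean > 1 and variance > 1 across samples."""
    degs = {r.pair_id for r in deg_results if r.direction != "ns"}
    mean = tpm.mean(axis=1)
    var = tpm.var(axis=1, ddof=1)
    ok = tpm.index[(mean > 1) & (var > 1)]
    return degs & set(ok)


def zscore_profiles(
    tpm: pd.DataFrame,
    kept: Set[str],
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene Z-score (ddof=1) of the four condition-mean TPM values."""
    cond_means = {}
    for species, stage in CONDITIONS:
        cols = meta.index[
            (meta["species"] == species) & (meta["stage"] == stage)
        ]
        if len(cols) == 0:
            raise ValueError(f"no samples for condition {(species, stage)}")
        cond_means[f"{species}-{stage}"] = tpm[cols].mean(axis=1)
    prof = pd.DataFrame(cond_means).loc[sorted(kept)]
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        log.info("excluding %d zero-variance profile(s)", int(zero.sum()))
        prof = prof[~zero]
        mu = mu[~zero]
        sd = sd[~zero]
    return prof.sub(mu, axis=0).div(sd, axis=0)


def _kmeanspp_init(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[i] = x[rng.integers(n)]
            continue
        probs = d2 / total
        centers[i] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((x - centers[i]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    x: np.ndarray,
    centers: np.ndarray,
    rng: np.random.Generator,
    max_iter: int = 100,
) -> Tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    labels = np.zeros(x.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for j in range(k):
            mask = new_labels == j
            if mask.any():
                centers[j] = x[mask].mean(axis=0)
            else:  # empty cluster: re-seed at the farthest point
                centers[j] = x[d2.min(axis=1).argmax()]
                new_labels[d2.min(axis=1).argmax()] = j
        if (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels
    d2 = ((x - centers[labels]) ** 2).sum(axis=1)
    return labels, centers, float(d2.sum())


def kmeans(
    profiles: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts Lloyd's k-means; returns (labels, centers, within-SS)."""
    x = np.asarray(profiles, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError("k exceeds number of profiles")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers = _kmeanspp_init(x, k, rng)
        labels, centers, wss = _lloyd(x, centers, rng)
        if best is None or wss < best[2]:
            best = (labels, centers, wss)
    return best


def _log_w(x: np.ndarray, k: int, n_restarts: int, seed: int) -> float:
    _, _, wss = kmeans(x, k, n_restarts=n_restarts, seed=seed)
    return float(np.log(max(wss, 1e-300)))


def gap_statistic(
    profiles: np.ndarray,
    kmax: int = 20,
    b: int = 100,
    seed: int = 0,
    n_restarts: int = 5,
) -> GapResult:
    """Gap statistic over k = 1..kmax with uniform-box reference data.

    ``gap(k) = mean_b log W_b(k) - log W(k)``;
    ``s_k = sd_b(log W_b) * sqrt(1 + 1/B)``; the chosen k is the smallest
    with ``gap(k) >= gap(k+1) - s_{k+1}``, else kmax.
    """
    if b < 10:
        raise ValueError("need at least 10 reference datasets")
    x = np.asarray(profiles, dtype=float)
    n = x.shape[0]
    if kmax > n:
        log.warning("kmax %d > n %d; clamping", kmax, n)
        kmax = n
    rng = np.random.default_rng(seed)
    lo = x.min(axis=0)
    hi = x.max(axis=0)

    ks = list(range(1, kmax + 1))
    log_w = [_log_w(x, k, n_restarts, seed + k) for k in ks]
    ref_log_w = np.empty((b, kmax))
    for i in range(b):
        ref = rng.uniform(lo, hi, size=x.shape)
        for j, k in enumerate(ks):
            ref_log_w[i, j] = _log_w(ref, k, n_restarts, seed + 1000 + i * kmax + k)
    e_log_w = ref_log_w.mean(axis=0)
    gap = e_log_w - np.array(log_w)
    se = ref_log_w.std(axis=0, ddof=1) * np.sqrt(1 + 1.0 / b)

    k_chosen = kmax
    for j in range(kmax - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            k_chosen = ks[j]
            break
    return GapResult(
        k_values=ks,
        log_w=list(map(float, log_w)),
        e_log_w=list(map(float, e_log_w)),
        gap=list(map(float, gap)),
        se=list(map(float, se)),
        k_chosen=k_chosen,
    )


def cluster_degs(
    profiles: pd.DataFrame,
    kmax: int = 20,
    b: int = 100,
    seed: int = 0,
    n_restarts: int = 10,
    k: Optional[int] = None,
) -> Tuple[Dict[str, int], GapResult]:
    """Choose k by the gap statistic (unless given) and assign clusters (1-based)."""
    x = profiles.to_numpy(dtype=float)
    gap = gap_statistic(x, kmax=kmax, b=b, seed=seed, n_restarts=max(3, n_restarts // 2))
    k_use = k if k is not None else gap.k_chosen
    labels, _, _ = kmeans(x, k_use, n_restarts=n_restarts, seed=seed)
    assignments = {g: int(l) + 1 for g, l in zip(profiles.index, labels)}
    return assignments, gap
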
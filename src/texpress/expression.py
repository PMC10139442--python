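"""Cross-species expression normalization and differential expression.

The pipeline per developmental stage: counts are corrected by the mean
total exonic length of each ortholog pair, genes below 1 corrected-CPM in
every sample are dropped, libraries are scaled by trimmed-mean-of-M
(TMM) factors, a common negative-binomial dispersion is estimated by
method of moments, and each gene is tested with a conditional NB exact
test; BH correction is applied within the stage.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .association import bh_adjust
from .models import OrthologPair

log = logging.getLogger(__name__)


@dataclass
class DEResult:
    pair_id: str
    stage: str
    logFC: float
    logCPM: float
    p: float
    q: float
    direction: str  # higher_in_A | higher_in_B | ns


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float

    def __post_init__(self):
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


def length_correct(
    counts: pd.DataFrame, pairs: Sequence[OrthologPair]
) -> pd.DataFrame:
    """Counts per kilobase of the pair's mean exonic length.

    ``corrected[g, s] = counts[g, s] * 1000 / mean_len(g)``.  Rows are keyed
    by the species-A gene id of each pair.
    """
    mean_len = {p.gene_a: p.mean_len for p in pairs}
    missing = [g for g in counts.index if g not in mean_len]
    if missing:
        raise ValueError(f"no ortholog pair for gene(s): {missing[:10]}")
    lens = np.array([mean_len[g] for g in counts.index], dtype=float)
    return counts.div(lens, axis=0) * 1000.0


def corrected_cpm(corrected: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column so it sums to one million."""
    sums = corrected.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero sample column(s): {zero}")
    return corrected.div(sums, axis=1) * 1e6


def filter_low_expression(corrected: pd.DataFrame) -> Set[str]:
    """Genes with corrected-CPM >= 1 in at least one sample."""
    cpm = corrected_cpm(corrected)
    keep = (cpm >= 1.0).any(axis=1)
    return set(corrected.index[keep])


def _choose_reference(mat: pd.DataFrame) -> str:
    cpm = mat.div(mat.sum(axis=0), axis=1) * 1e6
    uq = cpm.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    mat: pd.DataFrame,
    reference: Optional[str] = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Per-sample effective scale factors (library size x TMM), geomean 1.

    The composition factor for each sample is the weighted trimmed mean of
    per-gene log2 ratios (M) versus the reference sample, trimming the
    top/bottom 30% by M and 5% by average log intensity (A); weights are the
    inverse binomial variance approximation.  Genes with a zero in either
    sample are excluded.  The returned factor multiplies the composition
    factor by the library size, then rescales all factors to geometric
    mean 1, so a doubled library doubles its factor.
    """
    if mat.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = mat.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if reference is None:
        reference = _choose_reference(mat)
    yr = mat[reference].to_numpy(dtype=float)
    nr = lib[reference]

    comp = {}
    for s in mat.columns:
        if s == reference:
            comp[s] = 1.0
            continue
        ys = mat[s].to_numpy(dtype=float)
        ns = lib[s]
        ok = (ys > 0) & (yr > 0)
        if ok.sum() < 10:
            log.warning(
                "TMM: only %d usable genes for sample %s; unit factor",
                int(ok.sum()), s,
            )
            comp[s] = 1.0
            continue
        y1, y2 = ys[ok], yr[ok]
        m = np.log2((y1 / ns) / (y2 / nr))
        a = 0.5 * np.log2((y1 / ns) * (y2 / nr))
        w = (ns - y1) / (ns * y1) + (nr - y2) / (nr * y2)
        n = m.size
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            comp[s] = 1.0
        else:
            comp[s] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    eff = lib * pd.Series(comp)[mat.columns]
    eff = eff / np.exp(np.log(eff).mean())
    return eff


def estimate_common_dispersion(
    mat: pd.DataFrame,
    groups: Mapping[str, str],
    factors: Optional[pd.Series] = None,
) -> DispersionEstimate:
    """Pooled method-of-moments NB dispersion.

    Counts are first equalized by the effective factors; within each group,
    ``E[s^2 - m] = phi * m^2``, so phi is estimated by the ratio of the
    pooled sums ``sum(s^2 - m) / sum(m^2)`` over genes and groups, clamped
    at zero.  (A per-gene median of the same statistic is badly biased low
    at 4 replicates, which makes the downstream exact test anti-conservative.)
    """
    labels = pd.Series({s: groups[s] for s in mat.columns})
    for g, cols in labels.groupby(labels).groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has a single replicate")
    adj = mat if factors is None else mat.div(factors[mat.columns], axis=1)

    num = 0.0
    denom = 0.0
    for g in labels.unique():
        cols = labels.index[labels == g]
        x = adj[cols].to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        ok = m > 0
        num += float((v[ok] - m[ok]).sum())
        denom += float((m[ok] ** 2).sum())
    if denom == 0:
        return DispersionEstimate(0.0)
    return DispersionEstimate(max(num / denom, 0.0))


def _nb_logpmf(y: np.ndarray, size: float, mean: float) -> np.ndarray:
    if size <= 0 or mean <= 0:
        raise ValueError("size and mean must be positive")
    lp = size * math.log(size / (size + mean))
    return (
        gammaln(y + size)
        - gammaln(size)
        - gammaln(y + 1)
        + lp
        + y * math.log(mean / (size + mean))
    )


def _conditional_split_pvalue(
    ta: int, t: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided exact p for observing group-A total ``ta`` of ``t``.

    Conditions on the total pseudo-count; the probability of each split is
    the product of the two group-sum NB pmfs (binomial split when phi = 0),
    and the p-value sums probabilities <= the observed one.
    """
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if phi == 0:
        logp = (
            gammaln(t + 1)
            - gammaln(y + 1)
            - gammaln(t - y + 1)
            + y * math.log(n_a / (n_a + n_b))
            + (t - y) * math.log(n_b / (n_a + n_b))
        )
    else:
        mu = t / (n_a + n_b)
        logp = _nb_logpmf(y, n_a / phi, n_a * mu) + _nb_logpmf(
            y[::-1], n_b / phi, n_b * mu
        )
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[ta]
    return float(min(probs[probs <= p_obs * (1 + 1e-7)].sum(), 1.0))


def nb_exact_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    phi: float,
    factors: Optional[Sequence[float]] = None,
) -> float:
    """Exact two-sided NB test for one gene (group A vs group B).

    ``factors`` are per-sample effective library factors (A samples then B
    samples); counts are scaled to the geometric-mean pseudo-library before
    conditioning on the rounded total.
    """
    ya = np.asarray(counts_a, dtype=float)
    yb = np.asarray(counts_b, dtype=float)
    if (ya < 0).any() or (yb < 0).any():
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    y = np.concatenate([ya, yb])
    if factors is not None:
        f = np.asarray(factors, dtype=float)
        if f.shape != y.shape:
            raise ValueError("factors length mismatch")
        y = y / f * np.exp(np.mean(np.log(f)))
    ta = int(round(y[: ya.size].sum()))
    tb = int(round(y[ya.size:].sum()))
    return _conditional_split_pvalue(ta, ta + tb, ya.size, yb.size, phi)


def _exact_test_pvalues(
    ta: np.ndarray, tb: np.ndarray, n_a: int, n_b: int, phi: float
) -> np.ndarray:
    """Vectorized conditional exact test over genes.

    Splits of each gene's total are laid out in one flat array (segment
    g holds y = 0..t_g), so work scales with the sum of totals rather
    than n_genes x max(total).
    """
    ta = ta.astype(np.int64)
    tb = tb.astype(np.int64)
    t = ta + tb
    n = t.size
    if n == 0:
        return np.empty(0)
    seg_len = t + 1
    starts = np.concatenate([[0], np.cumsum(seg_len)[:-1]])
    total = int(seg_len.sum())
    gene = np.repeat(np.arange(n), seg_len)
    y = np.arange(total) - starts[gene]
    ty = t[gene] - y

    frac_a = n_a / (n_a + n_b)
    if phi == 0:
        logp = (
            gammaln(t[gene] + 1.0)
            - gammaln(y + 1.0)
            - gammaln(ty + 1.0)
            + y * math.log(frac_a)
            + ty * math.log(1 - frac_a)
        )
    else:
        ra = n_a / phi
        rb = n_b / phi
        mu = t / (n_a + n_b)  # per-sample mean under the null
        with np.errstate(divide="ignore"):
            la = np.log(n_a * mu) - np.log(ra + n_a * mu)
            lb = np.log(n_b * mu) - np.log(rb + n_b * mu)
        logp = (
            gammaln(y + ra)
            - gammaln(y + 1.0)
            + gammaln(ty + rb)
            - gammaln(ty + 1.0)
            + y * np.where(np.isfinite(la[gene]), la[gene], 0.0)
            + ty * np.where(np.isfinite(lb[gene]), lb[gene], 0.0)
        )
    # per-segment normalization without building a padded matrix
    seg_max = np.maximum.reduceat(logp, starts)
    probs = np.exp(logp - seg_max[gene])
    seg_sum = np.add.reduceat(probs, starts)
    probs /= seg_sum[gene]
    p_obs = probs[starts + ta]
    mask = probs <= p_obs[gene] * (1 + 1e-7)
    p = np.add.reduceat(np.where(mask, probs, 0.0), starts)
    p[t == 0] = 1.0
    return np.minimum(p, 1.0)


def call_degs(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: Sequence[OrthologPair],
    stage: str,
    alpha: float = 1e-5,
) -> List[DEResult]:
    """Full per-stage DE chain; see module docstring.

    ``meta`` is indexed by sample id with ``species`` and ``stage`` columns.
    Genes removed by the low-expression filter (evaluated on all samples)
    are appended with direction ``ns``.
    """
    if stage not in set(meta["stage"]):
        raise ValueError(f"stage {stage!r} absent from metadata")
    corrected = length_correct(counts, pairs)
    kept = filter_low_expression(corrected)
    kept_idx = [g for g in counts.index if g in kept]

    stage_samples = meta.index[meta["stage"] == stage]
    sub = corrected.loc[kept_idx, stage_samples]
    species = meta.loc[stage_samples, "species"]
    a_cols = list(stage_samples[species == "A"])
    b_cols = list(stage_samples[species == "B"])
    if not a_cols or not b_cols:
        raise ValueError(f"stage {stage!r} lacks samples for one species")

    factors = tmm_factors(sub)
    phi = estimate_common_dispersion(
        sub, groups=species.to_dict(), factors=factors
    ).phi

    pseudo = sub.div(factors[sub.columns], axis=1)
    ta = np.rint(pseudo[a_cols].sum(axis=1).to_numpy()).astype(np.int64)
    tb = np.rint(pseudo[b_cols].sum(axis=1).to_numpy()).astype(np.int64)
    pvals = _exact_test_pvalues(ta, tb, len(a_cols), len(b_cols), phi)
    qvals = np.array(bh_adjust(pvals))

    n_a, n_b = len(a_cols), len(b_cols)
    logfc = np.log2((ta / n_a + 0.5) / (tb / n_b + 0.5))
    mean_lib = float(np.exp(np.log(sub.sum(axis=0)).mean()))
    logcpm = np.log2(((ta + tb) / (n_a + n_b) + 0.5) / mean_lib * 1e6)

    results = []
    for i, g in enumerate(kept_idx):
        if qvals[i] < alpha:
            direction = "higher_in_A" if logfc[i] > 0 else "higher_in_B"
        else:
            direction = "ns"
        results.append(
            DEResult(
                pair_id=g,
                stage=stage,
                logFC=float(logfc[i]),
                logCPM=float(logcpm[i]),
                p=float(pvals[i]),
                q=float(qvals[i]),
                direction=direction,
            )
        )
    for g in counts.index:
        if g not in kept:
            results.append(
                DEResult(
                    pair_id=g,
                    stage=stage,
                    logFC=math.nan,
                    logCPM=math.nan,
                    p=math.nan,
                    q=math.nan,
                    direction="ns",
                )
            )
    return results


def compute_tpm(
    counts: pd.DataFrame,
    pairs: Sequence[OrthologPair],
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Transcripts per million using each sample's own species' exonic length."""
    len_a = {p.gene_a: p.len_a for p in pairs}
    len_b = {p.gene_a: p.len_b for p in pairs}
    missing = [g for g in counts.index if g not in len_a]
    if missing:
        raise ValueError(f"no lengths for gene(s): {missing[:10]}")
    la = np.array([len_a[g] for g in counts.index], dtype=float)
    lb = np.array([len_b[g] for g in counts.index], dtype=float)
    if (la <= 0).any() or (lb <= 0).any():
        raise ValueError("non-positive exonic length")
    out = {}
    for s in counts.columns:
        lens = la if meta.loc[s, "species"] == "A" else lb
        rate = counts[s].to_numpy(dtype=float) / lens
        total = rate.sum()
        if total == 0:
            raise ValueError(f"all-zero sample column: {s}")
        out[s] = rate / total * 1e6
    return pd.DataFrame(out, index=counts.index)


def pca_variance_explained(
    mat: pd.DataFrame,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Fractions of variance per component and per-sample scores.

    Rows (genes) are centered across samples, then the sample covariance is
    eigen-decomposed via SVD; fractions sum to 1.
    """
    if mat.shape[1] < 2 or mat.T.drop_duplicates().shape[0] < 2:
        raise ValueError("PCA requires at least two distinct samples")
    x = mat.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("zero total variance")
    fractions = var / total
    scores = pd.DataFrame(
        (vt * s[:, None]).T,
        index=mat.columns,
        columns=[f"PC{i+1}" for i in range(len(s))],
    )
    return fractions, scores
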
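"""Group-level statistics of instantaneous F0 contours.

Per-utterance order statistics and moments, pooled z-scoring per gender,
the relative deviation

    zeta = (F0_stroke - F0_control) / F0_control

of a group statistic, one-way ANOVA across groups, and a seeded 2-D t-SNE
embedding of per-speaker (mean, median, sd) F0 vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.manifold import TSNE
from sklearn.preprocessing import StandardScaler

from .zff import F0Contour


@dataclass
class F0Summary:
    """Order statistics and moments of one utterance's per-cycle F0 values."""

    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis: float  # plain (not excess) kurtosis
    n_cycles: int
    utterance_id: str = ""


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    cell_means: list = field(default_factory=list)


def summarize_f0(c: F0Contour, utterance_id: str = "") -> F0Summary:
    """Mean, median, sd (n-1), skewness and plain kurtosis of per-cycle F0."""
    if len(c) == 0:
        raise ValueError("unvoiced utterance: empty F0 contour")
    v = c.values
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    if v.size > 1 and sd > 0:
        skew = float(sps.skew(v, bias=True))
        kurt = float(sps.kurtosis(v, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    return F0Summary(
        mean=float(np.mean(v)), median=float(np.median(v)), sd=sd,
        skewness=skew, kurtosis=kurt, n_cycles=int(v.size), utterance_id=utterance_id,
    )


def zscore_pooled(groups) -> list:
    """Z-score a collection of groups by their pooled mean and sd.

    All groups are pooled (both clinical and control together), the pooled
    sample mean is subtracted and the pooled sample sd (n-1) divides; the
    pooled output then has mean 0 and sd 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if pooled.size < 2:
        raise ValueError("need at least two pooled values")
    mu = float(np.mean(pooled))
    sd = float(np.std(pooled, ddof=1))
    if sd == 0:
        raise ValueError("pooled standard deviation is zero")
    return [(a - mu) / sd for a in arrays]


def relative_deviation(f0_dys: float, f0_ctrl: float) -> float:
    """zeta = (F0_dys - F0_ctrl) / F0_ctrl; positive when the clinical group is higher."""
    if f0_ctrl == 0:
        raise ValueError("control value must be nonzero")
    return (f0_dys - f0_ctrl) / f0_ctrl


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA over two or more groups.

    F = MS_between / MS_within with the usual degrees of freedom; the p-value
    comes from the F distribution.  The p-value is invariant under any affine
    transformation of the data, so raw and z-normalized inputs agree.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = 0.0 if ss_between == 0 else float("inf")
    else:
        f = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(f, df_between, df_within)) if np.isfinite(f) else 0.0
    return AnovaResult(
        f_stat=float(f), p_value=p, df_between=df_between, df_within=df_within,
        cell_means=[float(a.mean()) for a in arrays],
    )


def embed_features(features: np.ndarray, labels, seed: int = 0,
                   perplexity: float = 30.0) -> list:
    """Seeded 2-D t-SNE of standardized per-speaker F0 feature vectors.

    Returns a list of ``(x, y, label)`` tuples, one per speaker.  Perplexity
    is capped below (n - 1) / 3 so small cohorts remain embeddable.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 speakers, got {n}")
    X = StandardScaler().fit_transform(X)
    perp = min(perplexity, max(2.0, (n - 1) / 3.0))
    emb = TSNE(
        n_components=2, random_state=seed, perplexity=perp, init="pca",
        learning_rate="auto",
    ).fit_transform(X)
    return [(float(x), float(y), lab) for (x, y), lab in zip(emb, labels)]
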
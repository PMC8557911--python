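"""Alpha diversity, Bray-Curtis dissimilarity, and one-factor PERMANOVA.

Shannon diversity is reported in nats (H = -sum p ln p, configurable base)
and "Simpson" means the complement form 1 - sum p^2, following the vegan
conventions common in freshwater community work.  Bray-Curtis is computed on
per-sample relative abundances by default because sequencing depths vary.

PERMANOVA here is the one-factor permutational MANOVA on a distance matrix:
pseudo-F from among/within sums of squared dissimilarities, with the null
distribution obtained either by random label permutation (Monte Carlo p with
the +1 correction) or by exhaustive enumeration of all distinct label
arrangements for small designs (exact p).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .source_partition import ASVTable

__all__ = ["DiversityResult", "shannon", "simpson", "alpha_diversity",
           "bray_curtis", "bray_curtis_matrix", "permanova", "PermanovaResult"]


@dataclass(frozen=True)
class DiversityResult:
    shannon: float
    simpson: float
    richness: int


def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample: diversity undefined")
    return x / total


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p ln p over taxa with p > 0 (nats by default)."""
    p = _proportions(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base is not None else h


def simpson(counts) -> float:
    """Simpson diversity in the complement form 1 - sum p^2."""
    p = _proportions(counts)
    return float(1.0 - (p ** 2).sum())


def alpha_diversity(table: ASVTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), Simpson (1 - sum p^2) and observed richness."""
    rows = {}
    for sid in table.sample_ids:
        c = table.counts.loc[sid].to_numpy()
        if c.sum() == 0:
            rows[sid] = {"shannon": np.nan, "simpson": np.nan, "richness": 0}
        else:
            rows[sid] = {"shannon": shannon(c), "simpson": simpson(c),
                         "richness": int((c > 0).sum())}
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(x, y, relative: bool = True) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), on proportions by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for an all-zero sample")
    if relative:
        x, y = x / x.sum(), y / y.sum()
    return float(np.abs(x - y).sum() / (x + y).sum())


def bray_curtis_matrix(table: ASVTable, relative: bool = True) -> pd.DataFrame:
    """Square symmetric Bray-Curtis matrix over all samples (zero diagonal)."""
    data = table.counts.to_numpy(dtype=float)
    if (data.sum(axis=1) == 0).any():
        raise ValueError("all samples need nonzero totals for Bray-Curtis")
    if relative:
        data = data / data.sum(axis=1, keepdims=True)
    dm = squareform(pdist(data, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.counts.index, columns=table.counts.index)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "monte_carlo" or "exhaustive"

    def to_dict(self) -> dict:
        return {"pseudo_f": self.pseudo_f, "p_value": self.p_value,
                "n_permutations": self.n_permutations, "method": self.method}


def _pseudo_f(dm2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-factor pseudo-F from a squared-distance matrix and group codes.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = sum over groups of the
    within-group pairwise d^2 / n_g; F = (SS_among/(a-1)) / (SS_within/(n-a)).
    """
    n = codes.size
    total = dm2.sum() / (2.0 * n)
    within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            within += dm2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    among = total - within
    if within == 0:
        return math.inf
    return (among / (n_groups - 1)) / (within / (n - n_groups))


def permanova(dist: pd.DataFrame, labels, n_permutations: int = 999,
              seed: int | None = None, exhaustive: bool = False) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Parameters
    ----------
    dist : square symmetric DataFrame (or array) of dissimilarities
    labels : per-sample group labels aligned with the matrix order (a Series
        indexed like the matrix is reindexed to it)
    n_permutations : number of random label permutations (ignored when
        ``exhaustive``)
    exhaustive : enumerate all distinct label arrangements; the p-value is the
        exact proportion of arrangements (identity included) whose pseudo-F is
        >= the observed one.

    The Monte Carlo p-value uses the standard correction
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` and is deterministic
    given ``seed``.
    """
    if isinstance(dist, pd.DataFrame):
        if isinstance(labels, pd.Series):
            labels = labels.reindex(dist.index)
            if labels.isna().any():
                raise ValueError("labels missing for some samples in the matrix")
        dm = dist.to_numpy(dtype=float)
    else:
        dm = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    if dm.shape[0] != dm.shape[1] or dm.shape[0] != labels.size:
        raise ValueError("distance matrix and labels are misaligned")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    codes, uniques = pd.factorize(labels)
    n_groups = uniques.size
    counts = np.bincount(codes)
    if n_groups < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")

    dm2 = dm ** 2
    f_obs = _pseudo_f(dm2, codes, n_groups)

    if exhaustive:
        perms = {p for p in itertools.permutations(codes.tolist())}
        hits = sum(_pseudo_f(dm2, np.array(p), n_groups) >= f_obs for p in perms)
        return PermanovaResult(pseudo_f=f_obs, p_value=hits / len(perms),
                               n_permutations=len(perms), method="exhaustive")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _pseudo_f(dm2, rng.permutation(codes), n_groups) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(pseudo_f=f_obs, p_value=p,
                           n_permutations=n_permutations, method="monte_carlo")
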
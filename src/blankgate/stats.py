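"""Ordination and inference: NMDS, one-factor PERMANOVA, Kruskal-Wallis, OLS.

These are the statistics used to validate a blank-derived detection
threshold against community data: a permutational MANOVA (adonis-style)
on a dissimilarity matrix partitions sums of squares between and within
groups; non-metric multidimensional scaling visualises the same matrix;
Kruskal-Wallis and ordinary least squares test whether filtered volume
carries any biomass signal.

All four are implemented here directly (the implementations in scipy /
scikit-bio serve as independent cross-checks in the test suite, never as
the computation).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, rankdata
from sklearn.isotonic import isotonic_regression

__all__ = [
    "OlsResult", "ols_r2",
    "KruskalResult", "kruskal_wallis",
    "PermanovaResult", "permanova",
    "NmdsResult", "nmds", "kruskal_stress",
]


# ---------------------------------------------------------------------------
# Ordinary least squares
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OlsResult:
    r2: float
    slope: float
    intercept: float


def ols_r2(x, y) -> OlsResult:
    """Least-squares line of ``y`` on ``x`` with the coefficient of
    determination R^2 = 1 - SS_res/SS_tot (0 when y is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("x has zero variance; the regression is undefined")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    ss_tot = float(((y - ym) ** 2).sum())
    if ss_tot == 0.0:
        return OlsResult(r2=0.0, slope=slope, intercept=intercept)
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    return OlsResult(r2=1.0 - ss_res / ss_tot, slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# Kruskal-Wallis rank-sum test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalResult:
    H_statistic: float
    df: int
    p_value: float


def kruskal_wallis(values, groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value.

    H = [12 / (N(N+1))] * sum_g n_g (Rbar_g - (N+1)/2)^2, divided by the
    tie correction 1 - sum(t^3 - t) / (N^3 - N).  When every value is
    identical the correction vanishes; H is then defined as 0 with p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be 1-D arrays of equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rankdata(values)  # average ranks for ties
    h = 0.0
    for g in labels:
        mask = groups == g
        n_g = int(mask.sum())
        if n_g == 0:
            raise ValueError(f"empty group {g!r}")
        rbar = ranks[mask].mean()
        h += n_g * (rbar - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - float((counts ** 3 - counts).sum()) / (n ** 3 - n)
    df = len(labels) - 1
    if correction == 0.0:  # all observations identical
        return KruskalResult(H_statistic=0.0, df=df, p_value=1.0)
    h /= correction
    return KruskalResult(H_statistic=float(h), df=df,
                         p_value=float(chi2.sf(h, df)))


# ---------------------------------------------------------------------------
# PERMANOVA (one factor)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r2: float
    p_value: float
    n_permutations: int
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    exhaustive: bool = False


def _align_groups(dist, groups) -> np.ndarray:
    ids = list(getattr(dist, "ids", range(_as_square(dist).shape[0])))
    if isinstance(groups, pd.Series):
        missing = [i for i in ids if i not in groups.index]
        if missing:
            raise ValueError(f"groups missing for samples {missing}")
        return groups.loc[ids].to_numpy()
    groups = np.asarray(groups)
    if groups.shape[0] != len(ids):
        raise ValueError("groups length does not match distance matrix")
    return groups


def _as_square(dist) -> np.ndarray:
    d = getattr(dist, "data", dist)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square distance matrix")
    return d


def ss_decomposition(dist, groups) -> tuple:
    """Distance-based sums of squares (SS_total, SS_within, SS_between).

    SS_total = (1/n) sum_{i<j} d_ij^2 ;
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2 ; between by difference.
    """
    d = _as_square(dist)
    labels = _align_groups(dist, groups)
    n = d.shape[0]
    d2 = d ** 2
    ss_total = float(np.triu(d2, 1).sum()) / n
    ss_within = 0.0
    for g in pd.unique(labels):
        mask = labels == g
        n_g = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += float(np.triu(sub, 1).sum()) / n_g
    return ss_total, ss_within, ss_total - ss_within


def _pseudo_f_many(d2: np.ndarray, label_matrix: np.ndarray,
                   group_codes: np.ndarray, ss_total: float) -> np.ndarray:
    """Pseudo-F for many label vectors at once.

    ``label_matrix`` is (P, n) integer codes; returns an array of P F values.
    Uses z D^2 z^T = 2 * sum_{i<j in g} d_ij^2 for each group indicator z.
    """
    n = d2.shape[0]
    a = len(group_codes)
    ss_within = np.zeros(label_matrix.shape[0])
    for code in group_codes:
        z = (label_matrix == code).astype(float)
        n_g = z.sum(axis=1)
        quad = np.einsum("pi,pi->p", z, z @ d2)
        ss_within += quad / (2.0 * n_g)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dist, groups, n_permutations: int = 999, seed=None,
              exhaustive: bool = False) -> PermanovaResult:
    """One-factor permutational MANOVA (adonis-style) on a distance matrix.

    The p-value uses the (1 + exceedances) / (1 + n_permutations)
    convention for sampled permutations; with ``exhaustive=True`` every
    distinct assignment of the observed labels to samples is enumerated
    and the p-value is the plain exceedance fraction (the observed
    assignment included).
    """
    d = _as_square(dist)
    labels = _align_groups(dist, groups)
    n = d.shape[0]
    uniq = pd.unique(labels)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if a >= n:
        raise ValueError("every sample in its own group leaves no within-group variance")
    code_of = {g: i for i, g in enumerate(uniq)}
    codes = np.array([code_of[g] for g in labels], dtype=np.int64)
    d2 = d ** 2
    ss_total, ss_within, ss_between = ss_decomposition(dist, groups)
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w)

    group_codes = np.arange(a)
    if exhaustive:
        seen = set()
        perms = []
        for p in itertools.permutations(codes):
            if p not in seen:
                seen.add(p)
                perms.append(p)
        label_matrix = np.array(perms, dtype=np.int64)
        f_perm = _pseudo_f_many(d2, label_matrix, group_codes, ss_total)
        p_value = float((f_perm >= f_obs - 1e-12).sum()) / len(f_perm)
        n_perm = len(f_perm)
    else:
        rng = np.random.default_rng(seed)
        n_perm = int(n_permutations)
        label_matrix = np.array([rng.permutation(codes) for _ in range(n_perm)],
                                dtype=np.int64)
        f_perm = _pseudo_f_many(d2, label_matrix, group_codes, ss_total)
        exceed = int((f_perm >= f_obs - 1e-12).sum())
        p_value = (1.0 + exceed) / (1.0 + n_perm)

    return PermanovaResult(
        pseudo_F=float(f_obs), r2=float(ss_between / ss_total), p_value=float(p_value),
        n_permutations=n_perm, ss_between=float(ss_between),
        ss_within=float(ss_within), ss_total=float(ss_total),
        df_between=df_b, df_within=df_w, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples x k, centred
    stress: float              # Kruskal stress-1
    n_starts: int
    converged: bool
    trajectory: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.stress = float(self.stress)


def _disparities(e: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Monotone (PAV) regression of configuration distances on the
    dissimilarity order; ties in d are ordered by current e (primary
    tie handling, so tied dissimilarities need not map to equal fits)."""
    order = np.lexsort((e, d))
    dhat = np.empty_like(e)
    dhat[order] = isotonic_regression(e[order])
    return dhat


def _stress1(e: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((e ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((dhat - e) ** 2).sum() / denom))


def kruskal_stress(dist, coordinates) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix:
    sqrt(sum (dhat - e)^2 / sum e^2) with dhat the monotone regression of
    the configuration distances e on the dissimilarity ranks."""
    d = squareform(_as_square(dist), checks=False)
    x = np.asarray(getattr(coordinates, "values", coordinates), dtype=float)
    e = pdist(x)
    return _stress1(e, _disparities(e, d))


def _guttman_update(x: np.ndarray, dhat: np.ndarray, e: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    ratio = np.zeros_like(e)
    nz = e > 0
    ratio[nz] = dhat[nz] / e[nz]
    b = -squareform(ratio, checks=False)
    np.fill_diagonal(b, -b.sum(axis=1))
    x_new = b @ x / n
    return x_new - x_new.mean(axis=0)


def nmds(dist, k: int = 2, n_starts: int = 20, seed=None,
         max_iter: int = 300, tol: float = 1e-7) -> NmdsResult:
    """Non-metric MDS of a dissimilarity matrix into ``k`` dimensions.

    Each random start alternates monotone (PAV) regression of the
    configuration distances on the dissimilarity ranks with a Guttman
    transform of the configuration, stopping when the stress-1 decrease
    falls below ``tol``; the lowest-stress configuration over
    ``n_starts`` starts is returned, centred at the origin.
    """
    dsq = _as_square(dist)
    ids = list(getattr(dist, "ids", range(dsq.shape[0])))
    n = dsq.shape[0]
    if k >= n:
        raise ValueError(f"k={k} requires at least {k + 1} samples, got {n}")
    d = squareform(dsq, checks=False)
    if d.size and d.max() == d.min():
        warnings.warn("all dissimilarities are equal; NMDS configuration is arbitrary")
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_starts):
        x = rng.standard_normal((n, k))
        x -= x.mean(axis=0)
        prev = np.inf
        traj = []
        converged = False
        for it in range(max_iter):
            e = pdist(x)
            dhat = _disparities(e, d)
            s = _stress1(e, dhat)
            traj.append(s)
            if prev - s < tol:
                converged = prev - s >= 0 or s < tol
                break
            prev = s
            if it < max_iter - 1:  # keep x in sync with traj[-1] on exhaustion
                x = _guttman_update(x, dhat, e)
        if best is None or traj[-1] < best[1]:
            best = (x, traj[-1], traj, converged)

    x, stress, traj, converged = best
    coords = pd.DataFrame(x - x.mean(axis=0), index=ids,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return NmdsResult(coordinates=coords, stress=stress, n_starts=n_starts,
                      converged=converged, trajectory=traj)
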
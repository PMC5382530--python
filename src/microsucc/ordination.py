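"""Ordination and distance-based inference.

Classical PCoA (principal coordinates analysis), PERMANOVA with
permutation or exhaustive-enumeration p-values, a multivariate
homogeneity-of-dispersions test (PERMDISP-style), and the symmetric
Procrustes test used to validate an OTU subset against the full table.

All permutation p-values use the add-one convention
p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm), so p >= 1/(n_perm+1);
ties count in favour of the null (>=, the conservative choice).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates on positive-eigenvalue axes.

    ``eigenvalues`` holds the full spectrum in decreasing order (negative
    eigenvalues are reported, never corrected); ``proportion_explained``
    is computed over positive eigenvalues only.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    method: str = "permutation"  # or "exhaustive"


@dataclass
class DispersionResult:
    F: float
    p_value: float
    group_mean_distance: pd.Series  # group -> mean distance to centroid


@dataclass
class ProcrustesResult:
    m2: float  # residual sum of squares after optimal superposition
    correlation: float  # sqrt(1 - m2)
    p_value: float


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def _gower_spectrum(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the double-centered squared-distance matrix,
    sorted by decreasing eigenvalue."""
    d2 = np.asarray(dist.data, dtype=float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Coordinates are eigenvector * sqrt(eigenvalue) for positive
    eigenvalues (tiny positives below numerical noise are dropped).
    """
    if len(dist.ids) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    eigvals, eigvecs = _gower_spectrum(dist)
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    if not pos.any():  # degenerate: all samples coincide
        coords = np.zeros((len(dist.ids), 1))
        prop = np.zeros(1)
    else:
        coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
        prop = eigvals[pos] / eigvals[pos].sum()
    frame = pd.DataFrame(
        coords, index=list(dist.ids),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, eigvals, prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_labels(
    dist: DistanceMatrix, groups: Mapping[str, str] | pd.Series | Sequence[str]
) -> np.ndarray:
    if isinstance(groups, (pd.Series, Mapping)):
        g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        missing = [s for s in dist.ids if s not in g.index]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        return g.loc[list(dist.ids)].to_numpy()
    labels = np.asarray(list(groups))
    if labels.size != len(dist.ids):
        raise ValueError("group vector length does not match distance matrix")
    return labels


def _n_distinct_assignments(codes: np.ndarray) -> int:
    from math import comb

    remaining = len(codes)
    total = 1
    for c in np.bincount(codes):
        total *= comb(remaining, int(c))
        remaining -= int(c)
    return total


def _distinct_assignments(codes: np.ndarray):
    """Yield every distinct assignment of the label multiset to positions
    (one representative per multiset permutation, no duplicates)."""
    counts = np.bincount(codes)
    n = len(codes)

    def rec(free: tuple[int, ...], group: int, current: np.ndarray):
        if group == len(counts) - 1:
            out = current.copy()
            out[list(free)] = group
            yield out
            return
        for chosen in itertools.combinations(free, int(counts[group])):
            nxt = current.copy()
            nxt[list(chosen)] = group
            rest = tuple(i for i in free if i not in chosen)
            yield from rec(rest, group + 1, nxt)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int, ss_total: float) -> float:
    """Anderson's distance-based pseudo-F from squared distances."""
    n = d2.shape[0]
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)) with sums of squares
    from squared inter-sample distances. ``exhaustive=True`` enumerates
    every distinct assignment of the label multiset to samples (feasible
    for small n) and returns p = #{F >= F_obs} / n_assignments.
    """
    labels = _group_labels(dist, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    n = d2.shape[0]
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    ss_total = d2.sum() / (2.0 * n)
    f_obs = _pseudo_f(d2, codes, k, ss_total)

    ss_within_obs = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss_within_obs += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    r2 = (ss_total - ss_within_obs) / ss_total

    if exhaustive:
        count = 0
        total = 0
        for assign in _distinct_assignments(codes):
            total += 1
            if _pseudo_f(d2, assign, k, ss_total) >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(float(f_obs), float(r2), count / total, total, "exhaustive")

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += _pseudo_f(d2, rng.permutation(codes), k, ss_total) >= f_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, "permutation")


def pairwise_permanova(
    dist: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 999,
    correction: str = "bh",
    seed: int | None = None,
    exhaustive: bool | str = "auto",
) -> pd.DataFrame:
    """PERMANOVA on every pair of groups, BH-adjusted p by default.

    ``exhaustive='auto'`` enumerates all distinct label assignments when a
    pair has few enough of them (<= 5000, e.g. two groups of 5 have 252),
    which gives exact p-values where random permutations would be noisy
    right at small-sample significance floors.
    """
    labels = _group_labels(dist, groups)
    ids = np.asarray(list(dist.ids))
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            mask = np.isin(labels, [uniq[i], uniq[j]])
            sub = dist.filter(ids[mask].tolist())
            _, sub_codes = np.unique(labels[mask], return_inverse=True)
            use_exhaustive = (
                exhaustive is True
                or (exhaustive == "auto"
                    and _n_distinct_assignments(sub_codes) <= 5000)
            )
            res = permanova(
                sub, labels[mask], n_perm=n_perm,
                seed=int(rng.integers(2**31)), exhaustive=use_exhaustive,
            )
            rows.append(
                {"group_a": uniq[i], "group_b": uniq[j], "pseudo_F": res.pseudo_F,
                 "R2": res.R2, "p_value": res.p_value}
            )
    out = pd.DataFrame(rows)
    if correction == "bh":
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    elif correction == "none":
        out["p_adjusted"] = out["p_value"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out


# ---------------------------------------------------------------------------
# Dispersion homogeneity (PERMDISP-style)
# ---------------------------------------------------------------------------

def _dist_to_centroids(
    pos: np.ndarray, neg: np.ndarray, codes: np.ndarray, k: int
) -> np.ndarray:
    """Anderson's distance-to-centroid with negative-eigenvalue correction:
    d^2 = ||x - c||^2 (real axes) - ||y - c~||^2 (imaginary axes), floored at 0."""
    z = np.empty(codes.size)
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        cp = pos[idx].mean(axis=0)
        d2 = ((pos[idx] - cp) ** 2).sum(axis=1)
        if neg.shape[1]:
            cn = neg[idx].mean(axis=0)
            d2 = d2 - ((neg[idx] - cn) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))
    return z


def dispersion_test(
    dist: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Permutation test of homogeneity of multivariate dispersions.

    Samples are embedded by PCoA keeping negative-eigenvalue axes as
    imaginary coordinates; the statistic is the one-way ANOVA F on the
    per-sample distances to group centroids, with a label-permutation
    p-value (centroids recomputed per permutation).
    """
    labels = _group_labels(dist, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")

    eigvals, eigvecs = _gower_spectrum(dist)
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    pos_axes = eigvals > tol
    neg_axes = eigvals < -tol
    pos = eigvecs[:, pos_axes] * np.sqrt(eigvals[pos_axes])
    neg = eigvecs[:, neg_axes] * np.sqrt(-eigvals[neg_axes])

    def f_stat(c: np.ndarray) -> float:
        z = _dist_to_centroids(pos, neg, c, k)
        groups_z = [z[c == g] for g in range(k)]
        if all(np.allclose(gz, gz.mean() if gz.size else 0.0) for gz in groups_z) and \
           np.allclose(z, z.mean()):
            return 0.0
        res = stats.f_oneway(*groups_z)
        return float(res.statistic) if np.isfinite(res.statistic) else 0.0

    f_obs = f_stat(codes)
    z_obs = _dist_to_centroids(pos, neg, codes, k)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += f_stat(rng.permutation(codes)) >= f_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    means = pd.Series(
        {uniq[g]: float(z_obs[codes == g].mean()) for g in range(k)},
        name="mean_distance_to_centroid",
    )
    return DispersionResult(float(f_obs), float(p), means)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    norm = np.sqrt((x ** 2).sum())
    if norm == 0:
        raise ValueError("configuration has zero spread")
    return x / norm


def _procrustes_m2(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Procrustes residual m^2 after centering, unit-scaling and
    optimal rotation (and reflection) of b onto a."""
    a = _standardize(a)
    b = _standardize(b)
    # trace of the optimal alignment = sum of singular values of a^T b
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(max(1.0 - s.sum() ** 2, 0.0))


def _pad_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    width = max(a.shape[1], b.shape[1])
    pad = lambda x: np.hstack([x, np.zeros((x.shape[0], width - x.shape[1]))])
    return pad(a), pad(b)


def procrustes_test(
    coords_a: pd.DataFrame | np.ndarray,
    coords_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes concordance of two ordinations of the same samples.

    correlation = sqrt(1 - m^2); the p-value permutes the row order of the
    second configuration.
    """
    if isinstance(coords_a, pd.DataFrame) and isinstance(coords_b, pd.DataFrame):
        if set(coords_a.index) != set(coords_b.index):
            raise ValueError("the two ordinations cover different samples")
        coords_b = coords_b.loc[coords_a.index]
        a, b = coords_a.to_numpy(float), coords_b.to_numpy(float)
    else:
        a = np.asarray(coords_a, dtype=float)
        b = np.asarray(coords_b, dtype=float)
        if a.shape[0] != b.shape[0]:
            raise ValueError("configurations have different numbers of samples")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    a, b = _pad_columns(a, b)
    m2 = _procrustes_m2(a, b)
    corr = float(np.sqrt(max(1.0 - m2, 0.0)))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_corr = np.sqrt(max(1.0 - _procrustes_m2(a, b[rng.permutation(b.shape[0])]), 0.0))
        count += perm_corr >= corr - 1e-12
    p = (1 + count) / (1 + n_perm)
    return ProcrustesResult(m2, corr, float(p))
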
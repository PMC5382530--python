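"""Successional response groups: filter, relativize, cluster, classify.

Responsive OTUs are those that (i) reach at least 0.5% relative abundance
in at least one sample, (ii) appear in three or more samples, and (iii)
vary significantly with time since disturbance (one-way ANOVA on relative
abundance with time as a categorical factor, disturbed samples only,
p < 0.01). Their per-time mean trajectories are relativized (max-scaled)
and clustered by Euclidean distance with Ward linkage; cutting the tree
at k groups yields the response groups, numbered by time of peak of the
group mean profile (earliest peak = group 1).

Phylum/class-level trajectories are classified into the verbal response
taxonomy (conventional recovery, positive secondary dynamics, stress
tolerant, no change) with Kruskal-Wallis + Nemenyi post-hoc comparisons
against the pre-disturbance time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import CommunityTable, SampleMetadata
from .ordination import ProcrustesResult, pcoa, procrustes_test

CONVENTIONAL = "conventional_recovery"
POSITIVE_SECONDARY = "positive_secondary"
STRESS_TOLERANT = "stress_tolerant"
NO_CHANGE = "no_change"


@dataclass
class ResponseProfile:
    """Per-taxon temporal profile over the disturbed time course."""

    taxon_id: str
    times: tuple[int, ...]
    mean_abundance: np.ndarray  # per-time mean relative abundance (disturbed)
    relativized: np.ndarray  # max-scaled; all-zero taxa stay zero (flagged)
    anova_p: float


@dataclass
class ResponseGroupAssignment:
    """OTU -> response-group mapping plus per-group mean profiles."""

    assignments: pd.Series  # taxon -> group id (1..k)
    group_profiles: pd.DataFrame  # groups x times, mean relativized profile
    group_taxonomy: pd.DataFrame | None = None  # group x taxon-group counts

    @property
    def k(self) -> int:
        return int(self.group_profiles.shape[0])


@dataclass
class KruskalPosthocResult:
    H: float
    p_value: float
    posthoc_p: pd.DataFrame  # groups x groups, all-pairs Nemenyi p
    posthoc_method: str  # "tukey" (studentized range) or "chisq" (ties)


def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples (on relative abundances)."""
    rel = table.relative_abundances().T.to_numpy(dtype=float)  # samples x taxa
    return DistanceMatrix(squareform(pdist(rel, metric="braycurtis")), ids=table.sample_ids)


def _profiles_frame(
    table: CommunityTable, metadata: SampleMetadata
) -> tuple[pd.DataFrame, tuple[int, ...]]:
    """Per-taxon per-time mean relative abundance over disturbed samples."""
    rel = table.relative_abundances()
    times = tuple(
        sorted(
            metadata.frame.loc[
                (metadata.frame["treatment"] == "disturbed")
                & metadata.frame.index.isin(rel.columns),
                "time_days",
            ].unique()
        )
    )
    cols = {}
    for t in times:
        samples = [s for s in metadata.samples_at(t, "disturbed") if s in rel.columns]
        cols[t] = rel[samples].mean(axis=1)
    return pd.DataFrame(cols), times


def filter_responsive_otus(
    table: CommunityTable,
    metadata: SampleMetadata,
    min_relabund: float = 0.005,
    min_samples: int = 3,
    alpha: float = 0.01,
) -> list[ResponseProfile]:
    """Select OTUs passing the abundance / prevalence / ANOVA rules.

    The ANOVA is one-way on per-sample relative abundance with time point
    as a categorical factor, over disturbed samples only; no multiplicity
    correction is applied (the threshold is a per-taxon rule).
    """
    metadata.check_covers(table)
    rel = table.relative_abundances()
    prevalence = (table.counts > 0).sum(axis=1)
    peak = rel.max(axis=1)

    disturbed = [
        s for s in table.sample_ids
        if metadata.frame.loc[s, "treatment"] == "disturbed"
    ]
    time_of = metadata.frame["time_days"]
    times = tuple(sorted({int(time_of[s]) for s in disturbed}))
    groups_by_time = {
        t: [s for s in disturbed if time_of[s] == t] for t in times
    }

    mean_profiles, _ = _profiles_frame(table, metadata)
    profiles: list[ResponseProfile] = []
    for taxon in table.taxon_ids:
        if peak[taxon] < min_relabund or prevalence[taxon] < min_samples:
            continue
        samples_by_time = [rel.loc[taxon, groups_by_time[t]].to_numpy() for t in times]
        if any(len(v) < 2 for v in samples_by_time):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-input warnings -> p=nan
            p = stats.f_oneway(*samples_by_time).pvalue
        if not np.isfinite(p) or p >= alpha:
            continue
        means = mean_profiles.loc[taxon, list(times)].to_numpy(dtype=float)
        profiles.append(
            ResponseProfile(taxon, times, means, _max_scale(means), float(p))
        )
    if not profiles:
        warnings.warn("no OTUs pass the responsiveness filter", stacklevel=2)
    return profiles


def _max_scale(profile: np.ndarray) -> np.ndarray:
    m = profile.max()
    return profile / m if m > 0 else profile.copy()


def relativize_profiles(
    profiles: Sequence[ResponseProfile] | pd.DataFrame, mode: str = "max"
) -> pd.DataFrame:
    """Relativize temporal profiles taxon-wise.

    ``max`` divides each taxon's per-time means by its maximum over time
    (profiles peak at 1); ``sum`` scales rows to sum to 1. All-zero taxa
    are left at zero with a warning. Idempotent for ``max``.
    """
    if isinstance(profiles, pd.DataFrame):
        frame = profiles.astype(float)
    else:
        if not profiles:
            raise ValueError("no profiles to relativize")
        frame = pd.DataFrame(
            {p.taxon_id: p.mean_abundance for p in profiles},
            index=list(profiles[0].times),
        ).T
    denom = frame.max(axis=1) if mode == "max" else frame.sum(axis=1)
    if mode not in ("max", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    zero = denom <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero profiles left unscaled", stacklevel=2)
        denom = denom.mask(zero, 1.0)
    return frame.div(denom, axis=0)


def cluster_response_groups(
    profiles: Sequence[ResponseProfile] | pd.DataFrame,
    k: int = 8,
    taxonomy: pd.DataFrame | None = None,
    taxonomy_rank: str | None = None,
) -> ResponseGroupAssignment:
    """Ward/Euclidean hierarchical clustering of relativized profiles.

    The tree is cut into ``k`` groups, renumbered by the time of peak of
    each group's mean profile (earliest peak = group 1; ties broken by
    peak height, then original cluster order).
    """
    rel = relativize_profiles(profiles) if not isinstance(profiles, pd.DataFrame) else profiles
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > rel.shape[0]:
        raise ValueError(f"k={k} exceeds the {rel.shape[0]} available taxa")
    X = rel.to_numpy(dtype=float)
    if k == rel.shape[0]:
        raw = np.arange(1, k + 1)
    elif k == 1:
        raw = np.ones(rel.shape[0], dtype=int)
    else:
        Z = linkage(X, method="ward", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust")
    times = np.array(rel.columns, dtype=float)
    order_keys = []
    for g in sorted(np.unique(raw)):
        mean_profile = X[raw == g].mean(axis=0)
        peak_idx = int(np.argmax(mean_profile))
        order_keys.append((times[peak_idx], -mean_profile[peak_idx], g))
    relabel = {g: rank + 1 for rank, (_, _, g) in enumerate(sorted(order_keys))}
    groups = pd.Series([relabel[g] for g in raw], index=rel.index, name="group")
    gp = pd.DataFrame(
        {gid: X[groups.to_numpy() == gid].mean(axis=0) for gid in sorted(relabel.values())},
        index=rel.columns,
    ).T
    gp.index.name = "group"
    comp = None
    if taxonomy is not None:
        rank = taxonomy_rank or taxonomy.columns[0]
        lineage = taxonomy.reindex(rel.index)[rank].fillna("unclassified")
        comp = pd.crosstab(groups, lineage)
    return ResponseGroupAssignment(groups, gp, comp)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Nemenyi post-hoc
# ---------------------------------------------------------------------------

def _exact_kruskal_p(samples: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p for Kruskal-Wallis H by exhaustive enumeration
    of distinct group assignments (feasible for small groups only)."""
    import itertools

    sizes = [len(s) for s in samples]
    pooled = np.concatenate(samples)
    codes = np.concatenate([[i] * n for i, n in enumerate(sizes)])
    count = total = 0
    seen: set[tuple] = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        arr = np.array(perm)
        h = stats.kruskal(*[pooled[arr == g] for g in range(len(sizes))]).statistic
        count += h >= h_obs - 1e-12
    return count / total


def kruskal_posthoc(
    values: Sequence[np.ndarray] | Mapping[object, np.ndarray],
    exact: bool = False,
) -> KruskalPosthocResult:
    """Kruskal-Wallis H (tie-corrected) with all-pairs Nemenyi post-hoc.

    Without ties the post-hoc uses the studentized-range approximation
    q = |Ri - Rj| / sqrt(N(N+1)/12 (1/ni + 1/nj)), p = SR.sf(q sqrt(2), k, inf);
    with ties it switches to the chi-square approximation with tie
    correction C = 1 - sum(t^3 - t)/(N^3 - N), stat/C ~ chi2(k-1).
    ``exact=True`` replaces the global chi-square p with the exact
    rank-permutation p (small samples only).
    """
    if isinstance(values, Mapping):
        keys = list(values.keys())
        samples = [np.asarray(values[key], dtype=float) for key in keys]
    else:
        samples = [np.asarray(v, dtype=float) for v in values]
        keys = list(range(len(samples)))
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")

    H, p = stats.kruskal(*samples)
    if exact:
        p = _exact_kruskal_p(samples, float(H))

    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = np.array([len(s) for s in samples])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(samples))]
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    C = 1.0 - float(((tie_counts**3 - tie_counts).sum()) / (n_total**3 - n_total))

    k = len(samples)
    pm = np.ones((k, k))
    base = n_total * (n_total + 1) / 12.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks[i] - mean_ranks[j])
            se2 = base * (1.0 / sizes[i] + 1.0 / sizes[j])
            if has_ties:
                chisq = diff**2 / se2
                pv = float(stats.chi2.sf(chisq / C, k - 1))
            else:
                q = diff / np.sqrt(se2)
                pv = float(stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
            pm[i, j] = pm[j, i] = min(pv, 1.0)
    frame = pd.DataFrame(pm, index=keys, columns=keys)
    return KruskalPosthocResult(
        float(H), float(p), frame, "chisq" if has_ties else "tukey"
    )


def classify_taxon_response(
    disturbed_profile: Mapping[int, float] | pd.Series,
    control_level: float,
    posthoc: KruskalPosthocResult | pd.DataFrame,
    alpha: float = 0.05,
) -> str:
    """Classify a temporal trajectory into the verbal response taxonomy.

    ``disturbed_profile`` maps time (days, including the pre-disturbance
    time 0) to mean relative abundance; ``posthoc`` holds all-pairs
    post-hoc p-values among time points (keys = times). Rules, against
    the pre-disturbance time point, with precedence top to bottom:

    - significantly *above* pre-disturbance at either of the first two
      post-disturbance times -> ``stress_tolerant``;
    - significantly below early AND significantly above the control level
      at some middle/late time -> ``positive_secondary``;
    - significantly below early AND not significantly below at the final
      time -> ``conventional_recovery``;
    - otherwise -> ``no_change``.
    """
    prof = pd.Series(dict(disturbed_profile)) if not isinstance(disturbed_profile, pd.Series) \
        else disturbed_profile
    prof = prof.sort_index()
    times = prof.index.tolist()
    if len(times) < 4:
        raise ValueError("need pre-disturbance plus at least three later time points")
    pm = posthoc.posthoc_p if isinstance(posthoc, KruskalPosthocResult) else posthoc
    missing = [t for t in times if t not in pm.index]
    if missing:
        raise ValueError(f"post-hoc matrix lacks time points {missing}")
    t0, early, late = times[0], times[1:3], times[-1]

    def sig(t: int) -> bool:
        return float(pm.loc[t, t0]) < alpha

    sig_below_early = any(sig(t) and prof[t] < prof[t0] for t in early)
    sig_above_early = any(sig(t) and prof[t] > prof[t0] for t in early)
    below_at_end = sig(late) and prof[late] < prof[t0]
    mid_late = times[3:]
    above_control_later = any(sig(t) and prof[t] > control_level for t in mid_late)

    if sig_above_early:
        return STRESS_TOLERANT
    if sig_below_early and above_control_later:
        return POSITIVE_SECONDARY
    if sig_below_early and not below_at_end:
        return CONVENTIONAL
    return NO_CHANGE


def validate_subset_procrustes(
    full_table: CommunityTable,
    subset_taxa: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Concordance of the responsive-OTU subset with the full table.

    Bray-Curtis matrices of full and subset tables are ordinated by PCoA
    and compared with the symmetric Procrustes permutation test.
    """
    subset_taxa = list(subset_taxa)
    if not subset_taxa:
        raise ValueError("subset is empty")
    full_dm = bray_curtis_matrix(full_table)
    sub_table = full_table.select_taxa(subset_taxa)
    keep = sub_table.counts.sum(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} samples empty under the subset; dropped", stacklevel=2
        )
        sub_table = sub_table.select_samples(keep[keep].index.tolist())
        full_dm = full_dm.filter(sub_table.sample_ids)
    sub_dm = bray_curtis_matrix(sub_table)
    ord_full = pcoa(full_dm)
    ord_sub = pcoa(sub_dm)
    n_axes = min(ord_full.coordinates.shape[1], ord_sub.coordinates.shape[1])
    return procrustes_test(
        ord_full.coordinates.iloc[:, :n_axes],
        ord_sub.coordinates.iloc[:, :n_axes],
        n_perm=n_perm,
        seed=seed,
    )
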
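"""Phylogenetic turnover: betaMNTD, tip-shuffle null model, betaNTI.

betaMNTD (abundance-weighted beta mean nearest taxon distance) measures,
for each taxon in one community, the patristic distance to its closest
relative in the other community, averaged with abundance weights over
both directions:

    betaMNTD(A, B) = 0.5 * [ sum_i f_iA * min_j d(i, j)
                           + sum_j f_jB * min_i d(i, j) ]

with i over taxa present in A, j over taxa present in B, and f the
within-community relative abundances. A taxon present in both communities
finds itself at distance 0.

The null model randomly reassigns taxa to tips of the phylogeny (one
permutation per randomization, abundances travelling with their taxa;
both communities of a pair shuffled together) and recomputes betaMNTD.
betaNTI is the z-score of the observed value against that null:

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null)

|betaNTI| < 2 is consistent with stochastic turnover; betaNTI < -2
indicates homogeneous selection (less turnover than expected by chance)
and betaNTI > +2 variable selection (more turnover than expected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .io import CommunityTable, PhylogeneticTree, SampleMetadata

HOMOGENEOUS = "homogeneous_selection"
STOCHASTIC = "stochastic"
VARIABLE = "variable_selection"

_NULL_CHUNK = 250  # randomizations per vectorized block (memory control)


class DegenerateNullError(ValueError):
    """Raised when a null distribution has zero spread (sd = 0)."""


@dataclass
class NullDistribution:
    """Draws of betaMNTD under the tip-shuffle null, with mean and sd."""

    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("null distribution needs at least one draw")
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=0))

    @property
    def n_rand(self) -> int:
        return int(self.values.size)

    @property
    def is_degenerate(self) -> bool:
        return self.sd == 0.0


@dataclass
class TurnoverResult:
    """betaMNTD / betaNTI for one unordered sample pair."""

    sample_a: str
    sample_b: str
    beta_mntd_obs: float
    null: NullDistribution
    beta_nti: float  # NaN when the null is degenerate
    classification: str | None  # None when degenerate
    time_days: int | None = None
    treatment: str | None = None

    @property
    def is_degenerate(self) -> bool:
        return self.null.is_degenerate


def patristic_distances(tree: PhylogeneticTree) -> DistanceMatrix:
    """Tip-to-tip path-length distances (input to betaMNTD)."""
    return tree.patristic_matrix()


def _as_abund(abund: Mapping[str, float] | pd.Series) -> pd.Series:
    s = abund if isinstance(abund, pd.Series) else pd.Series(dict(abund), dtype=float)
    s = s.astype(float)
    if (s < 0).any():
        raise ValueError("abundances must be nonnegative")
    s = s[s > 0]
    if s.empty:
        raise ValueError("community is empty")
    return s / s.sum()


def _mntd_terms(
    fa: np.ndarray, fb: np.ndarray, dab: np.ndarray, weighted: bool
) -> float:
    """0.5 * (weighted row minima + weighted column minima) of dab."""
    min_a = dab.min(axis=1)
    min_b = dab.min(axis=0)
    if weighted:
        return 0.5 * (float(fa @ min_a) + float(fb @ min_b))
    return 0.5 * (float(min_a.mean()) + float(min_b.mean()))


def beta_mntd(
    abund_a: Mapping[str, float] | pd.Series,
    abund_b: Mapping[str, float] | pd.Series,
    dists: DistanceMatrix,
    weighted: bool = True,
) -> float:
    """betaMNTD between two communities on a patristic distance matrix.

    Abundances are renormalized internally; every taxon with positive
    abundance must be present in ``dists``. Shared taxa contribute
    distance 0 (their nearest relative in the other community is itself).
    """
    a = _as_abund(abund_a)
    b = _as_abund(abund_b)
    idx = {t: i for i, t in enumerate(dists.ids)}
    try:
        ia = np.array([idx[t] for t in a.index])
        ib = np.array([idx[t] for t in b.index])
    except KeyError as exc:
        raise KeyError(f"taxon {exc} not in distance matrix") from exc
    dab = dists.data[np.ix_(ia, ib)]
    return _mntd_terms(a.to_numpy(), b.to_numpy(), dab, weighted)


def null_beta_mntd(
    abund_a: Mapping[str, float] | pd.Series,
    abund_b: Mapping[str, float] | pd.Series,
    tree: PhylogeneticTree | DistanceMatrix,
    n_rand: int = 999,
    seed: int | None = None,
    weighted: bool = True,
    tip_pool: Literal["all", "pair_union"] = "all",
) -> NullDistribution:
    """Null betaMNTD distribution under random taxon-to-tip reassignment.

    Each randomization draws one random injection of the pair's taxa onto
    distinct tips (uniformly over all tips of the phylogeny by default,
    or over the pair's taxon union with ``tip_pool='pair_union'``) and
    recomputes betaMNTD with the same abundance weighting. One shuffle is
    shared by both communities of the pair, so conspecific taxa keep
    contributing distance 0 under the null.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    dists = tree.patristic_matrix() if isinstance(tree, PhylogeneticTree) else tree
    a = _as_abund(abund_a)
    b = _as_abund(abund_b)
    union = list(dict.fromkeys(list(a.index) + list(b.index)))
    k = len(union)
    pos = {t: i for i, t in enumerate(union)}
    sel_a = np.array([pos[t] for t in a.index])
    sel_b = np.array([pos[t] for t in b.index])
    fa, fb = a.to_numpy(), b.to_numpy()

    if tip_pool == "pair_union":
        idx = {t: i for i, t in enumerate(dists.ids)}
        pool = np.array([idx[t] for t in union])
    elif tip_pool == "all":
        pool = np.arange(len(dists.ids))
    else:
        raise ValueError(f"unknown tip_pool {tip_pool!r}")
    if k > pool.size:
        raise ValueError("more taxa than available tips in the shuffle pool")

    D = dists.data
    rng = np.random.default_rng(seed)
    draws = np.empty(n_rand)
    done = 0
    # cap the (block, |A|, |B|) gather at ~4M doubles to bound memory
    max_block = max(1, min(_NULL_CHUNK, int(4e6 / max(len(sel_a) * len(sel_b), 1))))
    while done < n_rand:
        block = min(max_block, n_rand - done)
        # random distinct tip assignments: first k entries of a permutation
        perm = np.argsort(rng.random((block, pool.size)), axis=1)[:, :k]
        tips = pool[perm]  # (block, k)
        ta = tips[:, sel_a]  # (block, |A|)
        tb = tips[:, sel_b]  # (block, |B|)
        dab = D[ta[:, :, None], tb[:, None, :]]  # (block, |A|, |B|)
        min_a = dab.min(axis=2)
        min_b = dab.min(axis=1)
        if weighted:
            draws[done:done + block] = 0.5 * (min_a @ fa + min_b @ fb)
        else:
            draws[done:done + block] = 0.5 * (min_a.mean(axis=1) + min_b.mean(axis=1))
        done += block
    return NullDistribution(draws)


def beta_nti(obs: float, null: NullDistribution) -> float:
    """z-score of observed betaMNTD against its null; NaN if sd = 0.

    A zero-spread null (e.g. a star tree, where every tip assignment gives
    the same betaMNTD) makes the index undefined; the NaN is a deliberate
    degeneracy flag, never coerced to 0 or +/-inf.
    """
    if null.is_degenerate:
        return float("nan")
    return (float(obs) - null.mean) / null.sd


def classify_turnover(beta_nti_value: float, threshold: float = 2.0) -> str:
    """Map betaNTI to an assembly-process class at the +/-threshold rule."""
    if not np.isfinite(beta_nti_value):
        raise ValueError("betaNTI is not finite (degenerate null?)")
    if beta_nti_value < -threshold:
        return HOMOGENEOUS
    if beta_nti_value > threshold:
        return VARIABLE
    return STOCHASTIC


def _pair_seed(master_seed: int, pair_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(pair_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def turnover_timecourse(
    table: CommunityTable,
    tree: PhylogeneticTree,
    metadata: SampleMetadata,
    scope: Literal["within_time", "all_pairs"] = "within_time",
    n_rand: int = 999,
    seed: int = 0,
    weighted: bool = True,
    tip_pool: Literal["all", "pair_union"] = "all",
    treatments: Sequence[str] = ("disturbed", "control"),
) -> list[TurnoverResult]:
    """betaNTI for every unordered sample pair in scope.

    ``within_time`` compares replicates within each (treatment, time)
    group (treatment-stratified pools); ``all_pairs`` compares every pair
    of samples regardless of grouping. Each pair gets a freshly seeded
    null derived from the master seed and the pair index.
    """
    metadata.check_covers(table)
    dists = tree.patristic_matrix()
    rel = table.relative_abundances()

    pairs: list[tuple[str, str, int | None, str | None]] = []
    if scope == "within_time":
        for treatment in treatments:
            for t in metadata.time_points:
                group = [s for s in metadata.samples_at(t, treatment)
                         if s in rel.columns]
                if len(group) < 2:
                    if group:
                        warnings.warn(
                            f"group ({treatment}, t={t}) has <2 samples; skipped",
                            stacklevel=2,
                        )
                    continue
                for i in range(len(group)):
                    for j in range(i + 1, len(group)):
                        pairs.append((group[i], group[j], t, treatment))
    elif scope == "all_pairs":
        samples = [s for s in table.sample_ids]
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                pairs.append((samples[i], samples[j], None, None))
    else:
        raise ValueError(f"unknown scope {scope!r}")

    results: list[TurnoverResult] = []
    for k, (sa, sb, t, treatment) in enumerate(pairs):
        a, b = rel[sa], rel[sb]
        obs = beta_mntd(a, b, dists, weighted=weighted)
        null = null_beta_mntd(
            a, b, dists, n_rand=n_rand, seed=_pair_seed(seed, k),
            weighted=weighted, tip_pool=tip_pool,
        )
        z = beta_nti(obs, null)
        cls = classify_turnover(z) if np.isfinite(z) else None
        results.append(TurnoverResult(sa, sb, obs, null, z, cls, t, treatment))
    return results


def stochastic_fraction(results: Iterable[TurnoverResult | float], threshold: float = 2.0) -> float:
    """Percentage of comparisons with |betaNTI| < threshold.

    Degenerate (NaN) pairs are excluded from both numerator and denominator.
    """
    values = np.array([
        r.beta_nti if isinstance(r, TurnoverResult) else float(r) for r in results
    ])
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite betaNTI values")
    return 100.0 * float(np.mean(np.abs(values) < threshold))


def turnover_summary(results: Iterable[TurnoverResult]) -> pd.DataFrame:
    """Per (treatment, time) mean betaNTI, stochastic fraction, pair count."""
    rows = []
    frame = pd.DataFrame(
        [
            {"treatment": r.treatment, "time_days": r.time_days, "beta_nti": r.beta_nti}
            for r in results
            if r.time_days is not None
        ]
    )
    if frame.empty:
        raise ValueError("no grouped results to summarize")
    for (treatment, t), grp in frame.groupby(["treatment", "time_days"]):
        vals = grp["beta_nti"].to_numpy()
        finite = vals[np.isfinite(vals)]
        rows.append(
            {
                "treatment": treatment,
                "time_days": int(t),
                "n_pairs": len(vals),
                "mean_beta_nti": float(finite.mean()) if finite.size else float("nan"),
                "stochastic_fraction_pct": (
                    stochastic_fraction(finite) if finite.size else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows).sort_values(["treatment", "time_days"]).reset_index(drop=True)


def results_table(results: Iterable[TurnoverResult]) -> pd.DataFrame:
    """Flat per-pair table (for TSV output)."""
    return pd.DataFrame(
        [
            {
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "time_days": r.time_days,
                "treatment": r.treatment,
                "beta_mntd_obs": r.beta_mntd_obs,
                "null_mean": r.null.mean,
                "null_sd": r.null.sd,
                "beta_nti": r.beta_nti,
                "classification": r.classification,
            }
            for r in results
        ]
    )


def bnti_activity_regression(
    mean_beta_nti: Sequence[float], mean_activity: Sequence[float]
) -> dict[str, float]:
    """OLS of per-time mean betaNTI on per-time mean cDNA:DNA activity.

    Returns slope, intercept, Pearson r and its two-sided p-value.
    """
    x = np.asarray(mean_activity, dtype=float)
    y = np.asarray(mean_beta_nti, dtype=float)
    if x.size != y.size:
        raise ValueError("mismatched lengths")
    if x.size < 3:
        raise ValueError("need at least 3 time points")
    if np.allclose(x, x[0]):
        raise ValueError("activity predictor is constant")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p_value": float(fit.pvalue),
    }
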
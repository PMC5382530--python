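"""End-to-end pipeline: rarefy -> diversity -> UniFrac/PCoA -> PERMANOVA ->
phase assignment -> betaNTI time course -> response groups -> report.

Every stochastic stage receives a seed derived deterministically from the
master seed, so a run is byte-identical given identical inputs and config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, ordination, succession, turnover
from .io import (
    CommunityTable,
    PhylogeneticTree,
    SampleMetadata,
    align_table_and_tree,
    read_community_table,
    read_metadata,
    read_newick,
    read_qpcr,
    write_community_table,
    write_distance_matrix,
)

logger = logging.getLogger("microsucc")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    counts: str
    tree: str
    metadata: str
    qpcr: str | None = None
    taxonomy: str | None = None
    out_dir: str | None = None
    depth: int = 3500
    n_rand: int = 999
    n_perm: int = 999
    k_groups: int = 8
    min_relabund: float = 0.005
    min_samples: int = 3
    filter_alpha: float = 0.01
    phase_alpha: float = 0.01
    align_policy: str = "strict"
    normalized_unifrac: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("depth", "n_rand", "n_perm", "k_groups", "min_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("min_relabund", "filter_alpha", "phase_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master), sum(ord(c) for c in stage), len(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def assign_phases(
    pairwise: pd.DataFrame, times: list[int], alpha: float = 0.01,
    p_column: str = "p_value",
) -> dict[int, str]:
    """Merge contiguous time points into successional phases.

    A time point joins the current phase when its pairwise PERMANOVA p
    against the previous time point is >= alpha, i.e. the two are
    compositionally indistinguishable; otherwise it starts a new phase.
    Three resulting phases get the conventional names primary / secondary /
    stability; any other count is labelled ``phase_<i>``.

    The threshold is applied to the uncorrected pairwise p by default: at
    five replicates per time point the exact two-group enumeration floor
    is 2/252 ~ 0.008, so any multiplicity correction pushes every
    attainable p above 0.01 and would make phase boundaries undetectable
    by construction. Pass ``p_column='p_adjusted'`` to use BH-corrected
    p-values when replication is rich enough to support them.
    """
    def _key(x) -> str:
        try:
            f = float(x)
            if f.is_integer():
                return str(int(f))
        except (TypeError, ValueError):
            pass
        return str(x)

    times = sorted(times)
    lookup: dict[frozenset, float] = {}
    for row in pairwise.itertuples():
        lookup[frozenset((_key(row.group_a), _key(row.group_b)))] = float(
            getattr(row, p_column)
        )
    phase_idx = [1]
    for prev, cur in zip(times, times[1:]):
        key = frozenset((_key(prev), _key(cur)))
        if key not in lookup:
            raise ValueError(f"pairwise table lacks comparison {prev} vs {cur}")
        distinct = lookup[key] < alpha
        phase_idx.append(phase_idx[-1] + 1 if distinct else phase_idx[-1])
    n_phases = phase_idx[-1]
    if n_phases == 3:
        names = {1: "primary", 2: "secondary", 3: "stability"}
    else:
        names = {i: f"phase_{i}" for i in range(1, n_phases + 1)}
    return {t: names[i] for t, i in zip(times, phase_idx)}


def run_pipeline(
    config: RunConfig,
    table: CommunityTable | None = None,
    tree: PhylogeneticTree | None = None,
    metadata: SampleMetadata | None = None,
    qpcr: pd.DataFrame | None = None,
) -> dict:
    """Execute all stages and return the run report (also written as JSON).

    Inputs may be passed in memory; otherwise they are read from the paths
    in ``config``. Any stage failure aborts with the stage name logged.
    """
    stage = "load_inputs"
    try:
        if table is None:
            table = read_community_table(config.counts, config.taxonomy)
        if tree is None:
            tree = read_newick(config.tree)
        if metadata is None:
            metadata = read_metadata(config.metadata)
        if qpcr is None and config.qpcr is not None:
            qpcr = read_qpcr(config.qpcr)
        metadata.check_covers(table)

        stage = "align"
        table, tree = align_table_and_tree(table, tree, policy=config.align_policy)

        stage = "rarefy"
        rarefied = diversity.rarefy(table, config.depth, _stage_seed(config.seed, "rarefy"))
        kept_tree = tree
        metadata_r = metadata.subset(rarefied.sample_ids)

        stage = "alpha_diversity"
        div = diversity.diversity_table(rarefied, metadata_r, qpcr)

        stage = "unifrac"
        dm = diversity.unifrac_matrix(rarefied, kept_tree, normalized=config.normalized_unifrac)

        stage = "pcoa"
        ord_res = ordination.pcoa(dm)

        stage = "permanova"
        disturbed = [
            s for s in rarefied.sample_ids
            if metadata_r.frame.loc[s, "treatment"] == "disturbed"
        ]
        dm_dist = dm.filter(disturbed)
        groups = metadata_r.frame.loc[disturbed, "time_days"].astype(str)
        global_perm = ordination.permanova(
            dm_dist, groups, n_perm=config.n_perm, seed=_stage_seed(config.seed, "permanova")
        )
        dispersion = ordination.dispersion_test(
            dm_dist, groups, n_perm=config.n_perm, seed=_stage_seed(config.seed, "dispersion")
        )
        pairwise = ordination.pairwise_permanova(
            dm_dist, groups, n_perm=config.n_perm, seed=_stage_seed(config.seed, "pairwise")
        )

        stage = "phases"
        # successional phases are defined over post-disturbance time points
        disturbed_times = sorted(
            t for t in metadata_r.frame.loc[disturbed, "time_days"].unique().tolist() if t > 0
        )
        phases = assign_phases(pairwise, disturbed_times, alpha=config.phase_alpha)

        stage = "turnover"
        results = turnover.turnover_timecourse(
            rarefied, kept_tree, metadata_r, scope="within_time",
            n_rand=config.n_rand, seed=_stage_seed(config.seed, "turnover"),
        )
        tsummary = turnover.turnover_summary(results)

        stage = "activity_regression"
        regression = None
        if "activity" in div.columns and div["activity"].notna().any():
            dist_summary = tsummary[tsummary["treatment"] == "disturbed"]
            act = (
                div[div["treatment"] == "disturbed"]
                .groupby("time_days")["activity"].mean()
            )
            merged = dist_summary.set_index("time_days").join(act, how="inner").dropna(
                subset=["mean_beta_nti", "activity"]
            )
            if len(merged) >= 3 and merged["activity"].nunique() > 1:
                regression = turnover.bnti_activity_regression(
                    merged["mean_beta_nti"].tolist(), merged["activity"].tolist()
                )

        stage = "succession"
        profiles = succession.filter_responsive_otus(
            rarefied, metadata_r, config.min_relabund, config.min_samples,
            config.filter_alpha,
        )
        groups_res = None
        subset_val = None
        if profiles:
            k = min(config.k_groups, len(profiles))
            if k < config.k_groups:
                logger.info("only %d responsive OTUs; cutting tree at k=%d", len(profiles), k)
            groups_res = succession.cluster_response_groups(
                profiles, k=k, taxonomy=rarefied.taxonomy
            )
            subset_val = succession.validate_subset_procrustes(
                rarefied, [p.taxon_id for p in profiles], n_perm=config.n_perm,
                seed=_stage_seed(config.seed, "procrustes"),
            )

        stage = "report"
        per_time = _per_time_summary(div, tsummary)
        report = {
            "config": dataclasses.asdict(config),
            "n_samples": len(rarefied.sample_ids),
            "n_taxa": len(rarefied.taxon_ids),
            "per_time": per_time,
            "pcoa": {
                "axis1_pct": round(100.0 * float(ord_res.proportion_explained[0]), 6),
                "axis2_pct": round(100.0 * float(ord_res.proportion_explained[1]), 6)
                if len(ord_res.proportion_explained) > 1 else None,
            },
            "permanova": {
                "pseudo_F": round(global_perm.pseudo_F, 6),
                "R2": round(global_perm.R2, 6),
                "p_value": global_perm.p_value,
                "n_permutations": global_perm.n_permutations,
            },
            "dispersion": {
                "F": round(dispersion.F, 6),
                "p_value": dispersion.p_value,
            },
            "phases": {str(t): p for t, p in phases.items()},
            "bnti_activity_regression": (
                {k: round(v, 6) for k, v in regression.items()} if regression else None
            ),
            "n_responsive_otus": len(profiles),
            "response_groups": (
                {str(g): int(c) for g, c in
                 groups_res.assignments.value_counts().sort_index().items()}
                if groups_res else None
            ),
            "subset_procrustes": (
                {"correlation": round(subset_val.correlation, 6),
                 "m2": round(subset_val.m2, 6), "p_value": subset_val.p_value}
                if subset_val else None
            ),
        }

        if config.out_dir is not None:
            stage = "write_outputs"
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_community_table(rarefied, out / "rarefied_counts.tsv")
            div.to_csv(out / "diversity.tsv", sep="\t")
            write_distance_matrix(dm, out / "unifrac.tsv")
            ord_res.coordinates.to_csv(out / "coordinates.tsv", sep="\t")
            pd.Series(ord_res.eigenvalues, name="eigenvalue").to_csv(
                out / "eigenvalues.tsv", sep="\t"
            )
            pairwise.to_csv(out / "pairwise_permanova.tsv", sep="\t", index=False)
            turnover.results_table(results).to_csv(out / "turnover.tsv", sep="\t", index=False)
            tsummary.to_csv(out / "turnover_summary.tsv", sep="\t", index=False)
            if groups_res is not None:
                groups_res.assignments.to_csv(out / "groups.tsv", sep="\t")
                groups_res.group_profiles.to_csv(out / "group_profiles.tsv", sep="\t")
            (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
    return report


def _per_time_summary(div: pd.DataFrame, tsummary: pd.DataFrame) -> dict:
    """Per (treatment, time) means of the headline quantities."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        agg = div.groupby(["treatment", "time_days"]).agg(
            richness=("richness", "mean"),
            pielou=("pielou", "mean"),
            activity=("activity", "mean") if "activity" in div.columns else ("richness", "size"),
        )
    out = {}
    tidx = tsummary.set_index(["treatment", "time_days"])
    for (treatment, t), row in agg.iterrows():
        key = f"{treatment}_t{int(t)}"
        entry = {
            "richness": round(float(row["richness"]), 4),
            "pielou": round(float(row["pielou"]), 6),
        }
        if "activity" in div.columns:
            entry["activity"] = (
                round(float(row["activity"]), 6) if np.isfinite(row["activity"]) else None
            )
        if (treatment, t) in tidx.index:
            trow = tidx.loc[(treatment, t)]
            entry["mean_beta_nti"] = round(float(trow["mean_beta_nti"]), 6)
            entry["stochastic_fraction_pct"] = round(float(trow["stochastic_fraction_pct"]), 4)
        out[key] = entry
    return out
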
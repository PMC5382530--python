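"""Alpha diversity, rarefaction, activity ratio, and weighted UniFrac.

Richness is the observed OTU count, evenness is Pielou's J = H / ln(S)
with Shannon entropy H in nats, and the per-cell activity proxy is the
cDNA:DNA 16S copy-number ratio. Weighted UniFrac distances (via
scikit-bio) feed the ordination stage.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import skbio.diversity
from skbio import DistanceMatrix

from .io import CommunityTable, PhylogeneticTree, SampleMetadata


def rarefy(table: CommunityTable, depth: int, seed: int | None = None) -> CommunityTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning (all dropped -> error). Subsampling is multivariate
    hypergeometric, one draw per sample from a seeded generator.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    keep = totals[totals >= depth].index.tolist()
    if not keep:
        raise ValueError(f"no sample reaches depth {depth}")
    dropped = [s for s in table.sample_ids if s not in keep]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} samples below depth {depth}", stacklevel=2)
    rng = np.random.default_rng(seed)
    out = {}
    for sid in keep:
        col = table.counts[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    return CommunityTable(pd.DataFrame(out, index=table.taxon_ids), table.taxonomy)


def _as_counts(sample: Mapping[str, float] | pd.Series | np.ndarray) -> np.ndarray:
    if isinstance(sample, pd.Series):
        arr = sample.to_numpy(dtype=float)
    elif isinstance(sample, Mapping):
        arr = np.array(list(sample.values()), dtype=float)
    else:
        arr = np.asarray(sample, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def richness(sample: Mapping[str, float] | pd.Series | np.ndarray) -> int:
    """Observed OTU count (taxa with count > 0)."""
    return int(np.count_nonzero(_as_counts(sample)))


def shannon(sample: Mapping[str, float] | pd.Series | np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p (nats) over positive-count taxa."""
    arr = _as_counts(sample)
    arr = arr[arr > 0]
    if arr.size == 0:
        return 0.0
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def pielou_evenness(sample: Mapping[str, float] | pd.Series | np.ndarray) -> float:
    """Pielou's J = H / ln(S); NaN (with a warning) when S < 2."""
    s = richness(sample)
    if s < 2:
        warnings.warn("Pielou's evenness undefined for richness < 2", stacklevel=2)
        return float("nan")
    return shannon(sample) / np.log(s)


def activity_ratio(cdna: float, dna: float) -> float:
    """Per-cell activity proxy: cDNA / DNA 16S copies per g soil."""
    if dna <= 0:
        raise ValueError("dna copies must be > 0")
    if cdna < 0:
        raise ValueError("cdna copies must be >= 0")
    return float(cdna) / float(dna)


def weighted_unifrac(
    abund_a: Mapping[str, float] | pd.Series,
    abund_b: Mapping[str, float] | pd.Series,
    tree: PhylogeneticTree,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two communities on a rooted tree.

    Raw form: sum over branches of branch length times |p_A - p_B| where
    p_X is the fraction of community X descending from the branch. The
    normalized form divides by sum of branch length times (p_A + p_B),
    bounding the result in [0, 1].
    """
    a = pd.Series(dict(abund_a)) if not isinstance(abund_a, pd.Series) else abund_a
    b = pd.Series(dict(abund_b)) if not isinstance(abund_b, pd.Series) else abund_b
    if float(a.sum()) <= 0 or float(b.sum()) <= 0:
        raise ValueError("communities must be nonempty")
    taxa = sorted(set(a.index) | set(b.index))
    u = a.reindex(taxa).fillna(0.0).to_numpy(dtype=float)
    v = b.reindex(taxa).fillna(0.0).to_numpy(dtype=float)
    # skbio truncates counts to integers; rescale proportions to a fine
    # integer grid so fractional abundances survive the cast
    u = np.round(u / u.sum() * 1e12)
    v = np.round(v / v.sum() * 1e12)
    return float(
        skbio.diversity.beta.weighted_unifrac(
            u, v, taxa=taxa, tree=tree.tree, normalized=normalized
        )
    )


def unifrac_matrix(
    table: CommunityTable, tree: PhylogeneticTree, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise weighted UniFrac distance matrix for all samples."""
    counts = table.counts.T.to_numpy(dtype=float)  # samples x taxa
    return skbio.diversity.beta_diversity(
        "weighted_unifrac",
        counts,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree.tree,
        normalized=normalized,
        validate=True,
    )


def diversity_table(
    table: CommunityTable,
    metadata: SampleMetadata | None = None,
    qpcr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample richness, Shannon H, Pielou J (+ activity if qPCR given)."""
    rows = []
    for sid in table.sample_ids:
        col = table.counts[sid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            j = pielou_evenness(col)
        rows.append({"sample_id": sid, "richness": richness(col),
                     "shannon": shannon(col), "pielou": j})
    out = pd.DataFrame(rows).set_index("sample_id")
    if qpcr is not None:
        act = {
            sid: activity_ratio(row["cdna_copies"], row["dna_copies"])
            for sid, row in qpcr.iterrows() if sid in out.index
        }
        out["activity"] = pd.Series(act)
    if metadata is not None:
        out = out.join(metadata.frame[["time_days", "treatment", "replicate"]])
    return out
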
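"""Shared data model and file I/O.

The pipeline works on three plain-text inputs: a taxa x samples integer
count table (TSV, OTU IDs as rows, sample IDs as columns), a rooted Newick
phylogeny whose tip labels match the OTU IDs, and a sample metadata table
(sample ID, days since disturbance, treatment, replicate, optional qPCR
16S copy numbers for DNA and cDNA).

Trees are backed by :class:`skbio.TreeNode`; distance matrices use
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix

logger = logging.getLogger("microsucc")

TREATMENTS = ("disturbed", "control")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class AlignmentError(ValueError):
    """Raised when a count table and a tree cannot be reconciled."""


@dataclass(frozen=True)
class PhylogeneticTree:
    """A rooted phylogeny with branch lengths, backed by ``skbio.TreeNode``.

    Invariants enforced at construction: unique tip labels, every non-root
    node carries a nonnegative branch length.
    """

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if not tips:
            # A Newick like "(A:1);" parses to a root with one child tip.
            raise FormatError("tree has no tips")
        if any(name is None for name in tips):
            raise FormatError("tree has unnamed tips")
        if len(set(tips)) != len(tips):
            raise FormatError("tip labels are not unique")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise FormatError(
                    f"node {node.name!r} has no branch length "
                    "(use allow_missing_lengths=True to default to 0)"
                )
            if node.length < 0:
                raise FormatError(f"negative branch length on node {node.name!r}")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_newick(
        cls, source: str | Path, allow_missing_lengths: bool = False
    ) -> "PhylogeneticTree":
        """Parse a single-tree Newick file or string."""
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source and ";" not in source
        ):
            tree = skbio.TreeNode.read(str(source))
        else:
            tree = skbio.TreeNode.read([str(source)])
        if allow_missing_lengths:
            for node in tree.traverse(include_self=False):
                if node.length is None:
                    node.length = 0.0
        return cls(tree)

    # -- properties -------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.tips())

    # -- operations -------------------------------------------------------
    def patristic_matrix(self) -> DistanceMatrix:
        """Tip-to-tip path-length (patristic) distance matrix."""
        if self.n_tips == 1:
            return DistanceMatrix(np.zeros((1, 1)), ids=self.tip_labels)
        return self.tree.tip_tip_distances()

    def prune_to(self, labels: Iterable[str]) -> "PhylogeneticTree":
        """Restrict the tree to the given tip labels (shear)."""
        labels = list(labels)
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise AlignmentError(f"labels not in tree: {sorted(missing)[:5]} ...")
        sheared = self.tree.copy().shear(labels)
        sheared.prune()
        return PhylogeneticTree(sheared)

    def to_newick(self) -> str:
        return str(self.tree)

    def write(self, path: str | Path) -> None:
        self.tree.write(str(path))


@dataclass
class CommunityTable:
    """Taxa x samples count table with optional ranked taxonomy.

    ``counts`` rows are taxa, columns are samples; entries are nonnegative
    integers. Input row order is preserved.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx, cols = self.counts.index, self.counts.columns
        if idx.duplicated().any():
            raise FormatError(f"duplicate taxon IDs: {idx[idx.duplicated()].tolist()[:5]}")
        if cols.duplicated().any():
            raise FormatError(f"duplicate sample IDs: {cols[cols.duplicated()].tolist()[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(values < 0):
            raise FormatError("counts must be nonnegative")
        if not np.allclose(values, np.round(values)):
            raise FormatError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.counts.index = idx.astype(str)
        self.counts.columns = cols.astype(str)

    @property
    def taxon_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundances(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.sample_totals()
        if (totals == 0).any():
            raise ValueError("cannot relativize a sample with zero total count")
        return self.counts / totals

    def select_taxa(self, taxa: Iterable[str]) -> "CommunityTable":
        taxa = list(taxa)
        tax = self.taxonomy.loc[[t for t in taxa if t in self.taxonomy.index]] \
            if self.taxonomy is not None else None
        return CommunityTable(self.counts.loc[taxa].copy(), tax)

    def select_samples(self, samples: Iterable[str]) -> "CommunityTable":
        return CommunityTable(self.counts[list(samples)].copy(), self.taxonomy)


@dataclass
class SampleMetadata:
    """Per-sample design variables.

    One row per sample: ``time_days`` (int >= 0), ``treatment``
    (``disturbed`` or ``control``), ``replicate`` (string), and optional
    ``dna_copies`` / ``cdna_copies`` (16S copies per g soil, > 0 where
    present) for the cDNA:DNA activity ratio.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"time_days", "treatment", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            raise FormatError("duplicate sample IDs in metadata")
        if (self.frame["time_days"] < 0).any():
            raise FormatError("time_days must be >= 0")
        bad = set(self.frame["treatment"]) - set(TREATMENTS)
        if bad:
            raise FormatError(f"unknown treatment values: {sorted(bad)}")
        for col in ("dna_copies", "cdna_copies"):
            if col in self.frame.columns and (self.frame[col].dropna() <= 0).any():
                raise FormatError(f"{col} must be > 0 where present")
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)
        self.frame["time_days"] = self.frame["time_days"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def time_points(self) -> list[int]:
        return sorted(self.frame["time_days"].unique().tolist())

    def samples_at(self, time_days: int, treatment: str | None = None) -> list[str]:
        mask = self.frame["time_days"] == time_days
        if treatment is not None:
            mask &= self.frame["treatment"] == treatment
        return self.frame.index[mask].tolist()

    def check_covers(self, table: CommunityTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise AlignmentError(f"samples without metadata: {sorted(missing)[:5]} ...")

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_community_table(
    path: str | Path, taxonomy_path: str | Path | None = None
) -> CommunityTable:
    """Read a taxa x samples count TSV (header = sample IDs, col 0 = taxon IDs)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"duplicate sample IDs in header of {path}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    return CommunityTable(frame, taxonomy)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    out = metadata.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read per-sample 16S copy numbers (sample_id, dna_copies, cdna_copies)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"dna_copies", "cdna_copies"} - set(frame.columns)
    if missing:
        raise FormatError(f"qPCR table missing columns: {sorted(missing)}")
    if (frame["dna_copies"] <= 0).any():
        raise FormatError("dna_copies must be > 0")
    frame.index = frame.index.astype(str)
    return frame


def read_newick(path: str | Path, allow_missing_lengths: bool = False) -> PhylogeneticTree:
    """Read a single rooted Newick tree with branch lengths."""
    return PhylogeneticTree.from_newick(Path(path), allow_missing_lengths)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(), ids=[str(i) for i in frame.index])


def align_table_and_tree(
    table: CommunityTable,
    tree: PhylogeneticTree,
    policy: Literal["strict", "prune"] = "strict",
) -> tuple[CommunityTable, PhylogeneticTree]:
    """Reconcile the taxon set of a count table with the tip set of a tree.

    ``strict`` requires the two sets to be equal and returns the inputs
    unchanged; ``prune`` restricts both to their intersection. Pruning is
    opt-in because it changes the tip pool over which null models shuffle.
    """
    taxa = set(table.taxon_ids)
    tips = set(tree.tip_labels)
    common = taxa & tips
    if not common:
        raise AlignmentError("count table and tree share no taxa")
    if policy == "strict":
        if taxa != tips:
            raise AlignmentError(
                f"taxon/tip mismatch: {len(taxa - tips)} taxa not in tree, "
                f"{len(tips - taxa)} tips not in table (use policy='prune')"
            )
        return table, tree
    if policy != "prune":
        raise ValueError(f"unknown policy {policy!r}")
    dropped = (len(taxa) - len(common)) + (len(tips) - len(common))
    if dropped:
        logger.info("align_table_and_tree: dropped %d taxa/tips outside intersection", dropped)
    kept = [t for t in table.taxon_ids if t in common]  # preserve table order
    new_table = table.select_taxa(kept) if len(kept) != len(taxa) else table
    new_tree = tree.prune_to(kept) if len(common) != len(tips) else tree
    return new_table, new_tree
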
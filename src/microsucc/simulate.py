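"""Synthetic disturbance-recovery data generator.

Emulates a heat-shock microcosm experiment: replicated disturbed and
control soil communities destructively sampled over ~50 days. The
generator produces (i) a random rooted phylogeny, (ii) a heat-tolerance
trait evolved on it with tunable phylogenetic signal, (iii) latent
community trajectories in which disturbance mortality is trait-structured
and regrowth is staged through response archetypes (survivor ->
copiotroph -> recovered, with an "original" pool that stays suppressed),
and (iv) sequencing counts via a Dirichlet-multinomial read model, plus
a phenomenological cDNA:DNA activity curve.

Ground truth (traits, archetypes, latent relative abundances, phase
labels) is returned so downstream inference can be scored against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import skbio

from .io import CommunityTable, PhylogeneticTree, SampleMetadata, write_community_table, write_metadata

ARCHETYPES = ("survivor", "copiotroph", "original", "recovered")

DEFAULT_TIME_POINTS = (0, 1, 4, 10, 18, 24, 25, 29, 49)


@dataclass
class SimulationConfig:
    """Knobs of the disturbance-recovery simulation.

    Defaults encode the emulated study design: nine harvest days over 49
    days, five replicate microcosms per treatment and time, reads drawn at
    the analysis depth of 3500. ``mortality_strength`` is the log-abundance
    penalty per unit of heat-tolerance deficit; ``trait_signal`` in [0, 1]
    mixes a Brownian-motion trait (1 = fully phylogenetically conserved)
    with a label-shuffled copy (0 = no signal).
    """

    n_taxa: int = 1000
    time_points: tuple[int, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 5
    read_depth: int = 3500
    trait_signal: float = 1.0
    mortality_strength: float = 5.0
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "survivor": 0.10,
            "copiotroph": 0.15,
            "original": 0.45,
            "recovered": 0.30,
        }
    )
    regrowth_rate: float = 0.35  # per day, logistic approach to baseline
    lag_days: Mapping[str, float] = field(
        default_factory=lambda: {
            "survivor": 0.0,
            "copiotroph": 2.0,
            "recovered": 8.0,
            "original": 60.0,  # effectively unrecovered within the horizon
        }
    )
    overdispersion: float = 50.0  # Dirichlet concentration scale; 0 = plain multinomial
    baseline_sigma: float = 1.0  # sd of baseline log-abundances (lognormal community)
    drift_sigma: float = 0.03  # per sqrt(day) random-walk drift of latent log-abundance
    survivor_bloom: float = 2.0  # transient log-abundance boost of survivors
    copiotroph_bloom: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_fractions.get(a, 0.0) for a in ARCHETYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1, got {total}")
        for name in ("trait_signal",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("mortality_strength", "regrowth_rate", "overdispersion",
                     "baseline_sigma", "drift_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["time_points"] = list(self.time_points)
        d["archetype_fractions"] = dict(self.archetype_fractions)
        d["lag_days"] = dict(self.lag_days)
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "time_points" in d:
            d["time_points"] = tuple(d["time_points"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Generator ground truth used to score downstream inference."""

    traits: pd.Series  # taxon -> heat tolerance (z-scored)
    archetype: pd.Series  # taxon -> archetype label
    latent_relabund: pd.DataFrame  # taxa x samples, columns sum to 1
    phase_labels: dict[int, str]  # post-disturbance day -> primary|secondary|stability

    def __post_init__(self) -> None:
        sums = self.latent_relabund.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("latent relative abundances must sum to 1 per sample")


def _taxon_labels(n_taxa: int) -> list[str]:
    width = len(str(n_taxa))
    return [f"OTU{i + 1:0{width}d}" for i in range(n_taxa)]


def simulate_tree(n_taxa: int, seed: int) -> PhylogeneticTree:
    """Random rooted, ultrametric-ish birth tree.

    Coalescent-style: start from ``n_taxa`` tips at height 0 and repeatedly
    join two uniformly chosen lineages at a height increased by an
    exponential increment, so all branch lengths are strictly positive.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    labels = _taxon_labels(n_taxa)
    nodes: list[skbio.TreeNode] = [skbio.TreeNode(name=lbl) for lbl in labels]
    heights = [0.0] * n_taxa
    height = 0.0
    while len(nodes) > 1:
        height += rng.exponential(1.0 / len(nodes))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = height - heights[i]
        b.length = height - heights[j]
        parent = skbio.TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        heights = [h for k, h in enumerate(heights) if k not in (i, j)] + [height]
    root = nodes[0]
    return PhylogeneticTree(root)


def evolve_trait(tree: PhylogeneticTree, trait_signal: float, seed: int) -> pd.Series:
    """Evolve a heat-tolerance trait on the tree with tunable signal.

    A Brownian-motion trait (increment variance proportional to branch
    length) is blended with a label-shuffled copy of itself:
    ``trait_signal=1`` keeps the pure Brownian trait (phylogenetically
    conserved), ``trait_signal=0`` destroys any association with the tree.
    The result is z-scored across taxa.
    """
    if not 0.0 <= trait_signal <= 1.0:
        raise ValueError("trait_signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree): 0.0}
    tip_vals: dict[str, float] = {}
    for node in tree.tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(max(node.length, 0.0)))
        values[id(node)] = parent_val + step
        if node.is_tip():
            tip_vals[node.name] = values[id(node)]
    labels = tree.tip_labels
    bm = np.array([tip_vals[lbl] for lbl in labels])
    shuffled = rng.permutation(bm)
    mixed = trait_signal * bm + (1.0 - trait_signal) * shuffled
    sd = mixed.std()
    z = (mixed - mixed.mean()) / (sd if sd > 0 else 1.0)
    return pd.Series(z, index=labels, name="trait")


def _assign_archetypes(
    traits: pd.Series, fractions: Mapping[str, float], rng: np.random.Generator
) -> pd.Series:
    """Survivors = top trait quantile; remaining archetypes drawn at random."""
    n = len(traits)
    n_survivor = max(1, int(round(fractions["survivor"] * n)))
    order = np.argsort(-traits.to_numpy(), kind="stable")
    labels = np.empty(n, dtype=object)
    survivor_idx = order[:n_survivor]
    labels[survivor_idx] = "survivor"
    rest = order[n_survivor:]
    others = ("copiotroph", "recovered", "original")
    weights = np.array([fractions[a] for a in others], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * len(rest)).astype(int)
    while counts.sum() < len(rest):
        counts[int(np.argmax(weights * len(rest) - counts))] += 1
    pool = rng.permutation(rest)
    start = 0
    for arch, c in zip(others, counts):
        labels[pool[start:start + c]] = arch
        start += c
    return pd.Series(labels, index=traits.index, name="archetype")


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_dynamics(
    tree: PhylogeneticTree, traits: pd.Series, config: SimulationConfig
) -> SimulationTruth:
    """Latent relative-abundance trajectories for both treatments.

    Baseline log-abundances are lognormal. At t > 0 disturbed communities
    take a mortality penalty ``mortality_strength * max(0, q_s - trait)``
    (q_s = survivor trait quantile); archetype-specific recovery restores
    the penalty logistically after the archetype's lag, survivors and
    copiotrophs add transient blooms, and controls keep the baseline with
    a small random-walk drift. Replicates of one (treatment, time) cell
    share the same latent column: replicate noise enters only through the
    read model in :func:`sample_counts`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
    labels = traits.index.tolist()
    n = len(labels)
    z = traits.to_numpy()

    base = rng.normal(0.0, config.baseline_sigma, size=n)
    archetype = _assign_archetypes(traits, config.archetype_fractions, rng)
    q_s = np.quantile(z, 1.0 - config.archetype_fractions["survivor"])
    deficit = np.maximum(0.0, q_s - z)
    penalty = config.mortality_strength * deficit
    # survivors by definition pay no mortality penalty
    penalty[(archetype == "survivor").to_numpy()] = 0.0

    lag = archetype.map(dict(config.lag_days)).to_numpy(dtype=float)
    is_survivor = (archetype == "survivor").to_numpy()
    is_copio = (archetype == "copiotroph").to_numpy()

    times = sorted(config.time_points)
    # shared-drift random walks, one per treatment
    drift = {"disturbed": np.zeros(n), "control": np.zeros(n)}
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    prev_t = times[0]
    for t in times:
        dt = max(t - prev_t, 0)
        for treatment in ("disturbed", "control"):
            if dt > 0:
                drift[treatment] = drift[treatment] + rng.normal(
                    0.0, config.drift_sigma * np.sqrt(dt), size=n
                )
            x = base + drift[treatment]
            if treatment == "disturbed" and t > 0:
                # logistic recovery of the mortality penalty after the lag
                recov = _sigmoid(config.regrowth_rate * (t - lag - 4.0))
                x = x - penalty * (1.0 - recov)
                # blooms exploit niche space freed by mortality, so they
                # scale to zero with it (mortality 0 -> a true null run)
                bloom_scale = 1.0 - np.exp(-config.mortality_strength)
                bloom = np.zeros(n)
                bloom[is_survivor] = config.survivor_bloom * np.exp(-t / 8.0)
                bloom[is_copio] = (
                    config.copiotroph_bloom
                    * _sigmoid(1.5 * (t - config.lag_days["copiotroph"]))
                    * np.exp(-t / 10.0)
                )
                x = x + bloom_scale * bloom
            p = np.exp(x - x.max())
            p /= p.sum()
            for rep in range(1, config.n_replicates + 1):
                sid = f"{'D' if treatment == 'disturbed' else 'C'}{t:02d}R{rep}"
                columns[sid] = p
                meta_rows.append(
                    {"sample_id": sid, "time_days": t, "treatment": treatment,
                     "replicate": f"R{rep}"}
                )
        prev_t = t
    latent = pd.DataFrame(columns, index=labels)
    phases = {t: phase_of(t) for t in times if t > 0}
    truth = SimulationTruth(traits, archetype, latent, phases)
    truth.metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return truth


def phase_of(t: int) -> str:
    """Successional phase of a post-disturbance day (design convention)."""
    if t <= 4:
        return "primary"
    if t <= 25:
        return "secondary"
    return "stability"


def sample_counts(
    latent: pd.DataFrame | SimulationTruth,
    depth: int,
    overdispersion: float,
    seed: int,
) -> CommunityTable:
    """Draw sequencing counts from latent compositions.

    Per sample: Dirichlet-perturbed proportions with concentration
    ``overdispersion * latent`` (replicate-level biological/technical
    noise), then a multinomial of ``depth`` reads. ``overdispersion=0``
    means a plain multinomial.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if isinstance(latent, SimulationTruth):
        latent = latent.latent_relabund
    rng = np.random.default_rng(seed)
    out = {}
    for sid in latent.columns:
        p = latent[sid].to_numpy(dtype=float)
        p = p / p.sum()
        if overdispersion > 0:
            alpha = overdispersion * p
            positive = alpha > 0
            q = np.zeros_like(p)
            q[positive] = rng.dirichlet(alpha[positive])
            p = q
        out[sid] = rng.multinomial(depth, p)
    counts = pd.DataFrame(out, index=latent.index)
    return CommunityTable(counts)


def simulate_qpcr(
    metadata: SampleMetadata, seed: int, base_ratio: float = 0.8,
    dip: float = 0.5, noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Phenomenological cDNA:DNA activity curve: dip after disturbance,
    logistic recovery by ~day 18, Gaussian noise; controls stay at base."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid, row in metadata.frame.iterrows():
        t = float(row["time_days"])
        if row["treatment"] == "disturbed" and t > 0:
            ratio = base_ratio - dip * (1.0 - float(_sigmoid(0.3 * (t - 10.0))))
        else:
            ratio = base_ratio
        ratio = max(ratio + rng.normal(0.0, noise_sd), 0.01)
        dna = 1e9 * np.exp(rng.normal(0.0, 0.1))
        rows.append({"sample_id": sid, "dna_copies": dna, "cdna_copies": ratio * dna})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CommunityTable, PhylogeneticTree, SampleMetadata, pd.DataFrame, SimulationTruth]:
    """Run the full generation chain deterministically from ``config.seed``."""
    ss = np.random.SeedSequence(int(config.seed))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    tree = simulate_tree(config.n_taxa, seeds[0])
    traits = evolve_trait(tree, config.trait_signal, seeds[1])
    truth = simulate_dynamics(tree, traits, config)
    metadata = truth.metadata
    table = sample_counts(truth, config.read_depth, config.overdispersion, seeds[2])
    qpcr = simulate_qpcr(metadata, seeds[3])
    return table, tree, metadata, qpcr, truth


def write_dataset(
    out_dir: str | Path,
    table: CommunityTable,
    tree: PhylogeneticTree,
    metadata: SampleMetadata,
    qpcr: pd.DataFrame,
    truth: SimulationTruth | None = None,
) -> None:
    """Write counts.tsv, tree.nwk, metadata.tsv, qpcr.tsv (+ truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_community_table(table, out / "counts.tsv")
    tree.write(out / "tree.nwk")
    write_metadata(metadata, out / "metadata.tsv")
    q = qpcr.copy()
    q.index.name = "sample_id"
    q.to_csv(out / "qpcr.tsv", sep="\t")
    if truth is not None:
        payload = {
            "traits": truth.traits.round(10).to_dict(),
            "archetype": truth.archetype.to_dict(),
            "phase_labels": {str(k): v for k, v in truth.phase_labels.items()},
        }
        (out / "truth.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
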
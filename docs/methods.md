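# Methods

## Scope and data model

`microsucc` analyses replicated community time series around a pulse
disturbance. All computation happens on three objects: a
`CommunityTable` (taxa × samples integer counts, optionally with ranked
taxonomy), a `PhylogeneticTree` (rooted, branch lengths ≥ 0, unique tips;
backed by `skbio.TreeNode`), and `SampleMetadata` (day since disturbance,
treatment ∈ {disturbed, control}, replicate, optional qPCR 16S copy
numbers for DNA and cDNA). Tables are taxa-as-rows TSVs; trees are Newick.
Taxon/tip mismatches fail loudly by default; pruning to the intersection
is opt-in (`align_table_and_tree(policy="prune")`) because pruning changes
the tip pool over which the null model shuffles. Relative abundances are
always per-sample `count / sample total`, computed on the rarefied table
unless a caller supplies something else.

## Phylogenetic turnover (βMNTD / βNTI)

βMNTD is the abundance-weighted mean of nearest-taxon patristic distances,
averaged over both directions of a community pair; conspecific taxa
contribute distance 0, which matters whenever communities overlap and is
the convention of the standard `comdistnt`-style implementations. The
unweighted variant replaces abundances with 1/(number of present taxa).

The null model draws, for each randomization, one random injection of the
pair's taxa onto distinct tips — by default uniformly over **all** tips of
the supplied phylogeny, with a `tip_pool="pair_union"` flag for
sensitivity analysis. One shuffle is shared by the two communities of a
pair (abundances travel with their taxa), so shared taxa keep contributing
zero under the null as well; the information βNTI carries therefore comes
from where the *non-shared* taxa land. βNTI is the z-score of the observed
βMNTD against 999 null draws (configurable); each pair gets a fresh null
whose seed derives deterministically from the master seed and the pair
index. A null with zero spread (e.g. any star tree) makes βNTI undefined:
the result is flagged NaN, classification refuses it, and summaries
exclude it — it is never coerced to 0 or ±inf.

Classification: βNTI < −2 homogeneous selection, > +2 variable selection,
otherwise stochastic; the stochastic fraction is the percentage of
comparisons with |βNTI| < 2. `turnover_timecourse(scope="within_time")`
compares replicates within each (treatment, day) cell —
treatment-stratified pools, since mixing treatments would conflate the
treatment contrast with within-group turnover. The βNTI–activity
relationship is an OLS of per-day mean βNTI on per-day mean cDNA:DNA with
Pearson r and its two-sided p.

The vectorized null (a `(block, |A|, |B|)` distance gather with blocks
capped at ~4M doubles) matches a naive nested-loop implementation to
1e-12; calibration on data generated by the null's own mechanism gives
empirical mean βNTI within ±0.15 of 0 and a stochastic fraction of ~95-97%
at 999 randomizations (both asserted in the test suite).

## Diversity

Rarefaction is a single seeded multivariate-hypergeometric draw per sample
(without replacement) to the target depth, dropping shallower samples with
a warning. Shannon entropy uses natural logs, so Pielou's J = H/ln S
follows its original definition; J is NaN-flagged for S < 2. Weighted
UniFrac delegates to scikit-bio; the default is the normalized variant
(bounded in [0, 1]) with a flag for the raw form, whose value between two
single-taxon communities equals their patristic distance (asserted as a
cross-module consistency check). Because scikit-bio truncates counts to
integers, fractional abundances are rescaled to a 1e12 integer grid before
the call.

## Ordination and distance-based inference

PCoA is classical scaling: eigendecomposition of the double-centered
squared-distance matrix. Negative eigenvalues are reported, not corrected
(no Cailliez/Lingoes), and variance proportions are computed over positive
eigenvalues only. PERMANOVA uses Anderson's distance-based decomposition;
p-values come from label permutations with the add-one convention
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), ties counting toward the null.
For small groups the sampler is replaced by exact enumeration of all
distinct label assignments (`exhaustive=True`, automatic in the pairwise
test when a pair has ≤ 5000 assignments — two groups of five have 252).
Exactness matters at this design's replication: the smallest attainable
5-vs-5 p is 2/252 ≈ 0.0079, right at the 0.01 phase threshold, and random
permutations straddle it noisily.

The dispersion test embeds samples by PCoA keeping negative-eigenvalue
axes as imaginary coordinates; distance to the group centroid is
√max(Σ_pos(x−c)² − Σ_neg(y−c̃)², 0), the statistic is the one-way ANOVA F
on those distances, and permutations relabel samples with centroids
recomputed each time. The statistic matches scikit-bio's centroid PERMDISP
to numerical precision. Symmetric Procrustes centers both configurations,
scales each to unit sum of squares and aligns by SVD; m² is the residual,
correlation = √(1 − m²), and the p-value permutes the row order of one
configuration.

## Succession machinery

The responsive-OTU filter keeps taxa that (i) reach `min_relabund`
(default 0.5%) in at least one sample, (ii) occur in ≥ 3 samples, and
(iii) vary with time (one-way ANOVA of relative abundance on day as a
categorical factor, disturbed samples only, p < 0.01, no multiplicity
correction — the threshold is a per-taxon rule). Temporal profiles are the
per-day means over disturbed samples, relativized by max-scaling (a
sum-to-one mode exists behind a flag); max-scaling is idempotent and
leaves all-zero taxa flagged. Profiles are clustered with Ward linkage on
Euclidean distances and the tree is cut at k groups (default 8); groups
are renumbered by the time of peak of their mean profile so group 1 always
peaks earliest. Subset validity is checked by Bray–Curtis → PCoA →
symmetric Procrustes between full table and subset.

Kruskal–Wallis uses scipy's tie-corrected H. The all-pairs Nemenyi
post-hoc uses the studentized-range approximation
q = |R̄_i − R̄_j| / √(N(N+1)/12 · (1/n_i + 1/n_j)), p = SR.sf(q√2, k, ∞);
when ties are present it switches to the χ² approximation with tie
correction C = 1 − Σ(t³−t)/(N³−N) and stat/C ~ χ²(k−1), and the result
records which branch ran. An `exact=True` option replaces the global p
with the exhaustive rank-permutation p for small samples.

Taxon/phylum response classification formalizes a verbal taxonomy, with
precedence: significantly above the pre-disturbance level at either of the
first two post-disturbance days → *stress tolerant*; significantly below
early and significantly above the control level at some middle/late day →
*positive secondary*; significantly below early but not at the final day →
*conventional recovery*; otherwise *no change*. Taxa that drop early and
stay depressed to the end have no category of their own in this taxonomy
and fall through to *no change* — a documented limitation of the rule set.

Phase assignment walks the post-disturbance days in order and merges a day
into the current phase when its pairwise PERMANOVA p against the previous
day is ≥ α (default 0.01); a significant adjacent comparison opens a new
phase. Exactly three phases get the conventional names primary /
secondary / stability. The threshold applies to the *uncorrected* p by
default: at five replicates the exact enumeration floor (0.0079) exceeds
0.01 after any multiplicity correction, which would make boundaries
undetectable by construction; `p_column="p_adjusted"` restores BH-corrected
thresholds for richer designs.

## The synthetic-data generator

The generator emulates a heat-shock microcosm experiment: harvest days
(0, 1, 4, 10, 18, 24, 25, 29, 49), five replicate microcosms per treatment
and day, 3500 reads per sample. Its parts:

- **Tree** — a random coalescent-style tree: repeatedly join two uniform
  lineages at a height advanced by an exponential increment; branch
  lengths strictly positive, roughly ultrametric.
- **Trait** — Brownian motion along branches blended with a label-shuffled
  copy; `trait_signal` ∈ [0, 1] interpolates from no phylogenetic signal
  to full conservation; z-scored across taxa.
- **Dynamics** — baseline log-abundances are lognormal (σ = 1.0 by
  default). At day > 0 disturbed communities pay a mortality penalty of
  `mortality_strength × max(0, q_s − trait)` log-units, where q_s is the
  survivor trait quantile (top 10% by default pay nothing). The penalty is
  restored logistically (rate 0.35/day) after an archetype-specific lag:
  copiotrophs 2 d, recovered taxa 8 d, the "original" pool 60 d (i.e.
  effectively unrecovered within the horizon, mirroring persistently
  suppressed taxa). Survivors and copiotrophs add transient log-abundance
  blooms that scale with (1 − e^(−mortality)), so a zero-mortality run is
  an exact null: disturbed and control trajectories coincide in
  distribution. Controls follow the baseline with a small shared
  random-walk drift. Replicates of one (treatment, day) cell share the
  same latent composition — replicate noise enters only through the read
  model — so ground truth stays per-treatment.
- **Reads** — per sample, Dirichlet-perturbed proportions with
  concentration `overdispersion × latent` (default 50), then a multinomial
  of `read_depth` reads. The low total concentration makes replicate
  membership turn over near the detection threshold, which is what gives
  the βNTI signal room to appear: the index is only informative about
  taxa *not* shared by a pair, so a simulator whose replicates share all
  detected taxa would be silent regardless of how strong selection is.
- **Activity** — cDNA:DNA is a phenomenological dip-and-logistic-recovery
  curve (base 0.8, dip 0.5, recovery centered near day 10) with Gaussian
  noise; it is a stand-in for Fig-1-style trajectories, not a
  transcription model.

Default scale is 1000 taxa (the emulated study's rarefied table had
~3800); the free parameters were set once so that the defaults reproduce
the study's qualitative regime — a 30–50% richness drop on day 1 followed
by recovery, survivor-clade dominance immediately after the shock, mean
within-day βNTI ≤ −2 on day 1 under full trait signal and ≈ 0 both before
disturbance and under zero mortality, a positive βNTI–activity slope, and
contiguous response phases. Quantities the emulated study cannot
constrain (regrowth rates, lags, bloom sizes) are chosen for this
qualitative pattern only.

What the generator does **not** emulate: true biological replicate
divergence (independent community assembly per microcosm), taxonomy,
fungal/archaeal compartments, resource-explicit competition, or
compositional biases of extraction/PCR. Passing tests therefore show that
the statistics recover planted structure under idealized replicate noise,
not that they are robust to every failure mode of real amplicon data. The
scaled-down taxon pool also exaggerates the relative richness drop and
shrinks the number of responsive OTUs (~25–40 vs. 156 in the emulated
study).

## Numerical and reproducibility choices

All randomness flows from explicit seeds through `numpy` generators;
pipeline stages derive their seeds deterministically from the master seed,
and each βNTI pair derives its null seed from (master, pair index), so a
run is byte-identical given identical inputs and configuration (asserted
as a test). Permutation p-values can never be 0 (add-one convention);
permutation tie comparisons use ≥ with a 1e-12 guard. Distance matrices
validate symmetry and zero diagonals via `skbio.DistanceMatrix`. The
vectorized null caps its temporary arrays at ~4M doubles per block.
Degenerate inputs — empty communities, single-taxon evenness, star-tree
nulls, all-zero profiles, groups of one — raise or flag rather than
returning silent numbers.

Runtime envelope (single CPU): the default acceptance run (1000 taxa,
90 samples, 999 randomizations/permutations) completes in ~1.5 min; the
full test suite, including null-model calibration at 300 pairs × 999
randomizations and 40 simulated experiments for the selection-recovery
check, runs in about a minute. Problem sizes in tests were chosen as the
smallest that leave the statistical assertions comfortable margins.
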
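"""Alpha-diversity and activity trajectories after a disturbance.

Rarefies the count table, then tracks richness (observed OTUs), Pielou's
evenness J = H/ln(S) and the cDNA:DNA activity ratio through recovery,
and tests the time effect with Kruskal-Wallis + Nemenyi post-hoc.
"""

import microsucc as ms
from microsucc.diversity import diversity_table, rarefy
from microsucc.succession import kruskal_posthoc

cfg = ms.SimulationConfig(n_taxa=400, read_depth=2000, seed=7)
table, tree, metadata, qpcr, _ = ms.simulate_experiment(cfg)

rarefied = rarefy(table, depth=2000, seed=0)
div = diversity_table(rarefied, metadata, qpcr)
disturbed = div[div.treatment == "disturbed"]

print("disturbed means per day (richness / evenness / activity):")
summary = disturbed.groupby("time_days")[["richness", "pielou", "activity"]].mean()
print(summary.round(3).to_string())

groups = {t: g["richness"].to_numpy() for t, g in disturbed.groupby("time_days")}
kw = kruskal_posthoc(groups)
print(f"\nKruskal-Wallis on richness vs time: H = {kw.H:.2f}, p = {kw.p_value:.2g} "
      f"(post-hoc: {kw.posthoc_method})")
print(f"day 0 vs day 1 post-hoc p = {kw.posthoc_p.loc[0, 1]:.3g}")
# Richness and evenness dip right after the shock and recover by the last
# sampling day; a small post-hoc p for day 0 vs 1 confirms the initial drop.
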
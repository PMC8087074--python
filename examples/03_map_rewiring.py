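"""Quantify global modular-map rewiring across perturbed conditions.

Starts from a core-periphery reference condition, derives an "aggregated"
condition (cross edges added everywhere, clique-like map) and a "dispersed"
one (core pair scattered, surviving paths widened), then compares the three
modular maps: topology table, score-distribution chi-square shift, PCA of
bin frequencies and Euclidean architecture distance to the reference.
"""

import warnings

import pandas as pd

from imcc import (
    architecture_distance,
    bin_distribution,
    build_map,
    pca_profiles,
    quartile_edges,
    rewiring_test,
    score_condition,
    topo_summary,
)
from imcc.synthdata import core_periphery_design, make_modular_network, rewire_condition

design = core_periphery_design(seed=0)
net, part, _ = make_modular_network(design)
conditions = {"reference": (net, part)}
net_a, part_a, _ = rewire_condition(net, part, "aggregate", 0.8, seed=1)
conditions["aggregated"] = (net_a, part_a)
net_d, part_d, _ = rewire_condition(
    net, part, "disperse", 1.0, seed=2, pmp=("M01", "M02"), n_landing=6
)
conditions["dispersed"] = (net_d, part_d)

summaries, values = {}, {}
for name, (n, p) in conditions.items():
    table = score_condition(n, p)
    mmap = build_map(table, p)
    summaries[name] = topo_summary(mmap)
    v = table["imcc"].dropna()
    values[name] = v[v > 0].to_numpy()

print("modular-map topology per condition:")
print(pd.DataFrame({k: s.as_dict() for k, s in summaries.items()}).T.round(3).to_string())

edges = quartile_edges(values["reference"])
profiles = {k: bin_distribution(v, edges) for k, v in values.items()}
print("\nscore-distribution shift against the reference (chi-square):")
for name in ("aggregated", "dispersed"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = rewiring_test(profiles["reference"], profiles[name])
    print(f"  {name:10s} statistic = {stat:.2f}, p = {p:.3g}")

print("\nPCA of relative bin frequencies (first two components):")
print(pca_profiles(profiles).round(3).to_string())

print("\nEuclidean architecture distance to the reference")
print("(min-max normalized avg_weight / density / centrality):")
print(architecture_distance(summaries, "reference").round(3).to_string())
print(
    "\nUniform aggregation flattens the enrichment signal (fewer pairs stand"
    "\nout against the denser background), while dispersion concentrates"
    "\nweight on the surviving coordinated pairs, leaving a small clique-like"
    "\nmap; both rewirings register in the chi-square shift and move the"
    "\ncondition away from the reference architecture."
)
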
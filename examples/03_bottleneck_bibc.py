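"""Find the mediator between two network regions with bipartite betweenness.

Simulates two correlated feature modules joined only through a planted
bridge feature, reconstructs the network, ranks nodes by BiBC between the
modules, and scores the bridge's significance against 1,000 Erdos-Renyi
random networks with matched node and edge counts.
"""

from omicnet import (bibc, differential_stats, node_degree, random_network_null,
                     reconstruct_network, scale_scores, select_top_nodes)
from omicnet.simulate import simulate_bottleneck_network_data

study, truth = simulate_bottleneck_network_data(m1=30, m2=30, n_per_group=50,
                                                seed=0)
disease = differential_stats(study, ("disease", "reference"))
net, _, _ = reconstruct_network(study, disease, ["disease", "treatA", "treatB"])

g1 = [f for f in truth.module_members[0] if f in net]
g2 = [f for f in truth.module_members[1] if f in net]
raw = bibc(net, g1, g2)
scaled = scale_scores(raw)

print(f"\ntop 5 nodes by scaled BiBC (planted bridge: {truth.bottleneck}):")
print(scaled.nlargest(5).round(2).to_string())

top = select_top_nodes(raw, node_degree(net), mode="quantile")
print(f"joint top-10% by BiBC and degree: {top}")

null = random_network_null(net, g1, g2, truth.bottleneck, R=1000,
                           strategy="degree_matched", seed=0)
print(f"bridge BiBC = {null.observed_bibc:.1f}; empirical p vs G(n,m) nulls: "
      f"{null.formatted_p()}")
# A scaled BiBC of 100 means every cross-module shortest path runs through
# the bridge; an empirical p below 1/R says no degree-matched node in any
# random network reached the observed value.
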
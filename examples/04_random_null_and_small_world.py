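"""Compare an observed network against a size-matched Erdős–Rényi null
ensemble at the scale of the real soil co-occurrence network (745 nodes,
1800 edges).

A clustering coefficient far above the random expectation, with a path
length of the same order, is the small-world signature.
"""

import networkx as nx

from micronet import random_ensemble, small_world_report, topology_summary

n_nodes, n_edges = 745, 1800

ens = random_ensemble(n_nodes, n_edges, n_realizations=100, seed=1)
print(f"ER null ensemble, 100 x G({n_nodes}, {n_edges}):")
print(f"  mean APL = {ens.aplr_mean:.2f} +/- {ens.aplr_sd:.2f} (sd), "
      f"se {ens.aplr_se:.3f}")
print(f"  mean ACC = {ens.accr_mean:.4f} +/- {ens.accr_sd:.4f} (sd)")

# a clustered small-world graph of the same size, for contrast
obs_graph = nx.connected_watts_strogatz_graph(n_nodes, 4, 0.1, seed=3)
obs = topology_summary(obs_graph, seed=0)
null = random_ensemble(n_nodes, obs.edges, n_realizations=100, seed=2)
rep = small_world_report(obs, null)
print(f"\nWatts-Strogatz comparison graph ({obs.edges} edges): "
      f"ACC={obs.acc:.3f}, APL={obs.apl:.2f}")
print(f"  ACC ratio vs null = {rep['acc_ratio']:.1f} "
      f"(z = {rep['acc_z']:.1f}), APL ratio = {rep['apl_ratio']:.2f}")
print("an ACC ratio far above 1 at comparable APL marks small-world "
      "structure; ER graphs have ratio ~1 by construction.")
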
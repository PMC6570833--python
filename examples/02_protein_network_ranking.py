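"""Seed-network expansion, centrality ranking and MCL clustering.

Simulates a modular protein-association network (four planted modules),
expands a small seed list with up to 20 first-shell and 10 second-shell
interactors at the 0.400 confidence threshold, ranks nodes by the
combined centrality score (0.2 degree + 0.3 harmonic closeness + 0.5
betweenness, each min-max normalized), and clusters the result with MCL
at inflation 3.
"""

from ibdnet.clustering import MclParams, mcl
from ibdnet.graph_metrics import centrality_records
from ibdnet.netbuild import ShellCaps, expand_seed_network
from ibdnet.synthetic import NetworkSimSpec, simulate_ppa

table, truth = simulate_ppa(NetworkSimSpec(module_sizes=(10, 10, 10, 10), seed=7))
seeds = sorted(truth)[:4]  # pretend these four proteins carry risk variants

net = expand_seed_network(table, seeds, caps=ShellCaps(20, 10), min_score=0.400)
roles = [net.nodes[n]["role"] for n in net]
print(
    f"network: {net.number_of_nodes()} nodes "
    f"({roles.count('seed')} seed / {roles.count('shell1')} shell1 / "
    f"{roles.count('shell2')} shell2), {net.number_of_edges()} edges"
)

print("\ntop 5 proteins by combined centrality score:")
for rec in centrality_records(net)[:5]:
    print(
        f"  {rec.node}  deg={rec.c_deg:.3f} clo={rec.c_clo:.3f} "
        f"bet={rec.c_bet:.3f} -> combined={rec.combined:.3f}"
    )

clusters = mcl(net, MclParams(inflation=3.0))
print(f"\nMCL (inflation 3) found {clusters.n_clusters} clusters:")
for i, members in enumerate(clusters.clusters(), start=1):
    print(f"  cluster {i}: {sorted(members)}")
print("\nHigh combined scores flag hub/bottleneck proteins worth follow-up.")
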
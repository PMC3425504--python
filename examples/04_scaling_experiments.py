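"""Growth classes at desk scale: rings vs the bad graph.

Two seeded simulation sweeps: (i) mean rounds to a 1/2-approximate
matching on rings, which should grow logarithmically (bounded degree);
(ii) mean rounds to the bad graph's unique perfect matching from
near-perfect starts, which should grow geometrically.
"""

from prudent_matching import bad_graph_scaling_report, ring_scaling_report

ring = ring_scaling_report(sizes=(8, 16, 32, 64), reps=200, master_seed=0)
print("rings, mean rounds to a 1/2-approximate matching:")
for n, mu in ring["mean_rounds"].items():
    print(f"  n={n:3d}: {mu:.2f}")
print(f"log-model R2={ring['r2_log']:.3f} vs linear R2={ring['r2_linear']:.3f} "
      f"-> {ring['verdict']}")

bad = bad_graph_scaling_report(grid=(3, 4, 5, 6), reps=100, master_seed=0)
print("\nbad graph, mean rounds to the perfect matching from slow starts:")
for n, stats in bad["per_n"].items():
    print(f"  side {n}: {stats['mean_rounds']:.1f}")
print(f"successive ratios: {[round(r, 2) for r in bad['ratios']]} "
      f"-> geometric growth: {bad['geometric']}")
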
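"""Simulate passaging series under a stable and an unstable regime.

Runs the branching clonal-evolution simulator for a checkpoint-knockout
regime without aneuploidy tolerance (RB1-like) and for the chromosomally
unstable, WGD-tolerant regime (TP53-like), then prints the surviving clone
structure and the burden of large (>= 1 Mbp) detectable alterations.
"""

from cnaevo import GenomeBuild, SimulationConfig, simulate_lineage
from cnaevo.genome import event_length
from cnaevo.simulate import rb1_like_regime, tp53_like_regime

genome = GenomeBuild.from_pairs([(f"chr{i}", 80_000_000) for i in range(1, 5)])
passages = (8, 16, 24)

for regime in (rb1_like_regime(), tp53_like_regime()):
    config = SimulationConfig(
        genome=genome, regime=regime, n_passages=24, bottleneck_size=300,
        sampled_passages=passages, seed=14,
    )
    truth = simulate_lineage(config)
    surviving = truth.surviving_events()
    large = [
        e for e in surviving
        if truth.events[e].segment is not None
        and event_length(truth.events[e]) >= 1_000_000
        and max(truth.true_mcf(e, p) for p in passages) > 0.1
    ]
    wgd = [e for e in surviving if truth.events[e].kind == "wgd"]
    print(f"\n=== {regime.name} ===")
    print(f"clones ever created: {len(truth.clones)}")
    for p in passages:
        big = {c: f for c, f in truth.fractions[p].items() if f >= 0.05}
        print(f"  passage {p}: clones >= 5%: "
              + ", ".join(f"{c}={f:.2f}" for c, f in sorted(big.items())))
    print(f"large (>=1 Mbp) alterations detectable at >10% MCF: {len(large)}")
    if wgd:
        mcf = max(truth.true_mcf(wgd[0], p) for p in passages)
        print(f"whole-genome duplication present, max MCF {mcf:.2f}")
    else:
        print("no whole-genome duplication")

print("\nThe stable regime leaves essentially no detectable aneuploid clones;"
      "\nthe unstable regime accumulates large alterations, typically after a"
      "\ngenome-doubling sweep — the qualitative contrast the regimes encode.")
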
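"""Reconstruct a subclone tree from an MCF matrix and lay out its fishplot.

Uses a hand-written event x sample MCF matrix with a stem alteration
(MCF 1 everywhere), a sweeping subclone and a nested sub-subclone; builds
the containment/pigeonhole-constrained tree, prints the newick export, the
per-sample clone proportions (the pie-chart numbers), and the fishplot
band widths over passages.
"""

import numpy as np

from cnaevo import EventMatrix, build_tree, cluster_events, tree_to_newick
from cnaevo.genome import CNAEvent, GenomicSegment
from cnaevo.phylo import clone_proportions, detect_replacement
from cnaevo.stats import fishplot_layout

passages = [5, 15, 25, 35]


def ev(eid, kind, chrom, start_mb, len_mb):
    delta = {"gain": 1, "loss": -1}.get(kind, 0)
    seg = GenomicSegment(chrom, start_mb * 10**6, (start_mb + len_mb) * 10**6)
    return CNAEvent(eid, kind, seg, delta, label=f"{chrom}{kind[0]}")


matrix = EventMatrix(
    [ev("stem", "loss", "chr3", 150, 2), ev("sweep", "gain", "chr7", 60, 10),
     ev("nested", "loss", "chr9", 20, 4)],
    [f"P{p}" for p in passages],
    np.array([
        [1.00, 1.00, 1.00, 1.00],   # stem: in all cells at all passages
        [0.10, 0.45, 0.80, 0.95],   # sweeping subclone
        [0.00, 0.10, 0.40, 0.70],   # nested inside the sweep
    ]),
)
tree = build_tree(cluster_events(matrix, tau=0.10), tau=0.10)
print("newick:", tree_to_newick(tree))

for sample in matrix.samples:
    props = clone_proportions(tree, sample)
    pretty = {n: round(float(f), 2) for n, f in props.items() if f > 0}
    print(f"clone proportions in {sample}: {pretty}")

fp = fishplot_layout(tree, passages)
print("\nfishplot bands (cumulative fraction per node):")
for node in fp.nodes:
    bands = ", ".join(f"{v:.2f}" for v in fp.cumulative[node])
    print(f"  {node:5s} parent={fp.parents[node] or '-':5s} "
          f"emerges P{fp.emergence[node]}: [{bands}]")

props = {p: clone_proportions(tree, s) for p, s in zip(passages, matrix.samples)}
switch = detect_replacement(tree, props)
print(f"\ndominant-lineage replacement: "
      f"{'none' if switch is None else f'at passage {switch}'}"
      " (succession down one lineage is not a replacement)")
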
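"""Shared harness for parameter-recovery experiments.

Simulates sweep-dominated passaging lineages, runs the full array ->
calling -> phylogeny pipeline, and scores ancestor-descendant recovery over
*identifiable* event pairs: pairs whose orientation is shared by every
constraint-satisfying tree of the true MCF profiles (the exhaustive
enumeration is the identifiability oracle).  Pairs the constraints leave
ambiguous — e.g. a dominated sibling that could equally be a descendant —
are excluded from both precision and recall, mirroring the distinguishable-
fractions proviso of the noiseless recovery guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cnaevo.arrays import emulate_sample, make_probe_map
from cnaevo.fileio import RunConfig
from cnaevo.genome import GenomeBuild, reciprocal_overlap
from cnaevo.phylo import cluster_events, enumerate_trees
from cnaevo.pipeline import analyze_samples
from cnaevo.simulate import (
    RegimeConfig,
    SimulationConfig,
    simulate_lineage,
    true_mcf_matrix,
)

TAU = 0.10
#: Detectability convention for "recoverable" truth events: >= 1 Mbp and
#: MCF >= 0.2 in at least one sample.
TRUTH_MCF_FLOOR = 0.2

RECOVERY_GENOME = GenomeBuild.from_pairs(
    [(f"chr{i}", 80_000_000) for i in range(1, 9)]
)
#: Sweep-dominated chromosomally unstable culture: sparse events with
#: occasionally strong multiplicative fitness effects, so subclones rise to
#: detectable fractions over the 40-passage course.
RECOVERY_REGIME = RegimeConfig(
    "sweep-dominated", event_rate=0.08, kind_weights=(0.45, 0.45, 0.10),
    fitness_mean=1.08, fitness_sd=0.20,
)
RECOVERY_PASSAGES = (8, 16, 24, 32, 40)


@dataclass
class RecoveryResult:
    true_positive: int
    inferred_scored: int
    true_scored: int
    mcf_errors: np.ndarray


def simulate_instance(seed: int):
    """One admissible truth instance, or None if the draw is rejected.

    Admissible: 2-8 clones ever above 10%, at least 3 detectable segmental
    events, and no genomic overlap among detectable events (overlapping
    alterations collapse into complex states no caller can decompose).
    """
    sim = SimulationConfig(
        genome=RECOVERY_GENOME, regime=RECOVERY_REGIME, n_passages=40,
        bottleneck_size=300, sampled_passages=RECOVERY_PASSAGES,
        event_size_dist=(3e6, 2e7), seed=seed,
    )
    truth = simulate_lineage(sim)
    big = {
        c for p in RECOVERY_PASSAGES
        for c, f in truth.fractions[p].items() if f >= 0.1
    }
    detectable = [
        eid for eid in truth.surviving_events()
        if truth.events[eid].kind in ("gain", "loss", "cnloh")
        and max(truth.true_mcf(eid, p) for p in RECOVERY_PASSAGES)
        >= TRUTH_MCF_FLOOR
    ]
    if not (2 <= len(big) <= 8) or len(detectable) < 3:
        return None
    evs = [truth.events[e] for e in detectable]
    for i, a in enumerate(evs):
        for b in evs[i + 1:]:
            if a.segment.overlap_bp(b.segment) > 0:
                return None
    return truth, detectable


def determined_relations(truth, detectable):
    """Ordered event pairs with oracle-determined ancestor relations.

    Returns (always, never): pairs (a, b) for which a is an ancestor of b
    in every / in no constraint-satisfying tree of the true profiles; or
    None when the instance has more than 7 true clusters (enumeration
    guard).
    """
    m = true_mcf_matrix(truth, RECOVERY_PASSAGES)
    keep = [i for i, e in enumerate(m.events) if e.event_id in detectable]
    clusters = cluster_events(m.subset(keep), TAU)
    if len(clusters) > 7:
        return None
    maps = enumerate_trees(clusters, TAU)
    keys = [c.key for c in clusters]

    def ancestors(pm, k):
        out, cur = set(), pm.get(k)
        while cur is not None:
            out.add(cur)
            cur = pm.get(cur)
        return out

    always, never = set(), set()
    for i, ki in enumerate(keys):
        for j, kj in enumerate(keys):
            if i == j:
                continue
            rel = [ki in ancestors(pm, kj) for pm in maps]
            if all(rel):
                always.add((i, j))
            elif not any(rel):
                never.add((i, j))
    cluster_of = {
        e.event_id: i for i, c in enumerate(clusters) for e in c.events
    }
    det_true, det_false = set(), set()
    for a in detectable:
        for b in detectable:
            if a == b or cluster_of[a] == cluster_of[b]:
                continue
            ij = (cluster_of[a], cluster_of[b])
            if ij in always:
                det_true.add((a, b))
            elif ij in never:
                det_false.add((a, b))
    return det_true, det_false


def run_replicate(seed: int, config: RunConfig | None = None):
    """Full-pipeline recovery for one admissible instance; None if the
    seed's draw is rejected or not oracle-enumerable."""
    inst = simulate_instance(seed)
    if inst is None:
        return None
    truth, detectable = inst
    rel = determined_relations(truth, detectable)
    if rel is None:
        return None
    det_true, det_false = rel
    cfg = config or RunConfig()
    probemap = make_probe_map(RECOVERY_GENOME, seed=seed + 7)
    signals = {
        f"P{p}": emulate_sample(truth, p, probemap, seed=seed * 1000 + i,
                                sample_id=f"P{p}")
        for i, p in enumerate(RECOVERY_PASSAGES)
    }
    _, _, _, matrix, tree = analyze_samples(signals, RECOVERY_GENOME, cfg)

    surviving = truth.surviving_events()
    match: dict[str, str] = {}
    for ev in matrix.events:
        if ev.kind not in ("gain", "loss", "cnloh") or ev.segment is None:
            continue
        best, best_overlap = None, 0.5
        for eid in surviving:
            tev = truth.events[eid]
            if tev.kind != ev.kind or tev.segment is None:
                continue
            o = reciprocal_overlap(ev.segment, tev.segment)
            if o >= best_overlap:
                best, best_overlap = eid, o
        if best:
            match[ev.event_id] = best

    errors = []
    for i, ev in enumerate(matrix.events):
        if ev.event_id in match:
            tid = match[ev.event_id]
            errors.extend(
                matrix.mcf[i, j] - truth.true_mcf(tid, p)
                for j, p in enumerate(RECOVERY_PASSAGES)
            )
    inferred = set()
    for a, b in tree.ancestor_descendant_pairs():
        if a in match and b in match:
            inferred.add((match[a], match[b]))
    tp = len(inferred & det_true)
    fp = len(inferred & det_false)
    fn = len(det_true - inferred)
    return RecoveryResult(tp, tp + fp, tp + fn, np.asarray(errors))


def run_recovery(n_replicates: int, seed0: int = 1, max_seed: int = 5000):
    """Aggregate precision, recall and MCF RMSE over admissible replicates."""
    tp = inf = true = 0
    errors = []
    used, seed = 0, seed0 - 1
    while used < n_replicates and seed < seed0 + max_seed:
        seed += 1
        r = run_replicate(seed)
        if r is None:
            continue
        used += 1
        tp += r.true_positive
        inf += r.inferred_scored
        true += r.true_scored
        errors.append(r.mcf_errors)
    err = np.concatenate([e for e in errors if e.size])
    return {
        "replicates": used,
        "precision": tp / max(inf, 1),
        "recall": tp / max(true, 1),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "n_pairs": true,
        "n_entries": int(err.size),
    }
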
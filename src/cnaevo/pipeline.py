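"""End-to-end orchestration: simulate -> emulate -> call -> matrix -> tree
-> fishplot -> compare, plus the detectability benchmark.

`run_all` runs one passaging series per configured regime (the study
design: a wild-type longitudinal series plus checkpoint-knockout series),
calls events on every emulated sample, assembles per-regime MCF matrices,
trees and fishplot layouts, and compares event counts between regimes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arrays import ProbeMap, ProbeSignal, emulate_sample, make_probe_map
from .calling import (
    CalledSegment,
    CallThresholds,
    PloidyCall,
    build_event_matrix,
    call_events,
    detect_wgd,
    refine_event_matrix,
    segment_signal,
)
from .fileio import (
    RunConfig,
    comparisons_to_frame,
    environment_versions,
    fishplot_to_dict,
    load_genome_tsv,
    tree_to_dict,
    tree_to_newick,
    write_clone_truth,
    write_event_matrix,
    write_segment_file,
)
from .genome import CNAEvent, GenomeBuild, GenomicSegment, reciprocal_overlap
from .matrix import EventMatrix
from .phylo import SubcloneTree, build_tree, cluster_events, clone_proportions
from .simulate import (
    KO_SAMPLED_PASSAGES,
    REGIMES,
    WT_SAMPLED_PASSAGES,
    CloneTruth,
    SimulationConfig,
    programmed_truth,
    simulate_lineage,
    true_mcf_matrix,
)
from .stats import (
    FishplotData,
    GroupComparison,
    compare_groups,
    count_events,
    fishplot_layout,
    gain_loss_summary,
)

__all__ = [
    "RegimeResult",
    "PipelineResult",
    "run_all",
    "analyze_samples",
    "detection_rates",
    "empirical_detection_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class RegimeResult:
    regime: str
    truth: CloneTruth
    passages: tuple[int, ...]
    segments: dict[str, list[CalledSegment]]
    events: dict[str, list[tuple[CNAEvent, float]]]
    ploidy: dict[str, PloidyCall]
    matrix: EventMatrix
    tree: SubcloneTree
    fishplot: FishplotData
    counts_all: dict[str, int]
    counts_large: dict[str, int]


@dataclass
class PipelineResult:
    config: RunConfig
    regimes: dict[str, RegimeResult]
    comparisons_all: list[GroupComparison]
    comparisons_large: list[GroupComparison]


def analyze_samples(
    signals: dict[str, ProbeSignal],
    genome: GenomeBuild,
    config: RunConfig | None = None,
) -> tuple[
    dict[str, list[CalledSegment]],
    dict[str, list[tuple[CNAEvent, float]]],
    dict[str, PloidyCall],
    EventMatrix,
    SubcloneTree,
]:
    """Call events on a set of samples and reconstruct their subclone tree."""
    cfg = config or RunConfig()
    segments: dict[str, list[CalledSegment]] = {}
    events: dict[str, list[tuple[CNAEvent, float]]] = {}
    ploidy: dict[str, PloidyCall] = {}
    for sid, sig in signals.items():
        segs = segment_signal(sig, min_probes=cfg.min_probes, alpha=cfg.alpha,
                              merge_tol=cfg.merge_tol)
        # ploidy first: a genome-doubled sample is called against the
        # tetraploid baseline, and the doubling itself becomes an event
        pl = detect_wgd(segs, genome, centering=cfg.centering)
        ref = 4.0 if pl.wgd_flag else 2.0
        evs = call_events(segs, cfg.thresholds, reference_ploidy=ref)
        if pl.wgd_flag:
            wgd_mcf = float(np.clip((pl.psi_hat - 2.0) / 2.0, 0.0, 1.0))
            evs = [(CNAEvent(f"{sid}:wgd", "wgd"), wgd_mcf)] + evs
        segments[sid] = segs
        events[sid] = evs
        ploidy[sid] = pl
    matrix = build_event_matrix(events, match_overlap=cfg.match_overlap,
                                genome=genome)
    matrix = refine_event_matrix(
        matrix, signals, cfg.thresholds,
        reference_ploidy={
            s: 4.0 if ploidy[s].wgd_flag else 2.0 for s in signals
        },
    )
    clusters = cluster_events(matrix.without_kinds(("complex", "wgd")), cfg.tau)
    tree = build_tree(clusters, cfg.tau, samples=list(matrix.samples))
    return segments, events, ploidy, matrix, tree


def _run_regime(name: str, genome: GenomeBuild, probemap: ProbeMap,
                cfg: RunConfig, seed: int) -> RegimeResult:
    regime = REGIMES[name]()
    wt = name.startswith("WT")
    passages = WT_SAMPLED_PASSAGES if wt else KO_SAMPLED_PASSAGES
    sim = SimulationConfig(
        genome=genome, regime=regime,
        n_passages=cfg.n_passages_wt if wt else cfg.n_passages_ko,
        bottleneck_size=cfg.bottleneck_size,
        sampled_passages=tuple(p for p in passages),
        event_size_dist=cfg.event_size_dist,
        seed=seed,
    )
    truth = simulate_lineage(sim)
    signals = {
        f"{name}_P{p}": emulate_sample(
            truth, p, probemap, noise=cfg.noise,
            seed=seed + 1000 + i, sample_id=f"{name}_P{p}",
            centering=cfg.centering,
        )
        for i, p in enumerate(sim.sampled_passages)
    }
    segments, events, ploidy, matrix, tree = analyze_samples(
        signals, genome, cfg
    )
    fishplot = fishplot_layout(tree, list(sim.sampled_passages))
    counts_all = {s: count_events([e for e, _ in events[s]]) for s in signals}
    counts_large = {
        s: count_events([e for e, _ in events[s]], cfg.min_event_len)
        for s in signals
    }
    return RegimeResult(
        regime=name, truth=truth, passages=sim.sampled_passages,
        segments=segments, events=events, ploidy=ploidy, matrix=matrix,
        tree=tree, fishplot=fishplot, counts_all=counts_all,
        counts_large=counts_large,
    )


def run_all(config: RunConfig | None = None,
            outdir: str | Path | None = None,
            genome: GenomeBuild | None = None) -> PipelineResult:
    """Full pipeline over all configured regimes; optionally write outputs."""
    cfg = config or RunConfig()
    if genome is None:
        genome = (load_genome_tsv(cfg.genome_tsv) if cfg.genome_tsv
                  else GenomeBuild.default())
    probemap = make_probe_map(genome, spacing=cfg.probe_spacing,
                              het_fraction=cfg.het_fraction, seed=cfg.seed)
    regimes: dict[str, RegimeResult] = {}
    for i, name in enumerate(cfg.regimes):
        regimes[name] = _run_regime(name, genome, probemap, cfg,
                                    seed=cfg.seed + 10_000 * (i + 1))
    counts_all = {n: list(r.counts_all.values()) for n, r in regimes.items()}
    counts_large = {n: list(r.counts_large.values()) for n, r in regimes.items()}
    comparisons_all = (compare_groups(counts_all)
                       if len(regimes) >= 2 else [])
    comparisons_large = (compare_groups(counts_large)
                         if len(regimes) >= 2 else [])
    result = PipelineResult(cfg, regimes, comparisons_all, comparisons_large)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Emit the full output set: per-regime segment file, event-matrix TSV,
    tree newick + JSON, fishplot JSON, gain/loss summary TSV, the group
    comparisons, the effective config and a run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, r in result.regimes.items():
        d = out / name
        d.mkdir(exist_ok=True)
        write_segment_file(r.segments, d / "segments.tsv")
        write_clone_truth(r.truth, d / "truth.json")
        write_event_matrix(r.matrix, d / "event_matrix.tsv")
        (d / "tree.nwk").write_text(tree_to_newick(r.tree) + "\n")
        (d / "tree.json").write_text(json.dumps(tree_to_dict(r.tree), indent=2))
        (d / "fishplot.json").write_text(
            json.dumps(fishplot_to_dict(r.fishplot), indent=2)
        )
        gain_loss_summary(r.matrix).to_csv(
            d / "gain_loss_summary.tsv", sep="\t", index=False
        )
        with open(d / "ploidy.tsv", "w") as fh:
            fh.write("sample\tpsi_hat\twgd_flag\tfit_score\n")
            for s, pl in r.ploidy.items():
                fh.write(f"{s}\t{pl.psi_hat:.4g}\t{int(pl.wgd_flag)}\t"
                         f"{pl.fit_score:.6g}\n")
    comparisons_to_frame(result.comparisons_all).to_csv(
        out / "comparisons_all_events.tsv", sep="\t", index=False
    )
    comparisons_to_frame(result.comparisons_large).to_csv(
        out / "comparisons_large_events.tsv", sep="\t", index=False
    )
    result.config.to_json(out / "config.json")
    log = {
        "seed": result.config.seed,
        "versions": environment_versions(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "run.log").write_text(json.dumps(log, indent=2))


# ---------------------------------------------------------------------------
# detectability benchmark


def _loss_truth(genome: GenomeBuild, fraction: float,
                segment: GenomicSegment) -> CloneTruth:
    """Founder plus one subclone at the given fraction carrying one
    single-copy loss."""
    loss = CNAEvent("loss0", "loss", segment, -1)
    fractions = {0: {"C0": 1.0},
                 1: {"C0": round(1.0 - fraction, 12), "C1": fraction}}
    return programmed_truth(
        genome,
        {"C0": (None, []), "C1": ("C0", [loss])},
        fractions,
        sampled_passages=(1,),
    )


def detection_rates(
    fractions: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2)),
    n_replicates: int = 50,
    loss_size: int = 5_000_000,
    seed: int = 0,
    noise: tuple[float, float] = (0.15, 0.03),
    thresholds: CallThresholds | None = None,
    probe_spacing: int = 50_000,
) -> dict[float, float]:
    """Fraction of replicates in which a subclonal loss of ``loss_size`` is
    called, per clone fraction.

    One 60 Mbp chromosome carries the loss at 20-25 Mbp; each replicate
    draws a fresh probe map and noise realisation, then runs segmentation
    and event calling with default parameters.  A replicate counts as
    detected when a called loss reciprocally overlaps the true segment by
    >= 0.5 (the clone-size floor is applied inside event calling).
    """
    genome = GenomeBuild.from_pairs([("chr1", 60_000_000)])
    segment = GenomicSegment("chr1", 20_000_000, 20_000_000 + loss_size)
    th = thresholds or CallThresholds()
    rates: dict[float, float] = {}
    for i, f in enumerate(fractions):
        hits = 0
        for rep in range(n_replicates):
            rep_seed = seed + 100_000 * i + rep
            probemap = make_probe_map(genome, spacing=probe_spacing,
                                      seed=rep_seed)
            truth = _loss_truth(genome, float(f), segment)
            sig = emulate_sample(truth, 1, probemap, noise=noise,
                                 seed=rep_seed + 1)
            segs = segment_signal(sig)
            events = call_events(segs, th)
            detected = any(
                ev.kind == "loss" and ev.segment is not None
                and reciprocal_overlap(ev.segment, segment) >= 0.5
                for ev, _ in events
            )
            hits += detected
        rates[float(f)] = hits / n_replicates
    return rates


def empirical_detection_threshold(
    rates: dict[float, float], reliability: float = 0.95
) -> float | None:
    """Smallest grid fraction detected in at least ``reliability`` of
    replicates, or None if no fraction reaches it."""
    for f in sorted(rates):
        if rates[f] >= reliability:
            return f
    return None
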
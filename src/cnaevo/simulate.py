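"""Branching clonal-evolution simulator for passaged cell cultures.

Emulates a longitudinal passaging experiment: a karyotypically normal
founder population is subcultured for ``n_passages`` rounds, and at each
round every clone may acquire new copy-number alterations (mutation), clone
fractions shift by relative fitness (selection), and the population is
resampled down to the passage bottleneck (drift).  Regime presets encode
the qualitative knockout biology: a stable near-diploid regime in which
large-aberration clones rarely survive, versus a chromosomally unstable
regime with whole-genome duplication and aneuploidy tolerance in which
genome-doubled clones can sweep.

The per-passage update is discrete — mutation, then replicator-style
selection folded into a single multinomial resampling of ``bottleneck_size``
cells — which keeps an independent re-implementation of the same rules
trivial to write as a test oracle.  Events never revert (perfect
phylogeny), matching the assumption of the downstream tree reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import CNAEvent, GenomeBuild, GenomicSegment, event_length
from .matrix import EventMatrix

__all__ = [
    "RegimeConfig",
    "SimulationConfig",
    "Clone",
    "CloneTruth",
    "simulate_lineage",
    "true_mcf_matrix",
    "wt_regime",
    "rb1_like_regime",
    "cdkn2a_like_regime",
    "tp53_like_regime",
    "REGIMES",
    "WT_SAMPLED_PASSAGES",
    "KO_SAMPLED_PASSAGES",
    "programmed_truth",
]

#: Wild-type series: 7 sampled time points over 45 passages.
WT_SAMPLED_PASSAGES = (5, 10, 15, 20, 25, 35, 45)
#: Knockout series: 3 sampled time points within the stable culture window.
KO_SAMPLED_PASSAGES = (8, 16, 24)


@dataclass(frozen=True)
class RegimeConfig:
    """Knockout-specific evolutionary regime.

    ``event_rate`` is the Poisson mean of new CNAs per clone per passage;
    ``wgd_prob`` the per-clone per-passage probability of spawning a
    genome-doubled child; ``kind_weights`` the (gain, loss, cnloh) mix;
    ``fitness_mean``/``fitness_sd`` parameterise the multiplicative
    per-event fitness factor; ``aneuploidy_tolerance`` multiplies the
    survival weight of clones carrying at least one large (>= 1 Mbp)
    aberration; ``wgd_fitness`` multiplies fitness on genome doubling.
    """

    name: str
    event_rate: float = 0.05
    wgd_prob: float = 0.0
    kind_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    fitness_mean: float = 1.0
    fitness_sd: float = 0.10
    aneuploidy_tolerance: float = 1.0
    wgd_fitness: float = 1.0
    complex_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.event_rate < 0 or not (0.0 <= self.wgd_prob <= 1.0):
            raise ValueError("rates must be >= 0 and wgd_prob in [0, 1]")
        if abs(sum(self.kind_weights) - 1.0) > 1e-9 or min(self.kind_weights) < 0:
            raise ValueError("kind_weights must be non-negative and sum to 1")
        if self.aneuploidy_tolerance < 0 or not (0.0 <= self.complex_prob <= 1.0):
            raise ValueError("invalid tolerance or complex_prob")


def wt_regime() -> RegimeConfig:
    """Intrinsic instability of an immortalized near-diploid line: rare
    events, near-neutral fitness with enough spread for occasional sweeps."""
    return RegimeConfig("WT-like", event_rate=0.05, fitness_mean=1.0,
                        fitness_sd=0.10, aneuploidy_tolerance=1.0)


def rb1_like_regime() -> RegimeConfig:
    """Checkpoint knockout without aneuploidy tolerance: aberrant clones
    arise but essentially never persist as detectable populations."""
    return RegimeConfig("RB1-like", event_rate=0.05, fitness_mean=0.85,
                        fitness_sd=0.05, aneuploidy_tolerance=0.05)


def cdkn2a_like_regime() -> RegimeConfig:
    return replace(rb1_like_regime(), name="CDKN2A-like")


def tp53_like_regime() -> RegimeConfig:
    """Unstable regime: frequent events, whole-genome duplication with a
    fitness premium, tolerance of large aberrations — genome-doubled clones
    sweep and accumulate further segmental changes."""
    return RegimeConfig("TP53-like", event_rate=0.4, wgd_prob=0.05,
                        fitness_mean=1.02, fitness_sd=0.12,
                        aneuploidy_tolerance=1.2, wgd_fitness=2.0,
                        complex_prob=0.05)


REGIMES = {
    "WT-like": wt_regime,
    "RB1-like": rb1_like_regime,
    "CDKN2A-like": cdkn2a_like_regime,
    "TP53-like": tp53_like_regime,
}


@dataclass(frozen=True)
class SimulationConfig:
    genome: GenomeBuild
    regime: RegimeConfig
    n_passages: int = 45
    bottleneck_size: int = 1000
    sampled_passages: tuple[int, ...] = WT_SAMPLED_PASSAGES
    event_size_dist: tuple[float, float] = (50_000.0, 50_000_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genome.chromosomes:
            raise ValueError("empty genome")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        bad = [p for p in self.sampled_passages if not (1 <= p <= self.n_passages)]
        if bad:
            raise ValueError(f"sampled_passages outside [1, n_passages]: {bad}")
        lo, hi = self.event_size_dist
        if not (0 < lo <= hi):
            raise ValueError("event_size_dist must satisfy 0 < lo <= hi")


@dataclass
class Clone:
    clone_id: str
    parent_id: str | None
    new_events: tuple[str, ...]  # event ids acquired on the branch into this clone
    fitness: float


@dataclass
class CloneTruth:
    """Ground truth of a simulated (or hand-programmed) lineage.

    ``fractions[p][clone_id]`` is the clone's population fraction after
    passage ``p`` (passage 0 = founder at 1.0); absent ids are extinct.
    ``event_haplotype`` records which homolog each segmental event hit
    (needed to emulate allele-specific array signal).
    """

    genome: GenomeBuild
    clones: list[Clone]
    events: dict[str, CNAEvent]
    event_haplotype: dict[str, int]
    fractions: dict[int, dict[str, float]]
    sampled_passages: tuple[int, ...]

    def __post_init__(self) -> None:
        self._by_id = {c.clone_id: c for c in self.clones}
        for p, fr in self.fractions.items():
            tot = sum(fr.values())
            if fr and abs(tot - 1.0) > 1e-9:
                raise ValueError(f"fractions at passage {p} sum to {tot}")

    def clone(self, clone_id: str) -> Clone:
        return self._by_id[clone_id]

    def lineage_events(self, clone_id: str) -> list[str]:
        """Event ids along the root-to-clone path, in acquisition order."""
        path: list[Clone] = []
        cur: str | None = clone_id
        while cur is not None:
            c = self._by_id[cur]
            path.append(c)
            cur = c.parent_id
        out: list[str] = []
        for c in reversed(path):
            out.extend(c.new_events)
        return out

    def true_mcf(self, event_id: str, passage: int) -> float:
        """MCF of an event = summed fraction of clones carrying it."""
        if passage not in self.fractions:
            raise KeyError(f"passage {passage} was not simulated")
        total = 0.0
        for cid, frac in self.fractions[passage].items():
            if frac > 0 and event_id in self._carried(cid):
                total += frac
        return total

    def _carried(self, clone_id: str) -> frozenset[str]:
        cache = getattr(self, "_carried_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_carried_cache", cache)
        if clone_id not in cache:
            c = self._by_id[clone_id]
            base = self._carried(c.parent_id) if c.parent_id else frozenset()
            cache[clone_id] = base | frozenset(c.new_events)
        return cache[clone_id]

    def events_carried(self, clone_id: str) -> frozenset[str]:
        return self._carried(clone_id)

    def surviving_events(self, passages: tuple[int, ...] | None = None) -> list[str]:
        """Events with MCF > 0 at any of the given (default: sampled) passages,
        in acquisition order."""
        passages = passages or self.sampled_passages
        seen: list[str] = []
        for p in passages:
            for cid, frac in self.fractions[p].items():
                if frac <= 0:
                    continue
                for eid in self.lineage_events(cid):
                    if eid not in seen:
                        seen.append(eid)
        return seen


def _draw_event(
    rng: np.random.Generator,
    genome: GenomeBuild,
    size_dist: tuple[float, float],
    kind_weights: tuple[float, float, float],
    complex_prob: float,
    occupied: dict[int, list[GenomicSegment]],
    event_id: str,
    max_tries: int = 30,
) -> tuple[CNAEvent, int] | None:
    """One segmental event placed uniformly, avoiding the clone's existing
    events on the same haplotype.  Returns None if placement fails."""
    lo, hi = size_dist
    kinds = ("gain", "loss", "cnloh")
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    for _ in range(max_tries):
        kind = kinds[rng.choice(3, p=np.asarray(kind_weights))]
        if complex_prob > 0 and rng.random() < complex_prob:
            kind = "complex"
        size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        name, clen = genome.chromosomes[ci]
        if size >= clen:
            continue
        start = int(rng.integers(0, clen - size))
        seg = GenomicSegment(name, start, start + size)
        hap = int(rng.integers(0, 2))
        if any(seg.overlap_bp(s) > 0 for s in occupied.get(hap, [])):
            continue
        delta = {"gain": 1, "loss": -1}.get(kind, 0)
        return CNAEvent(event_id, kind, seg, delta), hap
    return None


def simulate_lineage(config: SimulationConfig) -> CloneTruth:
    """Run the mutation -> selection -> drift passaging loop.

    Deterministic given ``config.seed``.  Selection and drift are folded
    into one multinomial draw: cell counts at passage p+1 are
    Multinomial(bottleneck_size, p_i) with p_i proportional to
    count_i * w_i, where w_i is the clone's survival weight (multiplicative
    event fitness, times the aneuploidy-tolerance factor for clones
    carrying a large event).
    """
    rng = np.random.default_rng(config.seed)
    regime = config.regime
    genome = config.genome

    founder = Clone("C0", None, (), 1.0)
    clones: list[Clone] = [founder]
    by_id = {"C0": founder}
    events: dict[str, CNAEvent] = {}
    event_hap: dict[str, int] = {}
    counts: dict[str, int] = {"C0": config.bottleneck_size}
    # per clone: segments occupied per haplotype, has-large-event flag, wgd flag
    occupied: dict[str, dict[int, list[GenomicSegment]]] = {"C0": {0: [], 1: []}}
    has_large: dict[str, bool] = {"C0": False}
    has_wgd: dict[str, bool] = {"C0": False}
    fractions: dict[int, dict[str, float]] = {
        0: {"C0": 1.0}
    }
    next_event = 0
    next_clone = 1

    for passage in range(1, config.n_passages + 1):
        # --- mutation: each surviving clone may spawn at most one CNA child
        # and, independently, one genome-doubled child per passage.
        for cid in [c for c, n in counts.items() if n >= 1]:
            parent = by_id[cid]
            if regime.wgd_prob > 0 and not has_wgd[cid] and counts[cid] >= 1:
                if rng.random() < regime.wgd_prob:
                    eid = f"E{next_event}"
                    next_event += 1
                    events[eid] = CNAEvent(eid, "wgd")
                    child = Clone(
                        f"C{next_clone}", cid, (eid,),
                        parent.fitness * regime.wgd_fitness,
                    )
                    next_clone += 1
                    clones.append(child)
                    by_id[child.clone_id] = child
                    occupied[child.clone_id] = {
                        0: list(occupied[cid][0]), 1: list(occupied[cid][1])
                    }
                    has_large[child.clone_id] = has_large[cid]
                    has_wgd[child.clone_id] = True
                    counts[child.clone_id] = 1
                    counts[cid] -= 1
            if counts[cid] < 1:
                continue
            k = int(rng.poisson(regime.event_rate))
            if k < 1:
                continue
            child_occ = {0: list(occupied[cid][0]), 1: list(occupied[cid][1])}
            new_ids: list[str] = []
            fitness = parent.fitness
            large = has_large[cid]
            for _ in range(k):
                drawn = _draw_event(
                    rng, genome, config.event_size_dist, regime.kind_weights,
                    regime.complex_prob, child_occ, f"E{next_event}",
                )
                if drawn is None:
                    continue
                ev, hap = drawn
                next_event += 1
                events[ev.event_id] = ev
                event_hap[ev.event_id] = hap
                child_occ[hap].append(ev.segment)  # type: ignore[arg-type]
                if ev.kind == "cnloh":
                    # cn-LOH rewrites both homologs over the segment
                    child_occ[1 - hap].append(ev.segment)  # type: ignore[arg-type]
                new_ids.append(ev.event_id)
                factor = max(0.05, rng.normal(regime.fitness_mean, regime.fitness_sd))
                fitness *= factor
                if event_length(ev) >= 1_000_000:
                    large = True
            if not new_ids:
                continue
            child = Clone(f"C{next_clone}", cid, tuple(new_ids), fitness)
            next_clone += 1
            clones.append(child)
            by_id[child.clone_id] = child
            occupied[child.clone_id] = child_occ
            has_large[child.clone_id] = large
            has_wgd[child.clone_id] = has_wgd[cid]
            counts[child.clone_id] = 1
            counts[cid] -= 1
            if counts[cid] < 1:
                del counts[cid]

        # --- selection + drift: one multinomial over fitness-weighted counts
        ids = [c for c, n in counts.items() if n >= 1]
        weights = np.array(
            [
                counts[c] * by_id[c].fitness
                * (regime.aneuploidy_tolerance if has_large[c] else 1.0)
                for c in ids
            ],
            dtype=float,
        )
        if weights.sum() <= 0:
            weights = np.array([float(counts[c]) for c in ids])
        new_counts = rng.multinomial(config.bottleneck_size, weights / weights.sum())
        counts = {c: int(n) for c, n in zip(ids, new_counts) if n >= 1}
        fractions[passage] = {
            c: n / config.bottleneck_size for c, n in counts.items()
        }

    return CloneTruth(
        genome=genome,
        clones=clones,
        events=events,
        event_haplotype=event_hap,
        fractions=fractions,
        sampled_passages=tuple(config.sampled_passages),
    )


def true_mcf_matrix(
    truth: CloneTruth, sampled_passages: tuple[int, ...] | None = None
) -> EventMatrix:
    """Ground-truth MCF matrix over the sampled passages.

    Rows are events with MCF > 0 in at least one sample; sample ids are
    ``P<passage>``.  Founder-branch events have MCF 1.0 everywhere.
    """
    passages = tuple(sampled_passages or truth.sampled_passages)
    for p in passages:
        if p not in truth.fractions:
            raise KeyError(f"passage {p} was not simulated")
    event_ids = truth.surviving_events(passages)
    rows = []
    kept: list[CNAEvent] = []
    for eid in event_ids:
        vals = [truth.true_mcf(eid, p) for p in passages]
        if max(vals) > 0:
            kept.append(truth.events[eid])
            rows.append(vals)
    mcf = np.array(rows, dtype=float) if rows else np.empty((0, len(passages)))
    return EventMatrix(kept, [f"P{p}" for p in passages], mcf)


def programmed_truth(
    genome: GenomeBuild,
    clone_events: dict[str, tuple[str | None, list[CNAEvent]]],
    fractions: dict[int, dict[str, float]],
    event_haplotype: dict[str, int] | None = None,
    sampled_passages: tuple[int, ...] | None = None,
) -> CloneTruth:
    """Hand-build a :class:`CloneTruth` with explicit clones and fractions.

    ``clone_events`` maps clone_id -> (parent_id, events acquired on its
    branch); ``fractions`` maps passage -> clone fractions.  Used to state
    exact scenarios (a programmed sweep, a single subclone at fraction f)
    without running the stochastic loop.
    """
    clones = []
    events: dict[str, CNAEvent] = {}
    for cid, (parent, evs) in clone_events.items():
        clones.append(Clone(cid, parent, tuple(e.event_id for e in evs), 1.0))
        for e in evs:
            events[e.event_id] = e
    hap = dict(event_haplotype or {})
    for eid, ev in events.items():
        if ev.kind != "wgd":
            hap.setdefault(eid, 0)
    passages = sampled_passages or tuple(sorted(fractions))
    return CloneTruth(
        genome=genome,
        clones=clones,
        events=events,
        event_haplotype=hap,
        fractions=fractions,
        sampled_passages=tuple(passages),
    )
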
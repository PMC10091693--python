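"""Clonal dynamics layout and group statistics.

Fishplot layout turns a subclone tree plus per-passage MCF profiles into
nested band data (cumulative and own fractions per clone per timepoint,
with linear interpolation between sampled passages).  Event-count
statistics compare knockout groups with the Wilcoxon rank-sum test —
exactly, by complete enumeration of rank assignments, for small groups —
with Holm adjustment across the requested pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import CNAEvent, size_filter
from .matrix import EventMatrix
from .phylo import ROOT_ID, SubcloneTree, clone_proportions

__all__ = [
    "FishplotData",
    "GroupComparison",
    "fishplot_layout",
    "count_events",
    "ranksum_test",
    "compare_groups",
    "gain_loss_summary",
    "plot_fishplot",
    "EXACT_ENUMERATION_MAX_N",
]

#: Complete enumeration of rank assignments is used up to this combined n.
EXACT_ENUMERATION_MAX_N = 12


@dataclass
class FishplotData:
    """Nested clone-band layout over sampled passages.

    ``cumulative[node]`` is the node's MCF profile (its band including all
    descendants); ``own[node]`` the non-nested fraction from
    :func:`cnaevo.phylo.clone_proportions`.  ``interp_*`` carry per-passage
    linear interpolation for plotting.
    """

    timepoints: list[int]
    nodes: list[str]
    parents: dict[str, str | None]
    cumulative: dict[str, np.ndarray]
    own: dict[str, np.ndarray]
    emergence: dict[str, int | None]
    interp_passages: np.ndarray
    interp_cumulative: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        totals = np.sum([self.own[n] for n in self.nodes], axis=0)
        if np.any(np.abs(totals - 1.0) > 1e-6):
            raise ValueError("own fractions must sum to 1 at every timepoint")
        for n in self.nodes:
            p = self.parents[n]
            if p is not None and np.any(
                self.cumulative[n] > self.cumulative[p] + 1e-6
            ):
                raise ValueError(f"band of {n} exceeds its parent {p}")


def fishplot_layout(
    tree: SubcloneTree, passages: Sequence[int]
) -> FishplotData:
    """Fishplot layout for a tree whose samples are a passage series.

    ``passages[j]`` is the passage number of ``tree.samples[j]`` (must be
    strictly increasing).  A node's emergence is the first sampled passage
    with cumulative fraction > 0.
    """
    if len(passages) != len(tree.samples):
        raise ValueError("one passage number per tree sample required")
    pts = [int(p) for p in passages]
    if any(b <= a for a, b in zip(pts, pts[1:])):
        raise ValueError("passages must be strictly increasing")
    nodes = [n.node_id for n in tree.nodes]
    parents = {n.node_id: n.parent_id for n in tree.nodes}
    cumulative = {
        n.node_id: (np.ones(len(pts)) if n.is_root else n.profile.copy())
        for n in tree.nodes
    }
    own_rows = [clone_proportions(tree, s) for s in tree.samples]
    own = {nid: np.array([row[nid] for row in own_rows]) for nid in nodes}
    emergence = {}
    for nid in nodes:
        pos = np.nonzero(cumulative[nid] > 0)[0]
        emergence[nid] = pts[pos[0]] if len(pos) else None
    grid = np.arange(pts[0], pts[-1] + 1)
    interp = {
        nid: np.interp(grid, pts, cumulative[nid]) for nid in nodes
    }
    return FishplotData(
        timepoints=pts, nodes=nodes, parents=parents, cumulative=cumulative,
        own=own, emergence=emergence, interp_passages=grid,
        interp_cumulative=interp,
    )


def count_events(
    events: Sequence[CNAEvent], min_len: int | None = None
) -> int:
    """Number of events in one sample; with ``min_len``, only events of at
    least that size (genome-wide wgd always counts as one event)."""
    if min_len is None:
        return len(events)
    return len(size_filter(events, min_len))


# ---------------------------------------------------------------------------
# rank-sum statistics


@dataclass
class GroupComparison:
    group1: str
    group2: str
    n1: int
    n2: int
    w: float                 # rank-sum of group 1 (midranks under ties)
    p_two_sided: float
    exact_flag: bool
    p_holm: float | None = None

    def __post_init__(self) -> None:
        w_min = self.n1 * (self.n1 + 1) / 2.0
        w_max = self.n1 * (self.n1 + 2 * self.n2 + 1) / 2.0
        if not (w_min - 1e-9 <= self.w <= w_max + 1e-9):
            raise ValueError(f"W={self.w} outside [{w_min}, {w_max}]")
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError("p must be in (0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def ranksum_test(
    xs: Sequence[float], ys: Sequence[float],
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test; W is the rank-sum of ``xs``.

    For combined n <= 12 the null distribution of W is enumerated
    completely over all C(n1+n2, n1) assignments of the observed midranks
    (exact even under ties); otherwise the normal approximation with tie
    and continuity correction is used.  Two-sided p is
    min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    ranks = _midranks(np.concatenate([xs, ys]))
    w = float(ranks[:n1].sum())
    n = n1 + n2
    if n <= EXACT_ENUMERATION_MAX_N:
        sums = np.array([
            sum(ranks[list(c)]) for c in itertools.combinations(range(n), n1)
        ])
        lo = float(np.mean(sums <= w + 1e-9))
        hi = float(np.mean(sums >= w - 1e-9))
        p = min(1.0, 2.0 * min(lo, hi))
        exact = True
    else:
        mu = n1 * (n + 1) / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
        exact = False
    p = max(p, np.finfo(float).tiny)
    return GroupComparison(labels[0], labels[1], n1, n2, w, p, exact)


def _holm(ps: list[float]) -> list[float]:
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def compare_groups(
    counts_by_group: dict[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Pairwise rank-sum tests with Holm adjustment across the pairs.

    ``pairs`` defaults to all unordered group pairs in input order.  Each
    result carries both the raw and the Holm-adjusted two-sided p.
    """
    groups = list(counts_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if pairs is None:
        pairs = list(itertools.combinations(groups, 2))
    results = [
        ranksum_test(counts_by_group[a], counts_by_group[b], labels=(a, b))
        for a, b in pairs
    ]
    for r, p_adj in zip(results, _holm([r.p_two_sided for r in results])):
        r.p_holm = p_adj
    return results


def plot_fishplot(fp: FishplotData, ax=None):
    """Render a simple fishplot (stacked, nested clone bands over passages).

    Bands use the linearly interpolated cumulative fractions; each node's
    band is drawn inside its parent's.  Returns the matplotlib axes.
    Rendering is optional — everything else in this module is plain data.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = fp.interp_passages
    depth = {}
    for n in fp.nodes:
        d, p = 0, fp.parents[n]
        while p is not None:
            d, p = d + 1, fp.parents[p]
        depth[n] = d
    cmap = plt.get_cmap("viridis")
    order = sorted(fp.nodes, key=lambda n: depth[n])
    for i, n in enumerate(order):
        cum = fp.interp_cumulative[n]
        ax.fill_between(x, -cum / 2, cum / 2,
                        color=cmap(i / max(len(order) - 1, 1)),
                        alpha=0.8, label=n)
    ax.set_xlabel("passage")
    ax.set_yticks([])
    ax.legend(fontsize=7, ncol=2)
    return ax


def gain_loss_summary(matrix: EventMatrix) -> pd.DataFrame:
    """Per-chromosome gain/loss burden across samples (circos stand-in).

    One row per (chromosome, kind in gain/loss/cnloh): number of distinct
    events, total affected bp, and the number of samples with MCF > 0.
    """
    rows = []
    for i, ev in enumerate(matrix.events):
        if ev.segment is None or ev.kind not in ("gain", "loss", "cnloh"):
            continue
        vals = np.nan_to_num(matrix.mcf[i], nan=0.0)
        rows.append({
            "chrom": ev.segment.chrom,
            "kind": ev.kind,
            "n_events": 1,
            "total_bp": ev.segment.length,
            "n_samples": int(np.sum(vals > 0)),
        })
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "kind", "n_events", "total_bp", "n_samples"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["chrom", "kind"], as_index=False)
        .agg({"n_events": "sum", "total_bp": "sum", "n_samples": "max"})
    )
    return out
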
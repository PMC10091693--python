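"""Subclone tree reconstruction from the event x sample MCF matrix.

Events with indistinguishable MCF profiles are clustered (complete linkage,
Chebyshev distance, cut at tau) into candidate branches; branches are then
attached under two constraint families that any valid subclonal structure
must satisfy at tolerance tau in every sample:

* containment — a descendant's MCF cannot exceed its ancestor's, and
* pigeonhole — sibling branches' MCFs cannot sum beyond their parent's.

Construction is greedy (stem clusters chain under the normal root, the rest
attach to the closest feasible ancestor in descending-MCF order), with an
exhaustive enumeration oracle for small instances: the greedy output is
always one of the trees the constraints admit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .genome import CNAEvent
from .matrix import EventMatrix

__all__ = [
    "EventCluster",
    "SubcloneNode",
    "SubcloneTree",
    "cluster_events",
    "build_tree",
    "enumerate_trees",
    "clone_proportions",
    "detect_replacement",
    "DEFAULT_TAU",
]

logger = logging.getLogger(__name__)

#: MCF tolerance for clustering and constraint checks; matches the ~10%
#: clone-size detectability scale of array data.
DEFAULT_TAU = 0.10

ROOT_ID = "root"


@dataclass
class EventCluster:
    """A set of events with a shared MCF profile (one candidate branch)."""

    events: list[CNAEvent]
    profile: np.ndarray  # per-sample consensus MCF (median over members)
    samples: list[str]

    @property
    def key(self) -> frozenset[str]:
        return frozenset(e.event_id for e in self.events)


@dataclass
class SubcloneNode:
    node_id: str
    parent_id: str | None
    events: list[CNAEvent]
    profile: np.ndarray  # per-sample MCF; root profile is all-ones

    @property
    def is_root(self) -> bool:
        return self.parent_id is None


@dataclass
class SubcloneTree:
    nodes: list[SubcloneNode]
    samples: list[str]
    unplaced: list[CNAEvent] = field(default_factory=list)
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        self._by_id = {n.node_id: n for n in self.nodes}
        roots = [n for n in self.nodes if n.is_root]
        if len(roots) != 1 or roots[0].node_id != ROOT_ID:
            raise ValueError("tree must have exactly one root node 'root'")
        self._check_constraints()

    def node(self, node_id: str) -> SubcloneNode:
        return self._by_id[node_id]

    def children(self, node_id: str) -> list[SubcloneNode]:
        return [n for n in self.nodes if n.parent_id == node_id]

    def ancestors(self, node_id: str) -> list[str]:
        out = []
        cur = self._by_id[node_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self._by_id[cur].parent_id
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if a is a (strict) ancestor of b."""
        return a in self.ancestors(b)

    def parent_map(self) -> dict[frozenset[str], frozenset[str] | None]:
        """Cluster-level topology keyed by event-id sets (root = None)."""
        key = {
            n.node_id: frozenset(e.event_id for e in n.events)
            for n in self.nodes if not n.is_root
        }
        out: dict[frozenset[str], frozenset[str] | None] = {}
        for n in self.nodes:
            if n.is_root:
                continue
            out[key[n.node_id]] = (
                None if n.parent_id == ROOT_ID else key[n.parent_id]
            )
        return out

    def _check_constraints(self) -> None:
        tol = self.tau + 1e-9
        for n in self.nodes:
            if n.is_root:
                continue
            parent = self._by_id[n.parent_id]
            if np.any(parent.profile < n.profile - tol):
                raise ValueError(
                    f"containment violated on edge {parent.node_id}->{n.node_id}"
                )
        for n in self.nodes:
            kids = self.children(n.node_id)
            if kids:
                total = np.sum([k.profile for k in kids], axis=0)
                if np.any(total > n.profile + tol):
                    raise ValueError(f"pigeonhole violated at node {n.node_id}")

    def ancestor_descendant_pairs(self) -> set[tuple[str, str]]:
        """All (ancestor event id, descendant event id) pairs implied by the
        tree, over placed events on distinct nodes."""
        pairs: set[tuple[str, str]] = set()
        for n in self.nodes:
            if n.is_root:
                continue
            anc_events: list[str] = []
            for aid in self.ancestors(n.node_id):
                anc_events.extend(e.event_id for e in self._by_id[aid].events)
            for e in n.events:
                for a in anc_events:
                    pairs.add((a, e.event_id))
        return pairs


# ---------------------------------------------------------------------------


def _genome_order_key(ev: CNAEvent):
    if ev.segment is None:
        return ("", -1, -1)
    return (ev.segment.chrom, ev.segment.start, ev.segment.end)


def cluster_events(matrix: EventMatrix, tau: float = DEFAULT_TAU) -> list[EventCluster]:
    """Complete-linkage agglomeration of event MCF profiles under Chebyshev
    distance, cut at ``tau``; ties resolved by genome position ordering.

    Cluster profiles are per-sample medians of member events.
    """
    if not (0.0 < tau < 0.5):
        raise ValueError("tau must be in (0, 0.5)")
    if matrix.n_events == 0:
        return []
    order = sorted(range(matrix.n_events),
                   key=lambda i: _genome_order_key(matrix.events[i]))
    x = np.nan_to_num(matrix.mcf[order], nan=0.0)
    if len(order) == 1:
        labels = np.array([1])
    else:
        link = sch.linkage(pdist(x, metric="chebyshev"), method="complete")
        labels = sch.fcluster(link, t=tau, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for idx, lab in zip(order, labels):
        clusters.setdefault(int(lab), []).append(idx)
    out = []
    for members in clusters.values():
        members = sorted(members, key=lambda i: _genome_order_key(matrix.events[i]))
        prof = np.median(np.nan_to_num(matrix.mcf[members], nan=0.0), axis=0)
        out.append(EventCluster(
            events=[matrix.events[i] for i in members],
            profile=prof,
            samples=list(matrix.samples),
        ))
    # deterministic cluster order: by first member's genome position
    out.sort(key=lambda c: _genome_order_key(c.events[0]))
    return out


def _feasible_parent(parent_prof: np.ndarray, child_prof: np.ndarray,
                     tau: float) -> bool:
    return bool(np.all(parent_prof >= child_prof - tau - 1e-12))


def build_tree(
    clusters: list[EventCluster],
    tau: float = DEFAULT_TAU,
    samples: list[str] | None = None,
) -> SubcloneTree:
    """Greedy MCF-constrained tree construction.

    Stem clusters (MCF >= 1 - tau in every sample) chain directly under the
    normal root in descending-mean order.  Remaining clusters attach, in
    descending mean-MCF order, to the candidate parent that satisfies
    containment and post-attachment pigeonhole and minimizes the summed
    profile gap (the closest feasible ancestor); ties break toward the
    candidate whose first event is earliest in genome order.  Clusters with
    no feasible parent are reported as unplaced, never dropped silently.
    """
    if samples is None:
        samples = clusters[0].samples if clusters else []
    n_samples = len(samples)
    root = SubcloneNode(ROOT_ID, None, [], np.ones(n_samples))
    nodes = [root]
    children: dict[str, list[SubcloneNode]] = {ROOT_ID: []}
    unplaced: list[CNAEvent] = []

    stems = [c for c in clusters if np.all(c.profile >= 1.0 - tau - 1e-12)]
    rest = [c for c in clusters if not np.all(c.profile >= 1.0 - tau - 1e-12)]
    stems.sort(key=lambda c: (-float(np.mean(c.profile)),
                              _genome_order_key(c.events[0])))
    rest.sort(key=lambda c: (-float(np.mean(c.profile)),
                             _genome_order_key(c.events[0])))

    tip = root
    for i, c in enumerate(stems):
        node = SubcloneNode(f"N{len(nodes)}", tip.node_id, list(c.events),
                            c.profile.copy())
        nodes.append(node)
        children.setdefault(node.node_id, [])
        children[tip.node_id].append(node)
        tip = node

    def pigeonhole_ok(parent: SubcloneNode, prof: np.ndarray) -> bool:
        total = prof.copy()
        for kid in children.get(parent.node_id, []):
            total = total + kid.profile
        return bool(np.all(total <= parent.profile + tau + 1e-12))

    for c in rest:
        candidates = []
        for p in nodes:
            if _feasible_parent(p.profile, c.profile, tau) and pigeonhole_ok(p, c.profile):
                gap = float(np.sum(p.profile - c.profile))
                first = (_genome_order_key(p.events[0]) if p.events
                         else ("", -1, -1))
                candidates.append((gap, first, p))
        if not candidates:
            unplaced.extend(c.events)
            logger.warning(
                "cluster %s unplaceable under containment/pigeonhole",
                sorted(e.event_id for e in c.events),
            )
            continue
        candidates.sort(key=lambda t: (t[0], t[1]))
        parent = candidates[0][2]
        node = SubcloneNode(f"N{len(nodes)}", parent.node_id, list(c.events),
                            c.profile.copy())
        nodes.append(node)
        children.setdefault(node.node_id, [])
        children[parent.node_id].append(node)

    return SubcloneTree(nodes=nodes, samples=samples, unplaced=unplaced, tau=tau)


def enumerate_trees(
    clusters: list[EventCluster], tau: float = DEFAULT_TAU, max_clusters: int = 7
) -> list[dict[frozenset[str], frozenset[str] | None]]:
    """All rooted trees over the clusters satisfying containment and
    pigeonhole, as cluster-keyed parent maps (root parent = None).

    Exhaustive: every cluster picks a parent among {root, other clusters}
    with containment pruning, then acyclicity and pigeonhole are checked.
    Refuses more than ``max_clusters`` clusters (combinatorial guard).
    """
    n = len(clusters)
    if n > max_clusters:
        raise ValueError(f"refusing to enumerate over {n} > {max_clusters} clusters")
    if n == 0:
        return [{}]
    keys = [c.key for c in clusters]
    n_samples = len(clusters[0].profile)
    root_prof = np.ones(n_samples)
    feasible: list[list[int]] = []  # parent index; -1 = root
    for i, c in enumerate(clusters):
        opts = [-1] if _feasible_parent(root_prof, c.profile, tau) else []
        for j, p in enumerate(clusters):
            if i != j and _feasible_parent(p.profile, c.profile, tau):
                opts.append(j)
        feasible.append(opts)

    out = []
    for assignment in itertools.product(*feasible):
        # acyclicity: follow parents from each node; depth bounded by n
        ok = True
        for i in range(n):
            seen = set()
            cur = i
            while cur != -1:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = assignment[cur]
            if not ok:
                break
        if not ok:
            continue
        # pigeonhole at every node including root
        sums: dict[int, np.ndarray] = {}
        for i, p in enumerate(assignment):
            sums[p] = sums.get(p, np.zeros(n_samples)) + clusters[i].profile
        for p, total in sums.items():
            prof = root_prof if p == -1 else clusters[p].profile
            if np.any(total > prof + tau + 1e-12):
                ok = False
                break
        if not ok:
            continue
        out.append({
            keys[i]: (None if assignment[i] == -1 else keys[assignment[i]])
            for i in range(n)
        })
    return out


def clone_proportions(tree: SubcloneTree, sample: str) -> dict[str, float]:
    """Own (non-nested) cell fraction of every node in one sample.

    own(node) = node MCF minus its children's summed MCFs, clipped at 0;
    the root's own fraction is the residual wild-type compartment.  If
    clipping distorted the total it is renormalized to sum to 1.
    """
    j = tree.samples.index(sample)
    own: dict[str, float] = {}
    for n in tree.nodes:
        kid_total = sum(k.profile[j] for k in tree.children(n.node_id))
        base = 1.0 if n.is_root else n.profile[j]
        own[n.node_id] = max(0.0, base - kid_total)
    total = sum(own.values())
    if abs(total - 1.0) > 1e-9 and total > 0:
        logger.warning(
            "clone proportions in %s sum to %.4f after clipping; renormalizing",
            sample, total,
        )
        own = {k: v / total for k, v in own.items()}
    return own


def detect_replacement(
    tree: SubcloneTree,
    proportions_by_passage: dict[int, dict[str, float]],
) -> int | None:
    """Earliest passage at which the dominant lineage is replaced.

    The dominant node of a passage is the node with the largest own
    fraction (ties break toward the shallower node).  A replacement is the
    first passage whose dominant node is on a different lineage than the
    previous dominant — neither its ancestor nor its descendant (nor the
    same node).  Returns the passage number, or None.
    """
    if len(proportions_by_passage) < 2:
        raise ValueError("need at least two sampled passages")
    depth = {n.node_id: len(tree.ancestors(n.node_id)) for n in tree.nodes}

    def dominant(props: dict[str, float]) -> str:
        return min(props, key=lambda k: (-props[k], depth[k]))

    passages = sorted(proportions_by_passage)
    prev = dominant(proportions_by_passage[passages[0]])
    for p in passages[1:]:
        cur = dominant(proportions_by_passage[p])
        if cur != prev and not tree.is_ancestor(cur, prev) \
                and not tree.is_ancestor(prev, cur):
            return p
        prev = cur
    return None
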
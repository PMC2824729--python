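"""Network motifs in the domain interaction network.

A motif is a small connected subgraph shape that occurs in the real network
significantly more often than in degree-preserving randomized networks.
Three stages:

1. **Census** — every connected induced subgraph of size 3 or 4 is
   enumerated exactly once with the ESU algorithm and grouped by
   isomorphism class (canonicalization by brute force over the at most 4!
   node orderings, cheap at these sizes).
2. **Null model** — the network is repeatedly rewired by double edge swaps
   (u-v, x-y → u-x, v-y), which conserve every node's degree exactly;
   swaps that would create a self-loop or parallel edge are rejected and
   redrawn.
3. **Significance** — for each class, the one-sided empirical p-value of
   over-representation is (1 + #{null counts >= real}) / (iterations + 1),
   with a z-score against the null mean/sd for effect size.

Instances of significant classes that contain functionally unannotated
domains are then annotated via Pfam2GO-style process labels: the majority
process among the labeled members is proposed as the unannotated member's
function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MotifClass",
    "MotifResult",
    "MotifAnnotation",
    "canonical_form",
    "enumerate_subgraphs",
    "randomize_network",
    "motif_significance",
    "annotate_motif",
    "MOTIF_NAMES",
]

# human-readable labels for the connected classes on 3 and 4 nodes,
# keyed by canonical form (computed at import; see _build_names below)
MOTIF_NAMES: dict[tuple[int, int], str] = {}


@dataclass(frozen=True)
class MotifClass:
    """An isomorphism class of connected undirected subgraphs."""

    size: int
    canonical_form: int  # bitmask over the upper triangle, minimized over orderings

    @property
    def name(self) -> str:
        return MOTIF_NAMES.get(
            (self.size, self.canonical_form),
            f"size{self.size}_form{self.canonical_form}",
        )


@dataclass
class MotifResult:
    motif: MotifClass
    real_count: int
    null_counts: list[int]
    null_mean: float
    null_sd: float
    z_score: float | None
    p_value: float
    significant: bool


@dataclass
class MotifAnnotation:
    """Process labels for one motif instance and the inferred function."""

    instance: frozenset[str]
    processes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    predicted_function: tuple[str, ...] = ("unknown",)


def _edge_bit(i: int, j: int, size: int) -> int:
    """Bit index of the (i<j) pair in a fixed upper-triangle ordering."""
    if i > j:
        i, j = j, i
    # pairs ordered (0,1),(0,2),...,(0,s-1),(1,2),...
    return i * size - i * (i + 1) // 2 + (j - i - 1)


def canonical_form(nodes: Sequence, adjacency) -> int:
    """Canonical bitmask of the induced subgraph on ``nodes``.

    ``adjacency(u, v)`` must return truthy iff u-v is an edge.  The mask is
    minimized over all node orderings, so isomorphic subgraphs map to the
    same integer; with at most 4 nodes the 24 permutations are trivial.
    """
    size = len(nodes)
    best = None
    for perm in permutations(range(size)):
        mask = 0
        for a, b in combinations(range(size), 2):
            if adjacency(nodes[perm.index(a)], nodes[perm.index(b)]):
                mask |= 1 << _edge_bit(a, b, size)
        if best is None or mask < best:
            best = mask
    return best or 0


def _canonical_of_nodes(g: nx.Graph, nodes: Sequence) -> int:
    return canonical_form(list(nodes), lambda u, v: g.has_edge(u, v))


def _build_names() -> None:
    """Register the standard names of all connected 3-/4-node shapes."""

    def form(size: int, edges: list[tuple[int, int]]) -> tuple[int, int]:
        s = set(edges)
        return size, canonical_form(
            list(range(size)), lambda u, v: (u, v) in s or (v, u) in s
        )

    MOTIF_NAMES[form(3, [(0, 1), (1, 2)])] = "path"
    MOTIF_NAMES[form(3, [(0, 1), (1, 2), (0, 2)])] = "triangle"
    MOTIF_NAMES[form(4, [(0, 1), (1, 2), (2, 3)])] = "path"
    MOTIF_NAMES[form(4, [(0, 1), (0, 2), (0, 3)])] = "star"
    MOTIF_NAMES[form(4, [(0, 1), (1, 2), (2, 3), (3, 0)])] = "cycle"
    MOTIF_NAMES[form(4, [(0, 1), (1, 2), (0, 2), (2, 3)])] = "tadpole"
    MOTIF_NAMES[form(4, [(0, 1), (1, 2), (0, 2), (2, 3), (1, 3)])] = "diamond"
    MOTIF_NAMES[
        form(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
    ] = "clique"


_build_names()


def enumerate_subgraphs(
    network: nx.Graph,
    size: int,
    return_instances: bool = False,
) -> dict[MotifClass, int] | tuple[dict[MotifClass, int], dict[MotifClass, list[frozenset]]]:
    """Count every connected induced subgraph of ``size`` nodes, by class.

    ESU enumeration: each subgraph is grown from its minimum-labeled node
    through an extension set restricted to higher-labeled exclusive
    neighbors, so every connected node set is emitted exactly once.
    """
    if size not in (3, 4):
        raise ValueError(f"motif size must be 3 or 4, got {size}")
    label = {v: i for i, v in enumerate(sorted(network.nodes, key=str))}
    counts: dict[MotifClass, int] = {}
    instances: dict[MotifClass, list[frozenset]] = {}

    def record(sub: list) -> None:
        cls = MotifClass(size, _canonical_of_nodes(network, sub))
        counts[cls] = counts.get(cls, 0) + 1
        if return_instances:
            instances.setdefault(cls, []).append(frozenset(sub))

    def extend(sub: list, extension: set, v_label: int) -> None:
        if len(sub) == size:
            record(sub)
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            # exclusive neighbors of w: not adjacent to / part of current sub
            new_ext = ext | {
                u
                for u in network.neighbors(w)
                if label[u] > v_label
                and u not in sub
                and all(not network.has_edge(u, s) for s in sub)
                and u != w
            }
            extend(sub + [w], new_ext, v_label)

    for v in network.nodes:
        ext = {u for u in network.neighbors(v) if label[u] > label[v]}
        extend([v], ext, label[v])

    if return_instances:
        return counts, instances
    return counts


def randomize_network(
    network: nx.Graph,
    seed: int | np.random.Generator,
    swaps_per_edge: int = 10,
) -> nx.Graph:
    """Degree-preserving randomization by double edge swaps.

    Performs ``swaps_per_edge * m`` successful swaps (u-v, x-y → u-x, v-y);
    proposals creating self-loops or parallel edges are rejected and
    redrawn, so the output is a simple graph with exactly the input degree
    sequence.  If no valid swap exists (fewer than 2 edges, or a graph
    where every proposal collides) an unchanged copy is returned with a
    warning.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    g = network.copy()
    m = g.number_of_edges()
    if m < 2:
        logger.warning("network has %d edges; randomization is a no-op", m)
        return g
    edges = [tuple(sorted(e, key=str)) for e in g.edges()]
    target = swaps_per_edge * m
    done = 0
    attempts = 0
    max_attempts = 100 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        # direction of the rewiring: u-x, v-y or u-y, v-x
        if rng.integers(0, 2):
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if g.has_edge(u, x) or g.has_edge(v, y):
            continue
        g.remove_edge(u, v)
        g.remove_edge(x, y)
        g.add_edge(u, x)
        g.add_edge(v, y)
        edges[i] = tuple(sorted((u, x), key=str))
        edges[j] = tuple(sorted((v, y), key=str))
        done += 1
    if done == 0:
        logger.warning("no valid double edge swap found; returning a copy")
    return g


def motif_significance(
    network: nx.Graph,
    size: int,
    iterations: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> list[MotifResult]:
    """Over-representation of each motif class versus the rewired null.

    The empirical p-value (1 + exceedances) / (iterations + 1) is never
    exactly zero; classes absent from the real network trivially get p = 1.
    Classes observed only in null networks are reported with real count 0.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    real = enumerate_subgraphs(network, size)
    null_runs: list[dict[MotifClass, int]] = []
    for _ in range(iterations):
        g = randomize_network(network, rng, swaps_per_edge)
        null_runs.append(enumerate_subgraphs(g, size))
    classes = set(real)
    for counts in null_runs:
        classes |= set(counts)
    results = []
    for cls in sorted(classes, key=lambda c: c.canonical_form):
        hist = [counts.get(cls, 0) for counts in null_runs]
        real_count = real.get(cls, 0)
        arr = np.asarray(hist, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        exceed = int((arr >= real_count).sum())
        p = (1 + exceed) / (iterations + 1)
        z = (real_count - mean) / sd if sd > 0 else None
        results.append(
            MotifResult(
                motif=cls,
                real_count=real_count,
                null_counts=[int(h) for h in hist],
                null_mean=mean,
                null_sd=sd,
                z_score=z,
                p_value=p,
                significant=p <= alpha,
            )
        )
    return results


def annotate_motif(
    instance: Iterable[str],
    processes: Mapping[str, Iterable[str]],
) -> MotifAnnotation:
    """Label motif members with biological processes; infer the majority one.

    ``processes`` maps a domain to its process labels (typically GO
    biological-process names resolved through Pfam2GO).  The predicted
    function is the most frequent label among annotated members; ties are
    all reported, and an instance with no labeled member predicts
    ``("unknown",)``.
    """
    instance = frozenset(instance)
    labels: dict[str, tuple[str, ...]] = {}
    tally: dict[str, int] = {}
    for node in sorted(instance):
        procs = tuple(sorted(set(processes.get(node, ()))))
        labels[node] = procs if procs else ("unknown",)
        for p in procs:
            tally[p] = tally.get(p, 0) + 1
    if not tally:
        return MotifAnnotation(instance, labels, ("unknown",))
    top = max(tally.values())
    predicted = tuple(sorted(p for p, c in tally.items() if c == top))
    return MotifAnnotation(instance, labels, predicted)
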
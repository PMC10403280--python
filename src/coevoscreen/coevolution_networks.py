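"""Coevolutionary network construction and mutational pathway tracing.

Variable regions are fixed length, so edit distance reduces exactly to
Hamming (substitution-only) distance; this module states that explicitly
and refuses unequal lengths rather than falling back to indel alignment.

Networks:
  * SSN  - nodes are unique concatenated Z-A/Z-B pairs, edges connect nodes
           within a Hamming-distance threshold.
  * cluster graph - connected communities of the SSN collapsed to single
           weighted nodes, with inter-cluster edges drawn at a secondary
           (larger) distance threshold.
  * SpSN - nodes are unique Z-A sequences, edges connect Z-A sequences
           sharing at least ``min_shared`` Z-B partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from coevoscreen.pair_enrichment import EnrichedPairSet
from coevoscreen.screen_simulator import PairCountTable


def hamming(s1: str, s2: str) -> int:
    """Number of mismatched positions between equal-length strings."""
    if len(s1) != len(s2):
        raise ValueError(f"unequal lengths: {len(s1)} vs {len(s2)}")
    return sum(a != b for a, b in zip(s1, s2))


def _pair_nodes(
    tables: Sequence[PairCountTable] | EnrichedPairSet,
) -> pd.DataFrame:
    """Unique concatenated pairs with pooled count and first round seen."""
    if isinstance(tables, EnrichedPairSet):
        df = tables.df.copy()
        df["round"] = ",".join(tables.rounds)
        df = df.rename(columns={"k": "count"})
        rows = df[["seq_a", "seq_b", "count", "round"]]
        first = rows.assign(order=0)
    else:
        frames = []
        for order, t in enumerate(tables):
            frames.append(t.df.assign(round=t.round_label, order=order))
        first = pd.concat(frames, ignore_index=True)
    agg = (
        first.sort_values("order", kind="stable")
        .groupby(["seq_a", "seq_b"], as_index=False)
        .agg(count=("count", "sum"), first_round=("round", "first"))
    )
    agg["key"] = agg["seq_a"] + agg["seq_b"]
    return agg.sort_values("key", ignore_index=True)


def _encode_keys(keys: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(keys).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(keys), -1)


def _edges_within(keys: list[str], threshold: int, block: int = 512):
    """Yield (i, j, distance) for i < j with Hamming distance <= threshold.

    Works in row blocks so memory stays O(block * n * L) for large key sets.
    """
    arr = _encode_keys(keys)
    n = len(keys)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        dist = (arr[lo:hi, None, :] != arr[None, :, :]).sum(axis=2, dtype=np.int32)
        ii, jj = np.nonzero(dist <= threshold)
        for bi, j in zip(ii, jj):
            i = lo + bi
            if i < j:
                yield i, int(j), int(dist[bi, j])


def build_ssn(
    pairs: Sequence[PairCountTable] | EnrichedPairSet,
    threshold: int = 1,
) -> nx.Graph:
    """Sequence similarity network over unique Z-A/Z-B pairs.

    Node key = concatenated variable regions; attributes carry seq_a,
    seq_b, pooled count and first round of appearance. Edge iff Hamming
    distance <= threshold (no self loops). Node and edge insertion order is
    canonical (sorted), so output is invariant to input row order.
    """
    nodes = _pair_nodes(pairs)
    g = nx.Graph(kind="ssn", threshold=threshold)
    for row in nodes.itertuples():
        g.add_node(row.key, seq_a=row.seq_a, seq_b=row.seq_b,
                   count=int(row.count), first_round=row.first_round)
    keys = list(nodes["key"])
    if keys:
        lengths = {len(k) for k in keys}
        if len(lengths) != 1:
            raise ValueError(f"mixed concatenated-key lengths {sorted(lengths)}")
        for i, j, d in _edges_within(keys, threshold):
            g.add_edge(keys[i], keys[j], distance=d)
    return g


def cluster_graph(network: nx.Graph, secondary_threshold: int | None = None) -> nx.Graph:
    """Collapse each connected community of an SSN into one weighted node.

    Communities are connected components. An inter-cluster edge is drawn
    when some member pair across the two clusters lies within the
    secondary threshold (primary + 1 by default).
    """
    primary = network.graph.get("threshold", 1)
    if secondary_threshold is None:
        secondary_threshold = primary + 1
    components = [sorted(c) for c in nx.connected_components(network)]
    components.sort(key=lambda c: (-len(c), c[0]))
    g = nx.Graph(kind="cluster", threshold=primary,
                 secondary_threshold=secondary_threshold)
    member_of: dict[str, int] = {}
    for cid, members in enumerate(components):
        total = sum(network.nodes[m].get("count", 1) for m in members)
        g.add_node(cid, size=len(members), count=int(total),
                   representative=members[0])
        for m in members:
            member_of[m] = cid
    keys = sorted(network.nodes)
    if keys and len({len(k) for k in keys}) == 1:
        for i, j, d in _edges_within(keys, secondary_threshold):
            ci, cj = member_of[keys[i]], member_of[keys[j]]
            if ci != cj:
                if not g.has_edge(ci, cj) or d < g.edges[ci, cj]["distance"]:
                    g.add_edge(ci, cj, distance=d)
    return g


def build_spsn(enriched: EnrichedPairSet | pd.DataFrame, min_shared: int = 1) -> nx.Graph:
    """Specificity similarity network over Z-A sequences.

    Edge between two Z-A sequences iff they share >= ``min_shared`` Z-B
    partners in the filtered set; the edge stores the shared-partner count.
    """
    df = enriched.df if isinstance(enriched, EnrichedPairSet) else enriched
    if df.empty:
        raise ValueError("enriched pair set is empty")
    partners: dict[str, set[str]] = {}
    for row in df.itertuples():
        partners.setdefault(row.seq_a, set()).add(row.seq_b)
    g = nx.Graph(kind="spsn", min_shared=min_shared)
    seqs = sorted(partners)
    for a in seqs:
        g.add_node(a, n_partners=len(partners[a]))
    for i, a1 in enumerate(seqs):
        for a2 in seqs[i + 1:]:
            shared = len(partners[a1] & partners[a2])
            if shared >= min_shared:
                g.add_edge(a1, a2, shared=shared)
    return g


@dataclass
class CrossReactivityProfile:
    """Per-Z-A partner counts with scores normalized to sum to 1."""

    df: pd.DataFrame  # seq_a n_partners score

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def cross_reactivity_profile(
    enriched: EnrichedPairSet | pd.DataFrame,
    sample_n: int | None = 100,
    seed: int = 0,
) -> tuple[CrossReactivityProfile, pd.DataFrame]:
    """Cross-reactivity scores and a stratified representative subsample.

    score(a) = (# distinct Z-B partners of a) / (sum over all a). The
    subsample allocates ``sample_n`` pairs across Z-A groups by largest
    remainder proportional to each group's pair count (so per-group counts
    are within 1 of exact proportionality), then samples within groups
    with the given seed.
    """
    df = enriched.df if isinstance(enriched, EnrichedPairSet) else enriched
    if df.empty:
        raise ValueError("enriched pair set is empty")
    counts = (
        df.groupby("seq_a")["seq_b"].nunique().rename("n_partners").reset_index()
    ).sort_values("seq_a", ignore_index=True)
    counts["score"] = counts["n_partners"] / counts["n_partners"].sum()
    profile = CrossReactivityProfile(counts)

    if sample_n is None:
        return profile, df.copy()
    n_pairs = len(df)
    if sample_n > n_pairs:
        raise ValueError(f"sample_n={sample_n} exceeds number of pairs {n_pairs}")
    rng = np.random.default_rng(seed)
    group_sizes = df.groupby("seq_a").size().sort_index()
    raw = group_sizes.to_numpy() / n_pairs * sample_n
    alloc = np.floor(raw).astype(int)
    short = sample_n - alloc.sum()
    if short > 0:
        order = np.argsort(-(raw - alloc), kind="stable")
        alloc[order[:short]] += 1
    picked = []
    for (a, size), take in zip(group_sizes.items(), alloc):
        if take == 0:
            continue
        sub = df[df["seq_a"] == a].sort_values("seq_b", ignore_index=True)
        idx = rng.choice(len(sub), size=min(take, len(sub)), replace=False)
        picked.append(sub.iloc[sorted(idx)])
    sample = pd.concat(picked, ignore_index=True) if picked else df.iloc[:0].copy()
    return profile, sample


def chord_table(sample: pd.DataFrame) -> pd.DataFrame:
    """Chord-diagram export: `seq_a seq_b arc_weight` with equal-area arcs."""
    out = sample[["seq_a", "seq_b"]].copy()
    out["arc_weight"] = 1.0 / len(sample)
    return out


@dataclass
class PathwayResult:
    """Result of a mutational pathway search."""

    connected: bool
    path: list[str]

    @property
    def n_steps(self) -> int:
        return max(len(self.path) - 1, 0)


def trace_pathway(
    sequences_with_rounds: Mapping[str, int] | Sequence[str],
    start: str,
    end: str,
    round_monotone: bool = False,
    pvalues: Mapping[str, float] | None = None,
) -> PathwayResult:
    """Shortest single-mutation pathway between observed sequences.

    Builds the Hamming-distance-1 graph over the observed node set and
    breadth-first searches from ``start`` to ``end``. With
    ``round_monotone``, edges may only go from earlier-or-equal
    first-appearance rounds to later ones, so the path respects screening
    chronology. Disconnection is reported as a result, not an exception.

    Tie-breaking among equal-length shortest paths is deterministic: the
    path is reconstructed backwards choosing, at each step, the predecessor
    with the smallest (mean enrichment p-value if supplied, then
    lexicographic) key.
    """
    if isinstance(sequences_with_rounds, Mapping):
        rounds = dict(sequences_with_rounds)
    else:
        rounds = {s: 0 for s in sequences_with_rounds}
    if start not in rounds or end not in rounds:
        raise KeyError("start and end must be in the observed node set")
    nodes = sorted(rounds)
    g = nx.DiGraph() if round_monotone else nx.Graph()
    g.add_nodes_from(nodes)
    for i, s1 in enumerate(nodes):
        for s2 in nodes[i + 1:]:
            if hamming(s1, s2) == 1:
                if round_monotone:
                    if rounds[s1] <= rounds[s2]:
                        g.add_edge(s1, s2)
                    if rounds[s2] <= rounds[s1]:
                        g.add_edge(s2, s1)
                else:
                    g.add_edge(s1, s2)
    if start == end:
        return PathwayResult(True, [start])
    try:
        dist = nx.shortest_path_length(g, source=start)
    except nx.NodeNotFound:
        return PathwayResult(False, [])
    if end not in dist:
        return PathwayResult(False, [])

    def key(node: str) -> tuple[float, str]:
        p = pvalues.get(node, 1.0) if pvalues else 1.0
        return (p, node)

    path = [end]
    current = end
    while current != start:
        preds = g.predecessors(current) if round_monotone else g.neighbors(current)
        candidates = [p for p in preds if dist.get(p, np.inf) == dist[current] - 1]
        current = min(candidates, key=key)
        path.append(current)
    return PathwayResult(True, path[::-1])


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": u, "target": v, **data}
        for u, v, data in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
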
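"""Median-joining haplotype networks and the rare-haplotype spectrum.

Nodes are haplotype 0/1 strings; edges are labelled with the SNPs at which
their endpoints differ.  The network is the union of all minimum spanning
trees (a minimum spanning network) over observed haplotypes plus inferred
median vectors (site-wise majorities of triplets, the quasi-median for
binary data), iterated until no median shortens the network, as in the
classic median-joining construction.  Cycles ("torsos") indicate alternative
mutational pathways — the signature of recombination or recurrent mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .formats_io import HaplotypePanel, SnpMap


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _diff_sites(a: str, b: str, labels) -> tuple[str, ...]:
    return tuple(labels[i] for i in range(len(a)) if a[i] != b[i])


def _minimax_from_mst(seqs: list[str]) -> dict[tuple[str, str], int]:
    """Minimax path weight between every pair, computed on one MST.

    An edge (u, v) belongs to some minimum spanning tree iff
    d(u, v) == minimax(u, v); the union of all MSTs (the minimum spanning
    network) follows directly.
    """
    g = nx.Graph()
    for i, u in enumerate(seqs):
        for v in seqs[i + 1:]:
            g.add_edge(u, v, weight=_hamming(u, v))
    mst = nx.minimum_spanning_tree(g)
    out: dict[tuple[str, str], int] = {}
    for u in seqs:
        # DFS tracking the max edge weight en route
        stack = [(u, 0)]
        seen = {u}
        while stack:
            node, mx = stack.pop()
            for nb in mst.neighbors(node):
                if nb in seen:
                    continue
                seen.add(nb)
                w = max(mx, mst[node][nb]["weight"])
                out[(u, nb)] = w
                stack.append((nb, w))
    return out


def _msn(seqs: list[str], epsilon: int = 0) -> nx.Graph:
    """Minimum spanning network with tolerance ``epsilon``: edge (u, v)
    included iff d(u, v) <= minimax(u, v) + epsilon."""
    g = nx.Graph()
    g.add_nodes_from(seqs)
    if len(seqs) < 2:
        return g
    mm = _minimax_from_mst(seqs)
    for i, u in enumerate(seqs):
        for v in seqs[i + 1:]:
            if _hamming(u, v) <= mm[(u, v)] + epsilon:
                g.add_edge(u, v, weight=_hamming(u, v))
    return g


def _majority_median(u: str, v: str, w: str) -> str:
    # binary data: the quasi-median degenerates to the site-wise majority;
    # three-way ties cannot occur with two states
    return "".join(a if a == b else (a if a == c else b)
                   for a, b, c in zip(u, v, w))


@dataclass
class MjNetwork:
    """Median-joining network.

    ``graph`` nodes are haplotype strings with attributes ``kind``
    (observed / median-vector / ancestral), ``count``, ``freq`` and
    ``radius`` (log10 of the within-network normalized frequency, the
    node-size convention of haplotype-network figures); edges carry the
    tuple of differing SNP labels in ``snps``.
    """

    graph: nx.Graph
    snp_labels: tuple[str, ...]
    epsilon: int = 0

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "observed"]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "median-vector"]


def build_mj_network(panel_or_seqs, epsilon: int = 0,
                     labels: tuple[str, ...] | None = None) -> MjNetwork:
    """Median-joining network of a panel's haplotypes.

    Accepts a :class:`HaplotypePanel` or a sequence of 0/1 strings.  Median
    vectors are added in rounds: every pair linked in the current minimum
    spanning network is combined with every third node, the site-wise
    majority is computed, and the cheapest new medians (connection cost
    within ``epsilon`` of the round minimum) are admitted; the loop stops
    when no median shortens the network.  Median vectors that end up with
    degree <= 2 are pruned as obsolete.  Ties are broken lexicographically,
    so the construction is deterministic.
    """
    if isinstance(panel_or_seqs, HaplotypePanel):
        seq_list = panel_or_seqs.haplotype_strings()
        labels = panel_or_seqs.snp_map.labels
    else:
        seq_list = list(panel_or_seqs)
        if labels is None:
            width = len(seq_list[0]) if seq_list else 0
            labels = tuple(f"S{i + 1}" for i in range(width))
    counts: dict[str, int] = {}
    for s in seq_list:
        counts[s] = counts.get(s, 0) + 1
    observed = sorted(counts)
    nodes = list(observed)
    for _round in range(25):
        g = _msn(nodes, epsilon)
        candidates: dict[str, int] = {}
        for u, v in sorted(g.edges()):
            for w in nodes:
                if w in (u, v):
                    continue
                m = _majority_median(u, v, w)
                if m in nodes:
                    continue
                cost = (_hamming(u, m) + _hamming(v, m) + _hamming(w, m))
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        cmin = min(candidates.values())
        new = sorted(m for m, c in candidates.items() if c <= cmin + epsilon)
        # only admit medians that sit strictly on a geodesic between two
        # current nodes (they can shorten or re-route a connection)
        useful = []
        for m in new:
            if any(_hamming(u, m) + _hamming(m, v) == _hamming(u, v)
                   and _hamming(u, m) > 0 and _hamming(m, v) > 0
                   for i, u in enumerate(nodes) for v in nodes[i + 1:]):
                useful.append(m)
        if not useful:
            break
        nodes = sorted(set(nodes) | set(useful))
    # prune obsolete medians (degree <= 2 in the converged network)
    while True:
        g = _msn(nodes, epsilon)
        drop = [n for n in nodes
                if n not in counts and g.degree(n) <= 2]
        if not drop:
            break
        nodes = [n for n in nodes if n not in drop]
    g = _msn(nodes, epsilon)
    total = sum(counts.values())
    net = nx.Graph()
    for n in nodes:
        c = counts.get(n, 0)
        freq = c / total if total else 0.0
        net.add_node(n, kind="observed" if c else "median-vector",
                     count=c, freq=freq,
                     radius=(1.0 + math.log10(freq)) if c else 0.0)
    for u, v, d in g.edges(data=True):
        net.add_edge(u, v, weight=d["weight"],
                     snps=_diff_sites(u, v, labels))
    return MjNetwork(net, tuple(labels), epsilon)


# ---------------------------------------------------------------------------
# Network queries
# ---------------------------------------------------------------------------


def find_torsos(net: MjNetwork) -> list[dict]:
    """Cycle basis of the network; each torso lists its member nodes and the
    SNP labels of its edges."""
    out = []
    for cycle in nx.cycle_basis(net.graph):
        edges = []
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            edges.append(((a, b), net.graph[a][b]["snps"]))
        out.append({"nodes": cycle, "edges": edges})
    return out


def recurrent_mutations(net: MjNetwork) -> dict[str, int]:
    """Number of distinct edges whose label set contains each SNP; counts
    above 1 flag recurrent change at that SNP."""
    counts = {lab: 0 for lab in net.snp_labels}
    for _, _, d in net.graph.edges(data=True):
        for lab in d["snps"]:
            counts[lab] += 1
    return {lab: c for lab, c in counts.items() if c > 0}


def place_ancestral_node(net: MjNetwork,
                         snp_map: SnpMap | None = None) -> MjNetwork:
    """Add (or re-flag) the all-ancestral haplotype as the ANC node.

    If absent it is attached to its nearest node (lexicographic tie-break)
    with the exact-difference edge labels.
    """
    width = len(net.snp_labels)
    anc = "0" * width
    g = net.graph
    if anc in g:
        g.nodes[anc]["kind"] = "ancestral"
        return net
    nearest = min(sorted(g.nodes), key=lambda n: _hamming(anc, n))
    g.add_node(anc, kind="ancestral", count=0, freq=0.0, radius=0.0)
    g.add_edge(anc, nearest, weight=_hamming(anc, nearest),
               snps=_diff_sites(anc, nearest, net.snp_labels))
    return net


# ---------------------------------------------------------------------------
# Haplotype spectrum
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeSpectrum:
    """Haplotype-form frequency spectrum of one cohort."""

    table: pd.DataFrame  # haplotype, count, frequency (desc. by count)
    n_chromosomes: int
    rare_threshold: float
    n_forms: int
    rare_forms: int

    @property
    def rare_share(self) -> float:
        """Fraction of haplotype forms at or below the rare threshold."""
        return self.rare_forms / self.n_forms if self.n_forms else 0.0

    def form_count_by_count(self) -> pd.Series:
        """How many forms occur exactly k times, indexed by k."""
        return self.table["count"].value_counts().sort_index()


def haplotype_spectrum(panel: HaplotypePanel,
                       rare_threshold: float = 0.01) -> HaplotypeSpectrum:
    """Per-form counts and frequencies; forms at frequency <= threshold are
    rare."""
    if panel.n_chromosomes < 1:
        raise ValueError("empty panel")
    seqs = panel.haplotype_strings()
    ser = pd.Series(seqs).value_counts()
    n = len(seqs)
    df = pd.DataFrame({
        "haplotype": ser.index,
        "count": ser.to_numpy(),
    })
    df["frequency"] = df["count"] / n
    df.insert(0, "label", [f"H{i + 1}" for i in range(len(df))])
    rare = int((df["frequency"] <= rare_threshold).sum())
    return HaplotypeSpectrum(df, n, rare_threshold, len(df), rare)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_graphml(net: MjNetwork, path) -> None:
    g = net.graph.copy()
    for _, _, d in g.edges(data=True):
        d["snps"] = ",".join(d["snps"])
    nx.write_graphml(g, path)


def write_dot(net: MjNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("graph mj {\n")
        for n, d in sorted(net.graph.nodes(data=True)):
            fh.write(f'  "{n}" [kind="{d["kind"]}", count={d["count"]}, '
                     f'radius={d["radius"]:.3f}];\n')
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f'  "{u}" -- "{v}" [label="{";".join(d["snps"])}"];\n')
        fh.write("}\n")
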
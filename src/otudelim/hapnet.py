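"""Statistical-parsimony haplotype networks for a low-variation nuclear marker.

Haplotypes are connected by a minimum spanning network over pairwise Hamming
distances (number of differing comparable sites).  Edges longer than the 95%
parsimony connection limit are never drawn, which may leave the network in
several disconnected sub-networks.  Reticulations (equal-length alternative
paths) are resolved algorithmically in the priority order frequency >
topology > geography: prefer keeping links between high-frequency
haplotypes, links with fewer inferred intermediates, and links between
haplotypes found in the same group/locality.

The connection limit is the largest number of mutational steps j for which
the probability that j observed differences reflect exactly j substitutions
(no superimposed or parallel changes anywhere in the sequence) exceeds the
confidence level.  That probability is evaluated under a Jukes-Cantor
finite-sites model with per-site Poisson substitution counts, conditioning on
the observed difference count; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .errors import InputError
from .seqdata import HaplotypeTable

_GAP = ord("-")
_N = ord("N")

IUPAC_AMBIG = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}


# ---------------------------------------------------------------------------
# parsimony connection limit


def parsimony_probability(j: int, seq_length: int) -> float:
    """P(exactly j substitutions | j observed differences over seq_length sites).

    Per-site substitution counts are Poisson with mean d, the Jukes-Cantor
    corrected divergence for the observed proportion j/seq_length; a single
    hit is always visible, multiple hits are visible with the JC probability.
    """
    if j == 0:
        return 1.0
    m = seq_length
    p_hat = j / m
    if p_hat >= 0.75:
        return 0.0
    d = -0.75 * np.log(1.0 - 4.0 * p_hat / 3.0)
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    p_same = 1.0 - p_diff
    # joint probabilities of (single hit, visible) and (no hit, identical)
    one_visible = d * np.exp(-d)
    zero_same = np.exp(-d)
    return float((one_visible / p_diff) ** j * (zero_same / p_same) ** (m - j))


def connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest step count j whose parsimony probability exceeds ``confidence``."""
    if seq_length < 1:
        raise InputError("sequence length must be >= 1")
    limit = 0
    for j in range(1, seq_length):
        if parsimony_probability(j, seq_length) > confidence:
            limit = j
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# network construction


def hamming_steps(a: str, b: str) -> int:
    """Number of differing comparable sites (gaps and N treated as missing)."""
    u = np.frombuffer(a.encode(), dtype=np.uint8)
    v = np.frombuffer(b.encode(), dtype=np.uint8)
    if u.size != v.size:
        raise InputError("sequences differ in length")
    mask = (u != _GAP) & (u != _N) & (v != _GAP) & (v != _N)
    return int(((u != v) & mask).sum())


@dataclass
class HaploNetwork:
    """A haplotype graph; node attributes: sequence, frequency, groups."""

    graph: nx.Graph
    connection_limit: int

    @property
    def subnetworks(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_subnetworks(self) -> int:
        return nx.number_connected_components(self.graph)

    def with_intermediates(self) -> nx.Graph:
        """Expanded graph where an s-step edge becomes a path through s-1
        inferred nodes (frequency 0, no group label)."""
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, **data)
        k = 0
        for u, v, data in self.graph.edges(data=True):
            steps = data["steps"]
            prev = u
            for _ in range(steps - 1):
                k += 1
                mid = f"med{k}"
                g.add_node(mid, frequency=0, inferred=True)
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, v, steps=1)
        return g

    def to_gml(self, path) -> None:
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, frequency=data.get("frequency", 0),
                       groups=",".join(sorted(data.get("groups", []))))
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(u, v, steps=data["steps"])
        nx.write_gml(g, str(path))

    def to_dot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("graph hapnet {\n")
            for node, data in self.graph.nodes(data=True):
                fh.write(f'  "{node}" [label="{node} (n={data.get("frequency", 0)})"];\n')
            for u, v, data in self.graph.edges(data=True):
                fh.write(f'  "{u}" -- "{v}" [label="{data["steps"]}"];\n')
            fh.write("}\n")


def _edge_removal_priority(g: nx.Graph, criteria: tuple[str, ...]):
    """Sort key: the edge scoring WORST under the priority list is removed."""
    def key(edge):
        u, v, data = edge
        parts = []
        for crit in criteria:
            if crit == "frequency":
                # links between low-frequency haplotypes lose first
                parts.append(g.nodes[u].get("frequency", 0)
                             + g.nodes[v].get("frequency", 0))
            elif crit == "topology":
                # longer edges (more inferred intermediates) lose first
                parts.append(-data["steps"])
            elif crit == "geography":
                shared = set(g.nodes[u].get("groups", [])) & set(g.nodes[v].get("groups", []))
                parts.append(1 if shared else 0)
            else:
                raise InputError(f"unknown resolve criterion: {crit!r}")
        parts.append(tuple(sorted((u, v), reverse=True)))
        return tuple(parts)
    return key


def build_network(
    haps: HaplotypeTable,
    limit: int,
    resolve: tuple[str, ...] = ("frequency", "topology", "geography"),
    groups: dict[str, str] | None = None,
) -> HaploNetwork:
    """Minimum spanning network over Hamming distances, pruned of loops.

    All co-minimal edges are kept initially (edges joining distinct
    components at the start of their weight class), then cycles are broken by
    the ``resolve`` priority.  Edges longer than ``limit`` are never drawn.
    ``groups`` maps specimen ids to group/locality labels.
    """
    if haps.n_haplotypes == 0:
        raise InputError("no haplotypes")
    names = [f"H{k + 1}" for k in range(haps.n_haplotypes)]
    g = nx.Graph()
    for name, hap, mult in zip(names, haps.haplotypes, haps.multiplicity):
        labels = sorted({groups[s] for s in haps.members[hap] if s in groups}) if groups else []
        g.add_node(name, sequence=hap, frequency=mult,
                   members=list(haps.members[hap]), groups=labels)
    dists = {}
    for (i, a), (j, b) in combinations(enumerate(haps.haplotypes), 2):
        dists[(names[i], names[j])] = hamming_steps(a, b)

    # minimum spanning network: admit all co-minimal edges per weight class
    uf = {n: n for n in names}

    def find(a):
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    for w in sorted(set(dists.values())):
        if w > limit:
            break
        comp_before = {n: find(n) for n in names}
        added = []
        for (u, v), d in sorted(dists.items()):
            if d == w and comp_before[u] != comp_before[v]:
                g.add_edge(u, v, steps=max(d, 1))
                added.append((u, v))
        for u, v in added:
            uf[find(u)] = find(v)

    # prune reticulation loops by the resolve priority
    key = _edge_removal_priority(g, tuple(resolve))
    while True:
        cycles = nx.cycle_basis(g)
        if not cycles:
            break
        cycle = sorted(cycles, key=lambda c: sorted(c))[0]
        edges = []
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            edges.append((a, b, g.edges[a, b]))
        worst = min(edges, key=key)
        g.remove_edge(worst[0], worst[1])
    return HaploNetwork(g, limit)


def min_steps_between(haps: HaplotypeTable, group_a, group_b) -> int:
    """Minimum pairwise Hamming steps between two specimen groups."""
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise InputError("groups must be non-empty")
    if a & b:
        raise InputError(f"groups overlap: {sorted(a & b)}")
    seq_of = {}
    for hap, members in haps.members.items():
        for s in members:
            seq_of[s] = hap
    missing = (a | b) - set(seq_of)
    if missing:
        raise InputError(f"unknown specimens: {sorted(missing)}")
    return min(hamming_steps(seq_of[u], seq_of[v]) for u in a for v in b)


def expand_phased(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Deterministically expand diploid sequences with at most one IUPAC
    ambiguity into two phased haplotypes; reject more ambiguous records."""
    out = []
    for sid, seq in records:
        seq = seq.upper()
        ambig = [(k, c) for k, c in enumerate(seq) if c in IUPAC_AMBIG]
        if len(ambig) > 1:
            raise InputError(f"record {sid!r} has {len(ambig)} ambiguous sites; phase externally")
        if not ambig:
            out.append((f"{sid}_a", seq))
            out.append((f"{sid}_b", seq))
        else:
            k, c = ambig[0]
            x, y = sorted(IUPAC_AMBIG[c])
            out.append((f"{sid}_a", seq[:k] + x + seq[k + 1:]))
            out.append((f"{sid}_b", seq[:k] + y + seq[k + 1:]))
    return out
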
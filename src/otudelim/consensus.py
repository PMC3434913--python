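"""Consensus OTUs: the conservative >=2-of-3 agreement rule.

A candidate block is any block appearing in one of the input partitions; its
support is the number of methods whose partition contains exactly that block
(strict set identity).  Blocks reaching the minimum support are accepted
greedily (support desc, size desc, lexicographic id asc), skipping blocks
that overlap an accepted one; specimens left over are reported as flagged
orphan singletons rather than force-merged.
"""

from __future__ import annotations

from dataclasses import dataclass

from sklearn.metrics import adjusted_rand_score

from .errors import InputError
from .partition import Partition


@dataclass
class ConsensusOTU:
    members: frozenset[str]
    support: int
    methods: tuple[str, ...]


@dataclass
class ConsensusResult:
    otus: list[ConsensusOTU]
    orphans: list[str]

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def partition(self) -> Partition:
        blocks = [o.members for o in self.otus] + [frozenset([s]) for s in self.orphans]
        return Partition(blocks, method="consensus", parameter=None)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("otu_id\tsupport\tmethods\torphan\tmembers\n")
            for k, o in enumerate(self.otus):
                fh.write(f"OTU{k + 1}\t{o.support}\t{','.join(o.methods)}\t0\t"
                         f"{';'.join(sorted(o.members))}\n")
            for k, s in enumerate(self.orphans):
                fh.write(f"ORPH{k + 1}\t0\t\t1\t{s}\n")


def consensus_otus(
    p1: Partition, p2: Partition, p3: Partition, min_support: int = 2
) -> ConsensusResult:
    """Combine three method partitions into consensus OTUs."""
    parts = [p1, p2, p3]
    idsets = [p.ids for p in parts]
    if not (idsets[0] == idsets[1] == idsets[2]):
        diff = (idsets[0] | idsets[1] | idsets[2]) - (idsets[0] & idsets[1] & idsets[2])
        raise InputError(f"partitions cover different specimen sets; differing ids: {sorted(diff)}")
    support: dict[frozenset[str], list[str]] = {}
    for p in parts:
        tag = p.method or "method"
        for b in p.blocks:
            support.setdefault(b, []).append(tag)
    candidates = sorted(
        support.items(),
        key=lambda kv: (-len(kv[1]), -len(kv[0]), tuple(sorted(kv[0]))),
    )
    accepted: list[ConsensusOTU] = []
    covered: set[str] = set()
    for block, methods in candidates:
        if len(methods) < min_support or block & covered:
            continue
        accepted.append(ConsensusOTU(block, len(methods), tuple(methods)))
        covered |= block
    orphans = sorted(idsets[0] - covered)
    return ConsensusResult(accepted, orphans)


def compare_partitions(pa: Partition, pb: Partition) -> tuple[int, float]:
    """(number of identical blocks, adjusted Rand index) between partitions."""
    if pa.ids != pb.ids:
        raise InputError("partitions cover different specimen sets")
    shared = len(set(pa.blocks) & set(pb.blocks))
    ids = sorted(pa.ids)
    ari = float(adjusted_rand_score(pa.labels(ids), pb.labels(ids)))
    return shared, ari
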
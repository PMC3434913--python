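"""Partitions of specimens into disjoint OTU blocks, with provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

from .errors import InputError


def _canonical(blocks: Iterable[Iterable[str]]) -> tuple[frozenset[str], ...]:
    fs = [frozenset(b) for b in blocks]
    return tuple(sorted(fs, key=lambda b: min(b)))


@dataclass(frozen=True)
class Partition:
    """A division of specimens into disjoint, non-empty blocks.

    ``method`` records which delimitation method produced it and ``parameter``
    the threshold/level/model used.
    """

    blocks: tuple[frozenset[str], ...]
    method: str = ""
    parameter: Any = None

    def __init__(self, blocks, method: str = "", parameter: Any = None):
        blocks = _canonical(blocks)
        if any(len(b) == 0 for b in blocks):
            raise InputError("empty block in partition")
        seen: set[str] = set()
        for b in blocks:
            if seen & b:
                raise InputError(f"overlapping blocks: {sorted(seen & b)}")
            seen |= b
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "method", method)
        object.__setattr__(self, "parameter", parameter)

    @property
    def ids(self) -> frozenset[str]:
        out: set[str] = set()
        for b in self.blocks:
            out |= b
        return frozenset(out)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, sid: str) -> frozenset[str]:
        for b in self.blocks:
            if sid in b:
                return b
        raise InputError(f"unknown id: {sid!r}")

    def labels(self, ids: list[str]) -> list[int]:
        """Integer block label per id, for contingency-style comparisons."""
        lookup = {}
        for k, b in enumerate(self.blocks):
            for s in b:
                lookup[s] = k
        return [lookup[s] for s in ids]

    def same_blocks(self, other: "Partition") -> bool:
        return set(self.blocks) == set(other.blocks)

    def refines(self, other: "Partition") -> bool:
        """True when every block of self lies inside one block of other."""
        return all(any(b <= o for o in other.blocks) for b in self.blocks)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("block_id\tmethod\tparameter\tmembers\n")
            for k, b in enumerate(self.blocks):
                fh.write(f"B{k + 1}\t{self.method}\t{self.parameter}\t{';'.join(sorted(b))}\n")

    @classmethod
    def from_tsv(cls, path) -> "Partition":
        blocks = []
        method, parameter = "", None
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh
                     if ln.strip() and not ln.startswith("#")]
        if not lines or not lines[0].startswith("block_id"):
            raise InputError(f"not a partition TSV: {path}")
        for ln in lines[1:]:
            _, method, parameter, members = ln.split("\t")
            blocks.append(members.split(";"))
        return cls(blocks, method=method, parameter=parameter)
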
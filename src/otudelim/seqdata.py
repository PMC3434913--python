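"""Aligned-sequence handling: haplotype deduplication, site statistics and
uncorrected (net) p-distance matrices.

The central containers are :class:`Alignment` (a fixed-length DNA matrix over
``A C G T - N``), :class:`HaplotypeTable` (unique sequences with specimen
multiplicities) and :class:`DistanceMatrix` (pairwise p-distances with
comparable-site bookkeeping).  A p-distance is the proportion of differing
sites among the sites comparable in both sequences; gaps and ``N`` never count
as states.  The *net* between-group distance subtracts the mean of the two
within-group mean distances from the mean cross-group distance (the MEGA
convention), and is the quantity used for barcode-gap searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, InputError

VALID_CHARS = frozenset("ACGT-N")

# byte codes used in the packed representation
_GAP = ord("-")
_N = ord("N")


@dataclass
class Alignment:
    """A rectangular DNA alignment.

    Parameters
    ----------
    ids:
        Unique specimen identifiers, one per row.
    seqs:
        Equal-length uppercase strings over ``{A,C,G,T,-,N}``.
    labels:
        Optional specimen -> group map (e.g. species or clade labels).
    """

    ids: list[str]
    seqs: list[str]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("alignment is empty")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if lengths == {0}:
            raise AlignmentError("alignment length must be >= 1")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate specimen ids: {dupes}")
        for sid, seq in zip(self.ids, self.seqs):
            bad = set(seq) - VALID_CHARS
            if bad:
                raise InputError(f"illegal characters {sorted(bad)} in record {sid!r}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def matrix(self) -> np.ndarray:
        """Byte matrix view (n x length, uint8) for vectorised column work."""
        return np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            self.n, self.length
        )

    def subset(self, ids: list[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise InputError(f"unknown ids: {missing}")
        labels = {s: self.labels[s] for s in ids if self.labels and s in self.labels}
        return Alignment(list(ids), [self.seqs[index[s]] for s in ids], labels or None)


@dataclass
class HaplotypeTable:
    """Unique haplotypes in order of first occurrence."""

    haplotypes: list[str]
    multiplicity: list[int]
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def representative_ids(self) -> list[str]:
        """First specimen id carrying each haplotype."""
        return [self.members[h][0] for h in self.haplotypes]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype_id\tmultiplicity\tmembers\n")
            for k, hap in enumerate(self.haplotypes):
                fh.write(f"H{k + 1}\t{self.multiplicity[k]}\t{';'.join(self.members[hap])}\n")


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected p-distances with per-pair comparable-site counts."""

    ids: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.comparable_sites = np.asarray(self.comparable_sites)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")

    def index(self, sid: str) -> int:
        try:
            return self.ids.index(sid)
        except ValueError:
            raise InputError(f"unknown id: {sid!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.comparable_sites[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{sid}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        ids = header[1:]
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append([float(x) for x in parts[1:]])
        d = np.array(rows)
        L = np.full_like(d, -1, dtype=int)  # comparable sites unknown after round trip
        return cls(ids, d, L)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file.

    Case is normalised to upper and ``U`` mapped to ``T``.  Ragged lengths,
    duplicate ids and illegal characters raise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper().replace("U", "T") for r in records]
    return Alignment(ids, seqs)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def dedup_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Collapse exact duplicate sequences, preserving first-occurrence order."""
    members: dict[str, list[str]] = {}
    order: list[str] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        if seq not in members:
            members[seq] = []
            order.append(seq)
        members[seq].append(sid)
    return HaplotypeTable(order, [len(members[h]) for h in order], members)


def unique_alignment(aln: Alignment) -> Alignment:
    """Alignment restricted to one representative specimen per haplotype."""
    table = dedup_haplotypes(aln)
    return aln.subset(table.representative_ids())


def site_stats(aln: Alignment) -> tuple[int, int]:
    """Return (variable sites, parsimony-informative sites).

    A site is variable when >= 2 distinct non-gap, non-N states occur;
    parsimony informative when >= 2 states are each carried by >= 2 sequences.
    """
    m = aln.matrix()
    valid = (m != _GAP) & (m != _N)
    n_var = 0
    n_pi = 0
    for j in range(aln.length):
        col = m[valid[:, j], j]
        if col.size == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        if counts.size >= 2:
            n_var += 1
            if np.sum(counts >= 2) >= 2:
                n_pi += 1
    return n_var, n_pi


def pdist_matrix(
    aln: Alignment, deletion: str = "pairwise", allow_missing: bool = False
) -> DistanceMatrix:
    """Uncorrected p-distance matrix.

    ``deletion="pairwise"`` drops, per pair, sites where either sequence has a
    gap or ``N``; ``"complete"`` drops such columns globally first.  A pair
    with zero comparable sites raises unless ``allow_missing`` (then NaN).
    """
    if aln.n < 2:
        raise InputError("need >= 2 sequences for a distance matrix")
    if deletion not in ("pairwise", "complete"):
        raise InputError(f"unknown deletion mode: {deletion!r}")
    m = aln.matrix()
    valid = (m != _GAP) & (m != _N)
    if deletion == "complete":
        keep = valid.all(axis=0)
        m = m[:, keep]
        valid = valid[:, keep]
    n = aln.n
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        comp[i, i] = int(valid[i].sum())
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            L = int(mask.sum())
            comp[i, j] = comp[j, i] = L
            if L == 0:
                if not allow_missing:
                    raise InputError(
                        f"zero comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                    )
                d[i, j] = d[j, i] = np.nan
                continue
            mism = int(((m[i] != m[j]) & mask).sum())
            d[i, j] = d[j, i] = mism / L
    return DistanceMatrix(list(aln.ids), d, comp)


def _within_mean(dm: DistanceMatrix, group: list[str]) -> float:
    """Mean pairwise distance within a group; 0.0 for singletons."""
    if len(group) < 2:
        return 0.0
    idx = [dm.index(s) for s in group]
    sub = dm.d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.mean(sub[iu]))


def mean_between_distance(dm: DistanceMatrix, group_a, group_b) -> float:
    ia = [dm.index(s) for s in group_a]
    ib = [dm.index(s) for s in group_b]
    return float(np.mean(dm.d[np.ix_(ia, ib)]))


def net_between_distance(dm: DistanceMatrix, group_a, group_b) -> float:
    """Net between-group p-distance: d_AB - (d_A + d_B)/2.

    d_AB is the mean over all cross pairs; d_A and d_B are the mean
    within-group distances (0 for singleton groups).
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise InputError("groups must be non-empty")
    if set(a) & set(b):
        raise InputError(f"groups overlap: {sorted(set(a) & set(b))}")
    d_ab = mean_between_distance(dm, a, b)
    return d_ab - (_within_mean(dm, a) + _within_mean(dm, b)) / 2.0
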
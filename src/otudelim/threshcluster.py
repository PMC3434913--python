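"""Pairwise-distance threshold clustering (barcoding-style cluster sweep).

Two linkage modes are provided.  ``single`` reproduces the transitive-closure
behaviour of classic sequence-clustering tools: clusters are the connected
components of the graph with an edge wherever the pairwise distance is at or
below the threshold.  ``complete`` enforces the verbal rule that the maximum
pairwise distance *within* a cluster may not exceed the threshold,
agglomerating the closest admissible pair first.  A sweep over thresholds
(default 2-10% in 1% steps) reports one partition and cluster count per
threshold; under single linkage the counts are non-increasing in the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .errors import InputError
from .partition import Partition
from .seqdata import DistanceMatrix

DEFAULT_THRESHOLDS = tuple(t / 100 for t in range(2, 11))


@dataclass
class ThresholdSweep:
    thresholds: list[float]
    partitions: list[Partition]

    @property
    def counts(self) -> list[int]:
        return [p.n_blocks for p in self.partitions]

    def at(self, t: float) -> Partition:
        for th, p in zip(self.thresholds, self.partitions):
            if abs(th - t) < 1e-12:
                return p
        raise InputError(f"threshold {t} not in sweep")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tn_clusters\tblocks\n")
            for t, p in zip(self.thresholds, self.partitions):
                blocks = "|".join(";".join(sorted(b)) for b in p.blocks)
                fh.write(f"{t:.4f}\t{p.n_blocks}\t{blocks}\n")


def cluster_at_threshold(dm: DistanceMatrix, t: float, linkage: str = "single") -> Partition:
    """Partition specimens so pairwise distances respect threshold ``t``.

    Distances exactly equal to ``t`` are inside the threshold (<=).
    """
    if not (0 < t < 1):
        raise InputError(f"threshold must be in (0,1), got {t}")
    if linkage == "single":
        adj = dm.d <= t
        _, comp = connected_components(adj, directed=False)
        blocks: dict[int, list[str]] = {}
        for sid, c in zip(dm.ids, comp):
            blocks.setdefault(int(c), []).append(sid)
        out = list(blocks.values())
    elif linkage == "complete":
        out = _complete_linkage(dm, t)
    else:
        raise InputError(f"unknown linkage: {linkage!r}")
    return Partition(out, method=f"threshcluster-{linkage}", parameter=t)


def _complete_linkage(dm: DistanceMatrix, t: float) -> list[list[str]]:
    # Agglomerate while the merged cluster's max internal distance stays <= t,
    # always merging the closest admissible pair; ties broken by lowest id.
    clusters: list[list[str]] = [[s] for s in dm.ids]
    idx = {s: i for i, s in enumerate(dm.ids)}

    def link(a: list[str], b: list[str]) -> float:
        ia = [idx[s] for s in a]
        ib = [idx[s] for s in b]
        return float(dm.d[np.ix_(ia, ib)].max())

    while True:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = link(clusters[i], clusters[j])
                if dij > t:
                    continue
                key = (dij, min(min(clusters[i]), min(clusters[j])),
                       max(min(clusters[i]), min(clusters[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            return clusters
        _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]


def threshold_sweep(
    dm: DistanceMatrix,
    thresholds=DEFAULT_THRESHOLDS,
    linkage: str = "single",
) -> ThresholdSweep:
    """One partition per threshold; thresholds must be strictly increasing."""
    ts = list(thresholds)
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise InputError("thresholds must be strictly increasing")
    return ThresholdSweep(ts, [cluster_at_threshold(dm, t, linkage) for t in ts])
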
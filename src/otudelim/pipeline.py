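"""Orchestration: distances -> three delimitation methods -> consensus.

``run_pipeline`` is a pure function of (inputs, config, seed): it reads the
alignment (and optional tree/labels), deduplicates haplotypes, computes site
statistics and the p-distance matrix, runs the threshold sweep, the
ring/gap-search partitions, and the GMYC fit, combines the three method
partitions under the >=2-of-3 rule, and writes every intermediate plus a
summary to the output directory.  Each output file carries the config hash
in a header comment so runs can be matched to their settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import consensus as cns
from . import gmyc as gm
from . import seqdata as sq
from . import threshcluster as tc
from . import treepart as tp
from .errors import InputError, OtudelimError
from .partition import Partition

log = logging.getLogger("otudelim")


@dataclass
class RunConfig:
    """Inputs and method settings for one pipeline run."""

    fasta: str
    tree: str | None = None
    labels_tsv: str | None = None
    out_dir: str = "otudelim_out"
    pp_min: float = 0.95
    sweep_min: float = 0.02
    sweep_max: float = 0.10
    sweep_step: float = 0.01
    report_threshold: float = 0.05
    linkage: str = "single"
    ring_levels: int = 3
    gmyc_model: str = "single"
    min_support: int = 2
    seed: int = 0

    def thresholds(self) -> list[float]:
        ts = []
        t = self.sweep_min
        while t <= self.sweep_max + 1e-12:
            ts.append(round(t, 10))
            t += self.sweep_step
        if not all(0 < x < 1 for x in ts):
            raise InputError("sweep thresholds must lie in (0,1)")
        return ts

    def config_hash(self) -> str:
        data = asdict(self)
        data.pop("out_dir")  # analysis settings only
        payload = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunBundle:
    """Everything a pipeline run produced, in memory."""

    config: RunConfig
    haplotypes: sq.HaplotypeTable
    site_stats: tuple[int, int]
    dm: sq.DistanceMatrix
    sweep: tc.ThresholdSweep
    gap_reports: list[tp.GapReport]
    gmyc_fit: gm.GMYCFit | None
    method_partitions: dict[str, Partition]
    consensus: cns.ConsensusResult
    warnings: list[str] = field(default_factory=list)

    def summary_rows(self) -> list[tuple[str, str]]:
        nv, npi = self.site_stats
        rows = [
            ("n_specimens", str(sum(self.haplotypes.multiplicity))),
            ("n_unique_haplotypes", str(self.haplotypes.n_haplotypes)),
            ("n_variable_sites", str(nv)),
            ("n_parsimony_informative", str(npi)),
        ]
        for tag, part in self.method_partitions.items():
            rows.append((f"n_lineages_{tag}", str(part.n_blocks)))
        if self.gmyc_fit is not None:
            rows.append(("gmyc_n_clusters", str(self.gmyc_fit.n_clusters)))
            rows.append(("gmyc_n_singletons", str(self.gmyc_fit.n_singletons)))
            rows.append(("gmyc_lrt_p", f"{self.gmyc_fit.p_value:.6g}"))
        rows.append(("n_consensus_otus", str(self.consensus.n_otus)))
        rows.append(("n_orphans", str(len(self.consensus.orphans))))
        return rows


def _read_labels(path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        header = fh.readline()
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            labels[parts[0]] = parts[-1]
    return labels


def _stamp(path: Path, cfg_hash: str) -> None:
    text = path.read_text()
    path.write_text(f"# config={cfg_hash}\n" + text)


def run_pipeline(config: RunConfig) -> RunBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    notes: list[str] = []

    log.info("reading alignment %s", config.fasta)
    aln = sq.read_fasta(config.fasta)
    if config.labels_tsv:
        aln.labels = _read_labels(config.labels_tsv)
    haps = sq.dedup_haplotypes(aln)
    uniq = sq.unique_alignment(aln)
    stats = sq.site_stats(uniq)
    dm = sq.pdist_matrix(uniq)
    log.info("%d specimens, %d unique haplotypes, %d variable sites",
             aln.n, haps.n_haplotypes, stats[0])

    sweep = tc.threshold_sweep(dm, config.thresholds(), linkage=config.linkage)
    part2 = sweep.at(config.report_threshold)

    if config.tree:
        tree = tp.read_newick(config.tree)
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        reps = set(uniq.ids)
        if reps - tips:
            raise InputError(
                "tree is missing haplotype representatives: "
                f"{sorted(reps - tips)[:5]}..."
            )
        if tips - reps:
            # analyses run on unique haplotypes only, as duplicate sequences
            # carry no extra information for any of the three methods
            notes.append(f"pruned {len(tips - reps)} duplicate-haplotype tips from tree")
            tree.retain_taxa_with_labels(sorted(reps))
    else:
        notes.append("no tree supplied; falling back to UPGMA from p-distances")
        log.warning("no tree supplied; using UPGMA stand-in")
        tree = tp.upgma_tree(dm)
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        rings = tp.ring_partitions(tree, pp_min=config.pp_min, n_levels=config.ring_levels)
        notes.extend(str(w.message) for w in wrec)
    reports = tp.gap_search(rings, dm)
    preferred = next((r for r in reports if r.preferred), reports[-1])
    part1 = preferred.partition

    gmyc_fit = None
    try:
        bi = gm.branching_times(tree)
        if config.gmyc_model == "multiple":
            gmyc_fit = gm.fit_gmyc_multiple(bi)
        else:
            gmyc_fit = gm.fit_gmyc_single(bi)
        part3 = gmyc_fit.partition()
    except OtudelimError as exc:
        notes.append(f"GMYC stage skipped: {exc}")
        log.warning("GMYC stage skipped: %s", exc)
        part3 = Partition([frozenset(dm.ids)], method="gmyc-skipped", parameter=None)

    result = cns.consensus_otus(part1, part2, part3, min_support=config.min_support)
    bundle = RunBundle(
        config=config, haplotypes=haps, site_stats=stats, dm=dm, sweep=sweep,
        gap_reports=reports, gmyc_fit=gmyc_fit,
        method_partitions={"pdist_gap": part1, "cluster": part2, "gmyc": part3},
        consensus=result, warnings=notes,
    )

    haps.to_tsv(out / "haplotypes.tsv")
    dm.to_tsv(out / "distances.tsv")
    sweep.to_tsv(out / "sweep.tsv")
    tp.write_gap_reports(reports, out / "gap_reports.tsv")
    if gmyc_fit is not None:
        gm.write_gmyc_report(gmyc_fit, out / "gmyc.tsv")
        gmyc_fit.partition().to_tsv(out / "gmyc_entities.tsv")
    for tag, part in bundle.method_partitions.items():
        part.to_tsv(out / f"partition_{tag}.tsv")
    result.to_tsv(out / "consensus.tsv")
    with open(out / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in bundle.summary_rows():
            fh.write(f"{k}\t{v}\n")
    for f in out.glob("*.tsv"):
        _stamp(f, cfg_hash)
    return bundle


def render_report(bundle: RunBundle) -> str:
    """Human-readable run summary with the method-agreement table."""
    lines = [f"otudelim run (config {bundle.config.config_hash()})", ""]
    for k, v in bundle.summary_rows():
        lines.append(f"  {k:28s} {v}")
    lines.append("")
    lines.append("consensus OTUs (support = number of agreeing methods):")
    for k, otu in enumerate(bundle.consensus.otus, start=1):
        lines.append(f"  OTU{k:<3d} support={otu.support} [{','.join(otu.methods)}] "
                     f"members={';'.join(sorted(otu.members))}")
    if bundle.consensus.orphans:
        lines.append(f"  orphans (flagged singletons): {';'.join(bundle.consensus.orphans)}")
    counts = {1: 0, 2: 0, 3: 0}
    blocks = set()
    for part in bundle.method_partitions.values():
        blocks |= set(part.blocks)
    for b in blocks:
        s = sum(1 for p in bundle.method_partitions.values() if b in p.blocks)
        counts[s] += 1
    lines.append("")
    lines.append("block agreement: "
                 + ", ".join(f"{n} block(s) supported by {s} method(s)"
                             for s, n in sorted(counts.items()) if n))
    for w in bundle.warnings:
        lines.append(f"  note: {w}")
    return "\n".join(lines) + "\n"
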
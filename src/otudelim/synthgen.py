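"""Synthetic datasets with the statistical structure the delimitation
analyses assume: a Yule species tree, coalescent gene genealogies within it,
finite-sites sequence evolution, duplicated specimens, and phased nuclear
haplotypes.

The generator provides full ground truth (species labels, the true
chronogram, realized divergence summaries) so parameter recovery can be
tested without tree estimation.  The substitution rate is not a free input:
it is calibrated per dataset so that a chosen between-species p-distance
statistic hits a target (median 8% by default), because the analyses are
specified in terms of observed divergences, not rates.  The "set-3" regime
configuration reproduces the study condition of within-species divergences
below 3% and between-species divergences of at least 6%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import msprime
import numpy as np
from scipy.linalg import expm

from .errors import InputError
from .partition import Partition
from .seqdata import Alignment, pdist_matrix
from .treepart import _attach_supports, tree_to_newick

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SynthConfig:
    """Study-condition parameters for one synthetic dataset.

    ``theta`` is the within-species coalescent scale: the mean pairwise
    coalescence time between two samples of one species, in the time units of
    the species tree.  ``calibration`` is a (statistic, value) pair over
    between-species p-distances; ``min_depth_frac`` conditions the Yule tree
    on every speciation being at least that fraction of the root age deep.
    """

    K: int = 10
    lambda_sp: float = 1.0
    samples_per_species: int = 5
    theta: float = 0.02
    seq_length: int = 586
    model: str = "JC69"
    duplicate_fraction: float = 0.5
    seed: int = 0
    min_depth_frac: float = 0.0
    calibration: tuple[str, float] = ("median_between", 0.08)
    enforce_regime: bool = False
    within_max: float = 0.03
    between_min: float = 0.06
    max_attempts: int = 30

    @classmethod
    def set3_regime(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """The within <3% / between >=6% regime used for recovery studies."""
        cfg = cls(
            seed=seed,
            duplicate_fraction=0.0,
            min_depth_frac=0.2,
            calibration=("min_between", 0.07),
            enforce_regime=True,
        )
        return replace(cfg, **overrides)


@dataclass
class SynthTruth:
    """Ground truth attached to a synthetic dataset."""

    labels: dict[str, str]
    gene_tree_newick: str
    summaries: dict = field(default_factory=dict)

    def species_partition(self) -> Partition:
        blocks: dict[str, set[str]] = {}
        for sid, sp in self.labels.items():
            blocks.setdefault(sp, set()).add(sid)
        return Partition(list(blocks.values()), method="truth", parameter=None)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("specimen\tspecies\n")
            for sid in sorted(self.labels):
                fh.write(f"{sid}\t{self.labels[sid]}\n")


# ---------------------------------------------------------------------------
# species tree (Yule)


def _yule_once(K: int, lambda_sp: float, rng) -> dendropy.Tree:
    root = dendropy.Node()
    root.time = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    t = 0.0
    k = 2
    while k < K:
        t += rng.exponential(1.0 / (k * lambda_sp))
        i = int(rng.integers(k))
        nd = active.pop(i)
        nd.time = t
        for _ in range(2):
            child = dendropy.Node()
            nd.add_child(child)
            active.append(child)
        k += 1
    t_end = t + rng.exponential(1.0 / (K * lambda_sp))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for j, nd in enumerate(active):
        nd.time = t_end
        nd.taxon = taxa.require_taxon(f"sp{j + 1}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.time - nd.parent_node.time
        nd.age = t_end - nd.time
    return tree


def simulate_species_tree(
    K: int, lambda_sp: float = 1.0, seed: int = 0, min_depth_frac: float = 0.0
) -> dendropy.Tree:
    """Ultrametric K-tip Yule tree (2 lineages at the root; waiting time
    Exp(k*lambda) while k lineages, final stretch Exp(K*lambda)).

    With ``min_depth_frac`` > 0 the tree is rejection-sampled until every
    internal node age is at least that fraction of the root age, emulating
    datasets whose species are all well separated.
    """
    if K < 2:
        raise InputError("need K >= 2 species")
    rng = np.random.default_rng(seed)
    while True:
        tree = _yule_once(K, lambda_sp, rng)
        if min_depth_frac <= 0:
            break
        ages = [nd.age for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        if min(ages) >= min_depth_frac * max(ages):
            break
    _attach_supports(tree)
    return tree


# ---------------------------------------------------------------------------
# gene tree (coalescent within the species tree, via msprime)


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    samples_per_species: int | dict[str, int],
    theta: float,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Multispecies-coalescent gene tree glued into the species tree.

    All populations (tip and ancestral) share the coalescent scale ``theta``
    = mean pairwise coalescence time (haploid lineages coalesce at rate
    1/theta per pair).  Returns the ultrametric gene tree and a specimen ->
    species label map; specimen ids are ``<species>_<k>``.
    """
    if theta <= 0:
        raise InputError("theta must be > 0")
    newick = species_tree.as_string(schema="newick", suppress_rooting=True).strip()
    # haploid samples (ploidy=1): pairwise coalescence rate is 1/initial_size
    demography = msprime.Demography.from_species_tree(newick, initial_size=theta)
    species = [lf.taxon.label for lf in species_tree.leaf_node_iter()]
    if isinstance(samples_per_species, int):
        samples = {sp: samples_per_species for sp in species}
    else:
        samples = dict(samples_per_species)
    rng = np.random.default_rng(seed)
    ts = msprime.sim_ancestry(
        samples=samples, demography=demography, ploidy=1,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    t = ts.first()
    pop_name = {pid: pop.name for pid, pop in enumerate(demography.populations)}
    counter: dict[str, int] = {}
    labels: dict[str, str] = {}
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(u) -> dendropy.Node:
        nd = dendropy.Node()
        nd.age = t.time(u)
        kids = t.children(u)
        if not kids:
            sp = pop_name[ts.node(u).population]
            counter[sp] = counter.get(sp, 0) + 1
            sid = f"{sp}_{counter[sp]}"
            nd.taxon = taxa.require_taxon(sid)
            labels[sid] = sp
        for v in kids:
            child = build(v)
            child.edge.length = nd.age - child.age
            nd.add_child(child)
        return nd

    tree.seed_node = build(t.root)
    _attach_supports(tree)
    return tree, labels


# ---------------------------------------------------------------------------
# sequence evolution


def _rate_matrix(model: str, kappa: float = 2.0, freqs=None) -> tuple[np.ndarray, np.ndarray]:
    if model == "JC69":
        pi = np.full(4, 0.25)
        Q = np.full((4, 4), 1.0 / 3.0)
    elif model == "HKY85":
        pi = np.asarray(freqs if freqs is not None else [0.3, 0.2, 0.2, 0.3], dtype=float)
        pi = pi / pi.sum()
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = {i, j} in ({0, 2}, {1, 3})  # A<->G, C<->T
                Q[i, j] = (kappa if transition else 1.0) * pi[j]
    else:
        raise InputError(f"unknown substitution model: {model!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # normalise to one expected substitution per unit branch length
    scale = -float(np.sum(pi * np.diag(Q)))
    return Q / scale, pi


def simulate_sequences(
    gene_tree: dendropy.Tree,
    model: str = "JC69",
    seq_length: int = 586,
    rate: float = 1.0,
    seed: int = 0,
    kappa: float = 2.0,
    freqs=None,
) -> Alignment:
    """Evolve sequences along the tree; branch lengths are multiplied by
    ``rate`` to give expected substitutions per site."""
    Q, pi = _rate_matrix(model, kappa=kappa, freqs=freqs)
    rng = np.random.default_rng(seed)
    root = gene_tree.seed_node
    states = {id(root): rng.choice(4, size=seq_length, p=pi)}
    pmat_cache: dict[float, np.ndarray] = {}
    ids, seqs = [], []
    for nd in gene_tree.preorder_node_iter():
        if nd.parent_node is not None:
            bl = float(nd.edge.length or 0.0) * rate
            P = pmat_cache.get(bl)
            if P is None:
                P = expm(Q * bl) if bl > 0 else np.eye(4)
                P = np.maximum(P, 0)
                P = P / P.sum(axis=1, keepdims=True)
                pmat_cache[bl] = P
            parent = states[id(nd.parent_node)]
            cum = P.cumsum(axis=1)
            u = rng.random(seq_length)
            child = np.empty(seq_length, dtype=int)
            for s in range(4):
                mask = parent == s
                if mask.any():
                    child[mask] = np.searchsorted(cum[s], u[mask], side="right")
            states[id(nd)] = np.minimum(child, 3)
        if nd.is_leaf():
            ids.append(nd.taxon.label)
            seqs.append("".join(_BASES[s] for s in states[id(nd)]))
    return Alignment(ids, seqs)


def jc_expected_pdist(total_branch_length: float) -> float:
    """Expected p-distance for two tips separated by the given path of
    expected substitutions per site, under JC69."""
    return 0.75 * (1.0 - np.exp(-4.0 * total_branch_length / 3.0))


def _jc_distance(p: float) -> float:
    return -0.75 * np.log(1.0 - 4.0 * min(p, 0.7499) / 3.0)


def calibrate_rate(
    gene_tree: dendropy.Tree, labels: dict[str, str], calibration: tuple[str, float]
) -> float:
    """Substitution-rate scaler putting a between-species p-distance
    statistic (``min_between`` or ``median_between``) on target."""
    stat, target = calibration
    pdm = gene_tree.phylogenetic_distance_matrix()
    taxa = list(gene_tree.taxon_namespace)
    times = []
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1:]:
            if labels[ta.label] != labels[tb.label]:
                times.append(pdm.patristic_distance(ta, tb))
    if not times:
        raise InputError("no between-species pairs to calibrate on")
    if stat == "min_between":
        ref = min(times)
    elif stat == "median_between":
        ref = float(np.median(times))
    else:
        raise InputError(f"unknown calibration statistic: {stat!r}")
    return _jc_distance(target) / ref


# ---------------------------------------------------------------------------
# full dataset


def _divergence_summary(aln: Alignment, labels: dict[str, str]) -> dict:
    dm = pdist_matrix(aln)
    within, between = [], []
    for i, a in enumerate(aln.ids):
        for j in range(i + 1, aln.n):
            b = aln.ids[j]
            (within if labels[a] == labels[b] else between).append(dm.d[i, j])
    return {
        "max_within": max(within) if within else 0.0,
        "min_between": min(between) if between else float("nan"),
        "median_between": float(np.median(between)) if between else float("nan"),
    }


def _assign_supports(tree: dendropy.Tree, labels: dict[str, str], rng) -> None:
    # Deep (between-species) nodes and species MRCAs get high posterior-style
    # support; within-species nodes get low support, as in real consensus trees.
    totals: dict[str, int] = {}
    for sp in labels.values():
        totals[sp] = totals.get(sp, 0) + 1
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        tips = [lf.taxon.label for lf in nd.leaf_iter()]
        species = {labels[s] for s in tips}
        if len(species) >= 2 or len(tips) == totals[next(iter(species))]:
            nd.support = float(rng.uniform(0.97, 1.0))
        else:
            nd.support = float(rng.uniform(0.3, 0.9))


def make_dataset(config: SynthConfig) -> tuple[Alignment, SynthTruth, dendropy.Tree]:
    """One-call fixture: alignment (+duplicates), ground truth, and the true
    chronogram with synthetic support values.

    When ``enforce_regime`` is set, the gene-tree/sequence draw is retried
    (fresh subseed) until the realized alignment satisfies the configured
    within/between divergence regime, up to ``max_attempts``; the closest
    attempt is kept otherwise.
    """
    rng = np.random.default_rng(config.seed)
    best = None
    attempts = 0
    for attempt in range(max(1, config.max_attempts if config.enforce_regime else 1)):
        attempts = attempt + 1
        sub = int(rng.integers(0, 2**31 - 1))
        sp_tree = simulate_species_tree(
            config.K, config.lambda_sp, seed=sub, min_depth_frac=config.min_depth_frac
        )
        gene_tree, labels = simulate_gene_tree(
            sp_tree, config.samples_per_species, config.theta, seed=sub + 1
        )
        rate = calibrate_rate(gene_tree, labels, config.calibration)
        aln = simulate_sequences(
            gene_tree, model=config.model, seq_length=config.seq_length,
            rate=rate, seed=sub + 2,
        )
        summ = _divergence_summary(aln, labels)
        ok = (summ["max_within"] <= config.within_max
              and summ["min_between"] >= config.between_min)
        score = (max(0.0, summ["max_within"] - config.within_max)
                 + max(0.0, config.between_min - summ["min_between"]))
        if best is None or score < best[0]:
            best = (score, gene_tree, labels, aln, summ, rate)
        if ok or not config.enforce_regime:
            break
    _, gene_tree, labels, aln, summ, rate = best
    summ = dict(summ, rate=rate, attempts=attempts,
                regime_ok=bool(summ["max_within"] <= config.within_max
                               and summ["min_between"] >= config.between_min))

    _assign_supports(gene_tree, labels, rng)

    ids = list(aln.ids)
    seqs = list(aln.seqs)
    all_labels = dict(labels)
    n_extra = int(round(config.duplicate_fraction * len(ids)))
    if n_extra > 0:
        picks = rng.choice(len(aln.ids), size=n_extra, replace=True)
        for j, k in enumerate(picks):
            sid = f"{aln.ids[k]}_dup{j + 1}"
            ids.append(sid)
            seqs.append(aln.seqs[k])
            all_labels[sid] = labels[aln.ids[k]]
    full = Alignment(ids, seqs, labels=all_labels)
    truth = SynthTruth(
        labels=all_labels,
        gene_tree_newick=tree_to_newick(gene_tree),
        summaries=summ,
    )
    return full, truth, gene_tree


def make_nuclear_dataset(
    config: SynthConfig,
    shared_pairs: tuple[tuple[str, str], ...] = (),
    seq_length: int = 400,
    target_min_between: float = 0.012,
) -> tuple[Alignment, SynthTruth]:
    """Phased nuclear haplotypes on the same machinery at a lower rate.

    Two haplotypes per diploid specimen (ids ``<species>_<k>a/b``).  For each
    (donor, recipient) species pair in ``shared_pairs``, one recipient
    haplotype is overwritten with a donor haplotype, forcing cross-lineage
    haplotype sharing.
    """
    rng = np.random.default_rng(config.seed + 7)
    sp_tree = simulate_species_tree(
        config.K, config.lambda_sp, seed=int(rng.integers(0, 2**31 - 1)),
        min_depth_frac=config.min_depth_frac,
    )
    gene_tree, hap_labels = simulate_gene_tree(
        sp_tree, 2 * config.samples_per_species, config.theta,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    rate = calibrate_rate(gene_tree, hap_labels, ("min_between", target_min_between))
    aln = simulate_sequences(
        gene_tree, model=config.model, seq_length=seq_length, rate=rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    # rename haplotypes as a/b phases of diploid specimens
    ids, labels = [], {}
    for sid in aln.ids:
        sp, k = sid.rsplit("_", 1)
        k = int(k)
        spec = f"{sp}_{(k + 1) // 2}{'a' if k % 2 else 'b'}"
        ids.append(spec)
        labels[spec] = sp
    aln = Alignment(ids, list(aln.seqs), labels=labels)
    seqs = list(aln.seqs)
    for donor, recipient in shared_pairs:
        d_idx = [i for i, s in enumerate(aln.ids) if labels[s] == donor]
        r_idx = [i for i, s in enumerate(aln.ids) if labels[s] == recipient]
        if not d_idx or not r_idx:
            raise InputError(f"unknown species in shared pair ({donor}, {recipient})")
        seqs[r_idx[0]] = seqs[d_idx[0]]
    aln = Alignment(list(aln.ids), seqs, labels=labels)
    truth = SynthTruth(labels=labels,
                       gene_tree_newick=tree_to_newick(gene_tree),
                       summaries={"rate": rate})
    return aln, truth
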
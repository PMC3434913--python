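"""General mixed Yule-coalescent (GMYC) species delimitation.

The model treats an ultrametric single-locus tree as the concatenation of two
branching processes: older than a threshold time T, branching reflects
speciation (Yule-like, rate ``lambda1 * n^p1`` for n lineages); younger than
T, branching reflects within-species coalescence (rate ``lambda2 * n^p2`` on
the pooled coalescent lineages).  Waiting times between successive branching
events are modelled as independent exponentials whose rate sums the two class
rates; the exponents p allow departures from the strict Yule (p=1) and
neutral-coalescent scalings.  The maximum-likelihood T delimits entities (the
subtrees hanging below T); the model is compared against a single-process
null (no rate shift) by a likelihood-ratio test with 3 degrees of freedom.

A multiple-threshold variant lets the speciation-to-coalescent transition
vary across the tree: the set of species stems is generalised from the
branches crossing one global T to an arbitrary antichain ("cut"), grown
greedily from the single-threshold optimum one split at a time while each
added threshold (1 df) significantly improves the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .errors import ModelError
from .partition import Partition
from .treepart import set_node_ages

_EPS = 1e-12
_LOGLAM_BOUNDS = (np.log(1e-12), 30.0)
_P_BOUNDS = (0.0, 10.0)


# ---------------------------------------------------------------------------
# branching intervals


@dataclass
class BranchingIntervals:
    """Inter-event waiting intervals of an ultrametric tree, root to tips.

    Interval i runs between the (i+1)-th and (i+2)-th oldest branching event
    (the last one ends at the present) and carries ``n[i] = i + 2`` lineages
    for duration ``x[i]``.  Per-branch bookkeeping (parent/child ages, tip
    sets, child links) supports threshold classification and entity
    extraction.
    """

    n_tips: int
    ages: np.ndarray          # internal node ages, strictly decreasing
    x: np.ndarray             # interval durations, len m = n_tips - 1
    n: np.ndarray             # lineage counts per interval (2..n_tips)
    parent_age: np.ndarray    # per branch
    child_age: np.ndarray     # per branch (0 for tips)
    tips: list[frozenset[str]]            # per branch: descendant tip labels
    children: list[tuple[int, ...]]       # per branch: child branch indices
    root_children: tuple[int, ...]
    alive: np.ndarray = field(repr=False)  # (m, n_branches) incidence

    @property
    def m(self) -> int:
        return len(self.x)

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    def candidate_thresholds(self) -> np.ndarray:
        """Midpoints of every interval plus an older-than-root sentinel."""
        bounds = np.concatenate([self.ages, [0.0]])
        mids = (bounds[:-1] + bounds[1:]) / 2.0
        return np.concatenate([[self.root_age * (1 + 1e-6) + 1e-9], mids])

    def classify(self, T: float) -> tuple[np.ndarray, np.ndarray]:
        """(n_spec, n_coal) per interval for threshold T: a branch belongs to
        the speciation class while its parent node is older than T."""
        spec_mask = self.parent_age > T
        S = self.alive.astype(np.int64) @ spec_mask.astype(np.int64)
        return S, self.n - S

    def classify_cut(self, cut: list[int] | None) -> tuple[np.ndarray, np.ndarray]:
        """Classification for an arbitrary antichain of species-stem branches.

        ``cut`` lists branch indices whose subtrees are coalescent (the stem
        itself counts as speciation-class); ``None`` means the root, i.e. the
        whole tree is one coalescent population.
        """
        spec = np.zeros(len(self.parent_age), dtype=bool)
        if cut is not None:
            todo = list(cut)
            anc = self._ancestors()
            for b in todo:
                spec[b] = True
                p = anc[b]
                while p is not None and not spec[p]:
                    spec[p] = True
                    p = anc[p]
        S = self.alive.astype(np.int64) @ spec.astype(np.int64)
        return S, self.n - S

    def _ancestors(self) -> list[int | None]:
        anc: list[int | None] = [None] * len(self.children)
        for b, kids in enumerate(self.children):
            for k in kids:
                anc[k] = b
        return anc

    def crossing_branches(self, T: float) -> list[int]:
        return [b for b in range(len(self.parent_age))
                if self.parent_age[b] > T >= self.child_age[b]]

    def entities(self, T: float) -> tuple[frozenset[str], ...]:
        """Tip sets of the subtrees hanging below threshold T."""
        if T >= self.root_age:
            all_tips = frozenset().union(*(self.tips[b] for b in self.root_children))
            return (all_tips,)
        return tuple(self.tips[b] for b in self.crossing_branches(T))

    def cut_entities(self, cut: list[int] | None) -> tuple[frozenset[str], ...]:
        if cut is None:
            all_tips = frozenset().union(*(self.tips[b] for b in self.root_children))
            return (all_tips,)
        return tuple(self.tips[b] for b in cut)


def _jitter_ages(nodes, rng) -> None:
    # Enforce strictly decreasing internal-node ages (parents before children
    # in the sort) by nudging ties down by <= 1e-10; fixed seed upstream.
    prev = None
    for nd in nodes:
        if prev is not None and nd.age >= prev - 1e-13:
            nd.age = prev - float(rng.uniform(0.2, 1.0)) * 1e-10
        prev = nd.age


def branching_times(tree: dendropy.Tree, ultrametric_tol: float = 1e-9) -> BranchingIntervals:
    """Extract branching intervals from an ultrametric tree.

    Polytomies are resolved to zero-length binary branches first; tied node
    ages are separated by a deterministic jitter of at most 1e-10.
    """
    tree = tree.clone(depth=1)
    tree.resolve_polytomies()
    if sum(1 for _ in tree.leaf_node_iter()) < 3:
        raise ModelError("need >= 3 tips for branching intervals")
    set_node_ages(tree, ultrametric_tol=ultrametric_tol)

    order = {nd: k for k, nd in enumerate(tree.preorder_node_iter())}
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    internals.sort(key=lambda nd: (-nd.age, order[nd]))
    _jitter_ages(internals, np.random.default_rng(0))
    for lf in tree.leaf_node_iter():
        lf.age = 0.0

    branches = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    bindex = {nd: k for k, nd in enumerate(branches)}
    parent_age = np.array([nd.parent_node.age for nd in branches])
    child_age = np.array([nd.age for nd in branches])
    tips = [frozenset(lf.taxon.label for lf in nd.leaf_iter()) for nd in branches]
    children = [tuple(bindex[c] for c in nd.child_nodes()) for nd in branches]
    root_children = tuple(bindex[c] for c in tree.seed_node.child_nodes())

    ages = np.array(sorted((nd.age for nd in internals), reverse=True))
    bounds = np.concatenate([ages, [0.0]])
    x = bounds[:-1] - bounds[1:]
    m = len(x)
    n = np.arange(2, m + 2)
    alive = (parent_age[None, :] >= bounds[:-1, None] - _EPS) & (
        child_age[None, :] <= bounds[1:, None] + _EPS
    )
    if not np.array_equal(alive.sum(axis=1), n):
        raise ModelError("inconsistent lineage bookkeeping (tree may be malformed)")
    n_tips = m + 1
    return BranchingIntervals(
        n_tips=n_tips, ages=ages, x=x, n=n.astype(float),
        parent_age=parent_age, child_age=child_age, tips=tips,
        children=children, root_children=root_children, alive=alive,
    )


# ---------------------------------------------------------------------------
# null (single-process) model


@dataclass
class NullFit:
    lam: float
    p: float
    loglik: float


def null_loglik_profile(bi: BranchingIntervals, p: float) -> tuple[float, float]:
    """Closed-form lambda-hat and log-likelihood for fixed exponent p."""
    denom = float(np.sum(bi.n ** p * bi.x))
    m = bi.m
    lam = m / denom
    ll = m * np.log(lam) + p * float(np.sum(np.log(bi.n))) - m
    return lam, ll


def fit_null(bi: BranchingIntervals, fix_p: float | None = None) -> NullFit:
    """Single-process null: waiting times Exp(lambda * n^p).

    lambda has the closed form m / sum(n^p x); p is profiled by bounded
    1-D search on [0, 10] unless fixed.
    """
    if bi.m < 2:
        raise ModelError("need >= 2 intervals to fit the null model")
    if fix_p is not None:
        lam, ll = null_loglik_profile(bi, fix_p)
        return NullFit(lam, fix_p, ll)
    res = minimize_scalar(
        lambda p: -null_loglik_profile(bi, p)[1],
        bounds=_P_BOUNDS, method="bounded", options={"xatol": 1e-10},
    )
    lam, ll = null_loglik_profile(bi, float(res.x))
    return NullFit(lam, float(res.x), ll)


# ---------------------------------------------------------------------------
# GMYC likelihood and fits


def gmyc_loglik(S, C, x, lam1, p1, lam2, p2) -> float:
    A = np.where(S > 0, S, 1.0) ** p1 * (S > 0)
    B = np.where(C > 0, C, 1.0) ** p2 * (C > 0)
    b = lam1 * A + lam2 * B
    return float(np.sum(np.log(b)) - np.sum(b * x))


def _negll_grad(theta, S, C, x, lnS, lnC):
    l1, l2 = np.exp(theta[0]), np.exp(theta[1])
    p1, p2 = theta[2], theta[3]
    A = np.where(S > 0, S, 1.0) ** p1 * (S > 0)
    B = np.where(C > 0, C, 1.0) ** p2 * (C > 0)
    b = l1 * A + l2 * B
    ll = np.sum(np.log(b)) - np.sum(b * x)
    r = 1.0 / b - x
    g = np.array([
        l1 * np.sum(A * r),
        l2 * np.sum(B * r),
        l1 * np.sum(A * lnS * r),
        l2 * np.sum(B * lnC * r),
    ])
    return -ll, -g


def _opt_mixed(S, C, x, starts) -> tuple[float, np.ndarray]:
    """Maximise the two-class likelihood over (log lam1, log lam2, p1, p2)."""
    lnS = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), 0.0)
    lnC = np.where(C > 0, np.log(np.where(C > 0, C, 1.0)), 0.0)
    bounds = [_LOGLAM_BOUNDS, _LOGLAM_BOUNDS, _P_BOUNDS, _P_BOUNDS]
    best_ll, best_theta = -np.inf, None
    for th0 in starts:
        res = minimize(
            _negll_grad, np.asarray(th0, dtype=float), args=(S, C, x, lnS, lnC),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if -res.fun > best_ll:
            best_ll, best_theta = -float(res.fun), res.x.copy()
    return best_ll, best_theta


@dataclass
class GMYCFit:
    """Result of a GMYC fit (single or multiple threshold)."""

    model: str
    null_loglik: float
    gmyc_loglik: float
    lambda1: float
    p1: float
    lambda2: float
    p2: float
    T_hat: float
    lrt_stat: float
    lrt_df: int
    p_value: float
    entities: tuple[frozenset[str], ...]
    n_clusters: int
    n_singletons: int
    n_entities: int
    n_thresholds: int = 1
    single_loglik: float | None = None
    vs_single_stat: float | None = None
    vs_single_df: int | None = None
    vs_single_p: float | None = None

    def partition(self) -> Partition:
        return Partition(self.entities, method=f"gmyc-{self.model}", parameter=self.T_hat)


def _counts(entities) -> tuple[int, int, int]:
    clusters = sum(1 for e in entities if len(e) >= 2)
    singles = sum(1 for e in entities if len(e) == 1)
    return clusters, singles, clusters + singles


def entities_report(fit: GMYCFit) -> tuple[int, int, int]:
    """(clusters, singletons, total entities) of a fitted model."""
    return fit.n_clusters, fit.n_singletons, fit.n_entities


def _pure(S, C) -> bool:
    return bool(np.all(C == 0) or np.all(S == 0))


def _fit_from_best(bi, null, best_T, best_ll, best_theta, entities) -> GMYCFit:
    if best_theta is None:  # null-equivalent optimum
        lam1 = lam2 = null.lam
        p1 = p2 = null.p
    else:
        lam1, lam2 = float(np.exp(best_theta[0])), float(np.exp(best_theta[1]))
        p1, p2 = float(best_theta[2]), float(best_theta[3])
    lrt = max(0.0, 2.0 * (best_ll - null.loglik))
    ncl, nsi, nent = _counts(entities)
    return GMYCFit(
        model="single", null_loglik=null.loglik, gmyc_loglik=best_ll,
        lambda1=lam1, p1=p1, lambda2=lam2, p2=p2, T_hat=float(best_T),
        lrt_stat=lrt, lrt_df=3, p_value=float(chi2.sf(lrt, 3)),
        entities=entities, n_clusters=ncl, n_singletons=nsi, n_entities=nent,
    )


def fit_gmyc_single(
    bi: BranchingIntervals, candidate_thresholds: np.ndarray | None = None
) -> GMYCFit:
    """Profile the GMYC likelihood over candidate thresholds (interval
    midpoints) and return the ML fit.

    The sweep starts from the older-than-root sentinel, which reduces exactly
    to the null model, so the fitted likelihood can never fall below the null
    and ties resolve toward the older threshold (fewer entities).
    """
    if bi.m < 2:
        raise ModelError("cannot place a threshold with fewer than 3 node ages")
    null = fit_null(bi)
    null_theta = np.array([np.log(null.lam), np.log(null.lam), null.p, null.p])
    if candidate_thresholds is None:
        candidate_thresholds = bi.candidate_thresholds()
    cands = np.sort(np.asarray(candidate_thresholds, dtype=float))[::-1]

    best_T, best_ll, best_theta = float(cands[0]), null.loglik, None
    # sentinel / pure candidates score exactly the null likelihood
    prev_theta = null_theta
    for T in cands:
        S, C = bi.classify(float(T))
        if _pure(S, C):
            ll, theta = null.loglik, None
        else:
            ll, theta = _opt_mixed(S.astype(float), C.astype(float), bi.x,
                                   [prev_theta, null_theta])
            prev_theta = theta
        if ll > best_ll + 1e-9:
            best_T, best_ll, best_theta = float(T), ll, theta
    return _fit_from_best(bi, null, best_T, best_ll, best_theta, bi.entities(best_T))


def fit_gmyc_multiple(
    bi: BranchingIntervals,
    max_thresholds: int = 10,
    alpha: float = 0.05,
    single: GMYCFit | None = None,
) -> GMYCFit:
    """Multiple-threshold GMYC by greedy forward threshold addition.

    Starting from the single-threshold ML set of species stems, each step
    adds one local threshold: either a stem is split into its two children
    (that clade's transition moves tipward) or two sibling stems are merged
    into their parent (the transition moves rootward for that clade).  Each
    added threshold costs 1 df and is accepted while the chi-square
    improvement is significant at ``alpha``.  The multiple-threshold
    likelihood therefore never falls below the single-threshold one.
    """
    if single is None:
        single = fit_gmyc_single(bi)
    null = fit_null(bi)
    null_theta = np.array([np.log(null.lam), np.log(null.lam), null.p, null.p])

    if single.T_hat >= bi.root_age:
        cut: list[int] | None = None
    else:
        cut = bi.crossing_branches(single.T_hat)
    cur_ll = single.gmyc_loglik
    cur_theta = None if single.n_entities == 1 else np.array(
        [np.log(single.lambda1), np.log(single.lambda2), single.p1, single.p2])
    crit = chi2.isf(alpha, 1)
    n_thresholds = 1

    def evaluate(candidate_cut):
        S, C = bi.classify_cut(candidate_cut)
        if _pure(S, C):
            return null.loglik, None
        starts = [null_theta] if cur_theta is None else [cur_theta, null_theta]
        return _opt_mixed(S.astype(float), C.astype(float), bi.x, starts)

    anc = bi._ancestors()
    seen: set[frozenset[int]] = set()
    while n_thresholds < max_thresholds:
        moves = []
        if cut is None:
            moves.append(list(bi.root_children))
        else:
            for k, b in enumerate(cut):
                if bi.children[b]:
                    moves.append(cut[:k] + list(bi.children[b]) + cut[k + 1:])
            # merge sibling stems into their parent branch
            by_parent: dict[int | None, list[int]] = {}
            for b in cut:
                by_parent.setdefault(anc[b], []).append(b)
            for parent, sibs in by_parent.items():
                if parent is not None and len(sibs) == len(bi.children[parent]):
                    moves.append([parent] + [b for b in cut if b not in sibs])
        moves = [mv for mv in moves if frozenset(mv) not in seen]
        best_move = None
        for mv in moves:
            ll, theta = evaluate(mv)
            if best_move is None or ll > best_move[0]:
                best_move = (ll, theta, mv)
        if best_move is None or 2.0 * (best_move[0] - cur_ll) <= crit:
            break
        if cut is not None:
            seen.add(frozenset(cut))
        cur_ll, cur_theta, cut = best_move
        n_thresholds += 1

    entities = bi.cut_entities(cut)
    if cur_theta is None:
        lam1 = lam2 = null.lam
        p1 = p2 = null.p
    else:
        lam1, lam2 = float(np.exp(cur_theta[0])), float(np.exp(cur_theta[1]))
        p1, p2 = float(cur_theta[2]), float(cur_theta[3])
    lrt = max(0.0, 2.0 * (cur_ll - null.loglik))
    df = 3 + (n_thresholds - 1)
    vs_stat = max(0.0, 2.0 * (cur_ll - single.gmyc_loglik))
    vs_df = n_thresholds - 1
    ncl, nsi, nent = _counts(entities)
    return GMYCFit(
        model="multiple", null_loglik=null.loglik, gmyc_loglik=cur_ll,
        lambda1=lam1, p1=p1, lambda2=lam2, p2=p2, T_hat=single.T_hat,
        lrt_stat=lrt, lrt_df=df, p_value=float(chi2.sf(lrt, df)),
        entities=entities, n_clusters=ncl, n_singletons=nsi, n_entities=nent,
        n_thresholds=n_thresholds, single_loglik=single.gmyc_loglik,
        vs_single_stat=vs_stat, vs_single_df=vs_df,
        vs_single_p=float(chi2.sf(vs_stat, vs_df)) if vs_df > 0 else 1.0,
    )


def write_gmyc_report(fit: GMYCFit, path) -> None:
    with open(path, "w") as fh:
        fh.write("model\tnull_loglik\tgmyc_loglik\tlambda1\tp1\tlambda2\tp2\t"
                 "T_hat\tlrt_stat\tlrt_df\tp_value\tn_clusters\tn_singletons\tn_entities\n")
        fh.write(
            f"{fit.model}\t{fit.null_loglik:.6f}\t{fit.gmyc_loglik:.6f}\t"
            f"{fit.lambda1:.6g}\t{fit.p1:.4f}\t{fit.lambda2:.6g}\t{fit.p2:.4f}\t"
            f"{fit.T_hat:.6g}\t{fit.lrt_stat:.6f}\t{fit.lrt_df}\t{fit.p_value:.6g}\t"
            f"{fit.n_clusters}\t{fit.n_singletons}\t{fit.n_entities}\n"
        )
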
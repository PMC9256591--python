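"""Single-threshold GMYC (generalized mixed Yule-coalescent) species delimitation.

On an ultrametric tree, branching events older than a threshold height T are
attributed to between-species diversification and events younger than T to
within-cluster coalescence.  Inter-event waiting times are modelled as
exponential with rate

    b = lambda_div * n_div**p_div + lambda_coal * sum_k n_k * (n_k - 1)**p_coal

where ``n_div`` is the number of species-level lineages present and ``n_k``
the number of lineages inside cluster k (singleton clusters contribute no
coalescent rate).  For each candidate threshold (one per branching event,
plus "no threshold" = a single entity) the four parameters are fitted by
bounded maximum likelihood; the best T maximises the profile likelihood.  The
fit is compared against a single-class coalescent null
(``b = lambda * (n(n-1))**p``) with a likelihood-ratio test (chi-square,
3 degrees of freedom, the original single-threshold convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import ParameterError, TreeError
from .io import MotuPartition
from .trees import PhyloTree, is_ultrametric

_P_BOUNDS = (0.0, 3.0)
_LOGL_BOUNDS = (-25.0, 25.0)


@dataclass
class GmycFit:
    """Result of a single-threshold GMYC fit."""

    tree: PhyloTree
    thresholds: np.ndarray          # candidate T (event heights; inf = no threshold)
    logliks: np.ndarray             # maximised log-likelihood per candidate
    params: list[dict]              # fitted parameters per candidate
    best_index: int
    null_loglik: float
    null_params: dict
    assignments: dict[str, str]     # tip -> entity id at the best threshold
    n_entities: int                 # clusters + singletons
    n_clusters: int                 # entities with >= 2 tips

    @property
    def best_threshold(self) -> float:
        return float(self.thresholds[self.best_index])

    @property
    def best_loglik(self) -> float:
        return float(self.logliks[self.best_index])

    @property
    def lr_statistic(self) -> float:
        return max(0.0, 2.0 * (self.best_loglik - self.null_loglik))

    @property
    def lr_pvalue(self) -> float:
        return float(chi2.sf(self.lr_statistic, df=3))

    def partition(self, alpha: float | None = 0.05) -> MotuPartition:
        """MOTU partition at the best threshold.

        With *alpha* set, the single-entity null partition is returned when
        the likelihood-ratio test does not reject panmixia at that level.
        """
        if alpha is not None and self.lr_pvalue >= alpha:
            assignments = {tip: "C0" for tip in self.assignments}
        else:
            assignments = dict(self.assignments)
        return MotuPartition(
            assignments,
            method="GMYC",
            params={
                "threshold": self.best_threshold,
                "LR": self.lr_statistic,
                "p_value": self.lr_pvalue,
                "alpha": alpha,
            },
        ).canonical()

    def to_json_dict(self) -> dict:
        return {
            "method": "GMYC",
            "best_threshold": self.best_threshold,
            "loglik": self.best_loglik,
            "null_loglik": self.null_loglik,
            "LR": self.lr_statistic,
            "p_value": self.lr_pvalue,
            "n_entities": self.n_entities,
            "n_clusters": self.n_clusters,
            "params": self.params[self.best_index],
        }


def _event_table(tree: PhyloTree):
    """Internal nodes sorted by height (descending), with parent indices.

    Returns (heights, nodes, parent_index, tip_cluster_map builder inputs).
    Tied heights are separated by a tiny epsilon so event order is strict.
    """
    heights = tree.node_heights()
    internal = [n for n in tree.dendropy_tree.preorder_node_iter() if not n.is_leaf()]
    internal.sort(key=lambda n: -heights[n])
    h = np.array([heights[n] for n in internal], dtype=float)
    # enforce strictly decreasing heights (zero-length internal branches)
    for k in range(1, len(h)):
        if h[k] >= h[k - 1]:
            h[k] = h[k - 1] - 1e-12
    return h, internal


def _negloglik_mixed(theta, x, A, C_counts):
    """-logL for the mixed model.

    ``A``: per-interval diversification lineage count; ``C_counts``: list per
    interval of within-cluster lineage counts (array, possibly empty).
    """
    log_ld, log_lc, pd_, pc_ = theta
    ld, lc = np.exp(log_ld), np.exp(log_lc)
    b = ld * A**pd_
    for i, counts in enumerate(C_counts):
        if counts.size:
            b[i] += lc * np.sum(counts * (counts - 1.0) ** pc_)
    return -np.sum(np.log(b) - b * x)


def _negloglik_null(theta, x, n_lin):
    log_l, p = theta
    lam = np.exp(log_l)
    b = lam * (n_lin * (n_lin - 1.0)) ** p
    return -np.sum(np.log(b) - b * x)


def gmyc_partition(tree: PhyloTree, rel_tol: float = 1e-6) -> GmycFit:
    """Fit the single-threshold GMYC model to a rooted ultrametric tree."""
    if not tree.is_rooted:
        raise TreeError("GMYC requires a rooted tree")
    if tree.n_tips < 3:
        raise ParameterError("GMYC requires at least 3 tips")
    ok, dev = is_ultrametric(tree, rel_tol=rel_tol)
    if not ok:
        raise TreeError(
            f"GMYC requires an ultrametric tree (max relative depth deviation {dev:.3g})"
        )

    h, nodes = _event_table(tree)
    n_events = len(h)          # = n_tips - 1 for a binary tree
    node_rank = {id(n): k for k, n in enumerate(nodes)}

    # parent event rank for every internal node (root has none)
    parent_rank = np.full(n_events, -1, dtype=int)
    for k, node in enumerate(nodes):
        p = node.parent_node
        while p is not None and p.is_leaf():
            p = p.parent_node
        if p is not None:
            parent_rank[k] = node_rank[id(p)]

    # inter-event waiting times; interval i sits between events i and i+1
    x = h[:-1] - h[1:]
    n_int = len(x)
    if n_int == 0:
        raise ParameterError("tree has too few branching events for a GMYC fit")
    interval_rank = np.arange(1, n_int + 1)  # lineage count above = i+1

    def cluster_of(m: int, j: int) -> int:
        """Entity of event m (> j) under candidate j: the rank of its highest
        ancestor event that is itself below the threshold (<= j cut)."""
        k = m
        while parent_rank[k] > j - 1 and parent_rank[k] != -1:
            k = parent_rank[k]
        return k

    # --- null: one coalescent class over the whole tree --------------------
    n_lin = interval_rank + 1.0
    init0 = np.array([np.log(max(n_int / np.sum((n_lin * (n_lin - 1.0)) * x), 1e-8)), 1.0])
    res0 = minimize(
        _negloglik_null,
        init0,
        args=(x, n_lin),
        method="L-BFGS-B",
        bounds=[_LOGL_BOUNDS, _P_BOUNDS],
    )
    null_loglik = -float(res0.fun)
    null_params = {"lambda": float(np.exp(res0.x[0])), "p": float(res0.x[1])}

    # --- candidates: j = number of diversification (pre-threshold) events ---
    thresholds = np.empty(n_events + 1)
    logliks = np.empty(n_events + 1)
    params: list[dict] = []
    warm = np.array([0.0, 0.0, 1.0, 1.0])
    for j in range(n_events + 1):
        # diversification lineage count per interval: min(i, j) + 1
        A = np.minimum(interval_rank, j) + 1.0
        # within-cluster lineage counts for intervals i >= j
        C_counts: list[np.ndarray] = [np.empty(0)] * n_int
        if j < n_events:
            owner = np.array([cluster_of(m, j) for m in range(j, n_events)])
            # owner[m-j] = entity (event rank) containing coalescent event m;
            # in interval i the entity holds 1 stem lineage plus one per event
            for i in range(j, n_int):
                active = owner[: i - j + 1]
                if active.size:
                    _, counts = np.unique(active, return_counts=True)
                    C_counts[i] = counts + 1.0
        theta0 = warm.copy()
        res = minimize(
            _negloglik_mixed,
            theta0,
            args=(x, A, C_counts),
            method="L-BFGS-B",
            bounds=[_LOGL_BOUNDS, _LOGL_BOUNDS, _P_BOUNDS, _P_BOUNDS],
        )
        if not res.success and not np.isfinite(res.fun):
            raise ParameterError(
                f"GMYC optimiser failed at candidate {j}: {res.message}"
            )
        warm = res.x
        logliks[j] = -float(res.fun)
        thresholds[j] = np.inf if j == 0 else h[j - 1]
        params.append(
            {
                "lambda_div": float(np.exp(res.x[0])),
                "lambda_coal": float(np.exp(res.x[1])),
                "p_div": float(res.x[2]),
                "p_coal": float(res.x[3]),
                "n_diversification_events": j,
            }
        )

    best = int(np.argmax(logliks))

    # --- entities at the best threshold ------------------------------------
    j = best
    assignments: dict[str, str] = {}
    if j == 0:
        for tip in tree.tip_labels:
            assignments[tip] = "C0"
    else:
        # each tip belongs to the entity rooted where its ancestor chain last
        # crosses the threshold
        for leaf in tree.dendropy_tree.leaf_node_iter():
            p = leaf.parent_node
            rank = node_rank[id(p)]
            if rank <= j - 1:
                # parent is a diversification event: the tip is its own entity
                assignments[leaf.taxon.label] = f"T_{leaf.taxon.label}"
            else:
                assignments[leaf.taxon.label] = f"E{cluster_of(rank, j)}"
    sizes: dict[str, int] = {}
    for ent in assignments.values():
        sizes[ent] = sizes.get(ent, 0) + 1
    n_entities = len(sizes)
    n_clusters = sum(1 for s in sizes.values() if s >= 2)

    return GmycFit(
        tree=tree,
        thresholds=thresholds,
        logliks=logliks,
        params=params,
        best_index=best,
        null_loglik=null_loglik,
        null_params=null_params,
        assignments=assignments,
        n_entities=n_entities,
        n_clusters=n_clusters,
    )
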
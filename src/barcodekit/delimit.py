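"""MOTU delimitation: threshold clustering, barcode-gap ranking (ASAP-style),
the K/theta rule, the patristic distance threshold, and partition import.

All methods are deterministic given their inputs and recorded parameters.
MOTU ids are canonicalised (ordered by the lexicographically smallest member)
so partitions compare by value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .distances import DistanceMatrix
from .errors import (
    DegenerateInputError,
    ParameterError,
    PartitionError,
    SaturatedDistanceError,
)
from .io import MotuPartition, read_partition
from .trees import PhyloTree

from .gmyc import GmycFit, gmyc_partition  # noqa: F401  (re-exported, same module family)

__all__ = [
    "threshold_cluster",
    "asap_partition",
    "AsapResult",
    "kot_partition",
    "KotResult",
    "pdt_partition",
    "gmyc_partition",
    "GmycFit",
    "import_partition",
]


def threshold_cluster(
    dm: DistanceMatrix,
    t: float,
    linkage_method: str = "single",
    on_saturated: str = "error",
) -> MotuPartition:
    """Single-linkage clustering: MOTUs are connected components of the graph
    whose edges join pairs with distance strictly below *t*.

    With ``t = 0`` every specimen is its own MOTU (strict inequality); with
    *t* above the largest distance there is one MOTU.  Saturated (infinite)
    distances raise unless ``on_saturated="ignore"`` (infinite pairs simply
    contribute no edge).
    """
    if t < 0:
        raise ParameterError(f"threshold must be non-negative, got {t}")
    if linkage_method != "single":
        raise ParameterError("only single linkage is supported")
    if on_saturated not in ("error", "ignore"):
        raise ParameterError(f"unknown saturation policy {on_saturated!r}")
    if on_saturated == "error" and dm.saturated_pairs:
        raise SaturatedDistanceError(
            f"saturated pairs present: {dm.saturated_pairs}; "
            'pass on_saturated="ignore" to treat them as unlinked'
        )
    adj = dm.values < t
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(adj, directed=False)
    assignments = {sp: f"C{lab}" for sp, lab in zip(dm.ids, labels)}
    part = MotuPartition(
        assignments,
        method="threshold",
        params={"threshold": float(t), "linkage": "single"},
    )
    return part.canonical()


# ---------------------------------------------------------------------------
# ASAP-style barcode-gap ranking
# ---------------------------------------------------------------------------


@dataclass
class AsapResult:
    """Ranked nested candidate partitions from single-linkage agglomeration.

    Each candidate is scored by (a) a probability of panmixia ``p``
    (coalescent-motivated, aggregated multiplicatively over groups; lower
    means the groups are unlikely to be one panmictic species) and (b) the
    width ``w`` of the distance gap between the merge that created the
    partition and the next merge.  Candidates are ranked separately by ``p``
    (ascending) and ``w`` (descending); the ASAP score is the mean of the two
    ranks and the best partition minimises it.
    """

    table: pd.DataFrame
    partitions: list[MotuPartition]
    best_index: int

    @property
    def best_partition(self) -> MotuPartition:
        return self.partitions[self.best_index]

    @property
    def best_threshold(self) -> float:
        return float(self.table.loc[self.best_index, "d_star"])

    @property
    def best_score(self) -> float:
        return float(self.table.loc[self.best_index, "asap_score"])

    def to_json_dict(self) -> dict:
        return {
            "method": "ASAP",
            "best_index": int(self.best_index),
            "best_threshold": self.best_threshold,
            "best_score": self.best_score,
            "n_motus": self.best_partition.n_motus,
            "table": self.table.to_dict(orient="records"),
        }


def _pooled_within(values, members) -> "np.ndarray":
    """All within-group upper-triangle distances, pooled over groups."""
    chunks = []
    for idx in members:
        if len(idx) >= 2:
            sub = values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            chunks.append(sub[iu])
    return np.concatenate(chunks) if chunks else np.empty(0)


def asap_partition(dm: DistanceMatrix) -> AsapResult:
    """Rank the nested single-linkage partitions of a distance matrix.

    The candidate chain runs from the all-singleton partition through every
    partition formed at a distinct merge height up to the single cluster.
    Each candidate is scored by

    * a panmixia probability ``p``: under an exponential (coalescent) null at
      the partition's own within-group scale ``theta_hat`` (mean positive
      within-group distance, floored at the data's distance resolution), a
      group that is internally connected by merge height ``t_g`` yet
      separated from everything else by ``s_g`` has panmixia probability
      ``p_g = exp(-(s_g - t_g) / theta_hat)``.  Real, coherent species make
      ``p_g`` vanish (wide separation, shallow connection); fragments of a
      panmictic cluster (``s_g ~ t_g`` small) and lumped groups (internal
      links spanning the gap) both leave ``p_g`` near 1.  Aggregation over
      groups is multiplicative, normalised for group count (geometric mean).
    * the gap width ``w``: the distance between the merge that created the
      partition and the next merge.

    Candidates are ranked by ``p`` ascending and ``w`` descending; the score
    is the mean rank and the best partition minimises it (ties: lower p,
    then fewer MOTUs).  The reported threshold ``d_star`` is the midpoint of
    the interval over which the candidate is the clustering, i.e. inside the
    barcode gap for a gapped dataset.
    """
    n = len(dm)
    if n < 3:
        raise ParameterError(f"ASAP ranking needs at least 3 specimens, got {n}")
    if dm.saturated_pairs:
        raise SaturatedDistanceError(
            f"saturated pairs present: {dm.saturated_pairs}"
        )
    cond = dm.condensed()
    if np.allclose(cond, cond[0]):
        raise DegenerateInputError(
            "all pairwise distances are equal: no barcode gap is defined"
        )
    values = dm.values
    Z = linkage(cond, method="single")
    merge_heights = np.unique(Z[:, 2])

    from scipy.cluster.hierarchy import fcluster

    # internal connect height per cluster, tracked through the agglomeration:
    # active maps a scipy cluster id to (representative leaf, connect height)
    candidates = []  # (formed_at, next_height, labels, {leaf_rep: t})
    active = {i: (i, 0.0) for i in range(n)}
    candidates.append(
        (0.0, float(merge_heights[0]), np.arange(1, n + 1), dict(active.values()))
    )
    row = 0
    for k, h in enumerate(merge_heights):
        while row < len(Z) and Z[row, 2] <= h:
            a, b = int(Z[row, 0]), int(Z[row, 1])
            rep_a, _ = active.pop(a)
            active.pop(b)
            active[n + row] = (rep_a, float(Z[row, 2]))
            row += 1
        labels = fcluster(Z, t=np.nextafter(h, np.inf), criterion="distance")
        nxt = float(merge_heights[k + 1]) if k + 1 < len(merge_heights) else None
        candidates.append((float(h), nxt, labels, dict(active.values())))

    positive = cond[cond > 0]
    resolution = float(positive.min())  # the data's distance resolution
    rows = []
    partitions = []
    for formed_at, nxt, labels, connect in candidates:
        uniq = np.unique(labels)
        groups = [np.flatnonzero(labels == lab) for lab in uniq]
        within = _pooled_within(values, groups)
        within = within[within > 0]
        theta_hat = float(within.mean()) if within.size else resolution
        t_of_label = {labels[rep]: t for rep, t in connect.items()}
        log_p = 0.0
        if len(groups) > 1:
            parts = []
            for lab, idx in zip(uniq, groups):
                others = np.setdiff1d(np.arange(n), idx, assume_unique=True)
                s_g = float(values[np.ix_(idx, others)].min())
                t_g = t_of_label.get(lab, 0.0)
                parts.append(-max(0.0, s_g - t_g) / theta_hat)
            log_p = float(np.mean(parts))
        w = (nxt - formed_at) if nxt is not None else 0.0
        d_star = 0.5 * (formed_at + nxt) if nxt is not None else formed_at
        assignments = {dm.ids[i]: f"C{lab}" for i, lab in enumerate(labels)}
        part = MotuPartition(
            assignments, method="ASAP", params={"threshold": d_star}
        ).canonical()
        partitions.append(part)
        rows.append(
            {
                "formed_at": formed_at,
                "d_star": d_star,
                "n_motus": len(groups),
                "log_p": log_p,
                "p": float(np.exp(log_p)),
                "w": w,
            }
        )
    table = pd.DataFrame(rows)
    table["rank_p"] = rankdata(table["log_p"], method="average")
    table["rank_w"] = rankdata(-table["w"], method="average")
    table["asap_score"] = 0.5 * (table["rank_p"] + table["rank_w"])
    # best: lowest score; ties broken by lower p, then fewer MOTUs
    order = np.lexsort(
        (table["n_motus"], table["log_p"], table["asap_score"])
    )
    best = int(order[0])
    for part, rowt in zip(partitions, table.itertuples()):
        part.params.update({"asap_score": float(rowt.asap_score), "p": float(rowt.p)})
    return AsapResult(table=table, partitions=partitions, best_index=best)


# ---------------------------------------------------------------------------
# K/theta (the 4x rule)
# ---------------------------------------------------------------------------


@dataclass
class KotResult:
    """Hierarchical cut of a guide tree under the K/theta rule.

    At each visited node, K is the mean between-daughter-clade distance and
    theta the (maximal) mean within-daughter diversity; the node splits iff
    K/theta >= R.  ``records`` holds one row per tested node.
    """

    guide: PhyloTree
    threshold: float
    records: pd.DataFrame
    partition: MotuPartition

    def to_json_dict(self) -> dict:
        return {
            "method": f"KoT={self.threshold:g}",
            "n_motus": self.partition.n_motus,
            "records": self.records.to_dict(orient="records"),
        }


def _mean_within(values: np.ndarray, idx: list[int]) -> float | None:
    if len(idx) < 2:
        return None
    sub = values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def kot_partition(
    dm: DistanceMatrix, guide: PhyloTree, R: float = 4.0
) -> KotResult:
    """Apply the K/theta rule at every node of a guide tree.

    Sister clades are treated as distinct species when the mean between-clade
    distance K is at least *R* times the within-clade diversity theta
    (conservatively, theta is the larger of the daughters' diversities; a
    singleton daughter borrows its sister's theta, and when both daughters are
    singletons the smallest non-zero clade diversity elsewhere on the tree is
    used; nodes with no usable theta are untestable and do not split).

    Every internal node is tested and the tree is cut at every passing node:
    the MOTUs are the maximal clades that contain no passing node.  Deep
    nodes routinely fail the test (their "within-clade diversity" spans many
    species), so stopping the recursion at the first failure would collapse
    the whole tree into one MOTU; cutting at all passing nodes is what makes
    the rule behave as the splitter it is known to be.
    """
    if R <= 0:
        raise ParameterError(f"R must be positive, got {R}")
    if dm.saturated_pairs:
        raise SaturatedDistanceError(f"saturated pairs present: {dm.saturated_pairs}")
    tree = guide if guide.is_rooted else guide.midpoint_rooted()
    tips = set(tree.tip_labels)
    if tips != set(dm.ids):
        raise PartitionError(
            f"guide tree tips do not match distance matrix ids; "
            f"tree-only: {sorted(tips - set(dm.ids))}, "
            f"matrix-only: {sorted(set(dm.ids) - tips)}"
        )
    index = {sp: k for k, sp in enumerate(dm.ids)}
    values = dm.values

    dtree = tree.dendropy_tree
    tips_below: dict = {}
    cherry_thetas = []
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = [node.taxon.label]
        else:
            below = []
            for c in node.child_nodes():
                below.extend(tips_below[id(c)])
            tips_below[id(node)] = below
            # fallback yardstick: diversity of the shallowest clades only
            # (cherries), so it reflects within-population variation and not
            # the diversity of deep multi-species clades
            if all(c.is_leaf() for c in node.child_nodes()):
                th = _mean_within(values, [index[t] for t in below])
                if th is not None and th > 0:
                    cherry_thetas.append(th)
    fallback_theta = min(cherry_thetas) if cherry_thetas else None

    records = []
    passes: dict[int, bool] = {}
    contains_pass: dict[int, bool] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            contains_pass[id(node)] = False
            continue
        children = node.child_nodes()
        child_idx = [[index[t] for t in tips_below[id(c)]] for c in children]
        cross = []
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                cross.append(values[np.ix_(child_idx[a], child_idx[b])].ravel())
        K = float(np.concatenate(cross).mean())
        thetas = [_mean_within(values, idx) for idx in child_idx]
        defined = [t for t in thetas if t is not None]
        theta = max(defined) if defined else None
        if theta is None or theta == 0.0:
            # singleton daughters, or daughters without segregating variation:
            # borrow the smallest non-zero clade diversity seen on the tree
            theta = fallback_theta
        if theta:
            ratio = K / theta
            decision = "split" if ratio >= R else "merge"
        elif K > 0:
            # divergence against zero diversity anywhere on the tree
            ratio, decision = float("inf"), "split"
        else:
            ratio, decision = None, "untestable"
        passes[id(node)] = decision == "split"
        contains_pass[id(node)] = passes[id(node)] or any(
            contains_pass[id(c)] for c in children
        )
        records.append(
            {
                "clade_size": len(tips_below[id(node)]),
                "daughter_sizes": [len(i) for i in child_idx],
                "K": K,
                "theta": theta,
                "ratio": ratio,
                "decision": decision,
            }
        )

    clusters: list[list[str]] = []

    def visit(node):
        if node.is_leaf() or not contains_pass[id(node)]:
            clusters.append(tips_below[id(node)])
            return
        for c in node.child_nodes():
            visit(c)

    visit(dtree.seed_node)
    assignments = {}
    for k, members in enumerate(clusters):
        for sp in members:
            assignments[sp] = f"C{k}"
    part = MotuPartition(
        assignments, method="KoT", params={"R": float(R)}
    ).canonical()
    return KotResult(
        guide=tree,
        threshold=float(R),
        records=pd.DataFrame(records),
        partition=part,
    )


# ---------------------------------------------------------------------------
# Patristic distance threshold
# ---------------------------------------------------------------------------


def pdt_partition(dm_patristic: DistanceMatrix, t: float = 0.16) -> MotuPartition:
    """Patristic distance threshold: tips separated by a tree-path length of
    at least *t* substitutions per site (default 0.16, a published cut for
    crustacean COI) belong to different MOTUs.

    Implemented as single-linkage threshold clustering where path lengths
    strictly below *t* are conspecific edges.
    """
    part = threshold_cluster(dm_patristic, t=t, linkage_method="single")
    part.method = "PDT"
    part.params = {"threshold": float(t)}
    return part


# ---------------------------------------------------------------------------
# External partitions (e.g. BIN, PTP run elsewhere)
# ---------------------------------------------------------------------------


def import_partition(
    path: str | Path, method_name: str, specimens: list[str] | None = None
) -> MotuPartition:
    """Load an externally produced partition TSV and tag it with its method.

    When *specimens* is given, the file must not mention unknown specimens.
    """
    part = read_partition(path, method=method_name)
    if specimens is not None:
        unknown = sorted(set(part.assignments) - set(specimens))
        if unknown:
            raise PartitionError(
                f"partition {path} names specimens absent from the dataset: {unknown}"
            )
    return part
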
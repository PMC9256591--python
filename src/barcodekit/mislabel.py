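"""Reference-library auditing: flag sequences whose genetic placement
conflicts with their taxonomic label.

The manual practice this automates is inspecting a tree for "sequences of
species X clustering within species Y".  Here the decision rule is explicit
and distance-based so results are reproducible: a specimen is flagged when
its nearest heterospecific neighbour is closer than the species radius while
every conspecific (if any) lies at or beyond it; the flag is upgraded to
``strong`` when the specimen additionally sits inside another label's
single-linkage cluster with no conspecific alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix, encode
from .errors import DegenerateInputError, UndefinedDistanceError
from .io import BarcodeAlignment


@dataclass
class MislabelFlag:
    """A specimen whose placement conflicts with its label."""

    specimen_id: str
    label: str
    d_conspecific: float | None     # nearest same-label distance (None: singleton)
    d_heterospecific: float
    nearest_id: str
    suggested_label: str
    cluster_conflict: bool          # inside another label's cluster, no conspecific
    severity: str                   # "candidate" or "strong"


def audit_labels(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    species_radius: float = 0.07,
) -> list[MislabelFlag]:
    """Screen every labelled specimen against the species radius rule.

    *species_radius* defaults to 0.07 substitutions/site, the empirical scale
    above which COI-like barcodes usually separate species; pass the best
    barcode-gap threshold instead when one has been estimated.  Specimens
    that are the only sequence of their label can only be flagged via the
    heterospecific criterion and are capped at ``candidate`` severity.
    """
    label_arr = np.array([labels[i] for i in dm.ids])
    if len(set(label_arr)) < 2:
        raise DegenerateInputError(
            "audit requires at least two distinct labels"
        )
    values = dm.values
    n = len(dm.ids)

    # single-linkage clusters at the species radius (strict < edges)
    adj = values < species_radius
    np.fill_diagonal(adj, False)
    _, comp = connected_components(adj, directed=False)

    flags: list[MislabelFlag] = []
    for i in range(n):
        same = (label_arr == label_arr[i])
        same[i] = False
        other = ~same
        other[i] = False
        d_c = float(values[i, same].min()) if same.any() else None
        j = int(np.flatnonzero(other)[np.argmin(values[i, other])])
        d_h = float(values[i, j])
        if not (d_h < species_radius and (d_c is None or d_c >= species_radius)):
            continue
        mates = np.flatnonzero((comp == comp[i]) & (np.arange(n) != i))
        cluster_conflict = bool(
            mates.size
            and not np.any(label_arr[mates] == label_arr[i])
            and np.any(label_arr[mates] != label_arr[i])
        )
        severity = "strong" if (cluster_conflict and d_c is not None) else "candidate"
        flags.append(
            MislabelFlag(
                specimen_id=dm.ids[i],
                label=str(label_arr[i]),
                d_conspecific=d_c,
                d_heterospecific=d_h,
                nearest_id=dm.ids[j],
                suggested_label=str(label_arr[j]),
                cluster_conflict=cluster_conflict,
                severity=severity,
            )
        )
    return flags


@dataclass
class IdentityMatch:
    """Best reference match for a query sequence."""

    reference_id: str
    percent_identity: float
    n_comparable: int


def identity_report(query_seq: str, reference: BarcodeAlignment) -> IdentityMatch:
    """Best-matching reference sequence by percent identity.

    Identity = matches / comparable sites under pairwise deletion, over the
    reference with the highest identity (ties broken by more comparable
    sites, then by reference order).
    """
    q = encode(query_seq)
    best: IdentityMatch | None = None
    for rid, seq in zip(reference.ids, reference.seqs):
        r = encode(seq)
        if q.shape != r.shape:
            raise UndefinedDistanceError(
                f"query length {len(q)} does not match alignment width {len(r)}"
            )
        mask = (q < 4) & (r < 4)
        m = int(mask.sum())
        if m == 0:
            continue
        ident = 100.0 * float((mask & (q == r)).sum()) / m
        cand = IdentityMatch(rid, ident, m)
        if (
            best is None
            or cand.percent_identity > best.percent_identity
            or (
                cand.percent_identity == best.percent_identity
                and cand.n_comparable > best.n_comparable
            )
        ):
            best = cand
    if best is None:
        raise UndefinedDistanceError(
            "query shares no comparable sites with any reference sequence"
        )
    return best
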
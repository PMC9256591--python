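"""Barcode-gap analysis: intra- vs inter-specific distance decomposition.

The barcode gap is the empty interval between the distribution of distances
within morphospecies and the distribution of distances between them.  The gap
is defined on binned occupancy (does a bin contain any distance at all), not
on counts, mirroring the histogram presentation such analyses use: it is
therefore invariant to duplicating observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import DegenerateInputError, ParameterError


def split_intra_inter(
    dm: DistanceMatrix, morpho: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the finite upper-triangle distances into within- and
    between-morphospecies lists."""
    missing = sorted(set(dm.ids) - set(morpho))
    if missing:
        raise ParameterError(f"specimens without a morphospecies label: {missing}")
    labels = np.array([morpho[i] for i in dm.ids])
    iu = np.triu_indices(len(dm.ids), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    d = dm.values[iu]
    finite = np.isfinite(d)
    return d[same & finite], d[~same & finite]


def detect_gap(
    intra: np.ndarray, inter: np.ndarray, bin_width: float = 0.01
) -> tuple[float, float] | None:
    """Locate the empty-bin interval separating intra from inter distances.

    Bins of width *bin_width* are laid over ``[0, max)`` (half-open).  The gap
    is the run of bins, empty of both lists, between the highest bin holding
    an intraspecific distance and the lowest bin above it holding an
    interspecific one.  Returns ``(lo, hi)`` in distance units, or ``None``
    when no such empty run exists (overlapping distributions).
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    intra, inter = np.asarray(intra, float), np.asarray(inter, float)
    if intra.size == 0 or inter.size == 0:
        raise DegenerateInputError("both intra and inter lists must be non-empty")
    top = float(max(intra.max(), inter.max()))
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    occ_intra, _ = np.histogram(intra, bins=edges)
    occ_inter, _ = np.histogram(inter, bins=edges)
    i_hi = int(np.flatnonzero(occ_intra > 0).max())
    above = np.flatnonzero(occ_inter[i_hi + 1 :] > 0)
    if above.size == 0:
        return None
    j_lo = i_hi + 1 + int(above.min())
    between = slice(i_hi + 1, j_lo)
    if np.any(occ_intra[between] > 0) or np.any(occ_inter[between] > 0):
        return None  # unreachable given j_lo minimality; defensive
    if j_lo == i_hi + 1:
        return None  # adjacent occupied bins: no empty interval
    return float(edges[i_hi + 1]), float(edges[j_lo])


@dataclass
class GapReport:
    """Distance decomposition, binned histogram, modal bins and gap interval."""

    intra: np.ndarray
    inter: np.ndarray
    bin_width: float
    histogram: pd.DataFrame       # bin_lo, bin_hi, intra_count, inter_count
    gap: tuple[float, float] | None
    modal_inter_bins: list[tuple[float, float]]
    reference_threshold: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "n_intra_pairs": int(self.intra.size),
            "n_inter_pairs": int(self.inter.size),
            "bin_width": self.bin_width,
            "gap": list(self.gap) if self.gap is not None else None,
            "modal_inter_bins": [list(b) for b in self.modal_inter_bins],
            "max_intra": float(self.intra.max()) if self.intra.size else None,
            "min_inter": float(self.inter.min()) if self.inter.size else None,
            "reference_threshold": self.reference_threshold,
        }


def gap_report(
    dm: DistanceMatrix,
    morpho: Mapping[str, str],
    bin_width: float = 0.01,
    reference_threshold: float | None = None,
) -> GapReport:
    """Full barcode-gap report for a labelled distance matrix.

    *reference_threshold* records a delimitation threshold (e.g. the best
    barcode-gap ranking threshold) for display alongside the histogram.
    """
    intra, inter = split_intra_inter(dm, morpho)
    if intra.size == 0 or inter.size == 0:
        raise DegenerateInputError(
            "gap analysis needs both intra- and inter-specific pairs"
        )
    top = float(max(intra.max(), inter.max()))
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    c_intra, _ = np.histogram(intra, bins=edges)
    c_inter, _ = np.histogram(inter, bins=edges)
    hist = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "intra_count": c_intra,
            "inter_count": c_inter,
        }
    )
    peak = c_inter.max()
    modal = [
        (float(edges[k]), float(edges[k + 1]))
        for k in np.flatnonzero(c_inter == peak)
    ]
    return GapReport(
        intra=intra,
        inter=inter,
        bin_width=bin_width,
        histogram=hist,
        gap=detect_gap(intra, inter, bin_width),
        modal_inter_bins=modal,
        reference_threshold=reference_threshold,
    )
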
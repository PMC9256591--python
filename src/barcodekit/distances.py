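"""Pairwise genetic distances and the distance histogram.

Three distance models are provided, all under pairwise deletion (per pair of
sequences, only columns where both carry an unambiguous A/C/G/T are compared):

* ``k2p``   -- Kimura two-parameter distance.  With P the proportion of
  transitions and Q the proportion of transversions among comparable sites,
  d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).
* ``p``     -- uncorrected proportion of differing comparable sites.
* ``ndiff`` -- raw count of differing comparable sites.

Saturated pairs (the K2P logs undefined because 1-2P-Q <= 0 or 1-2Q <= 0) are
reported as ``+inf`` and must be excluded from downstream clustering by an
explicit policy rather than silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedDistanceError
from .io import BarcodeAlignment

MODELS = ("k2p", "p", "ndiff", "patristic")

# Base encoding: A,C,G,T -> 0..3 so that the transition partner of code b is
# (b + 2) % 4 and the two transversion partners are (b +/- 1) % 4.  Everything
# else (gaps, N, IUPAC ambiguity) is missing data under pairwise deletion.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (4 = missing/ambiguous)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _site_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(comparable, transitions, transversions) for two encoded sequences."""
    if a.shape != b.shape:
        raise UndefinedDistanceError("sequences have different lengths")
    mask = (a < 4) & (b < 4)
    m = int(mask.sum())
    if m == 0:
        raise UndefinedDistanceError("zero comparable sites under pairwise deletion")
    diff = mask & (a != b)
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return m, ts, tv


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance in substitutions per site.

    Returns ``inf`` when the pair is saturated.
    """
    m, ts, tv = _site_counts(encode(seq_a), encode(seq_b))
    P, Q = ts / m, tv / m
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("inf")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing comparable sites."""
    m, ts, tv = _site_counts(encode(seq_a), encode(seq_b))
    return (ts + tv) / m


def ndiff_distance(seq_a: str, seq_b: str) -> int:
    """Number of differing comparable sites (pairwise deletion)."""
    _, ts, tv = _site_counts(encode(seq_a), encode(seq_b))
    return ts + tv


_PAIRWISE = {"k2p": k2p_distance, "p": p_distance, "ndiff": ndiff_distance}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by specimen ids."""

    ids: list[str]
    values: np.ndarray
    model: str = "k2p"
    deletion_policy: str = "pairwise"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ParameterError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(np.diag(self.values), 0.0):
            raise ParameterError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values)
        sym = self.values.copy()
        sym[~finite] = -1.0
        if not np.allclose(sym, sym.T):
            raise ParameterError("distance matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        """Pairs whose distance is the +inf saturation sentinel."""
        out = []
        iu = np.triu_indices(len(self.ids), k=1)
        for i, j in zip(*iu):
            if not np.isfinite(self.values[i, j]):
                out.append((self.ids[i], self.ids[j]))
        return out

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(k) for k in keep]
        return DistanceMatrix(
            ids=list(keep),
            values=self.values[np.ix_(idx, idx)],
            model=self.model,
            deletion_policy=self.deletion_policy,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="specimen_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, model: str = "k2p") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(), model=model)


def distance_matrix(aln: BarcodeAlignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix for an alignment under the chosen model."""
    if model not in _PAIRWISE:
        raise ParameterError(f"unknown model {model!r}; choose from {sorted(_PAIRWISE)}")
    n = len(aln)
    if n < 2:
        raise ParameterError("need at least 2 sequences for a distance matrix")
    enc = [encode(s) for s in aln.seqs]
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                # reuse the encoded arrays rather than re-encoding strings
                m, ts, tv = _site_counts(enc[i], enc[j])
            except UndefinedDistanceError as exc:
                raise UndefinedDistanceError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}): {exc}"
                ) from exc
            if model == "ndiff":
                d = float(ts + tv)
            elif model == "p":
                d = (ts + tv) / m
            else:
                P, Q = ts / m, tv / m
                w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if w1 <= 0.0 or w2 <= 0.0:
                    d = float("inf")
                else:
                    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(aln.ids), values=values, model=model)


def distance_histogram(
    dm: DistanceMatrix, bin_width: float = 0.01
) -> pd.DataFrame:
    """Bin the upper-triangle distances into half-open bins ``[lo, hi)``.

    Saturated pairs are excluded from the counts (they are available from
    :attr:`DistanceMatrix.saturated_pairs`).  The counts sum to n(n-1)/2 minus
    the number of excluded pairs.
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    d = dm.condensed()
    d = d[np.isfinite(d)]
    hi = max(float(d.max()), 0.0) if d.size else 0.0
    n_bins = int(np.floor(hi / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )
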
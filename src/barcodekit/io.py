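"""Readers and writers for alignments, specimen metadata, MOTU partitions and trees.

The on-disk formats are deliberately plain: aligned multi-FASTA (gap ``-``),
UTF-8 TSV metadata with a header (``specimen_id``, ``morphospecies``,
``marker`` plus free extra columns), partition TSV (``specimen_id``,
``motu_id``) and newick trees with branch lengths.  Every reader validates the
type invariants and names offending records in its error message.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, ParameterError, PartitionError, ReconciliationError

MARKERS = ("COI-like", "16S-like", "other")

#: IUPAC nucleotide alphabet accepted in aligned sequences.
_ALPHABET = set("ACGTRYSWKMBDHVN-")

#: Genetic-code aliases -> NCBI translation table ids.
GENETIC_CODES = {
    "standard": 1,
    "vertebrate-mito": 2,
    "invertebrate-mito": 5,
}


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher specimen: id, morphospecies label and marker."""

    specimen_id: str
    morphospecies: str
    marker: str = "other"
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.specimen_id:
            raise ReconciliationError("specimen_id must be non-empty")
        if not self.morphospecies:
            raise ReconciliationError(
                f"specimen {self.specimen_id!r}: morphospecies must be non-empty"
            )


@dataclass
class BarcodeAlignment:
    """An aligned set of barcode sequences plus per-specimen metadata.

    Sequences are stored uppercased with U mapped to T; every sequence id must
    resolve to exactly one :class:`SpecimenRecord`.
    """

    ids: list[str]
    seqs: list[str]
    records: dict[str, SpecimenRecord]
    marker: str = "other"

    def __post_init__(self):
        if not self.ids:
            raise AlignmentError("alignment contains no sequences")
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            offenders = [
                f"{i} ({len(s)} bp)"
                for i, s in zip(self.ids, self.seqs)
                if len(s) != len(self.seqs[0])
            ]
            raise AlignmentError(
                "sequences are not all the same length: " + ", ".join(offenders)
            )
        missing = [i for i in self.ids if i not in self.records]
        if missing:
            raise ReconciliationError(
                f"sequence ids without metadata: {sorted(missing)}"
            )
        for i, s in zip(self.ids, self.seqs):
            bad = set(s) - _ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {i!r} contains unexpected symbols {sorted(bad)}"
                )

    @property
    def alignment_length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, specimen_id: str) -> str:
        return self.seqs[self.ids.index(specimen_id)]

    def morphospecies(self) -> dict[str, str]:
        """specimen_id -> morphospecies label, in alignment order."""
        return {i: self.records[i].morphospecies for i in self.ids}


@dataclass
class MotuPartition:
    """A species hypothesis: every specimen assigned to exactly one MOTU."""

    assignments: dict[str, str]
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.assignments:
            raise PartitionError("partition assigns no specimens")

    @property
    def n_motus(self) -> int:
        return len(set(self.assignments.values()))

    def motus(self) -> dict[str, list[str]]:
        """motu_id -> sorted member specimen ids."""
        groups: dict[str, list[str]] = {}
        for sp, motu in self.assignments.items():
            groups.setdefault(motu, []).append(sp)
        return {m: sorted(v) for m, v in groups.items()}

    def canonical(self) -> "MotuPartition":
        """Relabel MOTUs deterministically by their lexicographically smallest member."""
        groups = sorted(self.motus().values(), key=lambda g: g[0])
        width = max(4, len(str(len(groups))))
        assignments = {}
        for k, members in enumerate(groups, start=1):
            motu = f"M{k:0{width}d}"
            for sp in members:
                assignments[sp] = motu
        return MotuPartition(assignments, method=self.method, params=dict(self.params))

    def same_clustering(self, other: "MotuPartition") -> bool:
        """True iff the two partitions group specimens identically (ids ignored)."""
        mine = {frozenset(g) for g in self.motus().values()}
        theirs = {frozenset(g) for g in other.motus().values()}
        return mine == theirs


def _clean_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata TSV; extra columns are preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "morphospecies", "marker"}
    missing = required - set(df.columns)
    if missing:
        raise ReconciliationError(
            f"metadata {path} lacks required columns: {sorted(missing)}"
        )
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise ReconciliationError(f"duplicate specimen_id in metadata: {sorted(set(dupes))}")
    return df


def _records_from_metadata(df: pd.DataFrame) -> dict[str, SpecimenRecord]:
    extras = [c for c in df.columns if c not in ("specimen_id", "morphospecies", "marker")]
    records = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        records[d["specimen_id"]] = SpecimenRecord(
            specimen_id=d["specimen_id"],
            morphospecies=d["morphospecies"],
            marker=d["marker"] or "other",
            extra={c: d[c] for c in extras},
        )
    return records


def read_alignment(path: str | Path, metadata_path: str | Path) -> BarcodeAlignment:
    """Read an aligned FASTA plus its metadata TSV into a validated alignment.

    Raises :class:`AlignmentError` on unequal lengths and
    :class:`ReconciliationError` (naming the offenders) when FASTA ids and
    metadata rows do not match one-to-one.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(_clean_seq(str(rec.seq)))
    if not ids:
        raise AlignmentError(f"no sequences found in {path}")
    df = read_metadata(metadata_path)
    records = _records_from_metadata(df)
    in_fasta_only = sorted(set(ids) - set(records))
    if in_fasta_only:
        raise ReconciliationError(
            f"sequence ids absent from metadata: {in_fasta_only}"
        )
    present = {i: records[i] for i in ids}
    markers = {r.marker for r in present.values()}
    marker = markers.pop() if len(markers) == 1 else "other"
    return BarcodeAlignment(ids=ids, seqs=seqs, records=present, marker=marker)


def write_alignment(aln: BarcodeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n{s}\n")


def check_coding_frame(
    aln: BarcodeAlignment,
    genetic_code: int | str = "invertebrate-mito",
    frame: int = 0,
) -> pd.DataFrame:
    """Screen a protein-coding alignment for premature stop codons.

    Pseudogenes (NUMTs) of mitochondrial coding genes typically acquire frame
    shifts and premature stops, so any in-frame stop codon flags a sequence as
    a putative pseudogene.  Gap-only codons are skipped; codons containing
    gaps, N or IUPAC ambiguity codes translate to "unknown" and are never
    counted as stops.  Report-only: returns one row per sequence with columns
    ``specimen_id``, ``has_stop``, ``stop_codons`` (0-based codon indices).
    """
    if isinstance(genetic_code, str):
        table_id = GENETIC_CODES.get(genetic_code)
        if table_id is None:
            raise ParameterError(
                f"unknown genetic code {genetic_code!r}; use an NCBI table id "
                f"or one of {sorted(GENETIC_CODES)}"
            )
    else:
        table_id = int(genetic_code)
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    rows = []
    for sid, seq in zip(aln.ids, aln.seqs):
        hits = []
        for k, start in enumerate(range(frame, len(seq) - 2, 3)):
            codon = seq[start : start + 3]
            if set(codon) == {"-"}:
                continue  # gap-only codon: alignment padding, not sequence
            if any(c not in "ACGT" for c in codon):
                continue  # partial gap / ambiguity -> unknown amino acid
            if codon in stops:
                hits.append(k)
        rows.append({"specimen_id": sid, "has_stop": bool(hits), "stop_codons": hits})
    return pd.DataFrame(rows)


def read_partition(path: str | Path, method: str = "", params: dict | None = None) -> MotuPartition:
    """Read a partition TSV (columns ``specimen_id``, ``motu_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"specimen_id", "motu_id"}
    if not required <= set(df.columns):
        raise PartitionError(
            f"partition {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise PartitionError(f"specimen(s) listed more than once: {sorted(set(dupes))}")
    return MotuPartition(
        assignments=dict(zip(df["specimen_id"], df["motu_id"])),
        method=method,
        params=params or {},
    )


def write_partition(part: MotuPartition, path: str | Path) -> None:
    df = pd.DataFrame(
        {"specimen_id": list(part.assignments), "motu_id": list(part.assignments.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_newick(path: str | Path, metadata: Iterable[str] | None = None):
    """Read a newick tree; warn (not fail) if tips are absent from *metadata*."""
    from .trees import PhyloTree

    tree = PhyloTree.read(path)
    if metadata is not None:
        known = set(metadata)
        unknown = sorted(set(tree.tip_labels) - known)
        if unknown:
            import warnings

            warnings.warn(
                f"tree tips not present in metadata (tree-only use): {unknown}",
                stacklevel=2,
            )
    return tree


def write_newick(tree, path: str | Path) -> None:
    tree.write(path)
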
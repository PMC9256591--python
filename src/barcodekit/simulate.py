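"""Synthetic barcode datasets with known ground truth.

The generator emulates the statistical shape of a regional barcode survey:
a Yule species tree, a within-species Kingman coalescent grafted below each
species tip (no incomplete lineage sorting: each species coalesces fully
before joining the species tree), and site-independent two-parameter
(transition rate != transversion rate) sequence evolution, gap-free.
Scenario planting distorts the morphospecies labels relative to the genetic
truth: cryptic splits (two genetic species under one name), synonym lumps
(one genetic species under two names) and mislabels (a specimen carrying a
well-separated species' name).

Defaults mirror the survey the toolkit was built around: ~54 morphospecies,
a truncated-geometric 1..24 sequences per species with mean 5, 641 bp,
intraspecific diversity theta = 0.02 substitutions/site and a species tree
scaled so the modal interspecific distance sits near 0.22-0.24.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .distances import DistanceMatrix
from .errors import ParameterError
from .io import BarcodeAlignment, MotuPartition, SpecimenRecord, write_alignment, write_partition
from .trees import PhyloTree, patristic_matrix


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the generator, with survey-shaped defaults.

    ``theta`` is the expected intraspecific pairwise distance (subs/site);
    ``tree_height`` the species-tree root height and ``min_divergence`` a
    floor applied to internal node heights (guaranteeing a minimum species
    separation of twice that value); ``kappa`` the transition/transversion
    rate ratio of the substitution process.
    """

    n_species: int = 54
    seqs_per_species: int | Sequence[int] | str = "geometric"
    mean_seqs: float = 5.0
    min_seqs: int = 1
    max_seqs: int = 24
    locus_length: int = 641
    kappa: float = 4.0
    theta: float = 0.02
    tree_height: float = 0.115
    min_divergence: float = 0.05
    birth_rate: float = 1.0
    n_cryptic: int = 0
    n_synonym: int = 0
    n_mislabels: int = 0
    marker: str = "COI-like"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_species", "locus_length"):
            if getattr(self, name) < 2:
                raise ParameterError(f"{name} must be >= 2")
        for name in ("n_cryptic", "n_synonym", "n_mislabels"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.theta <= 0 or self.tree_height <= 0 or self.birth_rate <= 0:
            raise ParameterError("theta, tree_height and birth_rate must be positive")

    def to_json(self) -> str:
        d = asdict(self)
        if not isinstance(d["seqs_per_species"], (int, str)):
            d["seqs_per_species"] = list(d["seqs_per_species"])
        return json.dumps(d, indent=1)


def gapped_preset(
    n_species: int = 20, seqs_per_species: int = 5, seed: int = 42, **overrides
) -> SimulationConfig:
    """A preset with an unambiguous barcode gap.

    Effectively clonal intraspecific diversity (theta = 1e-6, i.e. species
    are single haplotypes) against deep, floored
    species divergences (internal heights in [0.12, 0.30], i.e. every
    interspecific path length >= 0.24).  The preset's defining property is
    that the gap is unambiguous, so recovery failures indicate an incorrect
    implementation rather than a lack of statistical power; power against
    realistic within-species coalescent variation is what the survey-shaped
    defaults exercise.
    """
    params = dict(
        n_species=n_species,
        seqs_per_species=seqs_per_species,
        theta=1e-6,
        tree_height=0.30,
        min_divergence=0.12,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "height", "label", "time")

    def __init__(self, label: str | None = None):
        self.children: list[_Node] = []
        self.height = 0.0
        self.label = label
        self.time = 0.0


def _emit(node: _Node) -> str:
    if not node.children:
        return node.label
    parts = [
        f"{_emit(c)}:{node.height - c.height:.12g}" for c in node.children
    ]
    return "(" + ",".join(parts) + ")"


def _leaves(node: _Node) -> list[_Node]:
    if not node.children:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves(c))
    return out


def _internal(node: _Node) -> list[_Node]:
    if not node.children:
        return []
    out = [node]
    for c in node.children:
        out.extend(_internal(c))
    return out


def simulate_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed=0,
    height: float | None = None,
    min_divergence: float | None = None,
) -> PhyloTree:
    """A Yule (pure-birth) species tree with *n_species* tips.

    Optionally rescaled so the root sits at *height* and every internal node
    at or above *min_divergence* (linear map of node heights; topology and
    height order preserved).  Deterministic for a fixed seed.
    """
    if n_species < 2:
        raise ParameterError("a species tree needs at least 2 species")
    rng = _rng(seed)
    root = _Node()
    active = [root]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.time = t
        node.children = [_Node(), _Node()]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / (n_species * birth_rate))
    for leaf in active:
        leaf.time = t_end
    for node in _internal(root) + _leaves(root):
        node.height = t_end - node.time
    width = max(2, len(str(n_species)))
    for k, leaf in enumerate(_leaves(root), start=1):
        leaf.label = f"sp{k:0{width}d}"

    if height is not None:
        internals = _internal(root)
        h = np.array([nd.height for nd in internals])
        h_root, h_min = h.max(), h.min()
        if min_divergence is not None and h_root > h_min:
            scale = (height - min_divergence) / (h_root - h_min)
            new = min_divergence + (h - h_min) * scale
        else:
            new = h * (height / h_root) if h_root > 0 else np.full_like(h, height)
        for nd, nh in zip(internals, new):
            nd.height = float(nh)
    return PhyloTree.from_newick(_emit(root) + ";", rooted=True)


def _coalesce(labels: list[str], theta: float, rng, max_height: float | None) -> _Node:
    """Kingman coalescent over *labels*; pairwise coalescence rate 2/theta so
    the expected pairwise distance on the resulting clock tree is theta."""
    nodes = [_Node(label=lab) for lab in labels]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(theta / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = _Node()
        parent.height = t
        parent.children = [nodes[i], nodes[j]]
        nodes = [nd for m, nd in enumerate(nodes) if m not in (i, j)] + [parent]
    root = nodes[0]
    if max_height is not None and root.height >= max_height:
        # squeeze the within-species genealogy under its species branch
        f = max_height / root.height
        for nd in _internal(root):
            nd.height *= f
    return root


def simulate_gene_tree(
    species_tree: PhyloTree,
    samples: Mapping[str, int] | int,
    theta: float,
    seed=0,
) -> PhyloTree:
    """Graft a within-species coalescent below each species tip.

    Tips are named ``<species>_<k>``.  Each species' genealogy is capped at
    90% of the height of its parent node in the species tree, so the gene
    tree is ultrametric and concordant with the species tree.
    """
    rng = _rng(seed)
    if isinstance(samples, int):
        samples = {sp: samples for sp in species_tree.tip_labels}
    heights = species_tree.node_heights()

    def build(node) -> _Node:
        if node.is_leaf():
            sp = node.taxon.label
            k = samples[sp]
            if k < 1:
                raise ParameterError(f"species {sp} needs at least 1 sample")
            labels = [f"{sp}_{m}" for m in range(1, k + 1)]
            parent_h = heights[node.parent_node] if node.parent_node else None
            cap = 0.9 * parent_h if parent_h else None
            return _coalesce(labels, theta, rng, cap)
        out = _Node()
        out.height = heights[node]
        out.children = [build(c) for c in node.child_nodes()]
        return out

    root = build(species_tree.dendropy_tree.seed_node)
    return PhyloTree.from_newick(_emit(root) + ";", rooted=True)


# ---------------------------------------------------------------------------
# sequence evolution (K80 process)
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def evolve_sequences(
    tree: PhyloTree,
    length: int = 641,
    kappa: float = 4.0,
    seed=0,
    marker: str = "COI-like",
) -> BarcodeAlignment:
    """Simulate gap-free sequences along *tree* under the two-parameter model.

    Branch lengths are expected substitutions per site; the process is
    normalised so one time unit equals one expected substitution.  Tip labels
    of the form ``<species>_<k>`` yield morphospecies ``<species>`` in the
    attached metadata.
    """
    if kappa <= 0:
        raise ParameterError("kappa must be positive")
    rng = _rng(seed)
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    dtree = tree.dendropy_tree
    seqs: dict[int, np.ndarray] = {}
    seqs[id(dtree.seed_node)] = rng.integers(0, 4, size=length).astype(np.int8)
    tips: dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            parent_seq = seqs[id(node)]
        else:
            t = node.edge.length or 0.0
            parent_seq = seqs[id(node.parent_node)]
            e1 = np.exp(-4.0 * beta * t)
            e2 = np.exp(-2.0 * (alpha + beta) * t)
            p_same = 0.25 + 0.25 * e1 + 0.5 * e2
            p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
            p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
            u = rng.random(length)
            child = parent_seq.copy()
            ts_mask = (u >= p_same) & (u < p_same + p_ts)
            tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
            tv2 = u >= p_same + p_ts + p_tv
            child[ts_mask] = (parent_seq[ts_mask] + 2) % 4
            child[tv1] = (parent_seq[tv1] + 1) % 4
            child[tv2] = (parent_seq[tv2] + 3) % 4
            seqs[id(node)] = child
            parent_seq = child
        if node.is_leaf():
            tips[node.taxon.label] = seqs[id(node)]
    ids = list(tips)
    strings = [_BASES[a.astype(np.uint8)].tobytes().decode() for a in tips.values()]
    records = {}
    for tid in ids:
        species = tid.rsplit("_", 1)[0] if "_" in tid else tid
        records[tid] = SpecimenRecord(tid, species, marker)
    return BarcodeAlignment(ids=ids, seqs=strings, records=records, marker=marker)


# ---------------------------------------------------------------------------
# scenario planting and orchestration
# ---------------------------------------------------------------------------


def _geometric_counts(cfg: SimulationConfig, rng) -> dict[str, int]:
    ks = np.arange(cfg.min_seqs, cfg.max_seqs + 1, dtype=float)

    def mean_for(r):
        w = r ** (ks - ks[0])
        return float((ks * w).sum() / w.sum())

    if abs(mean_for(1.0) - cfg.mean_seqs) < 1e-9:
        r = 1.0
    elif cfg.mean_seqs < mean_for(1.0):
        r = brentq(lambda r_: mean_for(r_) - cfg.mean_seqs, 1e-9, 1.0)
    else:
        r = brentq(lambda r_: mean_for(r_) - cfg.mean_seqs, 1.0, 100.0)
    w = r ** (ks - ks[0])
    pmf = w / w.sum()
    width = max(2, len(str(cfg.n_species)))
    names = [f"sp{k:0{width}d}" for k in range(1, cfg.n_species + 1)]
    counts = rng.choice(ks.astype(int), size=cfg.n_species, p=pmf)
    return dict(zip(names, (int(c) for c in counts)))


@dataclass
class SimulatedDataset:
    """A generated dataset plus its full ground truth."""

    alignment: BarcodeAlignment
    metadata: pd.DataFrame
    true_partition: MotuPartition
    true_mislabels: pd.DataFrame
    expected_codes: dict[str, str]
    species_tree: PhyloTree
    gene_tree: PhyloTree
    config: SimulationConfig

    def morphospecies(self) -> dict[str, str]:
        return dict(zip(self.metadata["specimen_id"], self.metadata["morphospecies"]))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, outdir / "sim.fasta")
        self.metadata.to_csv(outdir / "sim_metadata.tsv", sep="\t", index=False)
        write_partition(self.true_partition, outdir / "true_partition.tsv")
        self.true_mislabels.to_csv(outdir / "true_mislabels.tsv", sep="\t", index=False)
        self.species_tree.write(outdir / "species_tree.nwk")
        self.gene_tree.write(outdir / "gene_tree.nwk")
        (outdir / "config.json").write_text(self.config.to_json() + "\n")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: tree, genealogy, sequences, labels, scenarios."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    species_tree = simulate_species_tree(
        cfg.n_species,
        birth_rate=cfg.birth_rate,
        seed=rng,
        height=cfg.tree_height,
        min_divergence=cfg.min_divergence,
    )
    species = species_tree.tip_labels
    if isinstance(cfg.seqs_per_species, str):
        if cfg.seqs_per_species != "geometric":
            raise ParameterError(
                f"unknown seqs_per_species mode {cfg.seqs_per_species!r}"
            )
        samples = _geometric_counts(cfg, rng)
    elif isinstance(cfg.seqs_per_species, int):
        samples = {sp: cfg.seqs_per_species for sp in species}
    else:
        counts = list(cfg.seqs_per_species)
        if len(counts) != len(species):
            raise ParameterError(
                f"seqs_per_species has {len(counts)} entries for {len(species)} species"
            )
        samples = dict(zip(species, (int(c) for c in counts)))
    gene_tree = simulate_gene_tree(species_tree, samples, cfg.theta, seed=rng)
    alignment = evolve_sequences(
        gene_tree, length=cfg.locus_length, kappa=cfg.kappa, seed=rng, marker=cfg.marker
    )

    specimen_species = {sid: alignment.records[sid].morphospecies for sid in alignment.ids}
    morphospecies = dict(specimen_species)
    expected_codes = {sp: "OK" for sp in species}
    truth_rows = []

    # --- scenario planting -------------------------------------------------
    sp_dm = patristic_matrix(species_tree)
    gap_floor = 4.0 * cfg.theta  # proxy for the largest intraspecific distance
    free = list(species)  # species not yet consumed by a scenario

    def take(candidates, k, what):
        pool = [s for s in candidates if s in free]
        if len(pool) < k:
            raise ParameterError(
                f"not enough unused species for {what}: need {k}, have {len(pool)}"
            )
        chosen = list(rng.choice(pool, size=k, replace=False))
        for s in chosen:
            free.remove(s)
        return chosen

    for _ in range(cfg.n_cryptic):
        a, b = take(species, 2, "a cryptic split")
        merged = a  # two genetic species under one morphospecies name
        for sid, sp in specimen_species.items():
            if sp == b:
                morphospecies[sid] = merged
        expected_codes[merged] = "S"
        expected_codes.pop(b, None)

    for _ in range(cfg.n_synonym):
        (c,) = take([s for s in species if samples[s] >= 2], 1, "a synonym lump")
        members = [sid for sid, sp in specimen_species.items() if sp == c]
        half = len(members) // 2
        twin = f"{c}syn"
        for sid in members[half:]:
            morphospecies[sid] = twin
        expected_codes[c] = "L"
        expected_codes[twin] = "L"

    if cfg.n_mislabels:
        sources = take(
            [s for s in species if samples[s] >= 3], cfg.n_mislabels, "mislabels"
        )
        for src in sources:
            eligible = [
                t
                for t in free
                if sp_dm.get(src, t) >= 3.0 * gap_floor
            ]
            if not eligible:
                raise ParameterError(
                    f"no species far enough from {src} to plant a mislabel"
                )
            target = str(rng.choice(eligible))
            free.remove(target)
            members = [sid for sid, sp in specimen_species.items() if sp == src]
            victim = str(rng.choice(members))
            morphospecies[victim] = target
            truth_rows.append(
                {"specimen_id": victim, "planted_label": target, "true_species": src}
            )

    metadata = pd.DataFrame(
        {
            "specimen_id": alignment.ids,
            "morphospecies": [morphospecies[sid] for sid in alignment.ids],
            "marker": cfg.marker,
            "true_species": [specimen_species[sid] for sid in alignment.ids],
        }
    )
    # refresh alignment records with the distorted labels
    records = {
        sid: SpecimenRecord(sid, morphospecies[sid], cfg.marker)
        for sid in alignment.ids
    }
    alignment = BarcodeAlignment(
        ids=alignment.ids, seqs=alignment.seqs, records=records, marker=cfg.marker
    )
    true_partition = MotuPartition(
        dict(specimen_species), method="truth", params={"seed": cfg.seed}
    ).canonical()
    return SimulatedDataset(
        alignment=alignment,
        metadata=metadata,
        true_partition=true_partition,
        true_mislabels=pd.DataFrame(
            truth_rows, columns=["specimen_id", "planted_label", "true_species"]
        ),
        expected_codes=expected_codes,
        species_tree=species_tree,
        gene_tree=gene_tree,
        config=cfg,
    )


def simulate_coalescent_tree(n_tips: int, theta: float = 0.01, seed=0) -> PhyloTree:
    """A single-population Kingman coalescent tree (no species structure).

    Expected pairwise distance between tips is *theta*; useful as the null
    case for delimitation methods that test for structure.
    """
    if n_tips < 3:
        raise ParameterError("a coalescent tree needs at least 3 tips")
    rng = _rng(seed)
    labels = [f"t{k}" for k in range(1, n_tips + 1)]
    root = _coalesce(labels, theta, rng, None)
    return PhyloTree.from_newick(_emit(root) + ";", rooted=True)
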
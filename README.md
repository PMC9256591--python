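# barcodekit

A toolkit for the desk analysis of DNA-barcode reference libraries:
species delimitation from barcode sequences, congruence of the resulting
MOTUs (molecular operational taxonomic units) with morphology-based
taxonomy, barcode-gap analysis, and screening of reference libraries for
mislabelled sequences. It was built around a regional survey of
Ponto-Caspian amphipods (COI and 16S barcodes for 57 morphospecies) and
generalises to any aligned barcode library with specimen metadata.

## Who it is for

Taxonomists and molecular ecologists who have an aligned barcode matrix and
a morphospecies assignment per specimen, and want reproducible answers to:
how many MOTUs do standard delimitation algorithms find; which
morphospecies are split or lumped by the molecules; where is the barcode
gap; and which published sequences are probably misidentified.

## What it computes

* **Distances** — Kimura 2-parameter (K2P), p-distance and
  number-of-differences under pairwise deletion, with explicit saturation
  handling; distance histograms. For K2P, with P and Q the transition and
  transversion proportions over comparable sites,
  `d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`.
* **Trees** — neighbor joining (Saitou–Nei, negative branches clamped,
  exact on additive matrices), UPGMA, patristic distance matrices,
  ultrametricity checks, advisory NJ bootstrap.
* **Four delimitation algorithms** —
  barcode-gap ranking over the nested single-linkage partition chain
  (ASAP-style score = mean of panmixia-probability and gap-width ranks);
  the K/θ rule (sister clades are species when between-clade divergence K
  is at least R× the within-clade diversity θ, R = 4 or 5);
  the patristic distance threshold (0.16 substitutions/site for COI);
  and single-threshold GMYC (maximum-likelihood threshold between Yule
  branching and within-species coalescence on an ultrametric tree, with a
  likelihood-ratio test against the one-species null). External partitions
  (e.g. BIN, PTP) are imported from TSV.
* **Congruence** — one code per morphospecies per method: OK (congruent),
  S (split over several MOTUs), L (lumped with another species), S+L, or
  NA (no data at that marker); per-method summaries and across-method
  consensus. The published per-species table of the amphipod survey ships
  as a reference fixture.
* **Barcode gap** — intra/inter decomposition, binned-occupancy gap
  detection, modal interspecific bins.
* **Mislabel audit** — distance-rule flags (candidate/strong) with
  suggested labels, plus percent-identity reports.
* **Synthetic data** — Yule species trees, within-species coalescents, K80
  sequence evolution, and planted cryptic-species / synonymy / mislabel
  scenarios with full ground truth.

## Worked example

```python
import barcodekit as bk
from barcodekit.simulate import gapped_preset, simulate_dataset

ds = simulate_dataset(gapped_preset(n_species=20, seqs_per_species=5, seed=42))
dm = bk.distance_matrix(ds.alignment, model="k2p")

res = bk.asap_partition(dm)
print(f"best partition: {res.best_partition.n_motus} MOTUs at d* = {res.best_threshold:.3f}")

codes = bk.classify_species(ds.morphospecies(), res.best_partition)
print(bk.summarize({"ASAP": (codes, res.best_partition.n_motus)})
        [["n_species", "n_motus", "pct_congruent", "pct_lump", "pct_split"]])

intra, inter = bk.split_intra_inter(dm, ds.morphospecies())
print("barcode gap:", bk.detect_gap(intra, inter, bin_width=0.01))
```

prints

```
best partition: 20 MOTUs at d* = 0.110
        n_species  n_motus  pct_congruent  pct_lump  pct_split
method
ASAP           20       20          100.0       0.0        0.0
barcode gap: (0.01, 0.22)
```

All 20 simulated species are recovered as exactly one MOTU each (100%
congruent, nothing lumped or split), the best threshold 0.110 falls inside
the detected barcode gap (0.01–0.22 substitutions/site), and the same holds
for the K/θ, patristic-threshold and GMYC methods (see the test suite).

The published congruence table is reproducible from the packaged fixture:

```python
from barcodekit.congruence import reference_summary
print(reference_summary("COI"))   # per-method % congruent / lump / split + mean row
```

The same pipeline runs from the shell (`barcodekit simulate`, `distances`,
`tree`, `delimit {asap,kot,pdt,gmyc,import}`, `congruence`, `gap`, `audit`,
`report`); every run writes a `run_config.json` echo next to its outputs,
and identical invocations with the same seed are byte-identical.

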
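# Methods

This note documents the models and procedures implemented in `barcodekit`,
the assumptions behind them, and the design choices made where the
methodology left room.

## Scope and data model

The toolkit operates on a DNA-barcode reference library: an aligned
multi-FASTA of short mitochondrial markers (a COI-like protein-coding
fragment, typically 641 bp, and/or a 16S-like fragment with indels), a
specimen metadata table mapping each sequence to a morphospecies label, and
optionally trees produced by external phylogenetic software. Its outputs are
MOTU partitions (molecular operational taxonomic units — species hypotheses
from sequence clustering), per-morphospecies congruence codes, barcode-gap
reports, and mislabel flags.

## Distances

All pairwise distances use **pairwise deletion**: for each pair of
sequences, only columns where both carry an unambiguous A/C/G/T are
compared. IUPAC ambiguity codes are treated as missing, not as fractional
matches — the simplest defensible contract, and the one that makes the
handling of ambiguity-rich sequences explicit rather than model-dependent.
Three models are provided:

* **K2P** (Kimura two-parameter). With P and Q the transition and
  transversion proportions among comparable sites,
  `d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`. When `1-2P-Q <= 0` or
  `1-2Q <= 0` the distance is undefined (saturation); such pairs carry an
  `inf` sentinel and must be excluded from clustering by an explicit policy
  — they are never silently clamped. The implementation agrees with
  `ape::dist.dna(model="K80")` to machine precision on hand cases.
* **p-distance** and **number of differences** (the latter is the
  conventional input for quick NJ overview trees of reference libraries).

The distance histogram bins the upper triangle into half-open `[lo, hi)`
bins; bin width is a free parameter, default 0.01 substitutions/site (1%),
matching the granularity at which barcode gaps are conventionally read.

## Trees

**Neighbor joining** is the standard Saitou–Nei agglomeration with the
Q-matrix criterion. Negative branch-length estimates are clamped to zero
with the deficit moved to the sister branch of the joined pair (the
behaviour users of mainstream desktop phylogenetics software expect), so the
algorithm remains exact on additive matrices. Q-ties break on the smallest
(row, column) index pair, making results order-deterministic. A
column-resampling bootstrap with majority annotation is available for NJ
review trees; support values are advisory only — no decision rule in the
package conditions on them.

**UPGMA** is average-linkage agglomeration (via `scipy`), ultrametric by
construction; it supplies desk-scale clock trees where an externally dated
ultrametric tree is not available.

**Patristic distances** are path sums over branch lengths (via dendropy's
path machinery). **Ultrametricity** is judged by the relative spread of
root-to-tip depths, default tolerance 1e-6 (relative), configurable —
externally produced clock trees typically carry printing error well below
this.

## Species delimitation

### Threshold clustering

MOTUs are connected components of the graph joining pairs with distance
**strictly below** the threshold t. The strict inequality fixes the
coordinate convention: a rule phrased "separated by at least X" means
`d >= X` separates. Thresholding is monotone (smaller t refines larger t),
and MOTU ids are canonicalised by each group's lexicographically smallest
member so partitions compare by value.

### Barcode-gap ranking (ASAP-style)

Candidate partitions are the nested chain produced by single-linkage
agglomeration: the all-singleton partition, then one candidate per distinct
merge height. Each candidate is scored by two quantities:

* **Panmixia probability p.** The reference implementation's exact formula
  is not public in closed form; the package uses a documented
  coalescent-motivated surrogate. For a candidate partition, let
  `theta_hat` be its pooled mean positive within-group distance (floored at
  the smallest positive distance in the matrix, i.e. the data's
  resolution). Each group g is internally connected at single-linkage
  height `t_g` and separated from everything else by `s_g`; under an
  exponential null at scale `theta_hat`, the probability that a panmictic
  cluster would show so wide a margin is `p_g = exp(-(s_g - t_g)/theta_hat)`.
  Coherent, well-separated groups drive `p_g` toward zero; fragments of a
  panmictic cluster (`s_g ~ t_g`, both small) and lumped groups (whose
  internal link spans the gap, `t_g ~ s_g`, both large) leave `p_g` near 1.
  Aggregation over groups is multiplicative and normalised for group count
  (a geometric mean), so the rank is not an artefact of how many groups a
  candidate has. Two simpler formulations (separation-only per-group terms;
  a sum over refused merges) were rejected during development because each
  carried a systematic rank bias toward coarse or fine partitions
  respectively.
* **Gap width w**: the distance between the merge that created the
  candidate and the next merge.

Candidates are ranked by p (ascending) and w (descending); the score is the
mean of the two ranks and the best partition minimises it (ties: lower p,
then fewer MOTUs). The reported threshold `d*` is the midpoint of the
interval over which the candidate is the clustering — by construction it
falls inside the barcode gap when one exists. A matrix whose distances are
all equal has no gap and is rejected as degenerate.

### K/theta (the 4x rule)

At a node of a guide tree with daughter clades A and B, K is the mean
pairwise distance across the daughters and theta the within-clade diversity;
the daughters are distinct species when `K/theta >= R` (R = 4
conventionally; 5 as a conservative variant). Choices made explicit:

* theta is the **larger** of the daughters' mean within-clade distances —
  the hardest version of the test to pass, consistent with the rule's
  intent.
* A singleton daughter borrows its sister's theta. When no daughter has
  positive diversity, the fallback is the smallest non-zero diversity among
  **cherry-level clades** anywhere on the tree — the shallowest clades are
  the ones whose diversity is within-population-like; taking the minimum
  over all clades would substitute an interspecific diversity in
  low-variation data and invert the test. With no positive diversity
  anywhere, positive divergence splits (the ratio is unbounded) and zero
  divergence is untestable (no split).
* **Every** node is tested and the tree is cut at every passing node: MOTUs
  are the maximal clades containing no passing node. Stopping the recursion
  at the first failing node would terminate at the root of any real tree
  (where "within-clade diversity" spans many species and the ratio is near
  1) and return a single MOTU; cutting at all passing nodes is what makes
  the rule behave as the splitter it is empirically known to be.

The R=5 variant can never produce more MOTUs than R=4 on the same input
(passing nodes at 5 are a subset of those at 4).

Guide trees may be unrooted (NJ); they are midpoint-rooted before the
recursion.

### Patristic distance threshold (PDT)

Single-linkage threshold clustering of the patristic distance matrix of a
COI tree at t = 0.16 substitutions/site, the published crustacean COI cut.
Path lengths of at least t separate species (strict-inequality convention
as above).

### Single-threshold GMYC

On a rooted ultrametric tree, branching events older than a threshold
height T are diversification (between-species) events and events younger
than T are within-cluster coalescences. Inter-event waiting times are
exponential with rate

    b = lambda_div * n_div^p_div + lambda_coal * sum_k n_k (n_k - 1)^p_coal

where `n_div` counts species-level lineages and `n_k` the lineages inside
cluster k (singleton clusters contribute nothing). Candidate thresholds sit
at each event height (plus the no-structure candidate with a single
entity); for each candidate the four parameters are fitted by bounded
maximum likelihood (L-BFGS-B on log-rates, exponents bounded to [0, 3],
warm-started along the candidate chain), and the best T maximises the
profile likelihood. The fit is compared with a single-class coalescent null
`b = lambda (n(n-1))^p` by a likelihood-ratio test against chi-square with
3 degrees of freedom (the original single-threshold convention); the LR is
clamped at zero since the null is nested only up to the positivity bound on
`lambda_div`. `partition(alpha)` returns the single-entity partition when
the test does not reject at `alpha`. Tied node heights (zero-length internal
branches) are separated by a 1e-12 perturbation before interval extraction.
The final inter-event interval (last event to the present) carries no
terminating event and is excluded from the likelihood.

Calibration on simulated data (reproduced by the test suite): on pure
single-population coalescent trees the null is preferred at alpha = 0.05 in
well over 90% of replicates; on strongly structured trees (species splits
two orders of magnitude deeper than within-species coalescence) the true
cluster count is recovered in over 90%. Note the model has little power to
recognise *singleton-only* structure (a pure Yule tree with one tip per
species offers no coalescent contrast), which is a property of the method,
not of this implementation.

### External partitions

Clusterings produced by external services (e.g. database-side COI binning,
or Poisson tree process runs) enter as partition TSVs tagged with their
method name and are validated against the current specimen set.

## Congruence classification

The unit of accounting is the **morphospecies** (one code per species per
method). For morphospecies X with specimens spread over MOTU set M_X:
split iff |M_X| >= 2; lumped iff some MOTU in M_X also holds another
species' specimen; codes OK / S / L / S+L accordingly; species with no
sequence data at a marker are NA and excluded from that marker's
denominators. Summary percentages are computed over non-NA species,
rounded half-up to one decimal for display (raw fractions are retained);
the marker-level mean row is the arithmetic mean over methods computed on
raw fractions. Consensus flags use an inclusive "at least half of the
non-NA methods" majority.

The package ships the published per-species code table of the Ponto-Caspian
amphipod barcode survey (57 morphospecies, 12 marker/method columns) as a
reference fixture; `reference_summary()` recomputes the survey's summary
table from it. One cell of that fixture (one species' COI BIN code) was
normalised against the published summary row during transcription, as the
extracted source table and its printed summary disagreed by a single
specimen there.

## Barcode gap

Intra- and inter-specific distances are split by morphospecies label; the
gap is the run of bins (default width 1%) empty of both, between the
highest intra-occupied bin and the lowest inter-occupied bin above it.
Defining the gap on binned occupancy rather than order statistics makes it
invariant to duplicating observations and mirrors the histogram reading it
automates. The report carries the modal interspecific bins (so statements
like "most common distance ~22-24%" are reproducible on synthetic data) and
an optional reference threshold for display.

## Mislabel auditing

The manual practice this automates is scanning a tree for "species X
nested inside species Y". The explicit rule: with species radius r
(default 0.07 substitutions/site for COI-like markers — the empirical scale
above which such barcodes usually separate species; pass a barcode-gap
threshold when one has been estimated), specimen s with label X is flagged
**candidate** iff its nearest heterospecific is closer than r while every
conspecific (if any) is at or beyond r; the flag is upgraded to **strong**
iff s additionally sits inside another label's single-linkage cluster at r
with no conspecific in that cluster. Specimens that are the only sequence
of their label cap at candidate. The suggested label is the nearest
neighbour's. An NJ review tree (number of differences) is emitted alongside
for human inspection. `identity_report` supports the complementary
"percent identity to best reference" statement (matches / comparable sites
under pairwise deletion).

## Synthetic data generator

The generator produces datasets with known ground truth and the statistical
shape of a regional barcode survey:

1. **Species tree**: forward-simulated Yule (pure birth) tree; optionally
   rescaled so the root sits at a target height with a floor under internal
   node heights (a linear, order-preserving map), guaranteeing a minimum
   species separation.
2. **Gene tree**: a Kingman coalescent grafted below each species tip with
   pairwise coalescence rate 2/theta, so the expected within-species
   pairwise distance is theta. Each genealogy is capped at 90% of the
   height of the species' parent node; there is no incomplete lineage
   sorting (each species coalesces fully before joining the species tree)
   and no migration.
3. **Sequences**: site-independent two-parameter (K80) evolution with
   transition/transversion rate ratio kappa, total rate normalised to one
   substitution per unit branch length; gap-free (indel evolution is out of
   scope — the pairwise-deletion code paths are exercised with hand-crafted
   gapped fixtures instead).
4. **Scenarios** distort labels relative to genetic truth: a cryptic split
   merges two true species under one name (expected code S), a synonym
   lump gives one true species two names (both expected L), and mislabels
   reassign single specimens to species at least three gap-floors away
   (recorded in a ground-truth list). Scenario species are disjoint;
   mislabel sources keep at least two other specimens so no remaining
   specimen becomes an orphan of its own label.

**Defaults** mirror the survey that motivated the toolkit: 54 species,
sequences per species drawn from a truncated geometric on 1..24 with mean 5
(matching the survey's sampling imbalance), 641 bp, kappa = 4 (a typical
mitochondrial transition bias), theta = 0.02 (2% expected within-species
divergence, comfortably under the ~7% empirical species boundary), species
tree height 0.115 with internal floor 0.05 — placing the modal
interspecific K2P distance near 0.22-0.24 and the minimum near 0.1.

The **gapped preset** (`gapped_preset`) is a correctness fixture, not a
power study: theta = 1e-6 (species effectively clonal), root height 0.30,
internal floor 0.12, so every interspecific path exceeds 0.24 while
within-species variation is at the mutation-count floor. Under these
conditions the barcode gap is unambiguous and all four delimitation methods
recover the true partition exactly — any failure indicates an incorrect
implementation. This idealisation is deliberate: with realistic coalescent
variation the K/theta rule genuinely oversplits (deep within-species
coalescent splits against shallow subclade diversities routinely exceed the
4x ratio), which is the behaviour observed on real data and reproduced by
the survey-shaped defaults; a preset intended to separate implementation
errors from method behaviour must remove that variance. Passing the
recovery tests therefore demonstrates algorithmic correctness on separable
data, not performance on real libraries.

Everything is driven by a single integer-seeded PCG64 generator threaded
through the stages in a fixed order; reruns are byte-identical.

## Numerical and degenerate-input choices

* Saturated distances: `inf` sentinel, explicit exclusion policy, never
  clamped.
* Zero comparable sites between a pair: an error naming the pair.
* All-equal distance matrices: degenerate for gap ranking (no gap defined).
* GMYC optimiser bounds: log-rates in [-25, 25], exponents in [0, 3];
  non-finite optima raise with diagnostics.
* Rounding for display: decimal half-up, one decimal place; machine output
  keeps raw fractions.

## Known limitations

* The barcode-gap ranking's p is a surrogate, not the reference service's
  exact statistic; ranks and the nested candidate chain follow the
  published scoring structure, but p-values are not comparable across
  implementations.
* The K/theta implementation tests every node; tools that test only
  pre-selected candidate clades will differ on data without a clean gap.
* GMYC is single-threshold only and has no power against singleton-only
  structure.
* The simulator omits indels, rate heterogeneity across sites,
  incomplete lineage sorting and introgression; conclusions from synthetic
  recovery transfer to real data only to the extent those features do not
  dominate.
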
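# Methods

## The screening procedure

The package screens a glycoside-hydrolase family for candidate enzymes
suited to hot, alkaline process conditions. The procedure is:

1. **Admission.** A sequence enters the analysis only if one of its
   catalytic-domain hits covers at least 80 % of the domain model's
   consensus length (`(model_end − model_start + 1) / model_length ≥
   0.80`). The boundary is inclusive: only strictly lower coverage is
   discarded. Sub-threshold *catalytic* hits are dropped everywhere;
   accessory-domain hits pass through untouched.
2. **Domain architecture.** Hits on a retained sequence are
   overlap-resolved greedily by descending score (a hit is kept if it
   overlaps every kept hit by ≤ 10 aa), ordered by start coordinate, and
   joined with `+`. An unannotated C-terminal region of ≥ 50 aa after the
   last kept hit is appended as a length-binned `Ct` label; eukaryotic and
   archaeal DAs get `-E` / `-A` suffixes. Catalytic domains starting after
   residue 50 are flagged (not removed) as non-N-terminal; the 50-aa slack
   absorbs signal peptides, whose prediction is out of scope.
3. **Phylogeny.** Catalytic-domain subsequences are multiply aligned and a
   neighbor-joining tree is built from alignment p-distances, with
   bootstrap supports from column resampling.
4. **Screen.** Leaves are annotated with genus-level trait sets
   (Tr/Ak/Ac); maximal clades with defining-edge support ≥ 50, size ≥ 3
   and target-trait purity ≥ 0.6 are reported, and representatives are
   picked to cover as many distinct DAs as possible.

## Models and numerical choices

**Alignment.** Global alignment uses BLOSUM62 (taken from biopython's
substitution-matrix collection) with a linear gap penalty of −4 per gapped
column. The linear model keeps the exhaustive-enumeration oracle used in
the tests trivial; affine gaps are a possible extension. The progressive
MSA builds a UPGMA guide tree from 3-mer multiset distances
(`1 − shared/min-total`), then merges profiles leaf-to-root with
sum-of-pairs profile–profile scoring in which a residue paired with an
existing gap costs the gap penalty and gap–gap pairs cost nothing. The DP
recurrence is vectorised with a prefix-max scan (valid for linear gaps);
traceback tie-breaks are fixed — diagonal, then up (consume the first
profile), then left — so output is deterministic.

**Tree building.** Distances are p-distances over columns where neither
row is gapped (pairs with no comparable column get distance 1 with a
warning). Neighbor joining follows the Saitou–Nei Q-criterion; UPGMA uses
arithmetic-mean updates. Both break ties by the lexicographically smallest
label pair, where an agglomerated cluster carries the smallest label of
its members. Negative NJ branch-length estimates are clamped to zero, as
is standard. NJ is exact on additive matrices, which is the main oracle
property the tests exercise.

The published screen of this family used a maximum-likelihood tree (JTT
model); this package deliberately substitutes distance-based NJ. The
downstream clade screen consumes only topology and supports, and NJ keeps
the whole pipeline self-contained, fast and exactly testable. Agreement
with an ML tree on real data can therefore only be qualitative.

**Bootstrap.** Alignment columns are resampled with replacement
(`n_reps` default 1000 in the library; the pipeline default is 100, a
deliberate scale-down that the planted-clade tests show is already
decisive at desk scale); each internal edge of the main tree is annotated
with the rounded percentage of replicate trees containing the same
bipartition. Supports below 50 are conventionally non-significant; that is
the screen's default support threshold.

**Screen thresholds.** The published analysis identified trait-enriched
clusters by visual inspection of a cladogram. To make that reproducible,
the screen formalises: support ≥ 50, combined trait purity ≥ 0.6 (a leaf
counts as positive only if it carries *all* target traits; an "any-trait"
mode is available), minimum size 3, and maximality (no reported clade
nested in another). On unrooted trees each internal edge's bipartition is
evaluated, taking the side away from the outgroup, or the smaller side
when none is given; the full leaf set counts as a trivially supported
clade. Representative selection walks architectures by descending
frequency and picks the leaf with the longest terminal branch per
architecture, ties by id.

**Yield arithmetic.** Theoretical reducing sugars (mM) =
`1000 · loading · hemicellulose_fraction / anhydro_monomer_mass`, with the
monomer counted as anhydroxylose (xylose 150.13 minus water = 132.11
g/mol), since that is the per-residue mass inside xylan. For the headline
example the hemicellulose fraction is fixed at 0.20 — inside the substrate's
reported 18–25 % range and consistent with rounding the ceiling to
~151 mM; the range endpoints give 136–189 mM. Specific activity is
µmol reducing sugars · min⁻¹ · mg⁻¹. Molecular masses use average (not
monoisotopic) residue masses plus one water, matching common protein
parameter tools.

## The synthetic family generator

The generator emulates the statistical structure of the family snapshot
the screen assumes, with ground truth for every stage:

* **Phylogeny.** A random bifurcating tree grown by repeated leaf
  splitting, branch lengths uniform on [0.05, 0.15] — enough change per
  branch to be recoverable, far from saturation at desk-scale depths.
* **Planted trait clades.** `n_trait_clades` internal nodes (default 3,
  size 3–8) are chosen disjointly such that every ancestor keeps its
  planted-leaf fraction ≤ 0.5. The constraint makes each planted clade the
  unique maximal trait-enriched clade in its neighbourhood — without it,
  "recover the planted leaf set exactly" would be ill-posed, since a
  barely-diluted parent clade could legitimately pass the purity screen.
  Planted leaves get a thermophilic-alkalophilic genus (Tr+Ak in the
  emitted trait table); background leaves draw kingdom-specific genera
  that are traitless or acidophilic.
* **Sequences.** The catalytic region evolves along the tree under a
  20-state uniform-exchange (Jukes–Cantor-like) substitution model at rate
  1 substitution/site per unit branch length, sampled exactly through the
  model's closed-form mismatch probability. Accessory blocks (CBMs, the
  rare PKD domain) are fixed pseudo-random sequences per label — DA
  classification is driven by hit coordinates, not homology, so evolving
  them would add nothing. C-terminal tails are random residues with length
  uniform on [50, 500], matching the binning domain.
* **Composition.** Per kingdom, each sequence draws one DA class: bare
  (0.70 prokarya / 0.80 eukarya), one CBM (0.15, with a categorical
  distribution over CBM labels), Ct tail (0.12 / 0.03), and the residual
  mass (0.03 / 0.02) as a catalytic+PKD architecture. Using a non-CBM,
  non-Ct class for the remainder keeps the three published fractions
  exactly equal to their generative probabilities.
* **Hit table.** Every sequence gets a catalytic hit at its true
  coordinates with full model coverage, except a `frac_partial` fraction
  (default 0.10) whose hits are planted at 50–75 % model coverage — below
  the 80 % admission threshold, so exactly these sequences must be
  discarded downstream.
* **Counts.** The family's published size is ~1300 sequences with no
  stated kingdom breakdown; the default 1000 prokarya / 300 eukarya / 10
  archaea is a configurable choice of the same order. The acceptance
  script uses 40 000 + 40 000 to shrink Monte-Carlo error on the smallest
  percentage (3 %); the end-to-end tree/screen stages run at 50 sequences
  and 100 bootstrap replicates, sizes at which progressive alignment and
  resampling finish in seconds.

**What the generator does not emulate:** indels and rate heterogeneity,
real CBM homology, signal peptides, horizontal transfer, database biases,
or the actual family snapshot. Passing round-trips therefore demonstrate
that the screening logic is correct under its own assumptions — not that
the thresholds are optimal for real data.

## Determinism and degenerate inputs

All randomness descends from one integer seed per entry point
(`numpy.random.default_rng`); identical configuration gives byte-identical
output files. Degenerate cases are defined rather than left to chance:
coverage exactly at threshold is retained; tails shorter than 50 aa are
unlabelled; tails beyond 500 aa keep the last bin's label with a warning;
Ct bins are half-open `[lo, hi)` with the last closed (the published bin
edges share endpoints, which would otherwise be ambiguous); multiple
retained catalytic hits are all kept (and logged), so a DA may repeat the
catalytic label; alignment of an empty sequence is all gaps; a
single-replicate bootstrap yields supports in {0, 100}.

## Known limitations

* NJ on p-distances underestimates deep divergences (no correction for
  multiple hits); fine at desk scale, but a correction (e.g. Poisson)
  would be needed near saturation.
* Linear (not affine) gap penalties fragment long indels; irrelevant for
  the indel-free generator, visible on real sequences.
* Trait maps are genus-level and binary; real extremophily varies within
  genera.
* The published cluster inventory (62 DA strings, specific cluster
  memberships) depends on a database snapshot and is not reproduced;
  screen output on real data should be read as candidate lists, not
  classifications.
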
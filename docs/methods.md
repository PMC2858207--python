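# Methods

## Scope and model

`mitorho` implements the standard analysis chain for intraspecific complete
mitochondrial genome studies: variants scored relative to the 16,569-bp rCRS
coordinate system, motif-based subcluster classification, most-parsimonious
mutation-labeled haplotype trees, and coalescence dating via the ρ statistic.
The underlying model is the classic one for mtDNA genealogies: lineages
descend clonally from a founder haplotype; mutations accrue along each
lineage as a Poisson process at a constant rate; and the expected number of
mutations separating a sampled genome from the clade founder is proportional
to the founder's age.

## Variant nomenclature and scoring

Variants use forensic mtDNA convention: a bare position is a transition
(derived base inferred as the purine↔purine / pyrimidine↔pyrimidine partner
of the reference base), `16114A` a transversion, `249d` a deletion (one
variant per deleted position), `309.1C` an insertion with sequential indices.
Coordinates are 1-based and inclusive; the circular genome is linearized at
np 1.

Sample genomes are aligned to the reference with edlib (global alignment,
unit costs); mismatches become substitutions, indels are normalized to their
3'-most equivalent position, and `N` is missing data, never a variant.
Sequences under 95% alignment identity (configurable) are rejected as
non-homologous.

The default exclusion filter removes insertions, deletions and transversions
falling inside the two homopolymeric tracts nps 16180–16193 and 303–315,
where replication slippage makes such changes phylogenetically
uninformative. Transitions are retained everywhere — the C-tract transitions
(e.g. np 16192) are informative and used by classification motifs — and
indels/transversions outside the tracts are kept (e.g. the transversion
16114A is a diagnostic motif variant). A configuration switch supports the
stricter alternative of excluding all indels genome-wide; a user-supplied
extra-exclusion list can drop any variant at listed hotspot positions
(np 16519 and similar are retained by default).

Synonymy annotation translates the codon containing a substitution under the
vertebrate mitochondrial code, reverse-complementing light-strand genes and
padding incomplete terminal codons with A (completed by polyadenylation in
vivo). A substitution covered by overlapping protein genes (ATP8/ATP6,
ND4L/ND4) is called synonymous only if synonymous in every frame —
conservative for the synonymous clock. Positions in rRNA/tRNA genes are
`rna_gene`; everything outside annotated genes, including the control region
and the short intergenic spacers, is `noncoding` (the spacers are genuinely
noncoding DNA, so they are not treated as an annotation error).

## Packaged reference

The packaged reference (`data/rcrs_synthetic.fasta`) is a deterministic
synthetic stand-in for the rCRS: correct length and gene coordinates, human
mtDNA base composition, and the control-region landmark and motif positions
pinned to their real rCRS bases (16114=C, 16311=T, the 303–315 poly-C tract,
etc.) so that classic variant labels are well-formed. The rest of the
sequence is pseudo-random. Every computation is relative to whichever
reference is loaded, so analyses of real data should load the true rCRS via
`load_reference`; the packaged stand-in exists so the whole pipeline is
testable offline.

## Classification

Motif rules form a rooted hierarchy (clade, parent, diagnostic variants). A
profile is assigned to the deepest clade whose full motif chain (union of
motifs from the root) is contained in its variant set; ties between equally
deep candidates prefer the larger own motif, then lexicographic name, and
are logged. Profiles whose variants all lie in HVS-I (np ≥ 16024) are
matched against the HVS-I part of each motif only and the assignment is
flagged tentative, since coding-region motif variants cannot be verified. If
a strict descendant's own motif is fully present while an intermediate motif
variant is missing, a "possible back mutation" note is attached. The
packaged U5-style rule file is illustrative and user-replaceable.

## Parsimony tree construction

Each distinct haplotype is a binary character vector over the observed
variants, relative to a designated ancestral state (the clade founder;
empty = reference). With a known ancestral state, two characters are
compatible iff their carrier sets are nested or disjoint; a pairwise
compatible character set admits a unique perfect phylogeny, which is emitted
directly (tree length = number of distinct variants, no homoplasy).

When characters conflict, a backbone is built from a pairwise-compatible
subset and each remaining character is overlaid by small-parsimony dynamic
programming on the current topology with the root state fixed. The DP is
*grouping-aware*: the cost of a node in state *s* lets any number of its
children flip to the opposite state for a single shared mutation, realized
by inserting an internal node that gathers the flipped children. This prices
recurrent origins the way the final tree carries them and lets successive
overlay characters reuse each other's inserted structure.

When few characters are involved in conflicts (≤12 by default), the backbone
subset is chosen by exhaustive search over compatible subsets, trying
multiple overlay orders (all permutations when the work is small, otherwise
ascending and descending carrier count), and keeping the shortest result;
ties prefer fewer distinct homoplasious sites. Above that size the backbone
is chosen greedily — characters ranked by (weight descending, carrier count
descending, position) are kept when compatible — and homoplasy is accepted
at the lowest-weight (fastest) sites first, a deterministic order. On random
small instances (≤8 taxa, ≤12 sites) the resulting tree length matches an
exhaustive-enumeration oracle (branch-and-bound over unrooted topologies
with bit-parallel Fitch counting, the ancestral state included as a leaf).

Identical profiles collapse to one tip with multiplicity; every sample is a
pendant tip, so a sampled founder hangs on a zero-mutation edge. Site
weights default to uniform; a weight map lets users downweight known
hotspots. Child order, event order and all tie-breaks are deterministic, so
identical input yields byte-identical annotated newick output
(`(A:1[&muts=16311],...)`, back mutations marked `!`), and the serialization
round-trips through the bundled parser.

## ρ dating

For a clade root *c* with *n* sampled individuals (haplotype
multiplicities counted),

ρ = (1/n) Σ_tips (mutations on the path c→tip),  
σ² = (1/n²) Σ_edges n_e² ℓ_e,

with n_e the individuals below edge *e* and ℓ_e its counted mutations;
internally exact rational arithmetic is used. σ follows from treating
per-edge counts as independent Poisson draws; on a star genealogy σ² = ρ/n
exactly. Back-mutation events on a path are counted: they are observed
mutations.

Two calibrations are built in: the complete-genome clock (3,624 years per
mutation, counting retained substitutions; a switch includes retained
indels) and the synonymous clock (7,884 years per synonymous substitution).
Ages are `correction(ρ · rate)` with a 95% CI from the normal approximation
ρ ± 1.96σ, the lower bound floored at zero, and the synonymous column's
standard error reported as σ_syn × rate. The correction defaults to the
identity (strictly linear clock); a monotone piecewise-linear correction
curve can be supplied as (raw age → corrected age) knots for calculator-style
purifying-selection adjustments, since only the identity behaviour is
verifiable from first principles. The CI is a normal approximation; no
likelihood-based interval is attempted. In the age table each clade's root
is the MRCA of its assigned samples, and empty clades are flagged, not
dropped.

## Synthetic data generator

The generator emulates the statistical structure the dating machinery
assumes: a clade of complete genomes descending from one founder of known
age. Defaults describe the emulated study — 150 genomes, founder age 20,000
years, one mutation per 3,624 years — with star, Yule (pure-birth, rescaled
so all tips sit at the founder age) or user-supplied topologies. Mutations
per branch are Poisson(branch length / rate); sites are drawn from a
site-rate profile (uniform plus 15 hotspots at 30× by default, giving
occasional parallel and back mutations as in real control-region data);
kinds are 94% transitions, 5% transversions, 1% indels, reflecting the
strong mtDNA transition bias while giving the exclusion filter something to
remove. A repeat hit at a derived site reverts it. Founder motif variants
can be planted so classification is exercised end-to-end.

Two deliberate departures from free mutation keep the truth exactly
recoverable: indels are only placed where their 3'-most normal form is the
chosen position, and indels stay ≥3 bp from other derived sites on the same
lineage — adjacent edits admit multiple equally parsimonious alignments, so
their scored representation would not be unique for any aligner. What the
generator does not emulate: selection and real site-rate spectra,
heteroplasmy, sequencing error, and ancient-DNA damage. Passing the
validation suite therefore demonstrates the correctness of the machinery
under the model's assumptions, not robustness to real-data artefacts.

## Validation summary (what the tests compute)

* Codec bijectivity on 1,000 random variants; apply-then-score identity on
  random variant sets and on simulated genomes.
* Synonymy annotation vs whole-protein translation on 500 random coding
  substitutions and every substitution in the ATP8/ATP6 overlap.
* Tree length vs the exhaustive oracle on 50 random instances; closed-form
  ρ/σ identities; σ vs a 20,000-replicate Poisson parametric bootstrap
  (within 5%) on 10 random genealogies.
* Founder-age recovery on star genealogies (n = 100 tips, 20,000 years):
  mean over 200 replicates within 2 Monte-Carlo standard errors of truth,
  95% CI coverage within [90%, 99%] over 500 replicates.

Problem sizes (replicate counts, tip numbers) were chosen so the full suite
runs in about a minute on one core while keeping Monte-Carlo error well
below the tolerances being checked.

## Known limitations

* Topology-level agreement with any particular published tree is not
  promised — only parsimony-score optimality on small instances and the
  documented structural invariants; large heavily-conflicted datasets fall
  back to the deterministic greedy resolution, which is not guaranteed
  optimal.
* The identity clock correction makes old complete-genome ages upper-ish
  estimates relative to calculator-corrected values; supply correction knots
  to reproduce a specific calculator.
* The median-network style representation (median vectors, reticulations)
  and bootstrap/likelihood support values are out of scope.
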
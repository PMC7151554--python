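# Methods

## The question and the estimator

Eukaryotic genomes are evolutionary chimeras: part of the conserved gene
repertoire traces to the archaeal host lineage at the origin of eukaryotes,
part to bacteria (foremost the mitochondrial, and in photosynthetic lineages
the plastid, endosymbiont).  `epclust` implements the cluster-based protocol
for estimating, per eukaryote genome, the proportions of genes whose
prokaryotic homologs occur **only in bacteria** versus **only in archaea** —
deliberately without building gene trees, so the origin call for each family
is independent of phylogenetic inference.

The pipeline has four stages.

1. **Within-domain families.**  All-vs-all exact local alignment inside each
   domain (bacteria, archaea, eukaryotes); reciprocal best hits per genome
   pair at E ≤ 1e-10; each reciprocal pair annotated with global
   (Needleman–Wunsch, EMBOSS-needle semantics) percent identity and kept if it
   passes the domain cutoff (≥ 25% for prokaryote pairs, ≥ 40% for eukaryote
   pairs); Markov clustering (inflation 2.0) of the resulting weighted graph;
   retention filters of ≥ 5 sequences for prokaryotic families and ≥ 2 species
   for eukaryotic families.

2. **Eukaryote–prokaryote clusters (EPCs).**  Reciprocal best *cluster*
   linking: a eukaryote family and a prokaryote family are merged when ≥ 50%
   of each side's qualifying best interdomain hits (E ≤ 1e-10, local identity
   ≥ 30%) land in the other.  Best interdomain hits are taken per prokaryotic
   domain, so a family can expose both a bacterial and an archaeal partner.
   One exclusive link ⇒ origin *bacterial* or *archaeal*; a bacterial and an
   archaeal link whose prokaryote families are mutually homologous ⇒ *dual*
   (merged, excluded from proportions); multiple non-homologous links ⇒
   *ambiguous* (excluded).  Exclusive EPCs are then **rechecked**: any
   eukaryote member with a hit in the remaining prokaryotic domain at
   E ≤ 1e-10 and global identity ≥ 25% voids the exclusivity call.

3. **Downsampling estimator.**  Bacterial genome collections outnumber
   archaeal ones by an order of magnitude or more, so a eukaryote family has
   more chances to *detect* a bacterial partner.  Per replicate, a bacterial
   subsample of size equal to the archaeal genome count is drawn, stratified
   by genus (quotas proportional to genus sizes, integerized by largest
   remainder; uniform draws without replacement within genus).  A bacterial
   EPC scores +1 for every eukaryote genome in its presence set iff ≥ 1
   sampled bacterium carries the family; archaeal EPCs are scored against the
   full, replicate-independent archaeal set (computed once).  Each eukaryote
   genome counts at most once per EPC, so paralog expansions do not inflate
   counts.  Per-genome proportions are ratios of replicate-mean counts
   (robust to zero-total replicates; the mean-of-ratios alternative is not
   used).  With sample size = full population, the estimator reduces exactly
   to direct counting — the unbiasedness guard in the test suite.

4. **Reporting.**  Per-group unweighted means of per-genome proportions with
   composite rows (all; with/without plastids; parasites); squared Pearson
   correlations between per-genome mean counts and proteome size;
   majority-rule functional annotation of EPCs against a labeled reference
   (single best hit at E ≤ 1e-10 and ≥ 80% query coverage per member, modal
   function per cluster, unannotated members ignored, ties to the
   lexicographically smallest function id and flagged); and the EPC × genome
   presence/absence matrix, genomes ordered taxonomically and EPCs by their
   eukaryote-group distribution signature (clusters confined to the
   photosynthetic lineages — Archaeplastida, plus SAR/Hacrobia where shared
   with Archaeplastida only — first, then ascending presence density).

## Alignment layer

The search primitive is *exact* optimal local alignment, not a seeded
heuristic: a batched affine-gap Smith–Waterman score kernel (numba) that
aligns one query against a block of subjects simultaneously.  Per-residue
score planes are precomputed per subject block so the innermost loop contains
no table lookups and auto-vectorizes; on one core it sustains roughly a
billion DP cells per second, which is what makes exact all-vs-all search at
the scenario sizes below practical.  Identity and coverage of individual
passing hits are recovered with Biopython's `PairwiseAligner` under the
identical scheme; score agreement between the two routes is asserted in the
tests, and both are checked against a pure-Python DP oracle.

Scoring defaults (the upstream protocol does not specify matrix or gap
costs; all are config keys): BLOSUM62, gap of length *k* costs 11 + *k*;
E-values from the Karlin–Altschul formula with the published gapped constants
(λ = 0.267, K = 0.041) over a search space of query length × total database
length.  Global alignments use needle defaults (gap open 10, extend 0.5,
free end gaps) and count terminal gap columns in the identity denominator,
as needle reports.  Half-integer gap costs are handled by doubling scores
internally.  Ties everywhere resolve deterministically (best hits to the
lexicographically smallest subject; global traceback prefers diagonal, then
gap in the first sequence, then gap in the second).

No heuristic prefilter is applied anywhere: every pair is scored by the full
DP, so completeness above the identity cutoffs is exact by construction
rather than probabilistic.

Markov clustering runs per connected component (flow cannot cross a gap)
with self-loop weight = maximum incident edge weight, entry pruning at 1e-5,
convergence tolerance 1e-6, at most 200 iterations; attractor overlaps are
resolved by largest flow, ties toward the attractor containing the
lexicographically smallest node, which enforces a strict partition.  The
split/join distance between partitions is provided as a utility
(`epclust.mcl.split_join_distance`) for stability comparisons; the
large-scale pruning-parameter tuning loop it belongs to is scale-specific
and not reproduced.

## Synthetic data: what it emulates, and what it does not

The generator plants gene families of five categories (eukaryote-specific,
eukaryote+bacteria, eukaryote+archaea, eukaryote+both, prokaryote-only) and
evolves members from family roots by substitution-only mutation.  Two edge
retentions (root→domain ancestor, domain ancestor→member) are calibrated
against the pairwise identity targets, accounting for convergent
substitutions (uniform replacement among the other 19 residues), so realized
within-domain identities sit at ~80% and interdomain identities at ~45% —
straddling the pipeline's 25/30/40% cutoffs from above while random
cross-family pairs stay far below 25%.  Presence of a family in a genome is
an independent Bernoulli draw per domain; parasite-flagged eukaryotes lose
bacteria-linked families at a multiplied loss rate; bacterial genomes carry a
skewed genus-size distribution (archaea none — only bacteria are ever
downsampled); function labels are planted family-level with
P(metabolism | bacterial) = P(information | archaeal) = 0.8 by default.

Deliberately absent: indels (identity targets map cleanly onto substitution
probabilities, and the protocol's load-bearing parts are identity
thresholds, not gap handling), realistic residue frequencies (uniform
ancestors keep the random background low and the calibration closed-form),
phylogenetic correlation among genomes, codon-level evolution, and
per-protein annotation noise (the majority rule collapses annotation to
family level anyway, so labels are planted per family).  Passing tests on these
data therefore demonstrate the *machinery* — threshold behavior, accounting,
bias correction, sign structure — not performance on real divergence-time
distributions.

## Validation scenarios (the package's study conditions)

* **Balanced recovery** (`recovery_conditions`): 30 bacteria in 5 genera
  (sizes 14/8/4/3/1), 12 archaea, 8 eukaryotes; 60 bacteria-linked + 40
  archaea-linked families (planted fraction 0.600) plus small side categories
  (4 eukaryote-specific, 2 dual, 3 prokaryote-only); presence 0.7
  everywhere; lengths 120–200 aa; 200 replicates of 12 bacteria.  Over 10
  seeds the mean recovered fraction must sit within 0.600 ± 0.05.

* **Imbalance correction** (`imbalance_conditions`): the detection asymmetry
  downsampling corrects exists only when families are carried by a small
  fraction of a large bacterial pool (as in the real data, where a family in
  a few dozen of 5,443 bacteria is easily missed by a 212-genome subsample).
  A small pool with dense presence makes naive and downsampled counting
  numerically identical, while sparse presence with only a dozen archaea
  collides with the ≥ 5-member family filter.  The scenario therefore uses
  800 bacteria : 80 archaea (10:1), prokaryote presence 0.1 (symmetric,
  patchy), 12 + 8 families (planted 0.600), 1,000 replicates of 80.  Naive
  counting must exceed the downsampled estimate, which must stay within
  ± 0.05 of truth.  A residual +0.02–0.03 inflation remains by design:
  archaeal families that fall under the five-member filter are lost outright,
  and downsampling corrects detection bias, not filter bias.

* **Parasite/dichotomy signs** (`parasite_conditions`): 20 bacteria, 10
  archaea, 6 eukaryotes of which 3 parasites with doubled loss of
  bacteria-linked families; function labels planted at 0.8.  Parasites must
  recover lower bacterial fractions (sign test over 10 seeds), and the
  category summary must return metabolism majority-bacterial and
  information majority-archaeal.

Problem sizes were chosen so the whole validation suite completes in tens of
minutes on a single core while every stage still operates in its intended
regime; the annotation and matrix stages are skipped in the imbalance runs,
whose assertions concern only the estimator.

## Numerical and degenerate-input choices

Zero-total genomes are reported with undefined proportions and flagged, never
silently dropped.  Empty sequences, unknown residues, inconsistent genus
tables, sample sizes of zero or above the population, empty graphs and
inflation ≤ 1 raise immediately.  Replicate draws are keyed by
(seed, replicate index) through `numpy` `SeedSequence`, so estimates are
independent of EPC input order and bit-identical across reruns; the pipeline
manifest aborts on any violation of the accounting identities
(EPC total = bacterial + archaeal + dual; final = exclusive − rechecked) or of
sequence mass conservation across the clustering stages.

## Known limitations

The correspondence denominator ("members with qualifying hits" vs "all
members") and the recheck direction (eukaryote members queried against the
other prokaryotic domain) are under-determined by the protocol; both defaults
are explicit config keys.  Confidence intervals over eukaryote genomes
(nested bootstrap) and phylogenetically weighted group means are out of
scope.  Exact all-vs-all alignment scales quadratically in sequences — the
point of this implementation is reproducibility and oracle-checkability at
desk scale, not heuristic search at survey scale.
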
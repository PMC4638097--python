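# Methods

## Problem and model

A patient presents with several synchronous, physically separated tumours
plus a normal-mucosa sample, all exome-sequenced and jointly genotyped.
Under a **clonal origin**, all tumour foci descend from one founder clone:
they share a trunk of somatic single-nucleotide variants (SNVs) absent from
the normal sample, and each focus adds a small private set. Under a
**field effect**, foci transform independently: apart from the germline
they share (almost) nothing. Treating binarised SNV presence/absence
across samples as population-genetic markers turns the question into a tree
problem: do the tumour samples form a supported clade to the exclusion of
normal tissue and the reference genome?

## Marker construction

- Coordinates are VCF convention (1-based, inclusive) throughout.
- Multi-allelic rows are split per alternate allele; a sample is a carrier
  of a marker only if its genotype contains that specific allele. This
  keeps markers biallelic, matching the 0/1 model.
- High-confidence filter: site FILTER must be PASS, every sample genotyped,
  and the **called** allele supported by at least `min_reads` (default 4)
  reads in every sample. "Supporting reads" are AD[alt] for carriers and
  AD[ref] for homozygous-reference samples (DP fallback); a raw
  alt-allele-depth reading would be zero for every hom-ref sample and
  discard all somatic sites, so the called-allele reading is the only
  self-consistent one. `depth_mode="dp"` (total depth) is available.
- Records with any missing genotype are dropped, not imputed.
- Known-site exclusion matches on (chrom, pos, alt) — stricter than
  position-only, so somatic alleles coincident with common-SNP positions
  survive.
- Binarisation: 1 = het or hom-alt, 0 = hom-ref. All-zero columns carry no
  signal and are removed; an all-zero "reference" pseudo-sample row is
  appended for rooting.

## Sharing partition

With normal bit n and tumour bits T, each marker falls in exactly one of:
ALL_SHARED (n=1, all T=1), TUMOUR_SHARED (n=0, all T=1; the trunk),
TUMOUR_PRIVATE (n=0, one T=1), OTHER_TUMOUR (n=0, 2 ≤ |T=1| < all),
NORMAL_PRIVATE (n=1, no T), OTHER_NORMAL (n=1, some but not all T).
"Tumour-associated" = any class with n=0. The classifier accepts any
number ≥ 2 of tumour samples. All classes are reported separately rather
than aggregating an "Other" bar.

## Phylogenetics

- Distances: Euclidean on binary rows, d(a,b) = sqrt(# differing markers).
- **BioNJ** (Gascuel 1997) is the primary tree builder: variance-weighted
  neighbour joining with v initialised to d, pair choice by minimal
  Q(i,j) = (r−2)d(i,j) − S_i − S_j, branch lengths
  b_i = d(i,j)/2 + (S_i − S_j)/(2(r−2)), reduction weight
  λ = 1/2 + Σ_k(v(j,k) − v(i,k))/(2(r−2)v(i,j)) clamped to [0,1], and exact
  three-point lengths for the final three nodes. Q-ties break to the
  lowest index pair for determinism (note that with four nodes left the
  two complementary pairs tie structurally; different tie rules yield the
  same topology but may share length differently among the last three
  edges on non-additive input). Classical neighbour joining is the
  constant-variance special case (`neighbor_joining`), used for
  cross-checks. Negative branch lengths are retained, as is standard NJ
  practice.
- UPGMA (scipy average linkage, converted to the package's tree type) is a
  concordance check only.
- Rooting: the tree is rooted on the edge leading to the reference leaf,
  splitting that edge at its midpoint. Rooting is idempotent and preserves
  bipartitions, hence supports.
- **Bootstrap**: marker columns are resampled with replacement at full
  width (constant germline columns included, mirroring a bootstrap over all
  called mutations; `variable_only=True` restricts to variable columns).
  Support of an internal edge = % of replicate trees containing the same
  leaf bipartition; supports attach to bipartitions, so they are invariant
  to rooting. Default 10,000 replicates (CLI-tunable; the acceptance runs
  use 1,000). Deterministic for a fixed seed. Supports are invariant to
  column order only in distribution: the replicate stream depends on the
  actual column layout.
- Monophyly: the tumour samples are clonal when their exact bipartition
  (tumours | normal + reference) is present; otherwise the smallest clade
  containing all tumours is reported with its support.

### Normal-contamination heuristics

Three flags, any of which marks the normal sample as suspect:
(a) the normal leaf falls inside the smallest clade containing all tumours;
(b) the normal terminal branch is **at least as long as** the shortest
tumour terminal branch; (c) the tumour-associated marker fraction is below
0.20. Rule (b) is evaluated on a BioNJ tree built from **squared**
Euclidean distances (marker counts): counts are additive on tree-like
binary data, so terminal branches estimate per-sample somatic loads,
whereas on the sqrt scale the long germline path inflates the fitted normal
branch even for a clean patient. The 0.20 threshold sits between a clean
clonal patient at default scales (~0.37 tumour-associated) and a heavily
contaminated one (~0.11–0.15).

## Mutation contexts

Every SNV is collapsed onto the strand whose reference base is A or C:
for a G/T reference base the variant is read on the minus strand, so the
5′ neighbour is the complement of the plus-strand base *following* the
site, and central/alternate bases are complemented (the 3′ neighbour
mirrors accordingly). Each valid SNV maps to exactly one of eight
dinucleotide classes {A,C,G,T}p{A,C}*; TpC* marks the APOBEC deaminase
context, refined to TpC*pA by the trinucleotide variant. Contig edges and
non-ACGT neighbours yield UNKNOWN, which is excluded from frequency tables
and reported separately. Strand symmetry (classifying a sequence equals
classifying its reverse complement at the mirrored position) is enforced by
property tests.

## Functional impact and drivers

snpEff-style ANN strings are parsed per transcript; a site's tier is the
maximum severity across transcripts and it is "functional" iff the tier is
LOW, MODERATE or HIGH. Unannotated or malformed records are UNANNOTATED
(non-functional, counted separately). Driver overlap reports one row per
(gene, marker) for functional SNVs present in at least one tumour sample
whose annotation hits a user-supplied gene list, plus the TpC* fraction of
the listed-gene missense rows. When several genes annotate one SNV, all
are reported (losslessness preferred).

## Enrichment statistics

All comparisons are two-sided Fisher exact tests with the
point-probability (minimum-likelihood) rule — the p-value sums
hypergeometric probabilities of all tables with the observed margins whose
point probability is at most the observed one, within a 1e-7 relative
slack to absorb floating-point ties (the convention of R's `fisher.test`).
A zero margin is degenerate: p = 1, flagged. Effect sizes are ratios of
proportions, (k1/n1)/(k2/n2), with +inf (no pseudocounts) when the
denominator proportion is zero; the delta-method standard error
fold·sqrt((1−p1)/k1 + (1−p2)/k2) accompanies fold estimates. The timing
comparison pools private SNVs across tumours; a per-tumour breakdown is
also emitted. No multiple-testing correction is applied across the three
planned comparisons.

## Synthetic patients

The generator works at the variant-call level (no reads) and plants every
feature the pipeline measures:

| knob | default | meaning |
| --- | --- | --- |
| genome | 2 contigs, 100 kb + 50 kb, GC 0.41 | random reference; enough TpC/non-TpC sites for all placements |
| n_germline | 900 | markers in all samples (the individual's genotype) |
| n_trunk | 450 | markers in all tumours, none in normal (clonal trunk) |
| n_private | (40, 25, 15) | per-tumour private markers |
| other classes | 10 / 12 / 3 | other_normal / other_tumour / normal_private noise classes |
| TpC* fractions | 0.10 / 0.60 / 0.20 / 0.15 | germline / trunk / private / other |
| functional fractions | 0.20 / 0.40 / 0.40 / 0.30 | same order |
| contamination | 0 | per-trunk-marker leak probability into the normal sample |
| depth_mean, dropout, missing_rate, fail_filter_rate, known_fraction | 50, 0, 0, 0, 0 | call-level noise; zero by default |

Scales emulate a well-behaved patient of this sampling design at high-depth
exome coverage (≈1.4–1.5 k high-confidence SNVs, a dominant trunk, few
private SNVs, a
~6× trunk/germline and ~3× trunk/private TpC* contrast); the field-effect
preset removes the trunk and gives each focus its own full somatic load
(490/475/465). Context planting samples per-class TpC* counts
binomially and places each marker on a genome site whose strand-collapsed
context matches, so classifier output can be checked marker by marker.
One seed drives a single generator stream; FASTA/VCF/truth artifacts are
byte-reproducible.

What the simulator does **not** emulate: read-level sequencing error and
mapping artefacts, copy-number change and allelic imbalance, subclonal
cellular fractions (markers are strictly present/absent), indel realism
(indels are treated as generic markers), linkage between neighbouring
sites, and realistic genome composition beyond GC content. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under its own model, not robustness to every artefact of real exome data.

## Numerical choices and problem sizes

- Fisher p-values: scipy's hypergeometric pmf under the package's own
  two-sided rule; validated exhaustively against integer enumeration for
  all tables with total ≤ 30.
- BioNJ recovery is validated on 1,000 random additive trees of 4–8 taxa
  (branch lengths to 1e-9; the additive representation is unique, so
  recovering the generating tree is the full check), against an
  independent textbook NJ implementation under uniform variances, and
  against R `ape::bionj` where R is available.
- Bootstrap-based tests use 200–1,000 replicates; the model-discrimination
  study uses 50 clonal + 50 field seeds at 200 replicates each. The
  acceptance script uses 1,000 replicates for the support estimate and
  averages folds over 10 seeds. These sizes keep the full suite fast
  while leaving Monte-Carlo error far below every margin asserted.
- Type-I calibration of the exact test is checked at α = 0.05 over 2,000
  null replicates (n = 450 vs 80, p = 0.2 both).

## Known limitations

- The contamination flag is a heuristic triple, not a mixture model; it
  reports which criteria fired and is meant to prompt inspection, not to
  quantify contamination.
- Euclidean-on-binary distances are sub-additive across long shared paths;
  branch lengths on the display tree are therefore not mutation counts
  (use squared distances for count-scale readings, as the contamination
  rule does).
- The indel pathway treats indels as generic presence/absence markers;
  no indel-specific error model is attempted.
- Bootstrap supports on very few markers are quantised (multiples of
  100/reps) and can only take values 0/100 when a single distinct column
  dominates.
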
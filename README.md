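# clonetrace

**Clonality inference for synchronous multifocal tumours from multi-sample
exome variant calls**, with an APOBEC TpC* mutation-context timing analysis
and a synthetic multifocal-patient generator.

When several physically separated tumours are found in one organ at the
same time (common in non-muscle-invasive urothelial bladder cancer), two
origins are possible: a single founder clone whose cells migrated and
re-implanted (**clonal origin**), or independent transformation events
across a carcinogen-exposed epithelium (**field effect**). The two
hypotheses make opposite predictions about somatic variant sharing: a clone
carries a large shared "trunk" of mutations in every focus, while a field
effect leaves each focus with essentially private mutations on top of the
common germline.

`clonetrace` decides between them from one patient's multi-sample VCF (one
normal-mucosa sample plus two or more tumour samples):

1. **High-confidence filtering** — keep sites that pass the caller's
   filter, are genotyped in every sample, and have the called allele
   supported by ≥ 4 reads in every sample; optionally drop known
   polymorphic sites (dbSNP-style VCF).
2. **Binary markers** — code each sample 1 if it carries the alternate
   allele (het or hom), 0 otherwise; append an all-zero "reference genome"
   pseudo-sample.
3. **Sharing partition** — assign every marker to one of six classes
   (all-shared germline, all-tumour trunk, per-tumour private, …).
4. **Phylogenetics** — Euclidean distances on binary rows,
   d(a,b) = √(# differing markers); a **BioNJ** tree (Gascuel 1997; the
   variance-weighted neighbour joining Q(i,j) = (r−2)d(i,j) − S_i − S_j,
   robust to heterogeneous branch lengths) rooted on the reference row;
   UPGMA as a concordance check; **bootstrap support** = % of trees from
   column-resampled matrices containing each bipartition. A fully
   supported tumour clade ⇒ clonal origin.
5. **APOBEC contexts** — each SNV is collapsed onto the strand with an A/C
   reference base; a C preceded by a 5′ T is a **TpC\*** site, the APOBEC
   deaminase signature (most specific as TpC*pA). Exact Fisher tests
   compare TpC* proportions between trunk and germline (is the tumour
   APOBEC-driven?) and between trunk and private branches (did APOBEC act
   early — "mutation timing"?).
6. **Functional impact & drivers** — snpEff-style ANN tiers (LOW/MODERATE/
   HIGH = functional), trunk-vs-germline functional enrichment, and overlap
   of functional tumour SNVs with a candidate driver-gene list.

Because real patient data of this design are rarely shareable, the package
ships a first-class simulator (`clonetrace.simulate`) that emits a random
reference FASTA, a multi-sample VCF with per-sample genotypes/depths, a
known-sites VCF and a complete truth table, with sharing classes, TpC*
fractions and functional fractions planted per class — so the entire
pipeline is exercisable and testable end to end.

## Worked example

```bash
python examples/02_clonality_tree.py
```

prints (clonal patient, then field-effect patient):

```
--- clonal patient ---
(reference:11.32473516,(((T1B:4.006222231,T2B:3.342246997)90:0.4492503709,T1A:4.52731321)100:10.37044799,N:7.566419546):11.32473516);
tumours monophyletic: True, clade support 100 %

--- field-effect patient ---
(reference:11.08869694,(((N:6.909510653,T2B:15.02220155)57:0.2591961092,T1B:15.21466093)53:0.3415414973,T1A:15.26589658):11.08869694);
tumours monophyletic: False
```

The clonal patient's three tumour samples form a clade with 100 % bootstrap
support — every resampled marker matrix separates the tumours from the
normal mucosa and the reference genome, the signature of a shared somatic
trunk. In the field-effect patient the normal sample nests among the
tumours and supports collapse. The timing analysis
(`examples/03_apobec_timing.py`) prints

```
            group    n  TpC*  tpc_fraction
0      ALL_SHARED  900    90      0.100000
1   TUMOUR_SHARED  450   276      0.613333
2  TUMOUR_PRIVATE   80    11      0.137500
trunk vs germline: fold=6.13, Fisher p=5.37e-87
trunk vs private (timing): fold=4.46, Fisher p=6.39e-16
```

a ~6-fold TpC* enrichment on the trunk relative to the germline background,
and a significant excess over the private branches — APOBEC-type mutations
concentrated early in tumour development.

A thin CLI wraps the same library calls:

```bash
clonetrace simulate --seed 7 -o simdir/
clonetrace run --vcf simdir/calls.vcf --fasta simdir/genome.fa \
    --normal N --tumours T1A,T1B,T2B --known simdir/known.vcf \
    --reps 10000 --seed 17 -o outdir/
```

`outdir/` then holds the marker matrix, partition tables, the Newick tree
with supports, context/enrichment TSVs and a JSON + Markdown report; every
number in the report is re-derivable from the TSVs, and reruns with the
same seed are byte-identical.

## Layout

- `src/clonetrace/` — library (`variant_matrix`, `sharing`, `phylo`,
  `context`, `impact`, `stats`, `simulate`, `pipeline`, `cli`, `trees`)
- `examples/` — one short narrative script per capability
- `tests/` — pytest suite (unit, hypothesis property tests, acceptance)
- `docs/methods.md` — models, conventions, parameter defaults, limitations
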
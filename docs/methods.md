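# Methods

This note documents the models, defaults and numerical choices behind
`sgcseq`, and what its synthetic-data tests do and do not demonstrate.

## Coordinates and digestion

All coordinates are 0-based half-open (BED-native); 1-based coordinates
appear only in VCF output. A restriction cut position is a top-strand bond
index, so fragments for one enzyme partition a chromosome exactly and their
lengths sum to the chromosome length; zero-length terminal pieces (a cut at
a sequence end) are dropped. The bundled enzymes are the 4-base cutters
MseI `T^TAA`, BfaI `C^TAG`, Sau3AI `^GATC` and CviQI `G^TAC` with standard
cut chemistry; Sau3AI and its isoschizomer DpnII recognize the same site and
share one table entry. All four recognition sites are palindromic, so a
top-strand scan is double-strand complete. Sticky-end overhangs are ignored
for coordinate bookkeeping: fragment boundaries are top-strand cut
positions. User enzymes can be added via a YAML table.

## Capture design rules

A capture oligo is 20 + 40 + 20 nt: two genome-complementary arms around a
constant linker. Design per ROI (exon padded by `pad`, default 50 b,
clipped at chromosome ends) and per enzyme:

1. Fragment length ≤ `max_amplicon` (default 800, **inclusive**; the
   boundary is a parameter): one oligo, arms flush inside both cut ends,
   no flaps.
2. Oversized fragment: every amplicon is anchored flush at a cut end,
   because the circularization junction must ligate at a fragment end; only
   the other, internally-placed arm may leave a flap (cleaved enzymatically
   before ligation). The inner arm sits at the ROI boundary, or at maximal
   reach when the ROI extends further. ROI bases farther than
   `max_amplicon` from both cut ends are uncoverable by that enzyme — this
   is precisely why enzyme choice matters and what `rank_enzymes`
   quantifies. We deliberately emit no doubly-flapped interior amplicons:
   they have no anchored ligation junction, and allowing them would make
   every enzyme trivially cover every ROI.
3. ROIs spanning internal cut sites receive tiled designs, one set per
   overlapped fragment.
4. Arms may not overlap known SNP positions. A placement whose arm hits a
   SNP is emitted with a `design_failure` annotation and excluded from
   coverage accounting rather than silently shifted; coverage reports stay
   honest about what is designable.

Oligos are reported on the top strand; strand is metadata, not a
constraint. Coverage accounting measures the union of amplicon ∩ ROI
intervals of non-failed oligos. Summary rounding follows the design-summary
table convention: ROIs/gene to two decimals, oligo averages to the nearest
integer.

## Quality-control flags

* **W** — either 20-nt arm occurs more than once in the genome. Occurrence
  counting is exact-match, double-stranded and position-deduplicated (a
  palindromic arm is not double-counted); 1-mismatch counts are computed
  and reported as metadata but do not drive flags.
* **P** — both arms duplicated, and a second locus reproduces copies of
  both arms on one strand, in the same order, within 1 kb. "In phase" is
  not further specified by the assay description; same-strand same-order
  within-window is our operationalization, and it guarantees P ⇒ W by
  construction.
* **A** / **R** — the outer 14 bases of an arm (the end farthest from the
  linker; the length is a parameter) exactly match an Alu consensus /
  any other repeat consensus, either strand. Missing libraries leave the
  flag unset and mark the annotation unevaluated.

`alignment_site_prevalence` computes, per alignment column and enzyme, the
fraction of aligned sequences with a recognition site starting there
(gap-skipping, so per-sequence site calls are gap-invariant). It explains
off-target capture by enzymes whose sites are conserved inside repeat
elements.

## Repeat masking

Two per-base scores over a target interval, combined by logical OR:

* repeat score: every 14-base tile (1-base increments) with a perfect
  either-strand match to a repeat-library sequence adds 1 to all 14
  coordinates it covers; overlapping matches accumulate, so
  Σ score = 14 × (matching tiles).
* genome score: every 36-base tile occurring ≥ 2 times in the genome
  (the target itself lies in the genome, so multiplicity 2 means one extra
  locus) likewise adds 1.

The 14/36 defaults reflect the short-read operating point — shorter repeat
tiles delete true variants, longer ones inflate false positives — and both
are parameters. Matching is exact-only on both strands; whether 1-mismatch
hits should also mask is left off by default with the counts available.

## Coverage adjustment and covariates

Mean per-base FC over the amplicon (both strands) drives a three-tier
concentration adjustment: > 1000 → 5 pM, 100–1000 → 50 pM, < 100 → 500 pM.
Boundary values 100 and 1000 fall in the medium tier (the stated range is
inclusive). Normalized coverage tracks are `log10(depth / median)` with
zero-depth positions mapped to a configurable finite floor (default
`log10(0.5/median)`) so Pearson correlations between samples remain
computable; the transform is invariant under global depth rescaling.
Performance covariates stratify mean FC by amplicon length
(<200 / 200–600 / 601–800 / >800 b), arm GC (< 75% vs ≥ 75%) and flap size
(0 / ≤ 100 / > 100 b), the three factors that depress capture yield.

## SNV caller

The error matrix P is estimated by tabulating base calls grouped by each
position's majority base, with a pseudocount (default 0.5) preventing
structural zeros that would make log-likelihoods infinite. Ties for the
top and second base break by fixed order A<C<G<T. Heterozygotes
contaminate their own row of P; one re-estimation pass excluding the
identified candidates runs by default (`iterate=True`).

Candidate rule: per-strand LLR > c on both strands, per-strand depth ≥ 10,
combined second-allele fraction ≥ 13%, not repeat-masked. The default
threshold c = 10 was chosen by simulation at the assay operating point
(uniform 1% error, 300× per strand): a homozygous position needs ~30
second-allele reads on one strand to reach LLR 0, so c = 10 with
double-strand confirmation leaves essentially no false candidates per 10⁶
homozygous bases while true heterozygotes score in the hundreds; the
acceptance script measures both numbers. Genotype output distinguishes
heterozygotes from homozygous positions only; a homozygous non-reference
base appears as the position's top base rather than as a separate genotype
class.

Concordance reports het and hom agreement against a truth table as
percentages to one decimal. The diagnostic odds ratio it emits is **our
construction**: (het hits × hom hits) / (het misses × hom misses),
"Infinite" when a category has no misses; it is labelled as such in output.

Indel filtering consumes gapped-alignment records produced upstream and
applies three rules: ≥ 2 distinct breakpoints among forward supporting
reads and ≥ 2 among reverse; total FC > 50 at the indel's 5′ position; and
no alternative genome placement of any supporting read with < 3 mismatches
(scanned by brute force over both strands, excluding a window around the
indel locus).

## Somatic caller

The assay description gives the D statistic's surrounding prose but its
standard-error formula, t degrees of freedom, and the values of α and D0
only as unrendered equations; the implementation therefore uses the
standard two-proportion reconstruction consistent with that prose:

* `SE = sqrt(p_t(1−p_t)/N_t + p_n(1−p_n)/N_n)` with p the per-sample
  fraction of the candidate base b;
* Welch–Satterthwaite degrees of freedom by default (matching
  "approximately t distributed" at unequal depths), with pooled
  `N_t + N_n − 2` available via `df_method="pooled"`;
* defaults α = 0.05, D0 = 0.10, both configurable and recorded in VCF
  headers.

b is the highest-count tumor base excluding the normal's top base, ties by
base order; a zero-count b skips the position. The pass rule is applied
per strand and both strands must pass. LOH uses the same CI machinery on
the tumor allele-fraction imbalance `n_x/(n_x+n_y) − 0.5` at normal-het
sites, with a one-sample binomial SE and a configurable margin (default
0.10).

## Synthetic data: what it shows and what it does not

Generators emit the exact file dialects the pipeline consumes plus truth
manifests, and are deterministic per seed (one `SeedSequence` fans out to
per-component substreams). Pileups are per-strand multinomial draws from
genotype-mixed rows of P — they emulate depth, strandedness, miscall
structure, tumor fractions and LOH shifts, but **not** alignment artifacts,
correlated errors within reads, PCR duplicates, mapping bias around
indels, or capture-efficiency variation between amplicons. Passing the
statistical suites therefore demonstrates correctness of the estimators
and decision rules under the stated error model, not end-to-end accuracy
on real sequencing data. Barcode simulation corrupts only the index bases;
read bodies are not modelled.

Problem sizes in the test and acceptance suites — 10-kb oracle sweeps,
2 × 10⁴-position sensitivity panels, 10⁶-position specificity runs at
300× per strand, 2–3 × 10⁵-read demultiplexing — were chosen so each
statistical check has enough resolution for its stated bound (e.g. a
false-candidate bound of 1 per 10⁶ needs 10⁶ nulls) while the whole suite
completes in about a minute.

## Known limitations

* No thermodynamic arm optimization (Tm/ΔG) and no redesign around
  paralogous regions; flagged designs are reported, not repaired.
* Designs from different enzymes are not deduplicated; panels report
  per-enzyme counts.
* The genome-multiplicity mask rebuilds its k-mer index per target, which
  is fine at panel scale but not genome scale.
* The somatic caller assumes independent strands and binomial counts; it
  does not model purity, ploidy or copy number.
* Alignment itself (including gapped alignment for indels) is out of
  scope; the package consumes pileups and gapped-read records.
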
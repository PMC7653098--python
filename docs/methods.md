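# Methods

## Coordinate system and reference layer

All coordinates are 1-based inclusive on the 16,569-bp human
mitochondrial genome (rCRS numbering), the convention of the mtDNA
literature ("A663G"). The genome is circular; the control region
(D-Loop) is modelled as a single feature spanning the origin
(16024..576, length 1,122 bp), and all offset arithmetic wraps through
16569→1.

The bundled feature map uses canonical rCRS gene boundaries: 13 protein
genes, 22 tRNAs, 2 rRNAs, the D-Loop, explicit intergenic spacers (so
`locate()` is total — every position maps to at least one feature), and
regulatory sub-elements (TAS, CSB1–3, an L-strand promoter-associated
region, the H-strand promoter, and the L-strand replication origin
OLR1). Overlaps are real and intentional: ATP8/ATP6 share 8527..8572 in
different frames, ND4L/ND4 share 10760..10766, tRNA-I/tRNA-Q share three
bases, and OLR1 overlaps tRNA-N and tRNA-C; a variant in an overlap is
annotated once per feature. Published per-gene rate tables sometimes
imply slightly different lengths (a D-Loop of ~1,195 bp, ATP6 of 680 bp,
tRNA-T of 65 bp); this package keeps the canonical lengths (1,122, 681,
66) since the alternative boundary definitions are not stated anywhere
reproducible. ND1's canonical 956 bp is consistent with the printed
rates either way.

Genes whose length is not a multiple of three (ND1, ND2, CO3, ND3, ND4,
CYB) end in an incomplete stop codon completed by transcript
polyadenylation. Variants in those trailing one or two bases are
annotated `stop_region` rather than forced into a codon call.

The bundled reference sequence is a *synthetic stand-in* for the rCRS,
generated by `scripts/build_synthetic_reference.py` with a fixed seed:
protein genes get ATG starts, stop-free interiors in their own frame and
planted (or incomplete) stops; every variant position documented in the
tests carries the documented reference base; and the codons around
documented coding variants are chosen so the documented amino-acid
changes result (e.g. the Ala→Thr change of G13333A forces a GCn codon
with G at the mutated position). The build script re-annotates all
documented variants and fails if any label disagrees. Analyses of real
data should pass a genuine rCRS FASTA to `load_gene_map(fasta=...)`;
everything downstream is reference-agnostic.

The genetic code is NCBI translation table 2 (vertebrate mitochondrial)
taken from Biopython's codon tables; tests pin the four differences from
the standard code (ATA→M, TGA→W, AGA/AGG→stop).

## Variant identity, MAF and IO

A variant is the triple (position, ref, alt); alleles are normalised on
read (shared suffix then prefix trimmed, VCF anchor-base convention for
indels) so HGVS-style and VCF-style inputs unify. MAF is defined as
alt-supporting reads over total site depth. A variant undetected in one
tissue is an explicit observation with `alt_reads = 0` — the somatic
rule needs the blood zero, so missing records are never silently
dropped. Observations below 300× depth are excluded on read (the
matched-pair design assumes deep coverage; thresholds were calibrated
for it), with a logged count. VCFs are read through pysam, one record
per ALT allele (multiallelic sites decomposed, site depth = sum of AD).

## Origin and ploidy classification

Thresholds (`ClassificationConfig`): somatic requires blood MAF < 0.001
and tumor MAF > 0.01; germline requires blood MAF > 0.01; the band
between 0.001 and 0.01 in blood is "probable mutation" and is excluded
from downstream somatic analyses; everything at or below 0.01 in both
tissues is absent. Two boundary conventions are fixed here because the
verbal definitions leave them open: blood MAF exactly 0.001 is a
probable mutation (the somatic rule is strict), and MAF exactly 0.95 is
homoplasmic (closing the gap between "1% to <95% heteroplasmic" and
">95% homoplasmic").

The germline rule is cohort-level: a variant with blood MAF > 0.01 in
*any* patient is germline for every patient and can never be called
somatic elsewhere. This matches variant-level (not observation-level)
class accounting and protects against mistaking a shared polymorphism
with patchy blood detection for a recurrent somatic mutation.

Heteroplasmy shift per germline variant: per-carrier deltas (tumor MAF −
blood MAF), a flag count for carriers reaching homoplasmy in the tumor
only, and a two-sided Mann–Whitney U comparing the blood and tumor MAF
samples. The U test uses exact enumeration when both samples have n ≤ 8
and no ties, otherwise the normal approximation with tie correction
(scipy). The comparison treats the two tissues as independent samples —
statistically conservative for paired data, but it is the conventional
test in this setting and the per-patient deltas carry the paired signal.

## Cohort summaries

Counts are over distinct variants unless stated; because two ALT alleles
can share a position, both the distinct-variant and distinct-position
tallies are emitted. Per-gene counts assign a variant to every feature
covering its position (overlaps double-count, deliberately); rates are
count × 1000 / feature length, full precision internally, decimal
half-up rounding for display. Per-subtype mutation rates divide by the
whole genome length (16,569 bp). For tabulation a single primary
consequence is chosen per variant with priority protein effect > tRNA >
rRNA > regulatory > D-Loop > intergenic, so a tRNA variant inside OLR1
tabulates as tRNA and a D-Loop variant inside TAS as regulatory. A
recurrent somatic mutation counts as homoplasmic if any carrier's tumor
MAF reaches the threshold.

Association tests use Fisher's exact test for 2×2 tables with any
expected cell < 5 and otherwise the chi-square test without continuity
correction (larger sparse tables fall back to chi-square with a logged
warning). Subtype sharing is a Venn partition of somatic variant keys
over the four IHC subtypes; patients without an assigned subtype are
excluded with a logged count. Unsupervised clustering uses binary
patient × mutation presence matrices, Jaccard distance and average
linkage, with patients entered in sorted id order so leaf order is
deterministic.

## Survival analysis

Burden strata: `any_vs_none` (mutation-negative vs -positive) or
`mean_split` with the threshold at the cohort mean burden rounded to the
nearest integer and burden ≤ threshold → low. Kaplan–Meier curves come
from lifelines; the log-rank test is two-group; the Cox model uses
Efron's tie approximation (lifelines default) and reports the
group-indicator hazard ratio with a Wald 95% CI, optionally adjusted for
covariate columns (age, stage, receptor status) passed by name. No
events, a single group or a separated fit raise a non-estimable signal
rather than returning numbers.

## Haplogroup typing

A simplified marker-panel scorer, not a phylogenetic caller: each of the
seven top-level haplogroups (A, B, C, D, H, J, L) has a small set of
diagnostic marker variants; a patient's blood profile (variants with
blood MAF > 0.5, since lineage markers are effectively homoplasmic) is
restricted to the panel's marker universe and scored per haplogroup with
the Kulczynski measure, ½(recall + precision). The score is 1 exactly
when the observed marker set equals the expected set and decreases
strictly with both dropouts and extras; ties break lexicographically and
are flagged. The bundled panel is a fixture; a fuller Phylotree-derived
panel can be supplied in the same TSV format. Sub-haplogroup resolution
and tree traversal are out of scope.

## Synthetic cohort generator

The generator emulates the study conditions of a 92-patient matched-pair
breast-cancer cohort; its defaults are the conditions, not tuning knobs:

* per-site depth uniform 300–6000× per tissue; observed alt reads are
  beta-binomial around the true MAF with overdispersion ρ = 0.002 (small
  enough that threshold crossings are dominated by the true MAF, large
  enough to be non-binomial);
* germline count per patient ~ Normal(37, 9) truncated to 16..75;
* haplogroup backbone markers (frequencies A 44.6%, B 22.8%, C 11.9%,
  D 12%, L 5.4%, H 2.2%, J 1.1%) carried homoplasmically with 5% marker
  dropout by default;
* the remaining germline variants are drawn from a cohort-level pool of
  530 shared polymorphic sites with skewed popularity weights
  (Beta(0.25, 1)), reproducing the observed structure in which a few
  hundred germline positions recur across the whole cohort with a mix of
  common variants and near-singletons. Germline blood MAFs are a
  mixture: 30% homoplasmic (≥ 0.97), 40% very low heteroplasmy
  (1.2–2%), 30% heteroplasmic 2–20%; heteroplasmic variants shift in the
  tumor with probability 0.35, drawing the tumor MAF from Beta(8, 2)
  (skewed toward homoplasmy), otherwise keeping the blood MAF;
* somatic mutations: zero-inflated count (26.1% of tumors negative;
  positive tumors draw a geometric count with p = 0.369 truncated at 17,
  overall mean ≈ 2), planted at positions that are not germline-
  evidenced anywhere in the cohort (by the cohort-level class definition
  such sites cannot carry a somatic truth label), blood true MAF exactly
  0, tumor MAF a mixture with 21.4% homoplasmic and the rest spanning
  0.01–0.95 (Beta(1, 2) scaled);
* mutational spectrum: 84% transitions among somatic SNVs, 67% among
  germline; 2% indels (half insertions, half deletions);
* metadata: IHC subtypes LA 63.3%, LB 24.4%, TN 6.7%, H2 5.6% with a
  2/92 chance of being unassigned; age ~ Normal(53.8, 11.5) clipped to
  30..92; overall survival from an exponential baseline (0.009/month)
  with uniform administrative censoring over 30–124 months and a
  configurable burden-group log-hazard (default 0 — the emulated study
  found no burden–survival association).

Tumor variant counts are emergent (germline + somatic ≈ 39 on average),
not a separate dial. All draws come from one seeded numpy generator, so
a fixed seed reproduces the cohort exactly; truth (origin class, true
MAFs, planted effect label, haplogroup, burden, survival group) is
emitted alongside the data and tests never reach into generator
internals.

What the generator deliberately does **not** emulate, and hence what
passing recovery tests do and do not show: somatic hotspots (generated
somatic mutations are almost all singletons, unlike the ~15% recurrence
seen in real cohorts), regional enrichment (positions are uniform, so
the coding fraction of somatic mutations is ~69% rather than the ~59%
of D-Loop-enriched real data), contamination, strand-specific damage
artefacts, and copy-number effects. Recovery results therefore validate
the pipeline's bookkeeping and thresholds under realistic noise, not its
behaviour on artefact-laden real sequencing.

## Problem sizes and numerical checks

The test suite runs default-sized cohorts (92 patients, ~3,500 paired
records) for recovery checks; the transition-fraction calibration pools
ten cohorts so the check measures the planted rate rather than one
cohort's sampling noise. The consequence annotation is verified
exhaustively against a brute-force whole-gene retranslation oracle for
every possible SNV in one H-strand gene (ND1) and the L-strand gene
(ND6). Cox recovery uses 200 replicates of n = 1000 with a planted
hazard ratio of 1.6 (Wald-CI coverage) and 200 null replicates of
n = 200 for log-rank p uniformity. The acceptance script reruns the full
pipeline on one default cohort plus one n = 1000 survival experiment.

## Known limitations

* The ambiguous "probable mutation" band is classified but not analysed
  further; no likelihood-based heteroplasmy caller is provided — the
  classes are pure MAF thresholds by design.
* Indel consequence calls are coarse (frameshift vs in-frame by length
  mod 3); in-frame indels are labelled `in_frame` and counted among
  non-synonymous changes.
* Disruptions of a stop codon are reported as missense; there is no
  distinct stop-loss class.
* The Mann–Whitney shift test ignores pairing (see above).
* Haplogroup calls are top-level only and depend entirely on the
  supplied panel.
* No NUMT handling, no raw-read processing, no variant calling: input is
  assumed to be called variants with allelic depths from an upstream
  pipeline.
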
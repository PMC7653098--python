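# mitopair

Matched blood–tumor mitochondrial DNA variant analysis: origin
classification from mutant allele fractions, heteroplasmy–homoplasmy
calling and shift statistics, strand-aware consequence annotation on the
mitochondrial genome, cohort summaries, haplogroup typing and
burden-stratified survival analysis.

## The problem

Tumor cells carry hundreds to thousands of mitochondrial genomes, so a
mtDNA variant is not simply present or absent — it has a *mutant allele
fraction* (MAF, alt reads / depth) anywhere between 0 and 1
(heteroplasmy). With deep sequencing of matched tumor and blood from the
same patient one can (i) separate inherited variants from acquired
mutations, (ii) watch inherited heteroplasmies drift toward homoplasmy in
the tumor, and (iii) ask whether somatic mtDNA mutational burden predicts
outcome. `mitopair` implements that analysis as a tested, reusable
pipeline for cohorts of matched pairs, driven either by real paired VCF /
TSV data or by its own synthetic cohort generator.

## The classification model

For each patient and variant, with blood MAF *b* and tumor MAF *t*:

| class | rule |
|---|---|
| germline | *b* > 0.01 in this patient, **or** in ≥ 1 cohort patient (cohort propagation) |
| somatic | *b* < 0.001 and *t* > 0.01 |
| probable mutation | 0.001 ≤ *b* ≤ 0.01 and *t* > 0.01 (ambiguous origin, excluded downstream) |
| absent | *b* ≤ 0.01 and *t* ≤ 0.01 |

Ploidy per tissue is a step function of the MAF: ≥ 0.95 homoplasmic,
0.01–0.95 heteroplasmic, < 0.01 undetected. Consequences are computed
under the vertebrate mitochondrial genetic code (translation table 2,
ATA=Met, TGA=Trp, AGA/AGG=stop) with L-strand genes read on the
complementary strand; mutation rates are reported per kilobase of each
feature (count × 1000 / length). Survival uses the Kaplan–Meier
estimator, log-rank test and a Cox proportional-hazards model (Efron
ties, Wald CI) on burden groups. See `docs/methods.md` for details and
assumptions.

The bundled reference sequence is a **synthetic stand-in** for the rCRS
(`src/mitopair/data/rcrs_synthetic.fasta`): a simulated 16,569-bp
sequence consistent with the bundled gene map and with the reference
alleles and codons of all documented variants used in the tests. Supply
`load_gene_map(fasta=...)` with a real rCRS FASTA to annotate real data.

## Worked example

```python
from mitopair import *

gmap = load_gene_map()
code = GeneticCode.vertebrate_mitochondrial()

# synthetic 92-patient matched-pair cohort with known truth
records, metadata, truth = generate_cohort(SimulationParams(), seed=42)
classified = classify_cohort(records, gene_map=gmap, genetic_code=code)
cohort = CohortTable(patients=metadata, records=classified)

bd = class_breakdown(cohort)
print("distinct tumor variants:", bd["variants"]["distinct_variants"])
print("somatic mutations:", bd["somatic"]["distinct_mutations"])
print("somatic-positive tumors: %(count)d/%(denominator)d (%(pct).1f%%)"
      % bd["patients"]["somatic_positive"])
print("heteroplasmic somatic:  %(count)d/%(denominator)d (%(pct).1f%%)"
      % bd["somatic"]["heteroplasmic"])

res = shift_analysis(cohort, VariantKey(663, "A", "G"))
print(f"A663G: {res.n_pairs} carriers, median delta {res.deltas.median():+.3f}, "
      f"U={res.u_statistic:.0f}, p={res.p_value:.3g}")

strata = stratify(cohort, BurdenStrata("any_vs_none"))
stat, p = logrank(strata)
print(f"log-rank (positive vs negative burden): chi2={stat:.2f}, p={p:.2f}")
```

prints

```
distinct tumor variants: 534
somatic mutations: 190
somatic-positive tumors: 67/92 (72.8%)
heteroplasmic somatic:  149/190 (78.4%)
A663G: 41 carriers, median delta -0.002, U=967, p=0.243
log-rank (positive vs negative burden): chi2=0.00, p=0.98
```

534 distinct variants were detected across the 92 simulated tumors, 190
of them somatic (blood-absent); 67 of 92 tumors carry at least one
somatic mutation, and 78% of somatic mutations are heteroplasmic. The
haplogroup-A marker A663G is carried homoplasmically by 41 patients, so
its blood–tumor MAF difference is small; the null log-rank result
reflects the generator's default of no planted survival effect.

The same steps are available from a shell:

```sh
mitopair simulate --seed 42 --out-dir cohort/
mitopair classify --pairs cohort/pairs.tsv --out cohort/classified.tsv
mitopair summarize --pairs cohort/pairs.tsv --metadata cohort/metadata.tsv --by class
mitopair survival  --pairs cohort/pairs.tsv --metadata cohort/metadata.tsv --strata any
mitopair haplogroup --pairs cohort/pairs.tsv
```

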
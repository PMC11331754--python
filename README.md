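# oran — tumor antigen discovery and antigen-landscape analytics

`oran` is a library and CLI for predicting candidate **tumor rejection
antigens** from bulk tumor sequencing data, aimed at immunogenomics of
low-mutation-burden tumors such as medulloblastoma, where unmutated
tumor-associated antigens matter as much as classical neoantigens. It
predicts, for both MHC class I and class II:

- **neoantigens** — somatic SNVs/indels translated into mutant proteins,
  with mutation-spanning 8–12mer (class I) and 15mer (class II) windows;
- **fusion junction antigens** — chimeric proteins assembled from fusion
  calls, with junction-spanning and frameshift-tail peptides;
- **tumor-associated antigens (TAAs)** — genes whose tumor expression is
  an outlier against a normal-tissue panel, classified as cancer–testis
  (CTA), oncofetal, or other.

A candidate peptide–HLA pair becomes an epitope when predicted binding
IC50 < 500 nM (class I) / < 1000 nM (class II), the supporting expression
exceeds 1 TPM, and (for mutations) the RNA variant allele fraction
exceeds 0.6 — all strict inequalities — and the peptide survives an exact
substring screen against the reference proteome. A mutation, fusion or
gene harbouring any number of passing epitopes is a **single antigen**.
TAA candidate genes (TAGs) are genes with normal-panel μ+2σ expression
below 1 TPM in all of 29 organs (testis and fetal cerebellum held out for
classification) whose tumor gene TPM and top-isoform TPM both exceed 1.

Cohort analytics cover per-patient antigen burdens, targetable-patient
fractions (≥1/≥2/≥3 antigens per subgroup), recurring antigens (≥2
patients within a subgroup), shared antigens (≥2 patients cohort-wide,
upset-style), Kruskal–Wallis + pairwise rank-sum subgroup comparisons
with Bonferroni-coded significance, antigen-load vs survival correlation,
and concordance with mass-spectrometry peptides.

Binding prediction is pluggable: a file-based adapter consumes affinity
tables precomputed by an external predictor (NetMHCpan-style), and a
deterministic hash surrogate makes every stage runnable hermetically. A
synthetic-cohort generator with planted ground truth (`oran simulate`)
emulates all inputs — genome, transcript models, proteome, normal panel,
VCFs, fusion calls, expression, HLA genotypes, MS peptides — so the whole
pipeline is testable without controlled-access data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from oran import (SimParams, generate_cohort, inputs_from_cohort,
                  run_pipeline, burden_table, targetable_fraction_table)

cohort = generate_cohort(SimParams(rng_seed=42))       # 24 patients, 200 genes
result = run_pipeline(inputs_from_cohort(cohort))      # surrogate predictor

print(f"{len(result.calls)} antigen calls from {len(result.epitopes)} passing epitopes")
burden = burden_table(result.calls, cohort.patients)
print(targetable_fraction_table(burden, mhc_class="I", categories=("SNV", "indel")).round(1))
```

prints

```
482 antigen calls from 118529 passing epitopes
           1+     2+     3+
WNT     100.0  100.0  100.0
SHH     100.0  100.0  100.0
Group3  100.0  100.0  100.0
Group4  100.0  100.0  100.0
```

i.e. 482 per-patient antigen calls (each a mutation, fusion or gene with
≥1 passing epitope, counted once per MHC class), and every synthetic
patient in every molecular subgroup carries at least three targetable
MHC-I neoantigens under the permissive hash surrogate — with a real
predictor these fractions reflect actual binding biology. The same run
recovers every planted tumor-associated gene:
`[t for t in result.tag_records if t.qualifies]` matches
`cohort.truth.tags` exactly, and `result.taa_categories` labels the
planted testis-restricted genes as `CTA`.

The same flow from the shell:

```bash
oran simulate --out sim --seed 42
oran run --input-dir sim --out calls            # or: neoantigen / fusion / taa
oran landscape --calls calls/antigens.tsv --manifest sim/manifest.tsv \
     --epitopes calls/epitopes.tsv --ms sim/ms_peptides.tsv --out landscape
```

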
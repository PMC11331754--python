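# Methods

`oran` predicts candidate tumor rejection antigens from bulk tumor
sequencing data and summarises the antigen landscape of a cohort. Three
antigen classes are handled, all for both MHC class I (CD8⁺ epitopes) and
class II (CD4⁺ epitopes):

1. **Neoantigens** — somatic SNVs and small indels translated into mutant
   proteins; candidate epitopes are the mutation-spanning peptide windows.
2. **Fusion junction antigens** — chimeric proteins assembled from fusion
   calls; candidate epitopes span the junction or the frameshifted novel
   tail.
3. **Tumor-associated antigens (TAAs)** — unmutated genes whose expression
   is an outlier relative to a normal-tissue panel; every peptide of the
   expressed isoforms is a candidate.

## Antigen units and the filter cascade

The unit of counting is the *source* (a mutation, a fusion event, a gene),
not the peptide: a source harbouring many passing peptide–HLA pairs is
still one antigen per MHC class. Candidates pass a conjunction of strict
gates, applied stepwise with per-step drop counts logged:

| gate | class I | class II | applies to |
|---|---|---|---|
| predicted binding IC50 | < 500 nM | < 1000 nM | all |
| supporting expression | > 1 TPM | > 1 TPM | all |
| RNA variant allele fraction | > 0.6 | > 0.6 | SNV/indel only |

Boundary values always fail (IC50 = 500 nM, TPM = 1, VAF = 0.6 are
rejected). Because the cascade is a pure conjunction, the passing set is
invariant to predicate order, and tightening any threshold can only shrink
it — both properties are asserted by tests.

After the cascade, a **novelty filter** screens every surviving peptide
against the reference proteome by exact substring match (case-insensitive,
within each protein record). Mutation- and fusion-derived peptides are
removed on *any* hit — a peptide present in the normal proteome is by
definition not novel. TAA peptides are themselves substrings of their own
gene's proteins, so only hits in a *different* gene disqualify them; this
requires `gene=<symbol>` tags in the proteome FASTA headers.

Peptide lengths: 8–12mers (mutations/fusions, class I), 9–12mers (TAAs,
class I), 15mers (class II, all categories).

## Mutant and fusion protein construction

Transcript models carry CDS segments (0-based half-open, transcription
order, stop codon included) plus the forward-strand genomic sequence of
each segment. A variant is applied on the forward strand — the strand VCF
alleles live on — inside a single segment; the edited segments are
re-spliced in transcript orientation and translated with the standard
genetic code up to the first stop codon. Consequences are classified from
the protein diff (synonymous / missense / in-frame indel / frameshift /
stop-gain / stop-loss). The *altered span* holds every mutant residue that
differs from the reference; for frameshifts and stop-losses it runs to the
mutant protein's end. Two deliberate edge-case choices:

- A stop-gain whose mutant protein is a clean prefix of the reference has
  an empty altered span — no altered residue exists in the mutant — and
  contributes no peptides.
- A clean in-frame deletion (prefix/suffix trimming leaves nothing) marks
  the junction residue as altered, so the deletion breakpoint is still
  presented.
- Stop-loss read-through translates to the end of the modelled CDS;
  transcript models do not carry 3′ UTR sequence.

Fusions are ingested with CDS-coordinate breakpoints (last retained base
of the 5′ partner, first retained base of the 3′ partner; genomic→CDS
mapping is upstream's concern). The fusion is in frame when the right
partner lands back in its native reading frame; a breakpoint inside a
codon makes the junction residue chimeric and novel. Frameshifted right
portions are retranslated in the shifted frame to the first stop. Emitted
fusion peptides must span the junction or overlap novel residues, and any
peptide occurring verbatim in either parent protein is discarded. A stop
codon formed at or before the junction flags the event as truncated with
no novel contribution.

Variants are evaluated against every expressed transcript (TPM > 1 in
that patient) overlapping the position; peptides are deduplicated at the
sequence level but the antigen unit remains the variant. MNVs and
partial-CDS transcripts are excluded (skipped with a logged count) rather
than guessed at. Multi-allelic VCF records are split per ALT.

## TAG discovery (expression outliers)

The normal panel is summarised per gene and organ as μ + 2σ of TPM (σ =
sample standard deviation, n−1 denominator; single-sample organs get σ=0
with a logged caveat). The *normal ceiling* of a gene is the max of μ+2σ
over the 29-organ panel; adult testis and fetal cerebellum are held out of
the ceiling and used only for classification. A gene is a tumor-associated
gene (TAG) in a patient when

    normal ceiling < 1 TPM   AND   gene TPM > 1   AND   top isoform TPM > 1

with gene TPM defined as the sum of its isoform TPMs. Ties disqualify (the
stricter reading of the two published inequalities, so the rule is a single
consistent strict comparison). Genes absent from the panel default to
ceiling 0 but are flagged `unverified_normal` — absence of evidence is
surfaced, not silently trusted. An immunogenic TAG (a TAA) is classified
**CTA** (cancer–testis antigen) when its testis μ+2σ exceeds 1 TPM, else
**oncofetal** when the fetal-cerebellum μ+2σ exceeds 1 TPM, else *other*.
The >1 TPM classification cutoff is an operationalisation of what is
usually done by eye on a clustered heatmap; it is deliberately simple and
symmetric with the expression gate.

## Affinity backends

Binding prediction is pluggable. The **table backend** reads a
`(peptide, allele) → IC50 nM` TSV precomputed by any external predictor
(e.g. NetMHCpan/NetMHCIIpan runs); missing pairs are an error, keeping
silent gaps impossible. The **surrogate backend** is a deterministic,
platform-independent pseudo-affinity used for hermetic testing:

    IC50 = exp(u · ln 50000),   u = first 8 bytes of SHA-256("allele|peptide|salt") / 2⁶⁴

It is log-uniform on (1, 50000] nM, so a fixed, salt-controlled fraction
of peptides falls under any threshold (≈57% under 500 nM), and a
single-residue change re-rolls the value (hash avalanche). It carries no
biochemistry: surrogate results exercise plumbing, filters and analytics,
not binding biology.

## Cohort analytics

- **Burden table**: per patient × (MHC class × category) antigen counts,
  zero-filled; a source passing in both classes counts in both.
- **Targetable fractions**: % of patients per subgroup with ≥1/≥2/≥3
  antigens; rows are monotone non-increasing by construction.
- **Recurrence/sharing**: antigen identity is gene-level (gene symbol;
  unordered gene pair for fusions), MHC classes merged and SNV/indel
  pooled as "mutation", matching oncoprint row semantics. An antigen in
  ≥2 distinct patients of a subgroup is *recurring*; in ≥2 patients
  cohort-wide it is *shared*, with the set of expressing subgroups
  retained for upset-style summaries.
- **Subgroup comparisons**: Kruskal–Wallis across the four molecular
  subgroups plus all pairwise two-sided Wilcoxon rank-sum tests with
  Bonferroni correction over the number of pairs, coded
  ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001. The *unpaired*
  rank-sum test is used deliberately: subgroups are independent groups of
  unequal size, so a signed-rank (paired) test is not applicable.
  All-identical data takes a p=1 path instead of raising.
- **Survival correlation**: per (subgroup, class, category) stratum,
  correlation of per-patient antigen count with OS or PFS days. Spearman
  is the default (robust to survival-time skew); Pearson is available.
  Strata with n < 3, missing endpoints or zero count variance are skipped
  with a logged reason. No grouping or binning is applied.
- **MS concordance**: predicted epitopes count as validated when they are
  exact substrings of a mass-spectrometry peptide of the same patient with
  identification probability > 0.7.

## Synthetic cohort generator

`oran.simulate` emits a complete, internally consistent input bundle with
planted ground truth, so every stage is exercisable without controlled
clinical data. Defaults (the study conditions; all overridable via
`SimParams`):

- **Reference**: 200 genes on 4 contigs, 1–3 exons, both strands, ≤2
  isoforms per gene (the second is a codon-aligned internal excision);
  every CDS starts with ATG, ends with a stop, has no internal stop. The
  proteome FASTA carries every isoform's translation with `gene=` tags.
- **Normal panel**: 29 organs + testis + fetal cerebellum, 3 samples each,
  gene level. Background genes get TPM ≥ 1.2 in every included organ so
  they can never pass the μ+2σ < 1 gate; a 30-gene TAG pool stays under
  μ+2σ < 0.5; 8 of those light up in testis (CTA truth) and 4 in fetal
  cerebellum (oncofetal truth).
- **Cohort**: 24 patients (3 WNT / 7 SHH / 6 Group 3 / 8 Group 4 —
  scaled-down subgroup proportions of a published 170-patient cohort).
  Per patient: 1–5 planted TAGs (top isoform TPM > 2.5, silent isoforms
  elsewhere), Poisson(8) variants (60% missense / 20% synonymous / 20%
  1-nt frameshift; VAF ~ U(0.7, 0.95)) plus one low-VAF missense decoy,
  and 6 cohort-wide fusions alternating in-frame (codon-boundary) and
  frameshift breakpoints. Mutated and fused transcripts are forced above
  1.5 TPM. Planted margins sit ≥2× clear of every strict threshold so
  boundary decisions never flip truth labels. Frameshifts whose shifted
  frame stops immediately (no novel residue) are rejected at planting.
- **MS peptides**: 12-residue windows around planted missense residues at
  probability 0.75–0.99, plus sub-threshold decoys.
- **Determinism**: one seed feeds a `SeedSequence` hierarchy
  (reference / panel / cohort); the same seed yields byte-identical file
  trees, and two pipeline runs on the same cohort produce byte-identical
  reports.

What the generator does *not* emulate: real human gene structure and
isoform complexity, mutational signatures, germline variation, expression
covariance between genes, read-level noise, and real peptide–MHC binding
biology (the surrogate is a hash). Passing tests therefore demonstrate
that the rules, constructions and analytics are implemented exactly — not
that the pipeline's biological predictions are accurate on real tumors;
the latter depends entirely on the external predictor plugged into the
table backend and the quality of upstream calls.

## Numerical and design notes

- Internal coordinates are 0-based half-open; VCF positions convert at
  ingest; GTF (1-based inclusive) converts at ingest.
- RNA-VAF is carried in a configurable INFO key (default `RVAF`) rather
  than recomputed from alignments; VAF values are rounded to 6 decimals on
  read because htslib stores INFO floats in single precision.
- Fusion supporting expression is min(partner gene TPMs) — a fused
  transcript has no TPM of its own; no VAF gate applies to fusions.
- Percentile-rank filtering and proteasomal-cleavage/TAP scoring are out
  of scope; the cascade is affinity/expression/VAF only.
- Report rows are fully sorted (patient, category, gene, peptide, allele)
  so outputs are byte-stable regardless of evaluation order.

## Problem sizes used in the checked examples

The bundled test-suite and acceptance script run the default 24-patient /
200-gene cohort end-to-end (seconds on one CPU), the TAG-rule oracle
comparison on 50 random 200-gene × 29-organ panels with 20 tumors each,
1,000 random window-enumeration cases and 100-peptide novelty screens per
proteome — sizes chosen to make exact, exhaustive comparison with
independent brute-force oracles practical.
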
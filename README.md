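# isoprimer

Isoform-aware qPCR primer design and evaluation for gene-expression and
RNAi-knockdown studies.

Measuring a transcript by quantitative real-time PCR (qPCR) sounds routine
but hides three traps. First, a primer pair meant to report on a *gene* must
sit in sequence shared by **all** of its isoforms, and ideally inside the CDS
(UTR annotations churn far more than coding regions). Second, qPCR is very
sensitive to mispriming, so candidate pairs must be screened against the
*whole* transcriptome, not just their target. Third, when qPCR is used to
score RNAi knockdown, a primer pair whose product overlaps the long dsRNA
reagent will happily amplify the reagent itself and report a phantom rescue.
`isoprimer` packages the full workflow that addresses all three — from genome
FASTA + GFF3 to an annotated primer table, plus the downstream qPCR run
evaluation — for anyone building a primer resource or validating knockdowns
(fly-style long-dsRNA collections are the motivating case, but nothing is
organism-specific).

## What it computes

**Design.** For each gene, the CDS intervals of all isoforms are intersected
at genomic base resolution and projected onto a representative transcript
(longest CDS). If no usable common region exists, isoforms are dropped
greedily one at a time (the report flags these genes and lists excluded
isoforms). Candidate primers are all 18–25-nt windows with nearest-neighbor
melting temperature

    Tm = 1000·ΔH / (ΔS + 0.368·(N−1)·ln[Na⁺] + R·ln(C_T/4)) − 273.15

(unified NN parameter set; 50 mM Na⁺, 250 nM oligo) inside 57–63 °C,
GC 35–65 %, and passing poly-run, self-dimer and hairpin filters. Pairs with
products of 50–250 bp are scored by

    penalty = Σ_primers [ |Tm−60| + 0.5·|len−20| ] + |Tm_F − Tm_R| + 0.01·|product−110|

and the best *k* (default 3) gene-specific, amplicon-diverse pairs are kept.

**Specificity.** Every candidate is hybridized in silico against both strands
of every transcript (exhaustive Hamming scan: ≥80 % identity, ≤1 mismatch in
the 3′-terminal 12 nt, none in the last 3 nt), and virtual PCR assembles all
predicted products ≤1000 bp. A pair is gene-specific iff every product maps
to its target gene; the report also records isoform coverage, whether the
amplicon spans an exon–exon junction, and the smallest spliced-out intron
(junction-spanning amplicons over *small* introns are a known failure mode,
since genomic DNA then amplifies at nearly the same size).

**Reagent overlap.** RNAi reagent catalogs (primer-defined long dsRNAs,
assembled by virtual PCR; explicit-sequence shRNAs) are intersected with each
predicted amplicon per collection; any overlap with a long dsRNA flags the
pair as confounding for knockdown evaluation (19–21-nt shRNAs are too short
to be amplified and never confound).

**qPCR evaluation.** Standard curves (Cq vs log10 input over a 4-fold,
5-point dilution series) yield efficiency E% = (10^(−1/slope) − 1)·100 and
R²; a pair passes QC iff 90 ≤ E% ≤ 120, R² > 0.995, points are evenly spaced
(2 cycles apart at 4-fold dilution), the most dilute point crosses before
cycle 30, the no-template control is ≥5 cycles away, and the melt curve has a
single peak. Knockdown is quantified as 2^(−ΔΔCq) against the mean of
reference genes.

A deterministic synthetic-fixture generator (genomes with known common
regions, reagents with known intervals, Cq tables with known efficiency and
fold changes) makes the whole pipeline testable offline.

## Worked example

```bash
isoprimer simulate --seed 2 --genes 3 --out demo
isoprimer design --fasta demo/genome.fa --gff demo/annotation.gff3 \
                 --reagents demo/reagents.tsv --out demo/primers.tsv
isoprimer qc --dilution demo/dilution.csv --out demo/qc.csv
isoprimer knockdown --cq demo/knockdown.csv --refs ref1,ref2,ref3 --out demo/kd.csv
```

`primers.tsv` (selected columns):

```
 gene_id      pair_id              fwd_seq              rev_seq  fwd_tm  rev_tm  product_length   isoform_label  junction_spanning  min_intron  overlaps_DRSC
GENE0001 PP3588045441 ACTCCGTGGGGCCTTTGACT CAAGAGACCGCGCCGAATGT  59.887 59.9023             105 nonspecific_all                  0         NaN              0
GENE0001  PP420718150 GAACTGCTGCCCGTGCATCT CTTCGGTGCAGTTCGCTGGT  59.828 59.7621             103 nonspecific_all                  0         NaN              1
GENE0001 PP4275190020 AGCTTCAGCCTTGCCCCTCT AGATGCACGGGCAGCAGTTC  59.958 59.8280             155 nonspecific_all                  1       249.0              1
```

Three pairs per gene, melting temperatures ~60 °C, products 50–250 bp.
`isoform_label = nonspecific_all` means the pair amplifies every isoform
(the desirable outcome for gene-level expression); `junction_spanning = 1`
with `min_intron = 249` says the third amplicon crosses an exon–exon junction
whose spliced intron is 249 nt; `overlaps_DRSC = 1` warns that the product
overlaps a long dsRNA reagent from that collection, so this pair should not
be used to score knockdown by that reagent.

`qc.csv` — all three simulated assays pass the acceptance criteria:

```
  target   slope  r_squared  efficiency_pct  spacing  passed
GENE0001 -3.3014   0.999727          100.86    1.998       1
GENE0002 -3.3458   0.999118           99.02    1.996       1
GENE0003 -3.3041   0.999813          100.75    1.988       1
```

`kd.csv` — the simulated 0.4-fold knockdown is recovered:

```
query_gene  rel_expr  knockdown_pct  n_refs
        q1  0.380579          61.94       3
```

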
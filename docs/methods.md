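# Methods

This note documents the models, rules and numerical choices behind
`isoprimer`, in the order the pipeline applies them, together with what the
synthetic fixtures do and do not emulate.

## Transcriptome model

Genome FASTA plus GFF3 (gene → mRNA → exon/CDS) are parsed into gene and
transcript objects. All internal coordinates are 0-based half-open in
ascending genomic order; GFF3's 1-based closed intervals are converted at the
boundary, which keeps every downstream interval computation free of ±1
ambiguity. Transcript coordinates always run 5′→3′ in the mature mRNA:
minus-strand transcripts carry a reverse-complemented spliced sequence, and
the genome↔transcript maps are exact inverses on exonic bases. Each adjacent
exon pair defines a junction annotated with the genomic interval and length
of the spliced-out intron; the genomic interval identifies "the same
junction" across isoforms.

Validation policy: a feature on a chromosome missing from the FASTA is fatal
(the input is broken); a CDS interval outside its transcript's exons skips
that transcript with a warning and flags the gene (annotation glitches should
not kill a batch run). Non-coding transcripts are retained — they count for
the specificity screen — but are never used as design templates, because the
design targets CDS.

## Common regions and isoform relaxation

A genomic base is *common* iff it lies in the CDS of every coding isoform.
The intersection is computed directly in genomic coordinates (no sequence
alignment between isoforms is ever needed) and projected onto a
representative transcript — the isoform with the longest CDS, ties broken by
smallest transcript id. Adjacent common exons merge into contiguous segments
in transcript space; this is also why no separate "junction-region" input
pool is needed for design: a window spanning a common junction is already a
substring of the merged segment, and pairs are simply labelled
`junction_span` when their amplicon contains a junction.

When the common region is shorter than `min_template` (default 60 nt — the
minimum room for a 50-bp product with 18–25-nt primers), isoforms are removed
greedily one per round: the removal that maximizes the remaining common
length wins, ties going to the shortest-CDS and then smallest-id isoform.
The result records the excluded isoforms and an alert flag that propagates
into every report row for the gene, so users see that such primers do not
cover all isoforms. Removing an isoform can only grow the intersection, so
the procedure terminates with a monotone guarantee.

## Thermodynamics

Melting temperatures use the unified nearest-neighbor DNA/DNA set
(SantaLucia 1998): ΔH/ΔS stack summation plus terminal A·T / G·C initiation
terms, entropy salt-corrected by 0.368·(N−1)·ln[Na⁺], and

    Tm = 1000·ΔH / (ΔS_salt + R·ln(C_T/4)) − 273.15

with R = 1.9872 cal mol⁻¹ K⁻¹, C_T the total oligo concentration for a
non-self-complementary duplex with primer in excess. Defaults: 50 mM Na⁺,
250 nM oligo. The implementation is verified in tests against an independent
hand-summation over the published table and against Biopython's `Tm_NN`
configured identically (agreement to <0.01 °C; the residual comes from its
3-digit gas constant). The design enumerator evaluates the same model for
every fixed-length template window in O(n) via prefix sums over dinucleotide
stacks; window Tm equals the Tm of the window's reverse complement (duplex
symmetry), so one table serves both primer orientations.

## Primer hygiene filters

A window is discarded if it contains an ambiguity code; has a mononucleotide
run longer than 4; has GC outside 0.35–0.65; can form an antiparallel
self-dimer with a complementary run of ≥8 bases (detected exactly by asking
whether any 8-mer of the sequence has its reverse complement also present —
a run ≥8 exists iff such an 8-mer pair exists, covering 3′-anchored dimers
as a special case); or can fold into a hairpin with stem ≥6 and loop ≥3
(detected by the analogous 6-mer/reverse-complement test with a ≥3-nt gap).
Both shortcuts are proven equivalent to exhaustive fold-register scans by
property tests.

## Enumeration, scoring, selection

All (forward, reverse) window combinations with a 50–250-bp product are
candidates. The penalty is

    Σ over both primers of |Tm − 60| + 0.5·|len − 20| + 10·[GC outside range]
    + |Tm_F − Tm_R| + 0.01·|product − 110|

(the GC term is always zero under default filters but kept so the score is
complete if a caller relaxes them). Pairing is resolved per forward primer
over end-sorted windows, so cost scales with the number of valid pairs
rather than the square of the window count. Ordering is fully deterministic:
candidates rank by (penalty, amplicon start, forward sequence, reverse
sequence) — determinism was preferred over any attempt to reconstruct an
unspecified legacy ordering.

Selection keeps up to k = 3 gene-specific pairs, greedily requiring each new
amplicon to overlap every accepted amplicon by <50 % of the shorter one; if
diversity cannot fill k, the best remaining specific pairs top up and a
shortfall flag is set. Specificity verdicts are computed lazily in penalty
order with a cap (`max_classified` = 200 candidates per gene): with k = 3
the screen almost never needs more than a dozen verdicts, and the cap bounds
worst-case work on pathological genes; a gene exhausting the cap without a
single specific pair is reported as a design failure.

## Specificity screen and virtual PCR

Hybridization is an exhaustive ungapped (Hamming) scan of both template
strands of every transcript — exact, oracle-verifiable semantics rather than
heuristic seeding; no indels, no thermodynamic off-target energies. A site
qualifies iff overall identity ≥80 %, ≤1 mismatch in the 3′-terminal 12 nt
and 0 in the terminal 3 nt (all three configurable; they concretize the idea
of stringent cross-reactivity filtering — a primer with a compromised 3′ end
does not extend). Internally all transcripts are concatenated with separator
sentinels and mismatch profiles are computed by shifted adds; candidate
positions (rare) then get the 3′-window checks, and sites are cached per
primer. Virtual PCR pairs forward/reverse sites on the same transcript,
forward upstream, product ≤1000 nt — deliberately wider than the design
range, since qPCR chemistry can produce (and suffer from) products the
designer would never choose. A pair is gene-specific iff it has ≥1 product
and every product maps to the target gene. Junction spanning is defined by
amplicon *containment* of a junction (a primer merely abutting the junction
does not discriminate spliced template), and the smallest contained intron
is reported because junction-spanning amplicons over small introns are a
documented failure mode.

## RNAi reagent overlap

Primer-defined long dsRNA reagents are reconstructed by virtual PCR
restricted to their target gene (product on the longest-CDS representative
preferred; multiple loci are kept and flagged, never silently dropped);
explicit sequences are located by exact substring search. Reagents ≤25 nt
are shRNAs. Amplicon overlap is an interval intersection on a shared
transcript, or a genomic base-set intersection when pair and reagent live on
different isoforms. Any overlap ≥1 nt with a long dsRNA marks the pair
confounding for that collection (no threshold is defensible: even a partial
overlap lets the reagent template amplify); shRNAs never confound. The
report carries, per collection, the confounding flag and the maximum overlap
in nt, plus a column for whether a primer itself (not just the product)
intersects a reagent.

## qPCR evaluation

Standard curves regress mean Cq on log10 relative input; with a 4-fold,
5-point series the expected adjacent-point spacing is log2(4) = 2 cycles.
Efficiency is (10^(−1/slope) − 1)·100. The acceptance rule is: efficiency in
90–120 %, R² > 0.995, |spacing − log2(factor)| ≤ 0.5 cycles (the tolerance
encodes "evenly distributed" quantitatively), most-dilute Cq < 30, NTC ≥5
cycles away or undetected, and (when a melt trace is supplied) exactly one
melt peak — a local maximum of −dF/dT (3-point smoothed) above 20 % of the
global maximum.

Knockdown uses 2^(−ΔΔCq): the query Cq is normalized per condition to the
arithmetic mean Cq of the reference genes — the geometric mean of their
quantities, the conventional choice for multi-reference normalization (the
mean type is a package choice, not asserted as anyone else's). 100 %
amplification efficiency is assumed; replicate Cqs are averaged first, and
replicate SD is reported but never gates. Mismatched reference sets between
conditions are a typed error, not a silent intersection.

## Synthetic fixtures

The generator emulates exactly the structures the pipeline must get right,
and nothing else. Genes are built from a master exon chain (4–6 exons of
80–400 nt, introns 50–5000 nt log-uniform, alternating strands); isoforms
drop internal exons one at a time, so the true common region, junctions and
intron sizes are known by construction and recorded as ground truth. Every
gene carries a unique 30-nt barcode inside its first shared exon and the
common CDS is padded to ≥400 nt, guaranteeing ≥3 designable pairs per gene.
Optional paralogs (near-identical copies at configurable divergence, default
5 %) exercise the specificity screen; they may legitimately conserve a
barcode. Reagents are sampled inside known transcript intervals (long
dsRNAs 200–500 bp as primer pairs, 21-nt shRNAs as sequences), collections
assigned round-robin. Cq tables follow
Cq = anchor − log(quantity)/log(1+E) + N(0, σ), with 4-fold 5-point
dilutions and control/treated conditions at known fold changes (defaults:
E = 1.0, σ = 0.1 cycles, fold 0.4, 3 technical replicates — a clean
mid-abundance assay). All sampling comes from one seeded numpy generator;
a given spec is byte-reproducible.

What the fixtures do **not** emulate: realistic codon usage or splice
motifs, expression levels, genomic-DNA contamination, primer-template
mismatch thermodynamics, or inter-plate/batch effects. Passing tests
therefore demonstrate algorithmic correctness (coordinate arithmetic,
intersections, scans, selection, quantification math), not wet-lab success
rates.

## Statistical note on parameter recovery

With σ = 0.1 cycles and 3 replicates, the ΔΔCq estimator for a single
query/3-reference experiment has SD ≈ 0.094 cycles, i.e. ≈6.5 % CV on
relative expression. Recovery is therefore tested on the expression-point
scale: the recovered relative expression must be within 0.05 of truth
(≈1.9σ), and recovered efficiency within 2 percentage points (≈1.6σ). A
±5 % *relative* band on the fold change would be a ~0.75σ criterion — a coin
flip for any seed — and is deliberately not used.

## Problem sizes and determinism

The bundled verification runs use a 5-gene fixture for oracle-equivalence
suites (exhaustive oracles scale quadratically or worse) and a 50-gene
fixture for whole-pipeline constraint checks — large enough for ~150 pairs
and stable summary statistics, small enough to re-run casually. Every stage
is deterministic given the input files and seed: reports are byte-identical
across reruns, batch output equals the concatenation of single-gene runs,
and pair ids are content-derived (CRC32 of gene id and primer sequences) so
they do not depend on which genes were in the batch.

## Known limitations

- Ungapped hybridization only; an indel off-target site is invisible.
- No genomic-DNA (unspliced) off-target products; screening is
  transcriptome-only.
- Single amplification efficiency assumed in ΔΔCq (no per-gene Pfaffl
  correction), matching the reporting convention the pipeline targets.
- Melt-curve analysis expects monotone temperature grids and reasonably
  smooth traces; it is a peak counter, not a full melt model.
- The relaxation search is greedy (one isoform per round), not an optimal
  subset search; with ≤6 isoforms per gene this matches the exhaustive
  single-removal oracle on all fixtures.
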
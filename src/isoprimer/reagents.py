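"""RNAi reagent assembly by virtual PCR and amplicon overlap annotation.

Long dsRNA reagents (the ~200-500 bp amplicon libraries used for fly RNAi)
are distributed as primer pairs; their actual sequence is reconstructed here
by running virtual PCR against the target gene's transcripts.  Short hairpin
(shRNA) reagents (19-21 nt) are given as explicit sequences and located by
exact substring search.  A qPCR primer pair whose predicted product overlaps
a long dsRNA reagent would amplify the reagent itself in knockdown samples,
confounding the measurement — such overlaps are flagged as confounding.
shRNAs are too short to be amplified by qPCR primers and are never
confounding.

Reagent TSV columns: reagent_id, collection, gene_id, fwd_primer,
rev_primer, sequence (primers XOR sequence populated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .design import PrimerPair
from .specificity import VirtualAmplicon, virtual_pcr_seqs
from .transcriptome import TranscriptModel, Transcriptome

logger = logging.getLogger(__name__)

COLLECTIONS = ("DRSC", "NIG", "VDRC-GD", "VDRC-KK", "TRiP-long", "TRiP-shRNA")

SHRNA_MAX_LEN = 25  # reagents at or below this length are treated as shRNA
DSRNA_WARN_RANGE = (100, 800)  # long dsRNA expected ~200-500 bp; warn outside this


@dataclass
class RNAiReagent:
    reagent_id: str
    collection: str
    target_gene_id: str
    fwd_primer: str | None = None
    rev_primer: str | None = None
    sequence: str | None = None
    amplicon: VirtualAmplicon | None = None
    reagent_class: str = "long_dsRNA"  # long_dsRNA | shRNA
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class OverlapAnnotation:
    pair_id: str
    reagent_id: str
    collection: str
    overlap_nt: int
    confounding: bool
    primer_overlap: bool  # does either primer itself intersect the reagent?


def _parse_rows(tsv_path):
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"reagent_id", "collection", "gene_id"}
        if not required <= set(idx):
            raise ValueError(f"reagent TSV missing columns {required - set(idx)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")

            def get(col):
                i = idx.get(col)
                return parts[i] if i is not None and i < len(parts) and parts[i] else None

            fwd, rev, seq = get("fwd_primer"), get("rev_primer"), get("sequence")
            has_primers = fwd is not None and rev is not None
            if has_primers == (seq is not None):  # neither or both definitions
                logger.warning("reagent TSV line %d malformed; skipped", lineno)
                continue
            yield get("reagent_id"), get("collection"), get("gene_id"), fwd, rev, seq


def _representative(transcripts: list[TranscriptModel]) -> TranscriptModel:
    return sorted(transcripts, key=lambda t: (-t.cds_length, t.transcript_id))[0]


def assemble_reagents(tsv_path, transcriptome: Transcriptome,
                      params=None) -> list[RNAiReagent]:
    """Assemble reagent amplicons on their target gene's transcripts.

    Primer-defined reagents go through virtual PCR restricted to the target
    gene (products on the longest-CDS representative preferred); explicit
    sequences are located by exact substring search.  Reagents that cannot be
    located are flagged ``unlocated`` but kept.
    """
    out: list[RNAiReagent] = []
    for rid, coll, gid, fwd, rev, seq in _parse_rows(tsv_path):
        reagent = RNAiReagent(
            reagent_id=rid, collection=coll, target_gene_id=gid,
            fwd_primer=fwd, rev_primer=rev, sequence=seq,
        )
        gene = transcriptome.genes.get(gid)
        if gene is None:
            reagent.flags.append("unknown_gene")
            out.append(reagent)
            continue
        if seq is not None:
            reagent.reagent_class = "shRNA" if len(seq) <= SHRNA_MAX_LEN else "long_dsRNA"
            located = None
            for t in sorted(gene.transcripts,
                            key=lambda t: (-t.cds_length, t.transcript_id)):
                i = t.spliced_seq.find(seq.upper())
                if i >= 0:
                    located = VirtualAmplicon(
                        transcript_id=t.transcript_id, gene_id=gid,
                        start=i, end=i + len(seq), seq=seq.upper(),
                        junctions_contained=tuple(
                            j for j in t.junctions() if i < j.position < i + len(seq)
                        ),
                    )
                    break
            if located is None:
                reagent.flags.append("unlocated")
            reagent.amplicon = located
        else:
            reagent.reagent_class = "long_dsRNA"
            products = virtual_pcr_seqs(
                fwd, rev, transcriptome, max_product_scan=2000,
                params=params, transcripts=gene.transcripts,
            )
            if not products:
                reagent.flags.append("unlocated")
            else:
                rep = _representative(gene.transcripts)
                on_rep = [a for a in products if a.transcript_id == rep.transcript_id]
                chosen = (on_rep or products)[0]
                if len(on_rep or products) > 1:
                    reagent.flags.append("multi_locus")
                reagent.amplicon = chosen
                lo, hi = DSRNA_WARN_RANGE
                if not lo <= chosen.length <= hi:
                    reagent.flags.append("length_warn")
        out.append(reagent)
    return out


def _genomic_bases(transcriptome: Transcriptome, amp: VirtualAmplicon) -> frozenset[int]:
    t = transcriptome.transcripts[amp.transcript_id]
    return t.genomic_positions(amp.start, amp.end)


def annotate_overlap(
    pair: PrimerPair,
    pair_amplicon: VirtualAmplicon,
    reagents: list[RNAiReagent],
    transcriptome: Transcriptome,
) -> list[OverlapAnnotation]:
    """Overlap of one primer pair's predicted product with each reagent.

    Same-transcript amplicons are intersected in transcript coordinates;
    cross-isoform cases are projected to genomic base sets and intersected
    there.  ``confounding`` = any overlap with a long dsRNA reagent.
    """
    out: list[OverlapAnnotation] = []
    for reagent in reagents:
        if reagent.amplicon is None:
            continue
        ra = reagent.amplicon
        if ra.transcript_id == pair_amplicon.transcript_id:
            overlap = min(ra.end, pair_amplicon.end) - max(ra.start, pair_amplicon.start)
            overlap = max(0, overlap)
            fwd_iv = (pair.forward.start, pair.forward.start + pair.forward.length)
            rev_iv = (pair.reverse.start, pair.reverse.start + pair.reverse.length)
            primer_overlap = any(
                min(ra.end, e) - max(ra.start, s) > 0 for s, e in (fwd_iv, rev_iv)
            )
        else:
            rb = _genomic_bases(transcriptome, ra)
            pb = _genomic_bases(transcriptome, pair_amplicon)
            overlap = len(rb & pb)
            t = transcriptome.transcripts[pair_amplicon.transcript_id]
            fwd_b = t.genomic_positions(
                pair.forward.start, pair.forward.start + pair.forward.length
            )
            rev_b = t.genomic_positions(
                pair.reverse.start, pair.reverse.start + pair.reverse.length
            )
            primer_overlap = bool((fwd_b | rev_b) & rb)
        out.append(
            OverlapAnnotation(
                pair_id=pair.pair_id,
                reagent_id=reagent.reagent_id,
                collection=reagent.collection,
                overlap_nt=int(overlap),
                confounding=overlap >= 1 and reagent.reagent_class == "long_dsRNA",
                primer_overlap=primer_overlap,
            )
        )
    return out
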
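"""Common CDS regions and common junctions across the isoforms of a gene.

A qPCR primer pair meant to report on a *gene* (rather than one isoform)
must sit in sequence shared by every isoform.  This module intersects CDS
intervals across isoforms at genomic base resolution, projects the
intersection onto a representative transcript, and — when no usable common
region exists — relaxes the requirement by greedily dropping one isoform at
a time until enough shared template remains.  Genes that needed relaxation
are flagged so reports can alert the user that some isoforms are not covered.
"""

from __future__ import annotations

from dataclasses import dataclass

from .transcriptome import GeneModel, Junction, TranscriptModel, TranscriptomeError


class NoCodingTranscriptError(TranscriptomeError):
    """Raised when a gene has no coding transcript to design against."""


@dataclass
class CommonRegionSet:
    gene_id: str
    representative: str  # transcript_id of the projection target (longest CDS)
    segments: list[tuple[int, int]]  # half-open intervals on the representative
    covered_isoforms: list[str]
    excluded_isoforms: list[str]
    common_junctions: list[Junction]
    relaxed: bool = False

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def to_tsv_row(self) -> str:
        segs = ",".join(f"{s}-{e}" for s, e in self.segments)
        return "\t".join(
            [
                self.gene_id,
                self.representative,
                segs,
                ";".join(self.covered_isoforms),
                ";".join(self.excluded_isoforms),
                "1" if self.relaxed else "0",
            ]
        )


def _representative(isoforms: list[TranscriptModel]) -> TranscriptModel:
    # longest CDS; ties broken by lexicographically smallest transcript_id
    return sorted(isoforms, key=lambda t: (-t.cds_length, t.transcript_id))[0]


def _cds_bases(t: TranscriptModel) -> frozenset[int]:
    out: set[int] = set()
    for s, e in t.cds:
        out.update(range(s, e))
    return frozenset(out)


def _project_segments(rep: TranscriptModel, bases: frozenset[int]) -> list[tuple[int, int]]:
    """Project a genomic base set onto representative-transcript intervals."""
    tpos = sorted(
        p for p in (rep.genome_to_transcript(g) for g in bases) if p is not None
    )
    segments: list[tuple[int, int]] = []
    for p in tpos:
        if segments and p == segments[-1][1]:
            segments[-1] = (segments[-1][0], p + 1)
        else:
            segments.append((p, p + 1))
    return segments


def _common_set(gene_id: str, isoforms: list[TranscriptModel], excluded: list[str],
                relaxed: bool) -> CommonRegionSet:
    rep = _representative(isoforms)
    common = frozenset.intersection(*[_cds_bases(t) for t in isoforms])
    segments = _project_segments(rep, common)
    return CommonRegionSet(
        gene_id=gene_id,
        representative=rep.transcript_id,
        segments=segments,
        covered_isoforms=sorted(t.transcript_id for t in isoforms),
        excluded_isoforms=sorted(excluded),
        common_junctions=_junctions_common_to(rep, isoforms),
        relaxed=relaxed,
    )


def _junctions_common_to(rep: TranscriptModel,
                         isoforms: list[TranscriptModel]) -> list[Junction]:
    keys = [
        {j.genomic_key for j in t.junctions()} for t in isoforms
    ]
    shared = set.intersection(*keys) if keys else set()
    return [j for j in rep.junctions() if j.genomic_key in shared]


def common_cds_segments(gene: GeneModel) -> CommonRegionSet:
    """Genomic-base intersection of CDS across all coding isoforms.

    A genomic base belongs to a segment iff it lies in the CDS of *every*
    coding isoform; segments are reported on the representative transcript
    (longest CDS, ties by transcript_id).
    """
    coding = gene.coding_transcripts
    if not coding:
        raise NoCodingTranscriptError(f"{gene.gene_id}: no coding transcript")
    return _common_set(gene.gene_id, coding, excluded=[], relaxed=False)


def common_junctions(gene: GeneModel) -> list[Junction]:
    """Junctions whose spliced-out genomic intron occurs in every coding isoform,
    reported in representative-transcript coordinates."""
    coding = gene.coding_transcripts
    if not coding:
        raise NoCodingTranscriptError(f"{gene.gene_id}: no coding transcript")
    return _junctions_common_to(_representative(coding), coding)


def relax_isoforms(gene: GeneModel, min_template: int = 60) -> CommonRegionSet:
    """Drop isoforms one at a time until the common region reaches ``min_template``.

    Each round removes the isoform whose removal maximizes the total common
    segment length among the remaining isoforms (ties: shortest CDS, then
    smallest transcript_id).  Stops when the target is reached or only one
    isoform remains.  The result records excluded isoforms and is flagged
    ``relaxed`` when any removal occurred.
    """
    coding = gene.coding_transcripts
    if not coding:
        raise NoCodingTranscriptError(f"{gene.gene_id}: no coding transcript")
    covered = list(coding)
    excluded: list[str] = []
    current = _common_set(gene.gene_id, covered, excluded, relaxed=False)
    while current.total_length < min_template and len(covered) > 1:
        best = None
        for cand in covered:
            remaining = [t for t in covered if t is not cand]
            total = _common_set(gene.gene_id, remaining, [], False).total_length
            key = (-total, cand.cds_length, cand.transcript_id)
            if best is None or key < best[0]:
                best = (key, cand)
        covered = [t for t in covered if t is not best[1]]
        excluded.append(best[1].transcript_id)
        current = _common_set(gene.gene_id, covered, excluded, relaxed=True)
    return current
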
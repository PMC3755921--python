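"""Genome + GFF3 gene models as an in-memory transcriptome.

Parses a genome FASTA and a GFF3 (gene -> mRNA -> exon/CDS hierarchy) into
gene/transcript objects with exact genome<->transcript coordinate arithmetic,
spliced and coding sequences, and exon-exon junction metadata (including the
size of the intron spliced out at each junction, which downstream modules use
to warn about junction-spanning amplicons over small introns).

Coordinate conventions: all internal intervals are 0-based, half-open, in
ascending genomic order.  GFF3 input (1-based, closed) is converted at the
boundary.  Transcript coordinates run 5'->3' in the mature mRNA, so for
minus-strand transcripts position 0 is the genomically *last* exonic base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptomeError(ValueError):
    """Base class for transcriptome construction/validation errors."""


class MissingChromosomeError(TranscriptomeError):
    """A GFF3 feature references a sequence absent from the FASTA."""


@dataclass(frozen=True)
class Junction:
    """An exon-exon junction in a mature transcript.

    ``position`` is the transcript coordinate of the first base *after* the
    junction (so the junction sits between positions ``position - 1`` and
    ``position``).  ``intron_start``/``intron_end`` give the spliced-out
    intron as a genomic half-open interval, which lets junctions from
    different isoforms be compared by genomic identity.
    """

    transcript_id: str
    position: int
    intron_length: int
    intron_start: int
    intron_end: int

    @property
    def genomic_key(self) -> tuple[int, int]:
        return (self.intron_start, self.intron_end)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # ascending genomic order
    cds: tuple[tuple[int, int], ...]  # ascending genomic order, subset of exons
    spliced_seq: str
    cds_seq: str

    # derived, filled in __post_init__
    _order: tuple[tuple[int, int], ...] = field(init=False, repr=False)
    _cum: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TranscriptomeError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for (s, e) in self.exons:
            if e <= s:
                raise TranscriptomeError(f"{self.transcript_id}: empty exon {(s, e)}")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise TranscriptomeError(
                    f"{self.transcript_id}: exons not sorted/disjoint: {(a, b)} vs {(c, d)}"
                )
        for (s, e) in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise TranscriptomeError(
                    f"{self.transcript_id}: CDS {(s, e)} not contained in a single exon"
                )
        if len(self.spliced_seq) != sum(e - s for s, e in self.exons):
            raise TranscriptomeError(
                f"{self.transcript_id}: spliced_seq length != sum of exon lengths"
            )
        order = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        cum = [0]
        for s, e in order:
            cum.append(cum[-1] + (e - s))
        self._order = order
        self._cum = tuple(cum)
        if self.cds and self.cds_seq not in self.spliced_seq:
            raise TranscriptomeError(
                f"{self.transcript_id}: cds_seq is not a contiguous substring of spliced_seq"
            )

    # -- basic properties ---------------------------------------------------

    def __len__(self) -> int:
        return self._cum[-1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def genomic_span(self) -> int:
        return self.exons[-1][1] - self.exons[0][0]

    # -- coordinate arithmetic ----------------------------------------------

    def genome_to_transcript(self, g: int) -> int | None:
        """Transcript position of genomic base ``g``; None if intronic/outside."""
        for i, (s, e) in enumerate(self._order):
            if s <= g < e:
                if self.strand == "+":
                    return self._cum[i] + (g - s)
                return self._cum[i] + (e - 1 - g)
        return None

    def transcript_to_genome(self, t: int) -> int:
        """Genomic position of transcript base ``t`` (0 <= t < len)."""
        if not 0 <= t < len(self):
            raise IndexError(f"{self.transcript_id}: transcript position {t} out of range")
        for i, (s, e) in enumerate(self._order):
            if self._cum[i] <= t < self._cum[i + 1]:
                off = t - self._cum[i]
                return s + off if self.strand == "+" else e - 1 - off
        raise AssertionError("unreachable")

    def genomic_positions(self, tstart: int, tend: int) -> frozenset[int]:
        """Genomic base set covered by transcript interval [tstart, tend)."""
        out: set[int] = set()
        for i, (s, e) in enumerate(self._order):
            lo = max(tstart, self._cum[i])
            hi = min(tend, self._cum[i + 1])
            for t in range(lo, hi):
                off = t - self._cum[i]
                out.add(s + off if self.strand == "+" else e - 1 - off)
        return frozenset(out)

    def junctions(self) -> list[Junction]:
        """One Junction per adjacent exon pair, in transcript order."""
        out = []
        for i in range(len(self._order) - 1):
            a, b = self._order[i], self._order[i + 1]
            if self.strand == "+":
                intron = (a[1], b[0])
            else:
                intron = (b[1], a[0])
            out.append(
                Junction(
                    transcript_id=self.transcript_id,
                    position=self._cum[i + 1],
                    intron_length=intron[1] - intron[0],
                    intron_start=intron[0],
                    intron_end=intron[1],
                )
            )
        return out

    @property
    def cds_tstart(self) -> int:
        """Transcript coordinate of the first CDS base (requires coding)."""
        return self.spliced_seq.index(self.cds_seq)

    @property
    def cds_tend(self) -> int:
        return self.cds_tstart + len(self.cds_seq)


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    secondary_ids: list[str]
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise TranscriptomeError(f"{self.gene_id}: gene with no transcripts")
        for t in self.transcripts:
            if t.strand != self.strand or t.chrom != self.chrom:
                raise TranscriptomeError(
                    f"{self.gene_id}: transcript {t.transcript_id} disagrees on strand/chrom"
                )

    @property
    def coding_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.is_coding]

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class Transcriptome:
    genes: dict[str, GeneModel]

    @property
    def transcripts(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for g in self.genes.values() for t in g.transcripts}

    def gene_of_transcript(self, transcript_id: str) -> GeneModel:
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id == transcript_id:
                    return g
        raise KeyError(transcript_id)

    def __iter__(self):
        return iter(self.genes.values())


def _extract(fasta: Fasta, chrom: str, intervals, strand: str, feature: str) -> str:
    if chrom not in fasta:
        raise MissingChromosomeError(
            f"feature {feature!r} references chromosome {chrom!r} absent from FASTA"
        )
    seq = "".join(str(fasta[chrom][s:e]) for s, e in intervals).upper()
    return revcomp(seq) if strand == "-" else seq


def load_transcriptome(fasta_path, gff3_path, id_map_path=None) -> Transcriptome:
    """Load a genome FASTA plus GFF3 gene models into a Transcriptome.

    Minus-strand transcripts get their spliced sequence reverse-complemented so
    transcript coordinates always run 5'->3'.  Transcripts whose CDS intervals
    fall outside their exons are skipped with a warning and the gene flagged;
    a feature on a chromosome missing from the FASTA is fatal.
    """
    fasta = Fasta(str(fasta_path), as_raw=False, sequence_always_upper=True)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    id_aliases: dict[str, list[str]] = {}
    id_symbols: dict[str, str] = {}
    if id_map_path is not None:
        for primary, alias, symbol in iter_id_map(id_map_path):
            id_aliases.setdefault(primary, []).append(alias)
            id_symbols.setdefault(primary, symbol)

    genes: dict[str, GeneModel] = {}
    for gf in db.features_of_type("gene"):
        gene_id = gf.id
        symbol = gf.attributes.get("Name", [gene_id])[0]
        secondary = list(gf.attributes.get("Alias", []))
        flags: list[str] = []
        transcripts: list[TranscriptModel] = []
        for mf in db.children(gf, featuretype="mRNA", order_by="start"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mf, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(mf, featuretype="CDS")
            )
            bad = [c for c in cds if not any(s <= c[0] and c[1] <= e for s, e in exons)]
            if bad:
                logger.warning(
                    "transcript %s: CDS interval(s) %s outside exons; record skipped",
                    mf.id,
                    bad,
                )
                flags.append(f"cds_outside_exon:{mf.id}")
                continue
            spliced = _extract(fasta, gf.seqid, exons, gf.strand, mf.id)
            cds_seq = _extract(fasta, gf.seqid, cds, gf.strand, mf.id) if cds else ""
            transcripts.append(
                TranscriptModel(
                    transcript_id=mf.id,
                    gene_id=gene_id,
                    chrom=gf.seqid,
                    strand=gf.strand,
                    exons=tuple(exons),
                    cds=tuple(cds),
                    spliced_seq=spliced,
                    cds_seq=cds_seq,
                )
            )
        if not transcripts:
            logger.warning("gene %s: no usable transcripts; gene dropped", gene_id)
            continue
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            symbol=id_symbols.get(gene_id, symbol),
            secondary_ids=sorted(set(secondary) | set(id_aliases.get(gene_id, []))),
            chrom=gf.seqid,
            strand=gf.strand,
            transcripts=transcripts,
            flags=flags,
        )
    return Transcriptome(genes=genes)


def iter_id_map(path):
    """Yield (primary_id, alias, symbol) rows from a 3-column TSV."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            yield parts[0], parts[1], parts[2]
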
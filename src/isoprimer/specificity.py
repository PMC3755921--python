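"""Transcriptome-wide primer hybridization, virtual PCR and pair classification.

A primer is allowed to prime from a site when the duplex is close enough to
perfect: overall identity >= 80%, at most one mismatch in the 3'-terminal
12 nt, and no mismatch in the 3'-terminal 3 nt (all three thresholds
configurable).  Binding is evaluated against both template strands of every
transcript — a forward primer anneals to the antisense strand (its sequence
matches the sense transcript), a reverse primer anneals to the sense strand
(its reverse complement matches the transcript).  The scan is an exhaustive
ungapped (Hamming) scan, vectorized over all window positions.

Virtual PCR pairs forward and reverse sites on the same transcript with the
forward site upstream and the product no longer than ``max_product_scan``
(default 1000 nt — products a qPCR run could plausibly produce, deliberately
wider than the design range).  Classification then asks: does every predicted
amplicon map to the target gene (gene specificity)?  which isoforms are
amplified?  does any target amplicon span an exon-exon junction, and if so
how small is the smallest spliced-out intron?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import PrimerPair
from .transcriptome import Junction, GeneModel, TranscriptModel, Transcriptome, revcomp
from . import thermo


@dataclass(frozen=True)
class BindingSite:
    transcript_id: str
    strand_of_template: str  # sense | antisense
    start: int  # transcript interval of the site, half-open
    end: int
    mismatches_total: int
    mismatches_3prime: int  # mismatches in the primer's 3'-terminal 5 nt


@dataclass(frozen=True)
class VirtualAmplicon:
    transcript_id: str
    gene_id: str
    start: int
    end: int
    seq: str
    junctions_contained: tuple[Junction, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpecificityVerdict:
    gene_specific: bool
    isoform_coverage: frozenset[str]
    isoform_label: str  # nonspecific_all | specific_subset
    junction_spanning: bool
    min_intron: int | None
    amplicons: tuple[VirtualAmplicon, ...]


_GAP = 40  # separator longer than any primer, so windows never span transcripts


def _concat_cache(transcriptome: Transcriptome,
                  transcripts: list[TranscriptModel] | None = None):
    """Concatenated uint8 transcript array with 255-separators, plus offsets.

    The full-transcriptome version is cached on the object; restricted scans
    (e.g. reagent assembly on one gene) build a throwaway concatenation.
    """
    if transcripts is not None:
        items = sorted(transcripts, key=lambda t: t.transcript_id)
        return _build_concat([(t.transcript_id, t.spliced_seq) for t in items])
    cached = getattr(transcriptome, "_concat", None)
    if cached is None:
        tmap = transcriptome.transcripts
        cached = _build_concat(
            [(tid, tmap[tid].spliced_seq) for tid in sorted(tmap)]
        )
        transcriptome._concat = cached
    return cached


def _build_concat(items: list[tuple[str, str]]):
    gap = np.full(_GAP, 255, dtype=np.uint8)
    parts, tids, starts, ends = [], [], [], []
    pos = 0
    for tid, seq in items:
        arr = thermo.encode(seq)
        tids.append(tid)
        starts.append(pos)
        parts.append(arr)
        pos += len(arr)
        ends.append(pos)
        parts.append(gap)
        pos += _GAP
    big = np.concatenate(parts) if parts else np.empty(0, np.uint8)
    return big, tids, np.asarray(starts), np.asarray(ends)


def _mismatch_profile(big: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Hamming distance of ``probe`` against every window of ``big``."""
    L = len(probe)
    m = len(big) - L + 1
    if m <= 0:
        return np.empty(0, np.uint16)
    acc = np.zeros(m, dtype=np.uint16)
    for k in range(L):
        acc += big[k : k + m] != probe[k]
    return acc


def _scan_concat(big, probe, three_prime_left, max_total, max_mm_3p12, max_mm_3p3):
    """Qualifying (position, total_mm, mm_last5) hits of probe on the big array.

    ``three_prime_left`` says whether the probe's 3' end corresponds to the
    left end of the template window (true for sense-strand binding, where the
    reverse complement of the primer is being matched).
    """
    L = len(probe)
    w12 = min(12, L)
    acc = _mismatch_profile(big, probe)
    out = []
    for pos in np.nonzero(acc <= max_total)[0]:
        mm = big[pos : pos + L] != probe
        if three_prime_left:
            if mm[:w12].sum() > max_mm_3p12 or mm[:3].sum() > max_mm_3p3:
                continue
            m5 = int(mm[:5].sum())
        else:
            if mm[L - w12 :].sum() > max_mm_3p12 or mm[L - 3 :].sum() > max_mm_3p3:
                continue
            m5 = int(mm[L - 5 :].sum())
        out.append((int(pos), int(acc[pos]), m5))
    return out


def find_binding_sites(
    primer_seq: str,
    transcriptome: Transcriptome,
    params=None,
    transcripts: list[TranscriptModel] | None = None,
) -> list[BindingSite]:
    """All qualifying hybridization sites of one primer across the transcriptome.

    ``params`` supplies identity_min / max_mm_3p12 / max_mm_3p3 (DesignParams
    defaults apply when omitted).  ``transcripts`` restricts the scan (used
    when assembling reagents on their target gene only).
    """
    from .design import DesignParams

    params = params or DesignParams()
    primer_seq = primer_seq.upper()
    L = len(primer_seq)
    if L < 12:
        raise ValueError(f"primer too short to scan ({L} nt)")
    rules_key = (params.identity_min, params.max_mm_3p12, params.max_mm_3p3)
    if transcripts is None:
        cache = getattr(transcriptome, "_site_cache", None)
        if cache is None:
            cache = transcriptome._site_cache = {}
        key = (primer_seq, rules_key)
        if key in cache:
            return cache[key]
    max_total = int((1.0 - params.identity_min) * L + 1e-9)
    big, tids, starts, ends = _concat_cache(transcriptome, transcripts)
    p = thermo.encode(primer_seq)
    p_rc = thermo.encode(revcomp(primer_seq))
    sites: list[BindingSite] = []
    scans = (
        # primer matches the sense transcript -> anneals to the antisense strand
        ("antisense", p, False),
        # reverse complement matches the transcript -> anneals to the sense strand
        ("sense", p_rc, True),
    )
    for strand, probe, three_prime_left in scans:
        for pos, tot, m5 in _scan_concat(
            big, probe, three_prime_left, max_total,
            params.max_mm_3p12, params.max_mm_3p3,
        ):
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i < 0 or pos + L > ends[i]:
                continue  # window runs into the inter-transcript separator
            local = pos - int(starts[i])
            sites.append(
                BindingSite(tids[i], strand, local, local + L, tot, m5)
            )
    sites.sort(key=lambda s: (s.transcript_id, s.strand_of_template, s.start))
    if transcripts is None:
        cache[key] = sites
    return sites


def virtual_pcr(
    pair: PrimerPair,
    transcriptome: Transcriptome,
    max_product_scan: int = 1000,
    params=None,
    transcripts: list[TranscriptModel] | None = None,
) -> list[VirtualAmplicon]:
    """Predict all PCR products of a primer pair on the transcript database."""
    return virtual_pcr_seqs(
        pair.forward.seq, pair.reverse.seq, transcriptome,
        max_product_scan=max_product_scan, params=params, transcripts=transcripts,
    )


def virtual_pcr_seqs(
    fwd_seq: str,
    rev_seq: str,
    transcriptome: Transcriptome,
    max_product_scan: int = 1000,
    params=None,
    transcripts: list[TranscriptModel] | None = None,
) -> list[VirtualAmplicon]:
    fwd_sites = [
        s for s in find_binding_sites(fwd_seq, transcriptome, params, transcripts)
        if s.strand_of_template == "antisense"
    ]
    rev_sites = [
        s for s in find_binding_sites(rev_seq, transcriptome, params, transcripts)
        if s.strand_of_template == "sense"
    ]
    tmap = (
        transcriptome.transcripts
        if transcripts is None
        else {t.transcript_id: t for t in transcripts}
    )
    amplicons: list[VirtualAmplicon] = []
    for fs in fwd_sites:
        for rs in rev_sites:
            if fs.transcript_id != rs.transcript_id:
                continue
            if rs.start < fs.start:
                continue  # reverse site upstream of forward site: no product
            product = rs.end - fs.start
            if not 1 <= product <= max_product_scan:
                continue
            t = tmap[fs.transcript_id]
            contained = tuple(
                j for j in t.junctions() if fs.start < j.position < rs.end
            )
            amplicons.append(
                VirtualAmplicon(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    start=fs.start,
                    end=rs.end,
                    seq=t.spliced_seq[fs.start : rs.end],
                    junctions_contained=contained,
                )
            )
    amplicons.sort(key=lambda a: (a.transcript_id, a.start, a.end))
    return amplicons


def classify_pair(
    pair: PrimerPair,
    gene: GeneModel,
    transcriptome: Transcriptome,
    params=None,
    max_product_scan: int = 1000,
) -> SpecificityVerdict:
    """Gene specificity, isoform coverage and junction spanning of one pair."""
    amplicons = virtual_pcr(pair, transcriptome, max_product_scan, params)
    target = [a for a in amplicons if a.gene_id == gene.gene_id]
    off_target = [a for a in amplicons if a.gene_id != gene.gene_id]
    coverage = frozenset(a.transcript_id for a in target)
    all_isoforms = frozenset(t.transcript_id for t in gene.transcripts)
    label = "nonspecific_all" if coverage == all_isoforms else "specific_subset"
    introns = [
        j.intron_length for a in target for j in a.junctions_contained
    ]
    return SpecificityVerdict(
        gene_specific=bool(target) and not off_target,
        isoform_coverage=coverage,
        isoform_label=label,
        junction_spanning=bool(introns),
        min_intron=min(introns) if introns else None,
        amplicons=tuple(amplicons),
    )
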
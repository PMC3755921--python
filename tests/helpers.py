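"""Independent brute-force oracles and hand-built model helpers for tests.

Everything here is deliberately naive (per-base walks, exhaustive scans,
closed forms) and shares no code path with the package implementation.
"""

from __future__ import annotations

from isoprimer.transcriptome import TranscriptModel, GeneModel

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def make_transcript(genome: str, tid: str, exons, cds, strand="+", gene_id="G",
                    chrom="c") -> TranscriptModel:
    spliced = "".join(genome[s:e] for s, e in exons)
    cseq = "".join(genome[s:e] for s, e in cds)
    if strand == "-":
        spliced, cseq = rc(spliced), rc(cseq)
    return TranscriptModel(
        transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=tuple(cds), spliced_seq=spliced, cds_seq=cseq,
    )


def make_gene(gene_id, transcripts, strand="+", chrom="c") -> GeneModel:
    return GeneModel(gene_id=gene_id, symbol=gene_id, secondary_ids=[],
                     chrom=chrom, strand=strand, transcripts=transcripts)


# --- transcriptome oracles --------------------------------------------------


def spliced_seq_oracle(chrom_seq: str, exons, strand: str) -> str:
    """Per-base genome walk, 3'-aware."""
    bases = []
    for s, e in exons:
        for g in range(s, e):
            bases.append(chrom_seq[g])
    seq = "".join(bases)
    return rc(seq) if strand == "-" else seq


def genome_to_transcript_oracle(exons, strand, g):
    order = list(exons) if strand == "+" else list(reversed(exons))
    t = 0
    for s, e in order:
        for off in range(e - s):
            gg = s + off if strand == "+" else e - 1 - off
            if gg == g:
                return t
            t += 1
    return None


# --- common region oracle ---------------------------------------------------


def cds_bases(t: TranscriptModel) -> set[int]:
    out = set()
    for s, e in t.cds:
        out.update(range(s, e))
    return out


def common_bitmap_oracle(isoforms) -> set[int]:
    sets = [cds_bases(t) for t in isoforms]
    return set.intersection(*sets)


# --- thermo oracles ----------------------------------------------------------


def dimer_run_oracle(seq: str, max_run: int) -> bool:
    """Longest antiparallel complementary run between two copies of seq,
    over every alignment register."""
    n = len(seq)
    for total in range(2 * n - 1):
        run = best = 0
        for i in range(n):
            j = total - i
            if 0 <= j < n and seq[i] == COMP[seq[j]]:
                run += 1
                best = max(best, run)
            else:
                run = 0
        if best >= max_run:
            return True
    return False


def hairpin_oracle(seq: str, min_stem: int, min_loop: int) -> bool:
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n):
            s = 0
            while i + s < j - s and seq[i + s] == COMP[seq[j - s]]:
                s += 1
                loop = (j - s) - (i + s) + 1
                if s >= min_stem and loop >= min_loop:
                    return True
    return False


# --- design oracle -----------------------------------------------------------


def enumerate_pairs_oracle(segment: str, params):
    """Exhaustive double loop applying the same predicates via scalar calls."""
    from isoprimer.thermo import melting_temperature, gc_fraction, structural_filters

    windows = []
    for L in range(params.primer_len_min, params.primer_len_max + 1):
        for i in range(len(segment) - L + 1):
            w = segment[i : i + L]
            if "N" in w:
                continue
            tm = melting_temperature(w, params.monovalent_salt, params.oligo_conc)
            gc = gc_fraction(w)
            if not (params.tm_min <= tm <= params.tm_max):
                continue
            if not (params.gc_min <= gc <= params.gc_max):
                continue
            if not structural_filters(w, params):
                continue
            windows.append((i, L, tm, gc))
    pairs = {}
    for fi, fL, ftm, fgc in windows:
        for ri, rL, rtm, rgc in windows:
            product = (ri + rL) - fi
            if not params.product_min <= product <= params.product_max:
                continue
            pen = (
                abs(ftm - params.tm_opt) + 0.5 * abs(fL - params.primer_len_opt)
                + abs(rtm - params.tm_opt) + 0.5 * abs(rL - params.primer_len_opt)
                + abs(ftm - rtm) + 0.01 * abs(product - params.product_opt)
            )
            pairs[(fi, fL, ri, rL)] = pen
    return pairs


# --- specificity oracles -----------------------------------------------------


def hamming_sites_oracle(primer: str, transcripts: dict[str, str], identity_min=0.8,
                         max_mm12=1, max_mm3=0) -> set[tuple[str, str, int]]:
    """All-positions Hamming scan on both template strands."""
    L = len(primer)
    max_total = int((1 - identity_min) * L + 1e-9)
    out = set()

    def mm(a, b):
        return sum(x != y for x, y in zip(a, b))

    for tid, seq in transcripts.items():
        for i in range(len(seq) - L + 1):
            w = seq[i : i + L]
            # primer matches sense transcript (binds antisense template)
            if (mm(primer, w) <= max_total
                    and mm(primer[-12:], w[-12:]) <= max_mm12
                    and mm(primer[-3:], w[-3:]) <= max_mm3):
                out.add((tid, "antisense", i))
            # revcomp matches transcript (primer binds sense template)
            p = rc(primer)
            if (mm(p, w) <= max_total
                    and mm(p[:12], w[:12]) <= max_mm12
                    and mm(p[:3], w[:3]) <= max_mm3):
                out.add((tid, "sense", i))
    return out


def vpcr_oracle(fwd: str, rev: str, transcripts: dict[str, str],
                max_scan=1000, **rules) -> set[tuple[str, int, int]]:
    """Nested-loop pairing of forward/reverse oracle sites."""
    f_sites = [s for s in hamming_sites_oracle(fwd, transcripts, **rules)
               if s[1] == "antisense"]
    r_sites = [s for s in hamming_sites_oracle(rev, transcripts, **rules)
               if s[1] == "sense"]
    out = set()
    for ftid, _, fi in f_sites:
        for rtid, _, ri in r_sites:
            if ftid != rtid or ri < fi:
                continue
            end = ri + len(rev)
            if 1 <= end - fi <= max_scan:
                out.add((ftid, fi, end))
    return out


# --- overlap oracle ----------------------------------------------------------


def genomic_bases_oracle(t: TranscriptModel, tstart: int, tend: int) -> set[int]:
    return {t.transcript_to_genome(p) for p in range(tstart, tend)}


def overlap_bitmap_oracle(t1, iv1, t2, iv2) -> int:
    return len(genomic_bases_oracle(t1, *iv1) & genomic_bases_oracle(t2, *iv2))


# --- qPCR oracles ------------------------------------------------------------


def ols_slope_oracle(x, y):
    """Closed-form normal equations."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def peak_count_oracle(values, threshold) -> int:
    """Strict local maxima above a threshold, by neighbor comparison."""
    count = 0
    for i in range(1, len(values) - 1):
        if values[i] > values[i - 1] and values[i] > values[i + 1] \
                and values[i] > threshold:
            count += 1
    return count
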
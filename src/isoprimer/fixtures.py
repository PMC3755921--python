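"""Deterministic synthetic genomes, annotations, reagent catalogs and qPCR data.

Every other module is testable without downloads: this generator builds a
single-chromosome genome whose gene models are constructed from a master
exon chain per gene, with isoforms derived by dropping internal exons one at
a time.  Because isoform membership of every exon is known, the true common
CDS intervals, junctions and intron sizes are recorded as ground truth at
generation time — the pipeline's outputs can be compared against them
exactly.  Each gene carries a unique 30-nt barcode in its first shared exon,
guaranteeing unique, designable template.  Optional paralogs (near-identical
gene copies at a configurable divergence) exercise the specificity screen.

qPCR data are simulated from the standard exponential-amplification model,
Cq = anchor - log(quantity) / log(1 + E) + Normal(0, sd): four-fold serial
dilutions over five points for standard curves, and control/treated
conditions with known fold changes for knockdown evaluation.

All sampling comes from one seeded numpy Generator, so a given spec yields
byte-identical files on every run and platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reagents import COLLECTIONS
from .transcriptome import revcomp

_BASES = "ACGT"


class InfeasibleFixtureError(ValueError):
    """The fixture spec cannot produce valid gene models."""


@dataclass
class FixtureSpec:
    seed: int = 1
    n_genes: int = 5
    isoforms_per_gene: tuple[int, int] = (1, 4)
    exon_len: tuple[int, int] = (80, 400)
    intron_len: tuple[int, int] = (50, 5000)  # log-uniform
    n_exons: tuple[int, int] = (4, 6)
    paralog_fraction: float = 0.0
    paralog_divergence: float = 0.05
    reagents_per_gene: int = 3
    dsrna_len: tuple[int, int] = (200, 500)
    shrna_len: int = 21
    cq_noise_sd: float = 0.1
    true_efficiency: float = 1.0
    true_fold_changes: dict[str, float] | None = None
    min_common_cds: int = 400
    utr_len: int = 10
    barcode_len: int = 30
    intergenic: tuple[int, int] = (200, 600)
    chrom: str = "chrS"


@dataclass
class _GeneStruct:
    gene_id: str
    symbol: str
    alias: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, ascending
    isoform_exon_idx: list[list[int]]  # per isoform, indices into exons
    transcript_ids: list[str]
    barcode: str
    common_cds: list[tuple[int, int]] = field(default_factory=list)
    transcript_seqs: dict[str, str] = field(default_factory=dict)
    isoform_cds: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def rep_id(self) -> str:
        # the full-exon isoform is always longest; ties impossible by construction
        return self.transcript_ids[0]


@dataclass
class FixtureSet:
    spec: FixtureSpec
    out_dir: Path
    fasta_path: Path
    gff3_path: Path
    id_map_path: Path
    chrom_seq: str
    genes: list[_GeneStruct]
    truth: dict[str, pd.DataFrame]
    reagents_path: Path | None = None


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _trim_cds(exons: list[tuple[int, int]], strand: str, u5: int, u3: int):
    """CDS intervals: exons trimmed by the UTR lengths at the transcript ends."""
    cds = [list(iv) for iv in exons]
    if strand == "+":
        cds[0][0] += u5
        cds[-1][1] -= u3
    else:
        cds[-1][1] -= u5
        cds[0][0] += u3
    return [(s, e) for s, e in cds if e > s]


def _transcript_seq(chrom_seq: str, exons, strand: str) -> str:
    seq = "".join(chrom_seq[s:e] for s, e in exons)
    return revcomp(seq) if strand == "-" else seq


def make_genome(spec: FixtureSpec, out_dir) -> FixtureSet:
    """Generate the genome FASTA, GFF3, ID map and ground-truth tables."""
    lo_e, hi_e = spec.exon_len
    if hi_e < spec.barcode_len + spec.utr_len + 15:
        raise InfeasibleFixtureError(
            f"max exon length {hi_e} too short for a {spec.barcode_len}-nt barcode"
        )
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    parts: list[str] = []
    cursor = 0
    genes: list[_GeneStruct] = []
    barcodes: list[str] = []
    pending_paralogs: list[tuple[_GeneStruct, str]] = []  # (source, locus seq)

    for gi in range(spec.n_genes):
        gap = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
        parts.append(_rand_seq(rng, gap))
        cursor += gap

        n_iso = int(rng.integers(spec.isoforms_per_gene[0], spec.isoforms_per_gene[1] + 1))
        n_ex = max(int(rng.integers(spec.n_exons[0], spec.n_exons[1] + 1)), n_iso + 1)
        exon_lens = [int(rng.integers(lo_e, hi_e + 1)) for _ in range(n_ex)]
        intron_lens = [
            int(round(math.exp(rng.uniform(math.log(spec.intron_len[0]),
                                           math.log(spec.intron_len[1])))))
            for _ in range(n_ex - 1)
        ]
        # droppable internal exons, one per non-reference isoform
        internal = list(range(1, n_ex - 1))
        var_idx = sorted(rng.choice(internal, size=n_iso - 1, replace=False).tolist())
        core_idx = [i for i in range(n_ex) if i not in var_idx]
        core_total = sum(exon_lens[i] for i in core_idx) - 2 * spec.utr_len
        if core_total < spec.min_common_cds:
            exon_lens[0] += spec.min_common_cds - core_total

        locus_len = sum(exon_lens) + sum(intron_lens)
        locus = list(_rand_seq(rng, locus_len))
        # absolute exon intervals
        exons: list[tuple[int, int]] = []
        pos = cursor
        off = 0
        for k, L in enumerate(exon_lens):
            exons.append((pos + off, pos + off + L))
            off += L
            if k < n_ex - 1:
                off += intron_lens[k]
        barcode = _rand_seq(rng, spec.barcode_len)
        b_off = (exons[0][0] - cursor) + spec.utr_len + 5
        locus[b_off : b_off + spec.barcode_len] = list(barcode)
        locus_seq = "".join(locus)
        parts.append(locus_seq)
        cursor += locus_len

        gene_id = f"GENE{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        iso_idx = [list(range(n_ex))]
        for j in range(1, n_iso):
            iso_idx.append([i for i in range(n_ex) if i != var_idx[j - 1]])
        struct = _GeneStruct(
            gene_id=gene_id,
            symbol=f"sym{gi + 1}",
            alias=f"ALT{gi + 1:04d}",
            strand=strand,
            exons=exons,
            isoform_exon_idx=iso_idx,
            transcript_ids=[f"{gene_id}.T{j + 1}" for j in range(n_iso)],
            barcode=barcode,
        )
        # common CDS ground truth: exons in every isoform, UTR-trimmed
        shared = [exons[i] for i in core_idx]
        struct.common_cds = _trim_cds(shared, strand, spec.utr_len, spec.utr_len)
        genes.append(struct)
        barcodes.append(barcode)
        if rng.random() < spec.paralog_fraction:
            pending_paralogs.append((struct, locus_seq))

    for src, locus_seq in pending_paralogs:
        gap = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
        parts.append(_rand_seq(rng, gap))
        cursor += gap
        mutated = list(locus_seq)
        hits = rng.random(len(mutated)) < spec.paralog_divergence
        for i in np.nonzero(hits)[0]:
            choices = [b for b in _BASES if b != mutated[i]]
            mutated[i] = choices[int(rng.integers(0, 3))]
        parts.append("".join(mutated))
        # the source locus starts at its first exon and ends at its last
        gene_id = f"{src.gene_id}P"
        exons = [
            (cursor + (s - _locus_start(src)), cursor + (e - _locus_start(src)))
            for s, e in src.exons
        ]
        struct = _GeneStruct(
            gene_id=gene_id,
            symbol=f"{src.symbol}P",
            alias=f"{src.alias}P",
            strand=src.strand,
            exons=exons,
            isoform_exon_idx=[list(range(len(exons)))],
            transcript_ids=[f"{gene_id}.T1"],
            barcode="",
        )
        struct.common_cds = _trim_cds(exons, src.strand, spec.utr_len, spec.utr_len)
        genes.append(struct)
        cursor += len(mutated)

    chrom_seq = "".join(parts)
    if len(chrom_seq) != cursor:
        raise AssertionError("chromosome bookkeeping error")
    # barcode uniqueness guarantees designability; paralog copies may legally
    # conserve a barcode (they are meant to challenge the specificity screen)
    if not pending_paralogs:
        for bc in barcodes:
            if chrom_seq.count(bc) != 1 or revcomp(bc) in chrom_seq:
                raise InfeasibleFixtureError("barcode collision; change the seed")

    # per-isoform CDS and transcript sequences
    for g in genes:
        for tid, idxs in zip(g.transcript_ids, g.isoform_exon_idx):
            iso_exons = [g.exons[i] for i in idxs]
            g.isoform_cds[tid] = _trim_cds(iso_exons, g.strand, spec.utr_len, spec.utr_len)
            g.transcript_seqs[tid] = _transcript_seq(chrom_seq, iso_exons, g.strand)

    fasta_path = out_dir / "genome.fa"
    gff3_path = out_dir / "annotation.gff3"
    id_map_path = out_dir / "id_map.tsv"
    _write_fasta(fasta_path, spec.chrom, chrom_seq)
    _write_gff3(gff3_path, spec.chrom, genes)
    with open(id_map_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.alias}\t{g.symbol}\n")

    truth = {
        "common_cds": pd.DataFrame(
            [
                {"gene_id": g.gene_id, "start": s, "end": e}
                for g in genes
                for s, e in g.common_cds
            ]
        ),
        "junctions": _junction_truth(genes),
        "genes": pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol,
                    "strand": g.strand,
                    "n_isoforms": len(g.transcript_ids),
                    "barcode": g.barcode,
                    "common_cds_nt": sum(e - s for s, e in g.common_cds),
                }
                for g in genes
            ]
        ),
    }
    return FixtureSet(
        spec=spec,
        out_dir=out_dir,
        fasta_path=fasta_path,
        gff3_path=gff3_path,
        id_map_path=id_map_path,
        chrom_seq=chrom_seq,
        genes=genes,
        truth=truth,
    )


def _locus_start(g: _GeneStruct) -> int:
    return g.exons[0][0]


def _junction_truth(genes: list[_GeneStruct]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for tid, idxs in zip(g.transcript_ids, g.isoform_exon_idx):
            iso = [g.exons[i] for i in idxs]
            order = iso if g.strand == "+" else list(reversed(iso))
            tpos = 0
            for a, b in zip(order, order[1:]):
                tpos += a[1] - a[0]
                intron = (a[1], b[0]) if g.strand == "+" else (b[1], a[0])
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "transcript_id": tid,
                        "position": tpos,
                        "intron_start": intron[0],
                        "intron_end": intron[1],
                        "intron_length": intron[1] - intron[0],
                    }
                )
    return pd.DataFrame(rows)


def _write_fasta(path: Path, chrom: str, seq: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, chrom: str, genes: list[_GeneStruct]) -> None:
    def line(ftype, s, e, strand, attrs):
        return f"{chrom}\t.\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.exons[0][0], g.exons[-1][1]
            fh.write(
                line("gene", gs, ge, g.strand,
                     f"ID={g.gene_id};Name={g.symbol};Alias={g.alias}")
            )
            for tid, idxs in zip(g.transcript_ids, g.isoform_exon_idx):
                iso = [g.exons[i] for i in idxs]
                fh.write(
                    line("mRNA", iso[0][0], iso[-1][1], g.strand,
                         f"ID={tid};Parent={g.gene_id}")
                )
                for s, e in iso:
                    fh.write(line("exon", s, e, g.strand, f"Parent={tid}"))
                for s, e in g.isoform_cds[tid]:
                    fh.write(line("CDS", s, e, g.strand, f"Parent={tid}"))


# ---------------------------------------------------------------------------
# reagents


def make_reagents(spec: FixtureSpec, fixture: FixtureSet,
                  primer_len: int = 20) -> FixtureSet:
    """Sample RNAi reagents per gene with known target intervals.

    Collections rotate round-robin; the shRNA collection gets explicit
    sequences, the long-dsRNA collections get primer pairs whose virtual-PCR
    product is the sampled interval on the representative transcript.
    """
    rng = np.random.default_rng([spec.seed, 101])
    rows = []
    truth_rows = []
    coll_i = 0
    for g in fixture.genes:
        if g.gene_id.endswith("P"):
            continue  # paralogs carry no reagents
        rep = g.rep_id
        seq = g.transcript_seqs[rep]
        for r in range(spec.reagents_per_gene):
            coll = COLLECTIONS[coll_i % len(COLLECTIONS)]
            coll_i += 1
            rid = f"R-{g.gene_id}-{r + 1}"
            if coll == "TRiP-shRNA":
                start = int(rng.integers(0, len(seq) - spec.shrna_len + 1))
                end = start + spec.shrna_len
                rows.append(
                    {"reagent_id": rid, "collection": coll, "gene_id": g.gene_id,
                     "fwd_primer": "", "rev_primer": "",
                     "sequence": seq[start:end]}
                )
                rclass = "shRNA"
            else:
                amp_len = int(rng.integers(spec.dsrna_len[0], spec.dsrna_len[1] + 1))
                amp_len = min(amp_len, len(seq) - 1)
                start = int(rng.integers(0, len(seq) - amp_len + 1))
                end = start + amp_len
                rows.append(
                    {"reagent_id": rid, "collection": coll, "gene_id": g.gene_id,
                     "fwd_primer": seq[start : start + primer_len],
                     "rev_primer": revcomp(seq[end - primer_len : end]),
                     "sequence": ""}
                )
                rclass = "long_dsRNA"
            truth_rows.append(
                {"reagent_id": rid, "gene_id": g.gene_id, "transcript_id": rep,
                 "start": start, "end": end, "collection": coll,
                 "reagent_class": rclass}
            )
    path = fixture.out_dir / "reagents.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    fixture.reagents_path = path
    fixture.truth["reagents"] = pd.DataFrame(truth_rows)
    return fixture


# ---------------------------------------------------------------------------
# qPCR simulation


def _cq(quantity: float, efficiency: float, anchor: float) -> float:
    return anchor - math.log(quantity) / math.log(1.0 + efficiency)


def simulate_dilution(
    spec: FixtureSpec,
    targets: list[str],
    n_points: int = 5,
    dilution_factor: float = 4.0,
    n_reps: int = 3,
    anchor: float = 16.0,
    ntc_offset: float = 12.0,
) -> pd.DataFrame:
    """Serial-dilution Cq table (columns: sample, target, replicate,
    dilution_index, cq) plus an NTC row per target (dilution_index = -1)."""
    rng = np.random.default_rng([spec.seed, 202])
    rows = []
    for target in targets:
        base = anchor + float(rng.uniform(0, 4))
        for i in range(n_points):
            q = dilution_factor ** (-i)
            mu = _cq(q, spec.true_efficiency, base)
            for rep in range(1, n_reps + 1):
                rows.append(
                    {"sample": f"dil{i}", "target": target, "replicate": rep,
                     "dilution_index": i,
                     "cq": mu + float(rng.normal(0, spec.cq_noise_sd))}
                )
        max_mu = _cq(dilution_factor ** (-(n_points - 1)), spec.true_efficiency, base)
        rows.append(
            {"sample": "NTC", "target": target, "replicate": 1,
             "dilution_index": -1, "cq": max_mu + ntc_offset}
        )
    return pd.DataFrame(rows)


def simulate_knockdown(
    spec: FixtureSpec,
    query_genes: list[str] | None = None,
    ref_genes: tuple[str, ...] = ("ref1", "ref2", "ref3"),
    n_reps: int = 3,
    anchor: float = 20.0,
) -> pd.DataFrame:
    """Control/treated Cq table with known fold changes applied to queries."""
    folds = spec.true_fold_changes or {"q1": 0.4}
    if query_genes is not None:
        folds = {g: folds.get(g, 0.4) for g in query_genes}
    rng = np.random.default_rng([spec.seed, 303])
    rows = []
    for condition in ("control", "treated"):
        for gene in list(ref_genes) + sorted(folds):
            fold = 1.0
            if condition == "treated" and gene in folds:
                fold = folds[gene]
            mu = _cq(fold, spec.true_efficiency, anchor)
            for rep in range(1, n_reps + 1):
                rows.append(
                    {"sample": f"{condition}_{rep}", "condition": condition,
                     "target": gene, "replicate": rep,
                     "cq": mu + float(rng.normal(0, spec.cq_noise_sd))}
                )
    return pd.DataFrame(rows)


def simulate_melt(
    spec: FixtureSpec,
    peak_tms: tuple[float, ...] = (82.0,),
    t_min: float = 55.0,
    t_max: float = 95.0,
    step: float = 0.5,
    width: float = 1.2,
    noise_sd: float = 0.002,
):
    """Fluorescence melt trace with one sigmoid transition per peak Tm."""
    rng = np.random.default_rng([spec.seed, 404])
    temps = np.arange(t_min, t_max + step / 2, step)
    f = np.zeros_like(temps)
    for tm in peak_tms:
        f = f + 1.0 / (1.0 + np.exp((temps - tm) / width))
    f = f + 0.05 + rng.normal(0, noise_sd, size=temps.size)
    return temps, f
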
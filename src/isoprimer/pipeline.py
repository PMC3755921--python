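"""End-to-end design orchestration and the annotated primer report.

For each gene: extract common CDS regions (relaxing isoform coverage when
no usable region exists) -> enumerate and rank candidate pairs -> screen
specificity by virtual PCR against the whole transcriptome (lazily, in
penalty order) -> select up to k diverse gene-specific pairs -> annotate
predicted amplicons for overlap with RNAi reagents.  Genes that yield no
pairs are reported in a failures table with a reason code; per-gene failures
never abort a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import common_region, reagents as reagents_mod, specificity
from .design import DesignParams, PrimerPair, iter_ranked_pairs, merge_ranked, \
    select_top_pairs, stable_pair_id
from .reagents import COLLECTIONS, RNAiReagent
from .transcriptome import Transcriptome, load_transcriptome

logger = logging.getLogger(__name__)


class GeneNotFoundError(KeyError):
    pass


class AmbiguousGeneError(KeyError):
    def __init__(self, query: str, candidates: list[str]):
        super().__init__(query)
        self.candidates = candidates
        self.query = query

    def __str__(self) -> str:
        return f"{self.query!r} is ambiguous: {', '.join(self.candidates)}"


@dataclass
class DesignResult:
    records: pd.DataFrame
    failures: pd.DataFrame
    selections: dict[str, list[PrimerPair]] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _gene_reagents(assembled: list[RNAiReagent], gene_id: str) -> list[RNAiReagent]:
    return [r for r in assembled if r.target_gene_id == gene_id]


def design_gene(
    gene,
    transcriptome: Transcriptome,
    params: DesignParams,
    gene_reagents: list[RNAiReagent] | None = None,
):
    """Run the full design for one gene.

    Returns (rows, failure_reason): rows is a list of report dicts (empty on
    failure), failure_reason is None on success.
    """
    if not gene.coding_transcripts:
        return [], "no_cds"
    crs = common_region.common_cds_segments(gene)
    if crs.total_length < params.min_template:
        crs = common_region.relax_isoforms(gene, params.min_template)
    rep = gene.transcript(crs.representative)
    segments = [(s, e) for s, e in crs.segments if e - s >= params.product_min]
    if not segments:
        return [], "template_too_short"

    streams = [
        iter_ranked_pairs(rep.spliced_seq[s:e], params, offset=s) for s, e in segments
    ]
    verdicts: dict[tuple[str, str], specificity.SpecificityVerdict] = {}

    def verdict_of(pair: PrimerPair):
        key = (pair.forward.seq, pair.reverse.seq)
        if key not in verdicts:
            verdicts[key] = specificity.classify_pair(
                pair, gene, transcriptome, params, params.max_product_scan
            )
        return verdicts[key]

    selection = select_top_pairs(
        merge_ranked(streams), params.k, verdict_of, params.max_classified
    )
    if not selection.pairs:
        reason = "no_candidates" if selection.examined == 0 else "no_specific_pairs"
        return [], reason

    rows = []
    for pair in selection.pairs:
        pair.pair_id = stable_pair_id(gene.gene_id, pair)
        v = verdicts[(pair.forward.seq, pair.reverse.seq)]
        pair.design_source = "junction_span" if v.junction_spanning else "common_exon"
        target_amps = [a for a in v.amplicons if a.gene_id == gene.gene_id]
        rep_amp = next(
            (a for a in target_amps if a.transcript_id == rep.transcript_id),
            target_amps[0] if target_amps else None,
        )
        row = {
            "gene_id": gene.gene_id,
            "symbol": gene.symbol,
            "pair_id": pair.pair_id,
            "fwd_seq": pair.forward.seq,
            "rev_seq": pair.reverse.seq,
            "fwd_tm": round(pair.forward.tm, 4),
            "rev_tm": round(pair.reverse.tm, 4),
            "fwd_gc": round(pair.forward.gc, 4),
            "rev_gc": round(pair.reverse.gc, 4),
            "amplicon_start": pair.amplicon_start,
            "product_length": pair.product_length,
            "penalty": round(pair.penalty, 4),
            "design_source": pair.design_source,
            "isoform_label": v.isoform_label,
            "covered_isoforms": ";".join(sorted(v.isoform_coverage)),
            "excluded_isoforms": ";".join(crs.excluded_isoforms),
            "isoform_alert": int(crs.relaxed),
            "junction_spanning": int(v.junction_spanning),
            "min_intron": v.min_intron if v.min_intron is not None else "",
            "shortfall": int(selection.shortfall),
        }
        annos = []
        if gene_reagents and rep_amp is not None:
            annos = reagents_mod.annotate_overlap(
                pair, rep_amp, gene_reagents, transcriptome
            )
        for coll in COLLECTIONS:
            coll_annos = [a for a in annos if a.collection == coll]
            row[f"overlaps_{coll}"] = int(any(a.confounding for a in coll_annos))
            row[f"overlap_nt_{coll}"] = max(
                (a.overlap_nt for a in coll_annos), default=0
            )
        row["primer_overlap_any"] = int(any(a.primer_overlap for a in annos))
        rows.append(row)
    return rows, None


def run_design(
    fasta_path=None,
    gff3_path=None,
    params: DesignParams | None = None,
    reagents_path=None,
    id_map_path=None,
    genes: list[str] | None = None,
    transcriptome: Transcriptome | None = None,
) -> DesignResult:
    """Design and annotate primer pairs for every gene (or a subset).

    Either file paths or a pre-loaded ``transcriptome`` may be given.  Batch
    output is the concatenation of single-gene outputs in gene_id order.
    """
    params = params or DesignParams()
    if transcriptome is None:
        transcriptome = load_transcriptome(fasta_path, gff3_path, id_map_path)
    assembled: list[RNAiReagent] = []
    if reagents_path is not None:
        assembled = reagents_mod.assemble_reagents(reagents_path, transcriptome, params)

    all_rows: list[dict] = []
    failures: list[dict] = []
    gene_ids = sorted(transcriptome.genes) if genes is None else list(genes)
    for gid in gene_ids:
        gene = transcriptome.genes.get(gid)
        if gene is None:
            failures.append({"gene_id": gid, "reason": "unknown_gene"})
            continue
        try:
            rows, reason = design_gene(
                gene, transcriptome, params, _gene_reagents(assembled, gid)
            )
        except common_region.NoCodingTranscriptError:
            rows, reason = [], "no_cds"
        if reason is not None:
            failures.append({"gene_id": gid, "reason": reason})
            logger.info("gene %s: design failed (%s)", gid, reason)
        all_rows.extend(rows)
        logger.info("gene %s: %d pairs", gid, len(rows))

    records = pd.DataFrame(all_rows)
    fail_df = pd.DataFrame(failures, columns=["gene_id", "reason"])
    return DesignResult(records=records, failures=fail_df)


# ---------------------------------------------------------------------------
# gene ID resolution


def load_id_map(path) -> list[tuple[str, str, str]]:
    from .transcriptome import iter_id_map

    return list(iter_id_map(path))


def resolve_gene(query: str, id_map: list[tuple[str, str, str]]) -> str:
    """Map any identifier (primary id, alias, or symbol; case-insensitive)
    to the primary gene id."""
    q = query.lower()
    primaries = {p.lower(): p for p, _, _ in id_map}
    if q in primaries:
        return primaries[q]
    aliases = {a.lower(): p for p, a, _ in id_map}
    if q in aliases:
        return aliases[q]
    by_symbol: dict[str, list[str]] = {}
    for p, _, s in id_map:
        by_symbol.setdefault(s.lower(), []).append(p)
    if q in by_symbol:
        hits = sorted(set(by_symbol[q]))
        if len(hits) > 1:
            raise AmbiguousGeneError(query, hits)
        return hits[0]
    raise GeneNotFoundError(query)
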
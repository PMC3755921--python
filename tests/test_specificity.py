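"""Binding-site scan, virtual PCR and pair classification vs oracles."""

import random

import pytest

from isoprimer.design import DesignParams, Primer, PrimerPair
from isoprimer.specificity import classify_pair, find_binding_sites, virtual_pcr_seqs
from isoprimer.transcriptome import Transcriptome

from helpers import hamming_sites_oracle, make_gene, make_transcript, rc, vpcr_oracle

_rnd = random.Random(13)
GENOME = "".join(_rnd.choice("ACGT") for _ in range(2000))
PARAMS = DesignParams()


def _mini_transcriptome():
    t1 = make_transcript(GENOME, "t1", [(0, 500)], [(10, 490)], gene_id="gA")
    t2 = make_transcript(GENOME, "t2", [(600, 900), (1000, 1200)],
                         [(610, 900), (1000, 1190)], gene_id="gB")
    gA = make_gene("gA", [t1])
    gB = make_gene("gB", [t2])
    return Transcriptome(genes={"gA": gA, "gB": gB}), t1, t2


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[p]]
    return "".join(out)


def _pair(fwd, rev, fstart=0, product=100):
    f = Primer(fwd, "forward", fstart, len(fwd), 60.0, 0.5)
    r = Primer(rev, "reverse", fstart + product - len(rev), len(rev), 60.0, 0.5)
    return PrimerPair(forward=f, reverse=r, product_length=product, penalty=0.0)


class TestBindingSites:
    def test_exact_substring_gives_single_antisense_site(self):
        tr, t1, _ = _mini_transcriptome()
        primer = t1.spliced_seq[40:60]
        sites = find_binding_sites(primer, tr, PARAMS)
        sense = [s for s in sites if s.strand_of_template == "antisense"]
        assert len(sense) == 1
        assert (sense[0].transcript_id, sense[0].start, sense[0].mismatches_total) == (
            "t1", 40, 0,
        )

    def test_two_mismatches_in_last_three_bases_disqualify(self):
        tr, t1, _ = _mini_transcriptome()
        primer = _mutate(t1.spliced_seq[40:60], [18, 19])
        sites = find_binding_sites(primer, tr, PARAMS)
        assert all(not (s.transcript_id == "t1" and s.start == 40) for s in sites)

    def test_internal_mismatches_within_identity_budget_still_bind(self):
        tr, t1, _ = _mini_transcriptome()
        primer = _mutate(t1.spliced_seq[40:60], [2, 5])  # 90% identity, 3' intact
        sites = find_binding_sites(primer, tr, PARAMS)
        hit = [s for s in sites if s.transcript_id == "t1" and s.start == 40]
        assert hit and hit[0].mismatches_total == 2

    @pytest.mark.parametrize("mutations", [(), (3,), (2, 9)])
    def test_scan_matches_exhaustive_hamming_oracle(self, transcriptome, mutations):
        seqs = {tid: t.spliced_seq for tid, t in transcriptome.transcripts.items()}
        any_t = sorted(seqs)[0]
        primer = _mutate(seqs[any_t][100:120], list(mutations))
        got = {
            (s.transcript_id, s.strand_of_template, s.start)
            for s in find_binding_sites(primer, transcriptome, PARAMS)
        }
        assert got == hamming_sites_oracle(primer, seqs)


class TestVirtualPcr:
    def test_product_arithmetic(self):
        tr, t1, _ = _mini_transcriptome()
        fwd = t1.spliced_seq[10:30]
        rev = rc(t1.spliced_seq[90:110])
        amps = virtual_pcr_seqs(fwd, rev, tr)
        assert len(amps) == 1
        amp = amps[0]
        assert (amp.start, amp.end, amp.length) == (10, 110, 100)
        assert amp.seq.startswith(fwd) and amp.seq.endswith(rc(rev))

    def test_reverse_site_upstream_of_forward_gives_no_product(self):
        tr, t1, _ = _mini_transcriptome()
        fwd = t1.spliced_seq[200:220]
        rev = rc(t1.spliced_seq[90:110])
        assert virtual_pcr_seqs(fwd, rev, tr) == []

    def test_matches_nested_loop_pairing_oracle(self, transcriptome):
        seqs = {tid: t.spliced_seq for tid, t in transcriptome.transcripts.items()}
        tid = sorted(seqs)[0]
        fwd = seqs[tid][50:70]
        rev = rc(seqs[tid][200:220])
        got = {
            (a.transcript_id, a.start, a.end)
            for a in virtual_pcr_seqs(fwd, rev, transcriptome)
        }
        assert got == vpcr_oracle(fwd, rev, seqs)

    def test_amplicon_junction_containment(self):
        # two exons split at transcript position 300 with a 100-nt intron
        t = make_transcript(GENOME, "tj", [(600, 900), (1000, 1200)],
                            [(610, 900), (1000, 1190)], gene_id="gB")
        tr = Transcriptome(genes={"gB": make_gene("gB", [t])})
        fwd = t.spliced_seq[280:300]
        rev = rc(t.spliced_seq[320:340])
        (amp,) = virtual_pcr_seqs(fwd, rev, tr)
        assert [j.intron_length for j in amp.junctions_contained] == [100]


class TestClassification:
    def test_pair_on_shared_exon_is_nonspecific_all_isoforms(self):
        a = make_transcript(GENOME, "a", [(0, 300)], [(10, 290)], gene_id="g")
        b = make_transcript(GENOME, "b", [(0, 300), (400, 500)],
                            [(10, 300), (400, 490)], gene_id="g")
        c = make_transcript(GENOME, "c", [(0, 300), (600, 700)],
                            [(10, 300), (600, 690)], gene_id="g")
        gene = make_gene("g", [a, b, c])
        tr = Transcriptome(genes={"g": gene})
        fwd = GENOME[20:40]
        rev = rc(GENOME[120:140])
        v = classify_pair(_pair(fwd, rev, 20, 120), gene, tr, PARAMS)
        assert v.gene_specific
        assert v.isoform_coverage == {"a", "b", "c"}
        assert v.isoform_label == "nonspecific_all"

    def test_single_exon_amplicon_not_junction_spanning(self):
        tr, t1, _ = _mini_transcriptome()
        gene = tr.genes["gA"]
        fwd = t1.spliced_seq[20:40]
        rev = rc(t1.spliced_seq[120:140])
        v = classify_pair(_pair(fwd, rev, 20, 120), gene, tr, PARAMS)
        assert not v.junction_spanning and v.min_intron is None

    def test_junction_spanning_reports_smallest_intron(self):
        # junction at transcript pos 100 with a 60-nt intron
        t = make_transcript(GENOME, "t", [(0, 100), (160, 360)],
                            [(10, 100), (160, 350)], gene_id="g")
        gene = make_gene("g", [t])
        tr = Transcriptome(genes={"g": gene})
        fwd = t.spliced_seq[80:100]
        rev = rc(t.spliced_seq[160:180])
        v = classify_pair(_pair(fwd, rev, 80, 100), gene, tr, PARAMS)
        assert v.junction_spanning and v.min_intron == 60

    def test_conserved_paralog_flags_previously_specific_pair(self, transcriptome):
        # a pair designed on one gene is gene-specific on the clean fixture...
        gid = sorted(transcriptome.genes)[0]
        gene = transcriptome.genes[gid]
        rep = gene.coding_transcripts[0]
        fwd = rep.spliced_seq[30:50]
        rev = rc(rep.spliced_seq[130:150])
        pair = _pair(fwd, rev, 30, 120)
        assert classify_pair(pair, gene, transcriptome, PARAMS).gene_specific
        # ...but injecting a paralog that conserves both primer sites
        # (non-coding copy, retained for the screen) breaks specificity
        dup = make_transcript(
            rep.spliced_seq, "dupT", [(0, len(rep.spliced_seq))], [],
            gene_id="dupG", chrom="c2",
        )
        genes = dict(transcriptome.genes)
        genes["dupG"] = make_gene("dupG", [dup], chrom="c2")
        v = classify_pair(pair, gene, Transcriptome(genes=genes), PARAMS)
        assert not v.gene_specific
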
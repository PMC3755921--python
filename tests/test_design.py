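"""Pair enumeration against the brute-force oracle; ranking and selection."""

import random

import pytest

from isoprimer.design import (
    DesignParams,
    enumerate_pairs,
    iter_ranked_pairs,
    select_top_pairs,
)

from helpers import enumerate_pairs_oracle, rc


def _segment(n, seed=5):
    rnd = random.Random(seed)
    return "".join(rnd.choice("ACGT") for _ in range(n))


SEGMENT = _segment(300)
PARAMS = DesignParams()


def _pair_key(p):
    rstart = p.reverse.start
    return (p.forward.start, p.forward.length, rstart, p.reverse.length)


class TestEnumeration:
    def test_matches_exhaustive_double_loop_oracle(self):
        pairs = enumerate_pairs(SEGMENT, PARAMS)
        oracle = enumerate_pairs_oracle(SEGMENT, PARAMS)
        got = {_pair_key(p): p.penalty for p in pairs}
        assert set(got) == set(oracle)
        for key, pen in got.items():
            assert pen == pytest.approx(oracle[key], abs=1e-9)

    def test_pair_sequences_are_template_substrings(self):
        for p in enumerate_pairs(SEGMENT, PARAMS)[:50]:
            assert p.forward.seq in SEGMENT
            assert rc(p.reverse.seq) in SEGMENT
            amplicon = SEGMENT[p.amplicon_start : p.amplicon_end]
            assert amplicon.startswith(p.forward.seq)
            assert amplicon.endswith(rc(p.reverse.seq))

    def test_segment_shorter_than_min_product_yields_nothing(self):
        assert enumerate_pairs(_segment(40), PARAMS) == []

    def test_enumeration_is_deterministic(self):
        a = enumerate_pairs(SEGMENT, PARAMS)
        b = enumerate_pairs(SEGMENT, PARAMS)
        assert [(p.forward.seq, p.reverse.seq, p.penalty) for p in a] == [
            (p.forward.seq, p.reverse.seq, p.penalty) for p in b
        ]

    def test_all_pairs_satisfy_default_bounds(self):
        for p in enumerate_pairs(SEGMENT, PARAMS):
            assert PARAMS.product_min <= p.product_length <= PARAMS.product_max
            for primer in (p.forward, p.reverse):
                assert PARAMS.tm_min <= primer.tm <= PARAMS.tm_max
                assert PARAMS.gc_min <= primer.gc <= PARAMS.gc_max
                assert PARAMS.primer_len_min <= primer.length <= PARAMS.primer_len_max

    def test_ranked_iterator_yields_exact_penalty_order(self):
        ranked = list(iter_ranked_pairs(SEGMENT, PARAMS))
        expected = sorted(enumerate_pairs(SEGMENT, PARAMS), key=lambda p: p.key)
        assert [p.key for p in ranked] == [p.key for p in expected]

    def test_offset_shifts_transcript_coordinates(self):
        plain = enumerate_pairs(SEGMENT, PARAMS)
        shifted = enumerate_pairs(SEGMENT, PARAMS, offset=1000)
        assert [p.forward.start + 1000 for p in plain] == [
            p.forward.start for p in shifted
        ]


class _AllSpecific:
    gene_specific = True


def _always_specific(pair):
    return _AllSpecific()


class TestSelection:
    def test_single_candidate_returns_with_shortfall(self):
        cands = enumerate_pairs(SEGMENT, PARAMS)[:1]
        res = select_top_pairs(cands, 3, _always_specific)
        assert len(res.pairs) == 1 and res.shortfall

    def test_nonoverlapping_candidates_take_lowest_penalties(self):
        all_pairs = enumerate_pairs(SEGMENT, PARAMS)
        # pick 10 widely distinct-penalty pairs with disjoint amplicons
        chosen, used = [], []
        for p in sorted(all_pairs, key=lambda q: q.penalty):
            if all(
                p.amplicon_end <= u.amplicon_start or p.amplicon_start >= u.amplicon_end
                for u in chosen
            ):
                chosen.append(p)
            if len(chosen) == 3:
                break
        res = select_top_pairs(all_pairs, 3, _always_specific)
        assert len(res.pairs) == 3 and not res.shortfall
        assert res.pairs[0].penalty == min(p.penalty for p in all_pairs)

    def test_selection_invariant_to_candidate_input_order(self):
        cands = enumerate_pairs(SEGMENT, PARAMS)
        shuffled = cands[:]
        random.Random(0).shuffle(shuffled)
        a = select_top_pairs(cands, 3, _always_specific)
        b = select_top_pairs(shuffled, 3, _always_specific)
        assert [(p.forward.seq, p.reverse.seq) for p in a.pairs] == [
            (p.forward.seq, p.reverse.seq) for p in b.pairs
        ]

    def test_greedy_diversity_matches_reference_reimplementation(self):
        cands = sorted(enumerate_pairs(SEGMENT, PARAMS), key=lambda p: p.key)

        def overlap_frac(a, b):
            inter = min(a.amplicon_end, b.amplicon_end) - max(
                a.amplicon_start, b.amplicon_start
            )
            return max(0, inter) / min(a.product_length, b.product_length)

        accepted, reserve = [], []
        for p in cands:
            if len(accepted) == 3:
                break
            if all(overlap_frac(p, q) < 0.5 for q in accepted):
                accepted.append(p)
            else:
                reserve.append(p)
        while len(accepted) < 3 and reserve:
            accepted.append(reserve.pop(0))
        res = select_top_pairs(cands, 3, _always_specific)
        assert [p.key for p in res.pairs] == [p.key for p in accepted]

    def test_nonspecific_candidates_are_skipped(self):
        cands = enumerate_pairs(SEGMENT, PARAMS)

        class V:
            gene_specific = False

        res = select_top_pairs(cands, 3, lambda p: V(), max_classified=50)
        assert res.pairs == [] and res.shortfall and res.examined == 50


class TestParams:
    def test_config_file_round_trip(self, tmp_path):
        cfg = tmp_path / "params.cfg"
        cfg.write_text("k = 5\ntm_opt = 59.5\n# comment\nproduct_max = 200\n")
        p = DesignParams.from_file(cfg)
        assert (p.k, p.tm_opt, p.product_max) == (5, 59.5, 200)
        assert p.primer_len_opt == 20  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "params.cfg"
        cfg.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="bogus"):
            DesignParams.from_file(cfg)
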
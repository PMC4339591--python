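"""Ungapped conserved-block detection against exhaustive enumeration."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import brute_cns_blocks
from cnmskit.conservation import (
    CNSParams,
    conservation_support,
    detect_cns,
    support_for_span,
)
from cnmskit.seq_model import UpInterval, UpstreamSequence


def useq(gene, seq, species=""):
    return UpstreamSequence(gene_id=gene, seq=seq, species=species)


def block_tuples(blocks):
    return [(b.t_start, b.t_end, b.c_start, b.c_end, round(b.identity, 9))
            for b in blocks]


def mutated_copy(seq, rate, rng):
    bases = "ACGT"
    out = [
        bases[(bases.index(ch) + 1 + int(rng.integers(3))) % 4]
        if rng.random() < rate
        else ch
        for ch in seq
    ]
    return "".join(out)


class TestDetectCns:
    def test_identical_sequences_single_full_block(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=40))
        (block,) = detect_cns(useq("t", seq), useq("c", seq))
        assert (block.t_start, block.t_end) == (1, 40)
        assert (block.c_start, block.c_end) == (1, 40)
        assert block.identity == 1.0
        assert block.length == 40

    def test_planted_segment_recovered_exactly(self):
        # Backgrounds drawn from disjoint alphabets share no matching base,
        # so the only conserved signal is the planted 30-mer.
        rng = np.random.default_rng(11)
        tbg = "".join(rng.choice(list("AC"), size=300))
        cbg = "".join(rng.choice(list("GT"), size=300))
        planted = "".join(rng.choice(list("ACGT"), size=30))
        assert not (set(tbg) & set(cbg))
        t = tbg[:100] + planted + tbg[130:]
        c = cbg[:50] + planted + cbg[80:]
        (block,) = detect_cns(useq("t", t), useq("c", c))
        assert (block.t_start, block.t_end, block.c_start, block.c_end) == (
            101, 130, 51, 80,
        )
        assert block.identity == 1.0

    def test_no_shared_seed_kmer_gives_empty(self):
        t = "AC" * 50
        c = "GT" * 50
        assert detect_cns(useq("t", t), useq("c", c)) == []

    def test_n_never_matches(self):
        seq = "N" * 40
        assert detect_cns(useq("t", seq), useq("c", seq)) == []

    def test_identity_recomputes_from_raw_sequences(self, rng):
        params = CNSParams()
        for _ in range(20):
            t = "".join(rng.choice(list("ACGT"), size=200))
            c = mutated_copy(t, 0.15, rng)
            for b in detect_cns(useq("t", t), useq("c", c), params):
                seg_t = t[b.t_start - 1 : b.t_end]
                seg_c = c[b.c_start - 1 : b.c_end]
                assert len(seg_t) == len(seg_c) == b.length
                matches = sum(
                    x == y and x != "N" for x, y in zip(seg_t, seg_c)
                )
                assert matches / b.length == pytest.approx(b.identity)
                assert b.identity >= params.min_identity
                assert b.length >= params.min_len
                # blocks end on matches
                assert seg_t[0] == seg_c[0] and seg_t[-1] == seg_c[-1]


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "params",
        [
            CNSParams(seed_k=5, min_len=10, min_identity=0.70),
            CNSParams(seed_k=8, min_len=12, min_identity=0.75),
        ],
    )
    def test_short_pairs_match_exhaustive_enumeration(self, params):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            n = int(rng.integers(10, 51))
            t = "".join(rng.choice(list("ACGT"), size=n))
            # half the pairs are mutated copies so real blocks exist
            if rng.random() < 0.5:
                c = mutated_copy(t, 0.2, rng)
            else:
                c = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 51))))
            got = block_tuples(detect_cns(useq("t", t), useq("c", c), params))
            expected = [
                (ts, te, cs, ce, round(ident, 9))
                for ts, te, cs, ce, ident in brute_cns_blocks(t, c, params)
            ]
            assert sorted(got) == sorted(expected), (t, c)


class TestParameterEffects:
    def test_raising_min_len_filters_blocks(self, rng):
        loose = CNSParams(seed_k=6, min_len=10, min_identity=0.7)
        strict = CNSParams(seed_k=6, min_len=25, min_identity=0.7)
        for _ in range(20):
            t = "".join(rng.choice(list("ACGT"), size=150))
            c = mutated_copy(t, 0.2, rng)
            loose_set = set(block_tuples(detect_cns(useq("t", t), useq("c", c), loose)))
            strict_set = set(block_tuples(detect_cns(useq("t", t), useq("c", c), strict)))
            assert strict_set <= loose_set

    def test_blocks_respect_identity_threshold(self, rng):
        for min_identity in (0.7, 0.85, 1.0):
            params = CNSParams(seed_k=6, min_len=10, min_identity=min_identity)
            for _ in range(10):
                t = "".join(rng.choice(list("ACGT"), size=150))
                c = mutated_copy(t, 0.15, rng)
                for b in detect_cns(useq("t", t), useq("c", c), params):
                    assert b.identity >= min_identity - 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CNSParams(seed_k=25, min_len=20)
        with pytest.raises(ValueError):
            CNSParams(min_identity=0.4)


class TestConservationSupport:
    def test_containment_required(self):
        from cnmskit.conservation import CNSBlock

        full = CNSBlock("g", "A", "gA", 1, 40, 1, 40, 1.0)
        partial = CNSBlock("g", "A", "gA", 12, 40, 12, 40, 1.0)
        assert support_for_span(10, 25, {"A": [full]}) == ["A"]
        assert support_for_span(10, 25, {"A": [partial]}) == []

    def test_upstream_frame_interval(self):
        from cnmskit.conservation import CNSBlock

        # target length 100; upstream interval 10-25 = string 76-91
        block = CNSBlock("g", "B", "gB", 70, 95, 1, 26, 0.9)
        species = conservation_support(
            UpInterval(10, 25), {"B": [block], "C": []}, target_length=100
        )
        assert species == ["B"]

    def test_sorted_deduplicated(self):
        from cnmskit.conservation import CNSBlock

        b1 = CNSBlock("g", "Z", "g1", 1, 50, 1, 50, 1.0)
        b2 = CNSBlock("g", "Z", "g2", 1, 60, 1, 60, 1.0)
        b3 = CNSBlock("g", "A", "g3", 1, 50, 1, 50, 1.0)
        assert support_for_span(5, 20, {"Z": [b1, b2], "A": [b3]}) == ["A", "Z"]
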
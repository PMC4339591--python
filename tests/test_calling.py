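"""CNMS calling: the three-clause marker predicate, binning, density."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
import scipy.stats

from cnmskit.calling import (
    bin_positions,
    call_cnms,
    marker_density,
    summarize_markers,
)
from cnmskit.conservation import CNSBlock
from cnmskit.seq_model import UpInterval, UpstreamSequence
from cnmskit.ssr import SSRLocus
from cnmskit.tfbs import TFBSHit


@pytest.fixture()
def gene():
    # (GA)12 tract at string positions 101-124 in a 1000-bp window
    rng = np.random.default_rng(3)
    bg = "".join(rng.choice(list("CT"), size=1000))  # no GA-context artefacts
    seq = bg[:100] + "GA" * 12 + bg[124:]
    return UpstreamSequence(gene_id="g1", seq=seq)


def ssr_at(gene_id="g1", start=101, end=124, unit="GA", count=12):
    return SSRLocus(gene_id=gene_id, unit=unit, repeat_count=count,
                    start=start, end=end)


def hit_at(gene_id="g1", start=101, end=116, element="GAGA8HVBKN3"):
    return TFBSHit(element_name=element, gene_id=gene_id, start=start,
                   end=end, strand="+", matched_seq="GA" * 8)


def covering_block(species, comp_gene="c1", lo=80, hi=150):
    return CNSBlock("g1", species, comp_gene, lo, hi, 1, hi - lo + 1, 0.95)


class TestCallCnms:
    def test_full_composite_is_emitted(self, gene):
        markers = call_cnms(
            [ssr_at()],
            [hit_at()],
            {"g1": {"spA": [covering_block("spA")], "spB": [covering_block("spB")]}},
            {"g1": gene},
        )
        (m,) = markers
        assert m.marker_id == "CNMS0001"
        assert m.motif == "(GA)12"
        assert m.element_name == "GAGA8HVBKN3"
        assert m.supporting_species == ("spA", "spB")
        assert (m.comp_start, m.comp_end) == (101, 124)
        # ATG-relative frame: tract occupies 877-900 bp upstream
        assert (m.up_interval.start_up, m.up_interval.end_up) == (877, 900)

    def test_no_conservation_no_marker(self, gene):
        assert call_cnms([ssr_at()], [hit_at()], {"g1": {}}, {"g1": gene}) == []

    def test_partial_block_overlap_is_not_support(self, gene):
        blocks = {"g1": {"spA": [covering_block("spA", lo=110, hi=150)]}}
        assert call_cnms([ssr_at()], [hit_at()], blocks, {"g1": gene}) == []

    def test_no_tfbs_intersection_no_marker(self, gene):
        blocks = {"g1": {"spA": [covering_block("spA")]}}
        far_hit = hit_at(start=300, end=315)
        assert call_cnms([ssr_at()], [far_hit], blocks, {"g1": gene}) == []

    def test_one_marker_per_element_with_hit_count(self, gene):
        hits = [hit_at(start=s, end=s + 15) for s in (101, 103, 105)]
        blocks = {"g1": {"spA": [covering_block("spA")]}}
        (m,) = call_cnms([ssr_at()], hits, blocks, {"g1": gene})
        assert m.n_hits == 3

    def test_two_elements_two_markers(self, gene):
        hits = [hit_at(), hit_at(start=102, end=110, element="CTRMCAMV35S")]
        blocks = {"g1": {"spA": [covering_block("spA")]}}
        markers = call_cnms([ssr_at()], hits, blocks, {"g1": gene})
        assert [m.element_name for m in markers] == ["CTRMCAMV35S", "GAGA8HVBKN3"]
        assert len({(m.gene_id, m.ssr.start, m.ssr.end, m.element_name)
                    for m in markers}) == 2

    def test_ineligible_ssr_classes_excluded(self, gene):
        blocks = {"g1": {"spA": [covering_block("spA")]}}
        mono = ssr_at(start=101, end=120, unit="A", count=20)
        short = ssr_at(start=101, end=110, unit="GA", count=5)
        assert call_cnms([mono, short], [hit_at()], blocks, {"g1": gene}) == []

    def test_unknown_gene_id_rejected(self, gene):
        with pytest.raises(ValueError, match="gX"):
            call_cnms([ssr_at(gene_id="gX")], [], {}, {"g1": gene})

    def test_soundness_predicates_reverify(self, gene):
        hits = [hit_at(start=s, end=s + 15) for s in (101, 105)]
        blocks = {"g1": {"spA": [covering_block("spA")],
                         "spB": [covering_block("spB", lo=99, hi=126)]}}
        for m in call_cnms([ssr_at()], hits, blocks, {"g1": gene}):
            assert any(
                min(m.ssr.end, h.end) - max(m.ssr.start, h.start) + 1 >= 1
                for h in m.hits
            )
            for sp in m.supporting_species:
                assert any(
                    b.t_start <= m.comp_start and m.comp_end <= b.t_end
                    for b in blocks["g1"][sp]
                )


def marker_stub(mid, start_up, end_up):
    return SimpleNamespace(
        marker_id=mid, up_interval=UpInterval(start_up, end_up)
    )


class TestBinPositions:
    def test_midpoint_binning(self):
        markers = [
            marker_stub("m1", 145, 155),  # midpoint 150 -> bin 101-200
            marker_stub("m2", 175, 185),  # midpoint 180 -> bin 101-200
            marker_stub("m3", 945, 955),  # midpoint 950 -> bin 901-1000
        ]
        hist = bin_positions(markers)
        assert hist.total == 3
        assert hist.counts[1] == 2
        assert hist.counts[9] == 1
        assert sum(hist.counts) == hist.total

    def test_empty_set_all_zero(self):
        hist = bin_positions([])
        assert hist.total == 0 and set(hist.counts) == {0}

    def test_marker_outside_window_rejected(self):
        with pytest.raises(ValueError):
            bin_positions([marker_stub("m", 990, 1010)], window=1000)

    def test_uniform_markers_look_uniform(self):
        # sanity: binning uniform positions should not reject uniformity
        for seed in range(5):
            rng = np.random.default_rng(seed)
            markers = []
            for i in range(100):
                mid = int(rng.integers(10, 991))
                markers.append(marker_stub(f"m{i}", mid - 3, mid + 3))
            hist = bin_positions(markers)
            assert hist.total == 100
            _, p = scipy.stats.chisquare(hist.counts)
            assert p > 0.001


class TestMarkerDensity:
    @pytest.mark.parametrize(
        "n,span,expected",
        [
            (10, 1_000_000, 100.0),
            (3, 10_500, 3.5),
            (666, 347_252_400, 521.4),
        ],
    )
    def test_examples(self, n, span, expected):
        assert marker_density(n, span) == expected

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            marker_density(0, 1000)


class TestSummaries:
    def test_per_element_percentages_sum_to_100(self, gene):
        hits = [hit_at(), hit_at(start=102, end=110, element="CTRMCAMV35S")]
        blocks = {"g1": {"spA": [covering_block("spA")]}}
        markers = call_cnms([ssr_at()], hits, blocks, {"g1": gene})
        report = summarize_markers(markers)
        assert sum(report["per_element_pct"].values()) == pytest.approx(100.0, abs=0.1)
        assert report["n_markers"] == len(markers)
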
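"""CNMS calling: combine SSRs, TFBS hits and conservation into markers.

A conserved non-coding microsatellite (CNMS) is an SSR in a gene's 5'
upstream region whose tract intersects a known regulatory-element signal
match, and whose composite (SSR + signal) interval lies inside a
conserved non-coding block shared with at least one orthologous or
paralogous comparator gene. One marker is emitted per (SSR, element)
pair; multiple hits of one element inside a tract collapse into that one
marker (the hit count is kept as metadata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up
from .conservation import CNSBlock, support_for_span
from .seq_model import UpInterval, UpstreamSequence, to_upstream_frame
from .ssr import SSRLocus
from .tfbs import TFBSHit

__all__ = [
    "CallConfig",
    "CNMSMarker",
    "PositionalHistogram",
    "call_cnms",
    "bin_positions",
    "marker_density",
    "summarize_markers",
]


@dataclass(frozen=True)
class CallConfig:
    """Eligibility rules for marker calling. Mononucleotide tracts and
    sub-12-bp tracts are excluded by default; the overlap predicate is a
    minimum intersection (bp) between tract and signal hit."""

    eligible_classes: tuple[str, ...] = ("I", "II")
    exclude_mononucleotide: bool = True
    min_overlap_bp: int = 1


@dataclass(frozen=True)
class CNMSMarker:
    marker_id: str
    gene_id: str
    ssr: SSRLocus
    element_name: str
    signal: str
    n_hits: int
    hits: tuple[TFBSHit, ...]
    supporting_species: tuple[str, ...]
    comp_start: int  # composite interval, string frame
    comp_end: int
    up_interval: UpInterval
    primer_pair: object | None = None
    chromosome: str | None = None
    genomic_pos: int | None = None

    @property
    def ssr_class(self) -> str:
        return self.ssr.ssr_class

    @property
    def motif(self) -> str:
        return f"({self.ssr.unit}){self.ssr.repeat_count}"


@dataclass(frozen=True)
class PositionalHistogram:
    """Marker counts in fixed-width ATG-relative distance bins."""

    bin_width: int
    window: int
    counts: tuple[int, ...]
    total: int

    def bin_label(self, index: int) -> str:
        return f"{index * self.bin_width + 1}-{(index + 1) * self.bin_width}"


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start) + 1


def call_cnms(
    ssrs: Iterable[SSRLocus],
    tfbs_hits: Iterable[TFBSHit],
    cns_support_index: Mapping[str, Mapping[str, Sequence[CNSBlock]]],
    sequences: Mapping[str, UpstreamSequence],
    config: CallConfig | None = None,
) -> list[CNMSMarker]:
    """Emit one marker per (SSR, element) pair with overlapping signal hit
    and non-empty conservation support for the composite interval.

    ``cns_support_index`` maps gene id -> comparator species -> blocks on
    that gene. All inputs must refer to genes present in ``sequences``.
    """
    if config is None:
        config = CallConfig()
    ssr_list = list(ssrs)
    hit_list = list(tfbs_hits)
    for obj in (*ssr_list, *hit_list):
        if obj.gene_id not in sequences:
            raise ValueError(f"input refers to unknown gene id '{obj.gene_id}'")
    hits_by_gene: dict[str, list[TFBSHit]] = {}
    for h in hit_list:
        hits_by_gene.setdefault(h.gene_id, []).append(h)

    raw: list[tuple] = []
    for s in ssr_list:
        if s.ssr_class not in config.eligible_classes:
            continue
        if config.exclude_mononucleotide and s.unit_size == 1:
            continue
        by_element: dict[str, list[TFBSHit]] = {}
        for h in hits_by_gene.get(s.gene_id, []):
            if _overlap(s.start, s.end, h.start, h.end) >= config.min_overlap_bp:
                by_element.setdefault(h.element_name, []).append(h)
        for element, hits in sorted(by_element.items()):
            comp_start = min(s.start, min(h.start for h in hits))
            comp_end = max(s.end, max(h.end for h in hits))
            support = support_for_span(
                comp_start, comp_end, cns_support_index.get(s.gene_id, {})
            )
            if not support:
                continue
            raw.append((s, element, tuple(hits), tuple(support), comp_start, comp_end))

    raw.sort(key=lambda r: (r[0].gene_id, r[4], r[0].start, r[1]))
    markers: list[CNMSMarker] = []
    for serial, (s, element, hits, support, comp_start, comp_end) in enumerate(raw, 1):
        seq = sequences[s.gene_id]
        markers.append(
            CNMSMarker(
                marker_id=f"CNMS{serial:04d}",
                gene_id=s.gene_id,
                ssr=s,
                element_name=element,
                signal=hits[0].matched_seq,
                n_hits=len(hits),
                hits=hits,
                supporting_species=support,
                comp_start=comp_start,
                comp_end=comp_end,
                up_interval=to_upstream_frame(comp_start, comp_end, seq.length),
                chromosome=seq.chromosome,
                genomic_pos=seq.atg_genomic_pos,
            )
        )
    return markers


def bin_positions(
    markers: Sequence[CNMSMarker],
    bin_width: int = 100,
    window: int = 1000,
) -> PositionalHistogram:
    """Bin markers by the midpoint of their composite interval in the
    ATG-relative frame (bin 1 = the ``bin_width`` bp nearest the ATG)."""
    n_bins = -(-window // bin_width)
    counts = [0] * n_bins
    for m in markers:
        if m.up_interval.end_up > window:
            raise ValueError(
                f"{m.marker_id}: composite interval outside the {window} bp window"
            )
        counts[(m.up_interval.midpoint - 1) // bin_width] += 1
    return PositionalHistogram(
        bin_width=bin_width,
        window=window,
        counts=tuple(counts),
        total=len(markers),
    )


def marker_density(n_markers: int, span_bp: int) -> float:
    """Average physical density in kb per marker, to one decimal."""
    if n_markers < 1:
        raise ValueError("marker density undefined for zero markers")
    if span_bp < 1:
        raise ValueError("span must be positive")
    return round_half_up(span_bp / n_markers / 1000, 1)


def summarize_markers(markers: Sequence[CNMSMarker]) -> dict:
    """Per-element counts and percentages plus the class I/II split, the
    figures a discovery run reports."""
    per_element: dict[str, int] = {}
    per_class: dict[str, int] = {}
    for m in markers:
        per_element[m.element_name] = per_element.get(m.element_name, 0) + 1
        per_class[m.ssr_class] = per_class.get(m.ssr_class, 0) + 1
    total = len(markers)
    element_pct = {
        el: round_half_up(100 * n / total, 1) if total else 0.0
        for el, n in sorted(per_element.items())
    }
    return {
        "n_markers": total,
        "per_element": dict(sorted(per_element.items())),
        "per_element_pct": element_pct,
        "per_class": dict(sorted(per_class.items())),
    }
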
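"""End-to-end marker discovery: SSR mining -> signal scanning -> CNS
detection -> CNMS calling -> primer design -> summaries.

``discover`` works on in-memory objects (what the tests and the simulator
use); ``run_discover`` is the file-level wrapper that loads the input
bundle, runs ``discover`` and writes the marker table, GFF3, positional
histogram and a plain-text report. All outputs are deterministic
functions of the inputs: no timestamps, no unordered iteration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .calling import (
    CallConfig,
    CNMSMarker,
    PositionalHistogram,
    bin_positions,
    call_cnms,
    marker_density,
    summarize_markers,
)
from .conservation import CNSBlock, CNSParams, detect_cns
from .primers import PrimerConstraints, design_primers
from .seq_model import (
    LocatedFeature,
    OrthologyTable,
    UpstreamSequence,
    read_orthology_table,
    read_upstream_fasta,
    write_loci_gff3,
)
from .ssr import SSRThresholds, find_ssrs
from .tfbs import RegElement, parse_element_library, scan_elements

logger = logging.getLogger("cnmskit")

__all__ = ["RunConfig", "DiscoverResult", "discover", "run_discover",
           "markers_to_table", "write_histogram_tsv"]


@dataclass
class RunConfig:
    target_fasta: Path
    comparator_fastas: dict[str, Path]  # species -> FASTA path
    orthology_tsv: Path
    elements_tsv: Path
    outdir: Path
    thresholds: SSRThresholds = field(default_factory=SSRThresholds)
    cns_params: CNSParams = field(default_factory=CNSParams)
    call_config: CallConfig = field(default_factory=CallConfig)
    primer_constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    bin_width: int = 100
    window: int = 1000
    genome_span_bp: int | None = None


@dataclass
class DiscoverResult:
    markers: list[CNMSMarker]
    histogram: PositionalHistogram
    report: dict
    n_ssrs: int
    n_hits: int
    n_cns_blocks: int


def _stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("[%s] %d records in -> %d out", name, n_in, n_out)


def discover(
    sequences: Sequence[UpstreamSequence],
    comparators: Mapping[str, Sequence[UpstreamSequence]],
    orthology: OrthologyTable,
    elements: Sequence[RegElement],
    thresholds: SSRThresholds | None = None,
    cns_params: CNSParams | None = None,
    call_config: CallConfig | None = None,
    primer_constraints: PrimerConstraints | None = None,
    bin_width: int = 100,
    window: int | None = None,
    genome_span_bp: int | None = None,
    design: bool = True,
) -> DiscoverResult:
    """Run the full discovery pipeline over loaded inputs."""
    thresholds = thresholds or SSRThresholds()
    cns_params = cns_params or CNSParams()
    call_config = call_config or CallConfig()
    primer_constraints = primer_constraints or PrimerConstraints()
    seq_by_id = {rec.gene_id: rec for rec in sequences}
    comp_by_id = {
        sp: {rec.gene_id: rec for rec in records}
        for sp, records in comparators.items()
    }
    orthology.validate(seq_by_id, {sp: d.keys() for sp, d in comp_by_id.items()})
    window = window or max((rec.length for rec in sequences), default=1000)

    ssrs = []
    for rec in sequences:
        ssrs.extend(find_ssrs(rec.seq, thresholds, gene_id=rec.gene_id))
    _stage("ssr", len(sequences), len(ssrs))

    hits = []
    for rec in sequences:
        hits.extend(scan_elements(rec.seq, elements, gene_id=rec.gene_id))
    _stage("scan", len(sequences), len(hits))

    cns_index: dict[str, dict[str, list[CNSBlock]]] = {}
    n_blocks = 0
    for rec in sequences:
        per_species: dict[str, list[CNSBlock]] = {}
        for species, comp_gene in orthology.comparators(rec.gene_id):
            comp_rec = comp_by_id[species][comp_gene]
            blocks = detect_cns(rec, comp_rec, cns_params)
            n_blocks += len(blocks)
            per_species.setdefault(species, []).extend(blocks)
        cns_index[rec.gene_id] = per_species
    _stage("cns", len(sequences), n_blocks)

    markers = call_cnms(ssrs, hits, cns_index, seq_by_id, call_config)
    _stage("call", len(ssrs), len(markers))

    if design:
        designed: list[CNMSMarker] = []
        for m in markers:
            pair = design_primers(
                seq_by_id[m.gene_id], m.comp_start, m.comp_end, primer_constraints
            )
            designed.append(dataclasses.replace(m, primer_pair=pair))
        markers = designed
        _stage("primers", len(markers), sum(m.primer_pair is not None for m in markers))

    histogram = bin_positions(markers, bin_width=bin_width, window=window)
    report = summarize_markers(markers)
    report["n_genes"] = len(sequences)
    report["n_ssrs"] = len(ssrs)
    report["n_tfbs_hits"] = len(hits)
    report["n_cns_blocks"] = n_blocks
    report["n_primer_pairs"] = sum(
        1 for m in markers if m.primer_pair is not None
    )
    positions = [m.genomic_pos for m in markers if m.genomic_pos is not None]
    span = genome_span_bp
    if span is None and len(positions) >= 2:
        span = max(positions) - min(positions) + 1
    if span is not None and markers:
        report["marker_density_kb"] = marker_density(len(markers), span)
    return DiscoverResult(
        markers=markers,
        histogram=histogram,
        report=report,
        n_ssrs=len(ssrs),
        n_hits=len(hits),
        n_cns_blocks=n_blocks,
    )


def markers_to_table(markers: Sequence[CNMSMarker]) -> list[dict]:
    """Marker rows in the reference-table column layout."""
    rows = []
    for m in markers:
        pair = m.primer_pair
        rows.append(
            {
                "marker_id": m.marker_id,
                "gene_id": m.gene_id,
                "chromosome": m.chromosome or "",
                "genomic_pos": m.genomic_pos if m.genomic_pos is not None else "",
                "motif": m.motif,
                "ssr_class": m.ssr_class,
                "element": m.element_name,
                "signal_match": m.signal,
                "n_signal_hits": m.n_hits,
                "ssr_start": m.ssr.start,
                "ssr_end": m.ssr.end,
                "comp_start": m.comp_start,
                "comp_end": m.comp_end,
                "up_start": m.up_interval.start_up,
                "up_end": m.up_interval.end_up,
                "supporting_species": ",".join(m.supporting_species),
                "fwd_primer": pair.fwd_seq if pair else "",
                "rev_primer": pair.rev_seq if pair else "",
                "product_size": pair.product_size if pair else "",
            }
        )
    return rows


def write_markers_tsv(markers: Sequence[CNMSMarker], path: Path) -> None:
    rows = markers_to_table(markers)
    header = [
        "marker_id", "gene_id", "chromosome", "genomic_pos", "motif",
        "ssr_class", "element", "signal_match", "n_signal_hits", "ssr_start",
        "ssr_end", "comp_start", "comp_end", "up_start", "up_end",
        "supporting_species", "fwd_primer", "rev_primer", "product_size",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[col]) for col in header) + "\n")


def write_histogram_tsv(histogram: PositionalHistogram, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_bp_upstream\tn_markers\n")
        for i, count in enumerate(histogram.counts):
            fh.write(f"{histogram.bin_label(i)}\t{count}\n")
        fh.write(f"total\t{histogram.total}\n")


def _write_report(result: DiscoverResult, path: Path) -> None:
    rep = result.report
    lines = [
        "cnmskit discovery report",
        f"genes analysed:      {rep['n_genes']}",
        f"SSR loci:            {rep['n_ssrs']}",
        f"signal hits:         {rep['n_tfbs_hits']}",
        f"CNS blocks:          {rep['n_cns_blocks']}",
        f"CNMS markers:        {rep['n_markers']}",
        f"primer pairs:        {rep['n_primer_pairs']}",
        "",
        "markers per element (n, %):",
    ]
    for el, n in rep["per_element"].items():
        lines.append(f"  {el:<20s} {n:>4d}  {rep['per_element_pct'][el]:5.1f}")
    lines.append("")
    lines.append("markers per SSR class:")
    for cls, n in rep["per_class"].items():
        lines.append(f"  class {cls:<6s} {n:>4d}")
    if "marker_density_kb" in rep:
        lines.append("")
        lines.append(f"average marker density: {rep['marker_density_kb']} kb")
    path.write_text("\n".join(lines) + "\n")


def run_discover(config: RunConfig) -> DiscoverResult:
    """Load the input bundle, run discovery, write all output files."""
    sequences = read_upstream_fasta(config.target_fasta, species="target")
    comparators = {
        sp: read_upstream_fasta(path, species=sp)
        for sp, path in sorted(config.comparator_fastas.items())
    }
    orthology = read_orthology_table(config.orthology_tsv)
    elements = parse_element_library(config.elements_tsv)
    result = discover(
        sequences,
        comparators,
        orthology,
        elements,
        thresholds=config.thresholds,
        cns_params=config.cns_params,
        call_config=config.call_config,
        primer_constraints=config.primer_constraints,
        bin_width=config.bin_width,
        window=config.window,
        genome_span_bp=config.genome_span_bp,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_markers_tsv(result.markers, outdir / "markers.tsv")
    seq_lengths = {rec.gene_id: rec.length for rec in sequences}
    features = [
        LocatedFeature(
            gene_id=m.gene_id,
            ftype="CNMS_marker",
            start=m.comp_start,
            end=m.comp_end,
            strand="+",
            attributes={"ID": m.marker_id, "motif": m.motif,
                        "element": m.element_name},
        )
        for m in result.markers
    ]
    write_loci_gff3(features, outdir / "markers.gff3", seq_lengths)
    write_histogram_tsv(result.histogram, outdir / "histogram.tsv")
    _write_report(result, outdir / "report.txt")
    return result
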
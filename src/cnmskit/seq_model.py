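"""Core sequence and interval types shared by every pipeline stage.

All stages work on 5' upstream regions of protein-coding genes: the
(default 1000 bp) window immediately 5' of the translation start codon,
stored on the coding-strand orientation so the last base of ``seq`` is the
base adjacent to the A of ATG.

Two coordinate frames are used throughout:

* **string frame** — 1-based inclusive positions on the stored sequence,
  as in GFF3;
* **upstream (ATG-relative) frame** — 1-based distances from the start
  codon, where position 1 is the base immediately 5' of the ATG and
  positions grow moving away from the gene.

``to_upstream_frame`` converts between the two; the transform is its own
inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "UpstreamSequence",
    "UpInterval",
    "LocatedFeature",
    "OrthologyTable",
    "read_upstream_fasta",
    "write_upstream_fasta",
    "to_upstream_frame",
    "to_string_frame",
    "write_loci_gff3",
    "read_loci_gff3",
    "read_orthology_table",
    "write_orthology_table",
]


class FastaFormatError(ValueError):
    """Malformed upstream-FASTA header or sequence."""


@dataclass(frozen=True)
class UpstreamSequence:
    """One gene's 5' upstream region.

    ``seq`` is written 5'->3' on the strand read toward the ATG; its last
    base is immediately adjacent to the A of the start codon.
    ``atg_genomic_pos`` is the 1-based genomic coordinate of that A, when
    known.
    """

    gene_id: str
    seq: str
    species: str = ""
    chromosome: str | None = None
    strand: str | None = None
    atg_genomic_pos: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.seq:
            raise ValueError(f"{self.gene_id}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.gene_id}: illegal sequence characters {sorted(bad)}"
            )
        if self.strand is not None and self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class UpInterval:
    """Closed interval in the ATG-relative upstream frame (1 = closest base)."""

    start_up: int
    end_up: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_up <= self.end_up:
            raise ValueError(f"invalid upstream interval {self.start_up}-{self.end_up}")

    @property
    def midpoint(self) -> int:
        return (self.start_up + self.end_up) // 2


def to_upstream_frame(i: int, j: int, seq_length: int) -> UpInterval:
    """Map string positions ``(i, j)`` (1-based inclusive) to the ATG-relative
    frame. Self-inverse: feeding the result back returns ``(i, j)``."""
    if not 1 <= i <= j <= seq_length:
        raise ValueError(f"string interval {i}-{j} outside 1..{seq_length}")
    return UpInterval(seq_length - j + 1, seq_length - i + 1)


def to_string_frame(interval: UpInterval, seq_length: int) -> tuple[int, int]:
    """Inverse of :func:`to_upstream_frame` (same reflection)."""
    if interval.end_up > seq_length:
        raise ValueError(
            f"upstream interval {interval.start_up}-{interval.end_up} "
            f"outside 1..{seq_length}"
        )
    return seq_length - interval.end_up + 1, seq_length - interval.start_up + 1


# ---------------------------------------------------------------------------
# FASTA I/O.  Header dialect: ">geneID|chrom|strand|atgPos"; fields after
# geneID are optional but positional.
# ---------------------------------------------------------------------------

def _parse_header(title: str, lineno: int) -> tuple[str, str | None, str | None, int | None]:
    fields = title.split()[0].split("|") if title.split() else [""]
    gene_id = fields[0]
    if not gene_id:
        raise FastaFormatError(f"line {lineno}: empty gene id in header '>{title}'")
    chromosome = fields[1] if len(fields) > 1 and fields[1] else None
    strand: str | None = None
    if len(fields) > 2 and fields[2]:
        strand = fields[2].replace("−", "-")  # tolerate typographic minus
        if strand not in "+-":
            raise FastaFormatError(
                f"line {lineno}: bad strand field '{fields[2]}' in header '>{title}'"
            )
    atg_pos: int | None = None
    if len(fields) > 3 and fields[3]:
        try:
            atg_pos = int(fields[3])
        except ValueError:
            raise FastaFormatError(
                f"line {lineno}: bad ATG position '{fields[3]}' in header '>{title}'"
            ) from None
    return gene_id, chromosome, strand, atg_pos


def read_upstream_fasta(path: str | Path, species: str = "") -> list[UpstreamSequence]:
    """Read a multi-FASTA of upstream regions.

    Sequences are uppercased and U is converted to T; characters outside
    A/C/G/T/N and duplicate gene ids are rejected.
    """
    path = Path(path)
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                header_lines.append(lineno)
    records: dict[str, UpstreamSequence] = {}
    with open(path) as fh:
        for idx, (title, raw_seq) in enumerate(SimpleFastaParser(fh)):
            lineno = header_lines[idx]
            gene_id, chromosome, strand, atg_pos = _parse_header(title, lineno)
            if gene_id in records:
                raise FastaFormatError(
                    f"line {lineno}: duplicate gene id '{gene_id}' in {path.name}"
                )
            seq = raw_seq.upper().replace("U", "T")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaFormatError(
                    f"line {lineno}: gene '{gene_id}' has illegal characters "
                    f"{sorted(bad)}"
                )
            records[gene_id] = UpstreamSequence(
                gene_id=gene_id,
                seq=seq,
                species=species,
                chromosome=chromosome,
                strand=strand,
                atg_genomic_pos=atg_pos,
            )
    return list(records.values())


def _format_header(rec: UpstreamSequence) -> str:
    fields = [rec.gene_id]
    for value in (rec.chromosome, rec.strand, rec.atg_genomic_pos):
        if value is None:
            break
        fields.append(str(value))
    return "|".join(fields)


def write_upstream_fasta(records: Iterable[UpstreamSequence], path: str | Path,
                         width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{_format_header(rec)}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 for located features (the seqid is the upstream record's gene id, so
# coordinates are string-frame positions on that record).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocatedFeature:
    """A typed interval on one upstream record, GFF3-serialisable."""

    gene_id: str
    ftype: str
    start: int
    end: int
    strand: str = "."
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid feature interval {self.start}-{self.end}")


def write_loci_gff3(features: Iterable[LocatedFeature], path: str | Path,
                    seq_lengths: Mapping[str, int] | None = None) -> None:
    """Write features as GFF3; when ``seq_lengths`` is given, ATG-relative
    coordinates are added as ``up_start``/``up_end`` attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            if seq_lengths and f.gene_id in seq_lengths:
                up = to_upstream_frame(f.start, f.end, seq_lengths[f.gene_id])
                attrs["up_start"] = str(up.start_up)
                attrs["up_end"] = str(up.end_up)
            attr_col = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.gene_id,
                        "cnmskit",
                        f.ftype,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attr_col,
                    ]
                )
                + "\n"
            )


def read_loci_gff3(path: str | Path) -> list[LocatedFeature]:
    features: list[LocatedFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"not a 9-column GFF3 line: {line!r}")
            attrs: dict[str, str] = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    key, _, value = pair.partition("=")
                    attrs[key] = value
            features.append(
                LocatedFeature(
                    gene_id=cols[0],
                    ftype=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return features


# ---------------------------------------------------------------------------
# Orthology / paralogy table: target gene -> (comparator species, gene).
# ---------------------------------------------------------------------------

@dataclass
class OrthologyTable:
    mapping: dict[str, list[tuple[str, str]]]

    def comparators(self, gene_id: str) -> list[tuple[str, str]]:
        return self.mapping.get(gene_id, [])

    def validate(
        self,
        target_ids: Iterable[str],
        comparator_ids: Mapping[str, Iterable[str]],
    ) -> None:
        """Check every referenced gene id exists in the loaded FASTA sets."""
        targets = set(target_ids)
        comp_sets = {sp: set(ids) for sp, ids in comparator_ids.items()}
        for gene, pairs in self.mapping.items():
            if gene not in targets:
                raise ValueError(f"orthology table references unknown target gene '{gene}'")
            for species, comp_gene in pairs:
                if species not in comp_sets:
                    raise ValueError(
                        f"orthology table references unknown species '{species}'"
                    )
                if comp_gene not in comp_sets[species]:
                    raise ValueError(
                        f"orthology table references unknown gene "
                        f"'{comp_gene}' of species '{species}'"
                    )


def read_orthology_table(path: str | Path) -> OrthologyTable:
    """Read a 3-column TSV: target_gene, comparator_species, comparator_gene."""
    mapping: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated columns")
            mapping.setdefault(cols[0], []).append((cols[1], cols[2]))
    return OrthologyTable(mapping)


def write_orthology_table(table: OrthologyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in table.mapping:
            for species, comp_gene in table.mapping[gene]:
                fh.write(f"{gene}\t{species}\t{comp_gene}\n")
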
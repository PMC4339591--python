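"""Seeded simulator of multi-species upstream sequence sets with planted
SSR + regulatory-element composites, decoys, and conserved blocks.

The generator emulates the input structure of an upstream-region marker
survey: a target-species multi-FASTA of (default 1000 bp) windows 5' of
the ATG, one upstream FASTA per comparator species, an orthology table,
and an element library. Each gene carries one planted feature:

* ``cnms`` — an SSR tract whose expansion contains a regulatory-element
  signal, copied (with point mutations) into the upstream regions of a
  chosen number of comparator orthologs: a true marker;
* ``ssr_only`` — an SSR matching no element (conserved, but no signal);
* ``tfbs_only`` — a single signal occurrence with no qualifying SSR;
* ``unconserved`` — an SSR + signal composite present in the target only;
* ``none`` — plain background.

The three decoy kinds mirror the three clauses of the marker predicate,
so specificity is testable per clause. Backgrounds are i.i.d. at a fixed
GC; comparator copies receive i.i.d. point substitutions outside the
signal cores and segment edges (no indels, matching the ungapped
conservation model). Each gene is verified against its own truth record
(planted substrings present, no unintended SSR x element pairs, exactly
the intended conservation support) with bounded re-drawing from the same
seeded stream, so the truth table is correct by construction and a given
seed always yields byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import CallConfig
from .conservation import CNSParams, detect_cns, support_for_span
from .seq_model import (
    OrthologyTable,
    UpstreamSequence,
    to_upstream_frame,
    write_orthology_table,
    write_upstream_fasta,
)
from .ssr import SSRThresholds, find_ssrs
from .tfbs import IUPAC, RegElement, core_element_library, scan_elements

__all__ = ["PlantSpec", "SimConfig", "GeneTruth", "SimBundle",
           "simulate_upstream_set", "simulate_genotypes"]

#: SSR unit/count pairs whose expansions contain each core element's signal.
ELEMENT_UNITS: dict[str, tuple[str, int]] = {
    "GAGA8HVBKN3": ("GA", 12),
    "CTRMCAMV35S": ("TC", 8),
    "RAV1AAT": ("CAA", 7),
    "S1FBOXSORPS1L21": ("ATGGT", 3),
    "CANBNNAPA": ("ACACAA", 4),
}

_MAX_DRAWS = 200


@dataclass(frozen=True)
class PlantSpec:
    """What to plant in one gene's upstream region."""

    kind: str  # cnms | ssr_only | tfbs_only | unconserved | none
    element: str | None = None
    unit: str | None = None
    count: int | None = None
    offset_up: int | None = None  # ATG-relative start of the tract; None = random
    n_supporting: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"cnms", "ssr_only", "tfbs_only", "unconserved", "none"}:
            raise ValueError(f"unknown plant kind '{self.kind}'")


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 12
    window: int = 1000
    n_comparator_species: int = 3
    gc_content: float = 0.38
    mutation_rate: float = 0.05
    flank_bp: int = 25  # conserved context copied on each side of a feature
    n_true: int = 4
    n_ssr_only: int = 1
    n_tfbs_only: int = 1
    n_unconserved: int = 1
    seed: int = 0
    plants: tuple[PlantSpec, ...] | None = None  # explicit per-gene override
    cns_params: CNSParams = field(default_factory=CNSParams)

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1 - self.cns_params.min_identity:
            raise ValueError(
                "mutation_rate must lie in [0, 1 - min_identity) so planted "
                "blocks stay detectable"
            )
        if self.plants is None and (
            self.n_true + self.n_ssr_only + self.n_tfbs_only + self.n_unconserved
            > self.n_genes
        ):
            raise ValueError("more planted features than genes")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    kind: str
    element: str | None
    unit: str | None
    count: int | None
    start: int  # planted feature, string frame (0 when kind == 'none')
    end: int
    up_start: int
    up_end: int
    expected_cnms: bool
    expected_elements: tuple[str, ...]  # elements expected to yield a marker
    supporting_species: tuple[str, ...]


@dataclass
class SimBundle:
    target: list[UpstreamSequence]
    comparators: dict[str, list[UpstreamSequence]]
    orthology: OrthologyTable
    elements: list[RegElement]
    truth: list[GeneTruth]
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["target"] = outdir / "target.fa"
        write_upstream_fasta(self.target, paths["target"])
        for species, records in self.comparators.items():
            p = outdir / f"{species}.fa"
            write_upstream_fasta(records, p)
            paths[species] = p
        paths["orthology"] = outdir / "orthology.tsv"
        write_orthology_table(self.orthology, paths["orthology"])
        paths["elements"] = outdir / "elements.tsv"
        with open(paths["elements"], "w") as fh:
            for el in self.elements:
                fh.write(f"{el.name}\t{el.signal_raw or el.signal}\t{el.source}\n")
        paths["truth"] = outdir / "truth.tsv"
        pd.DataFrame([t.__dict__ for t in self.truth]).assign(
            expected_elements=lambda d: d["expected_elements"].map(",".join),
            supporting_species=lambda d: d["supporting_species"].map(",".join),
        ).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _default_plants(cfg: SimConfig) -> list[PlantSpec]:
    plants: list[PlantSpec] = []
    names = list(ELEMENT_UNITS)
    for i in range(cfg.n_true):
        element = names[i % len(names)]
        unit, count = ELEMENT_UNITS[element]
        plants.append(
            PlantSpec(
                kind="cnms",
                element=element,
                unit=unit,
                count=count,
                n_supporting=1 + i % cfg.n_comparator_species,
            )
        )
    for _ in range(cfg.n_ssr_only):
        plants.append(PlantSpec(kind="ssr_only", unit="AAT", count=5, n_supporting=1))
    for _ in range(cfg.n_tfbs_only):
        plants.append(
            PlantSpec(kind="tfbs_only", element="CTRMCAMV35S", n_supporting=1)
        )
    for _ in range(cfg.n_unconserved):
        element = "S1FBOXSORPS1L21"
        unit, count = ELEMENT_UNITS[element]
        plants.append(
            PlantSpec(kind="unconserved", element=element, unit=unit, count=count)
        )
    while len(plants) < cfg.n_genes:
        plants.append(PlantSpec(kind="none"))
    return plants


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1 - gc) / 2
    return "".join(
        rng.choice(np.array(list("ACGT")), size=length,
                   p=[at, gc / 2, gc / 2, at])
    )


def _instantiate_signal(signal: str, rng: np.random.Generator) -> str:
    """Pick a concrete A/C/G/T realisation of a degenerate consensus."""
    out = []
    for code in signal:
        choices = [b for b in IUPAC[code] if b != "N"]
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _planted_insert(spec: PlantSpec, rng: np.random.Generator,
                    elements_by_name: dict[str, RegElement]) -> str:
    if spec.kind in {"cnms", "ssr_only", "unconserved"}:
        return spec.unit * spec.count
    if spec.kind == "tfbs_only":
        return _instantiate_signal(elements_by_name[spec.element].signal, rng)
    return ""


def _eligible_pairs(
    seq: str,
    elements: Sequence[RegElement],
    thresholds: SSRThresholds,
    call_cfg: CallConfig,
) -> set[tuple[int, int, str]]:
    """(ssr_start, ssr_end, element) pairs that would enter marker calling."""
    pairs: set[tuple[int, int, str]] = set()
    ssrs = [
        s
        for s in find_ssrs(seq, thresholds)
        if s.ssr_class in call_cfg.eligible_classes
        and not (call_cfg.exclude_mononucleotide and s.unit_size == 1)
    ]
    hits = scan_elements(seq, elements)
    for s in ssrs:
        for h in hits:
            if min(s.end, h.end) - max(s.start, h.start) + 1 >= call_cfg.min_overlap_bp:
                pairs.add((s.start, s.end, h.element_name))
    return pairs


def _mutate_copy(
    segment: str,
    protected: set[int],
    rate: float,
    rng: np.random.Generator,
) -> str:
    bases = "ACGT"
    out = list(segment)
    for i in range(len(segment)):
        if i in protected:
            continue
        if rng.random() < rate:
            out[i] = bases[(bases.index(out[i]) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


def simulate_upstream_set(config: SimConfig | None = None) -> SimBundle:
    """Generate the full input bundle plus its truth table."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    elements = core_element_library()
    el_by_name = {el.name: el for el in elements}
    thresholds = SSRThresholds()
    call_cfg = CallConfig()
    species_names = [f"comp{i + 1}" for i in range(cfg.n_comparator_species)]
    plants = list(cfg.plants) if cfg.plants is not None else _default_plants(cfg)
    if len(plants) != cfg.n_genes:
        raise ValueError("plants must list one spec per gene")

    target: list[UpstreamSequence] = []
    comparators: dict[str, list[UpstreamSequence]] = {sp: [] for sp in species_names}
    mapping: dict[str, list[tuple[str, str]]] = {}
    truth: list[GeneTruth] = []

    for idx, spec in enumerate(plants):
        gene_id = f"g{idx + 1:03d}"
        insert = _planted_insert(spec, rng, el_by_name)
        if insert and len(insert) + 2 * cfg.flank_bp + 20 > cfg.window:
            raise ValueError(f"{gene_id}: planted feature larger than window")
        supporting = tuple(species_names[: spec.n_supporting])

        for attempt in range(_MAX_DRAWS):
            seq = _random_seq(rng, cfg.window, cfg.gc_content)
            if insert:
                if spec.offset_up is not None:
                    end_str = cfg.window - spec.offset_up + 1  # string end
                    start0 = end_str - len(insert)  # 0-based
                else:
                    lo = cfg.flank_bp + 5
                    hi = cfg.window - len(insert) - cfg.flank_bp - 5
                    start0 = int(rng.integers(lo, hi + 1))
                if not 0 <= start0 <= cfg.window - len(insert):
                    raise ValueError(f"{gene_id}: planted feature outside window")
                seq = seq[:start0] + insert + seq[start0 + len(insert) :]
                f_start, f_end = start0 + 1, start0 + len(insert)
            else:
                f_start = f_end = 0

            pairs = _eligible_pairs(seq, elements, thresholds, call_cfg)
            if spec.kind in {"cnms", "unconserved"}:
                own = {p for p in pairs if (p[0], p[1]) == (f_start, f_end)}
                ok = pairs == own and any(p[2] == spec.element for p in own)
            else:
                ok = not pairs
            if ok:
                break
        else:
            raise RuntimeError(f"{gene_id}: could not generate a clean background")

        expected_elements = tuple(sorted({p[2] for p in pairs}))
        # The conserved segment copied into supporting comparators: the
        # planted feature plus flanking context, wide enough to contain
        # any composite interval built on it.
        seg_start0 = max(0, f_start - 1 - cfg.flank_bp)
        seg_end0 = min(cfg.window, f_end + cfg.flank_bp)

        for attempt in range(_MAX_DRAWS):
            comp_records: dict[str, UpstreamSequence] = {}
            for sp in species_names:
                bg = _random_seq(rng, cfg.window, cfg.gc_content)
                if insert and sp in supporting:
                    segment = seq[seg_start0:seg_end0]
                    protected: set[int] = set()
                    # Never mutate signal cores or segment edges so that
                    # containment of the composite survives.
                    for h in scan_elements(segment, elements):
                        protected.update(range(h.start - 1, h.end))
                    protected.update(range(0, 3))
                    protected.update(range(len(segment) - 3, len(segment)))
                    copy = _mutate_copy(segment, protected, cfg.mutation_rate, rng)
                    pos = int(rng.integers(0, cfg.window - len(copy) + 1))
                    bg = bg[:pos] + copy + bg[pos + len(copy) :]
                comp_records[sp] = UpstreamSequence(
                    gene_id=f"{sp}_{gene_id}", seq=bg, species=sp
                )
            if not insert:
                break
            # Verify conservation support of the planted span is exactly
            # the intended species set.
            t_rec = UpstreamSequence(gene_id=gene_id, seq=seq)
            blocks = {
                sp: detect_cns(t_rec, comp_records[sp], cfg.cns_params)
                for sp in species_names
            }
            got = support_for_span(f_start, f_end, blocks)
            if tuple(got) == tuple(sorted(supporting)):
                break
        else:
            raise RuntimeError(f"{gene_id}: could not realise conservation pattern")

        chrom = f"Chr{idx % 8 + 1}"
        target.append(
            UpstreamSequence(
                gene_id=gene_id,
                seq=seq,
                species="target",
                chromosome=chrom,
                strand="+",
                atg_genomic_pos=(idx + 1) * 500_000,
            )
        )
        for sp in species_names:
            comparators[sp].append(comp_records[sp])
        mapping[gene_id] = [(sp, f"{sp}_{gene_id}") for sp in species_names]
        if insert:
            up = to_upstream_frame(f_start, f_end, cfg.window)
            up_start, up_end = up.start_up, up.end_up
        else:
            up_start = up_end = 0
        truth.append(
            GeneTruth(
                gene_id=gene_id,
                kind=spec.kind,
                element=spec.element,
                unit=spec.unit,
                count=spec.count,
                start=f_start,
                end=f_end,
                up_start=up_start,
                up_end=up_end,
                expected_cnms=spec.kind == "cnms",
                expected_elements=expected_elements if spec.kind == "cnms" else (),
                supporting_species=tuple(sorted(supporting)) if spec.kind != "unconserved" else (),
            )
        )

    return SimBundle(
        target=target,
        comparators=comparators,
        orthology=OrthologyTable(mapping),
        elements=elements,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Genotype matrix simulation (repeat-length allele series).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSim:
    """Allele series of one marker: fragment sizes (bp) and per-group
    sampling frequencies over those alleles."""

    marker_id: str
    alleles: tuple[int, ...]
    group_freqs: dict[str, tuple[float, ...]]


def simulate_genotypes(
    marker_specs: Sequence[MarkerSim],
    group_sizes: dict[str, int],
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a marker x individual matrix of homozygous fragment-size calls.

    Individuals are assigned to groups with group-specific allele
    frequencies; missing calls are injected at ``missing_rate``. Returns
    (matrix, per-individual group labels); deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    individuals: list[str] = []
    labels: list[str] = []
    for group, size in group_sizes.items():
        for i in range(size):
            individuals.append(f"{group}_{i + 1:03d}")
            labels.append(group)
    data: dict[str, list] = {}
    for ind, group in zip(individuals, labels):
        column = []
        for spec in marker_specs:
            freqs = spec.group_freqs[group]
            allele = spec.alleles[int(rng.choice(len(spec.alleles), p=freqs))]
            column.append(float(allele))
        data[ind] = column
    matrix = pd.DataFrame(
        data, index=[s.marker_id for s in marker_specs], dtype=float
    )
    if missing_rate > 0:
        mask = rng.random(matrix.shape) < missing_rate
        matrix = matrix.mask(mask)
    return matrix, pd.Series(labels, index=individuals, name="group")
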
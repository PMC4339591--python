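"""Regulatory-element signal scanning with IUPAC degenerate consensi.

Elements are named signal sequences (PLACE/PlantCARE/TRANSFAC style), e.g.
RAV1AAT = CAACA or GAGA8HVBKN3 = (GA)8. Matching is exact-degenerate: a
consensus letter matches exactly the base set it denotes, no mismatches.
A sequence N matches only a consensus N, so masked regions cannot spawn
spurious hits. Both strands are scanned by default; minus-strand hits are
reported in plus-strand coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from ._util import revcomp_iupac

__all__ = [
    "IUPAC",
    "RegElement",
    "TFBSHit",
    "expand_signal",
    "parse_element_library",
    "core_element_library",
    "iupac_matches",
    "scan_elements",
]

#: Base sets denoted by each IUPAC code. Consensus N additionally matches a
#: sequence N (no other code does).
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}


@dataclass(frozen=True)
class RegElement:
    """A named regulatory-element signal; ``signal`` is the expanded plain
    IUPAC consensus, ``signal_raw`` the form it was declared in."""

    name: str
    signal: str
    signal_raw: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.signal) < 4:
            raise ValueError(f"{self.name}: expanded signal shorter than 4 nt")
        bad = set(self.signal) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: illegal IUPAC letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.signal)


@dataclass(frozen=True)
class TFBSHit:
    """One signal match. Coordinates are 1-based inclusive positions on the
    stored (plus) strand; for a minus-strand hit the reverse complement of
    ``matched_seq`` matches the consensus."""

    element_name: str
    gene_id: str
    start: int
    end: int
    strand: str
    matched_seq: str


_REPEAT = re.compile(r"\(([A-Za-z]+)\)(\d+)")


def expand_signal(signal: str) -> str:
    """Expand repeat notation like ``(GA)8`` into a plain IUPAC string."""
    out: list[str] = []
    i = 0
    while i < len(signal):
        if signal[i] == "(":
            m = _REPEAT.match(signal, i)
            if not m:
                raise ValueError(f"malformed repeat notation in '{signal}'")
            out.append(m.group(1) * int(m.group(2)))
            i = m.end()
        elif signal[i] == ")":
            raise ValueError(f"unbalanced ')' in '{signal}'")
        else:
            out.append(signal[i])
            i += 1
    expanded = "".join(out).upper()
    bad = set(expanded) - set(IUPAC)
    if bad:
        raise ValueError(f"illegal IUPAC letters {sorted(bad)} in '{signal}'")
    return expanded


def parse_element_library(path: str | Path) -> list[RegElement]:
    """Read a TSV element library (name, signal[, source]); '#' lines are
    comments. Signals may use repeat notation; duplicate names are rejected."""
    elements: list[RegElement] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ValueError(f"row {lineno}: expected 'name<TAB>signal'")
            name, raw = cols[0], cols[1]
            source = cols[2] if len(cols) > 2 else ""
            if name in seen:
                raise ValueError(f"row {lineno}: duplicate element name '{name}'")
            seen.add(name)
            try:
                expanded = expand_signal(raw)
                elements.append(
                    RegElement(name=name, signal=expanded, signal_raw=raw, source=source)
                )
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from None
    return elements


def core_element_library() -> list[RegElement]:
    """The packaged five-element reference library (GAGA8HVBKN3,
    CTRMCAMV35S, RAV1AAT, S1FBOXSORPS1L21, CANBNNAPA)."""
    with resources.as_file(
        resources.files("cnmskit").joinpath("data/core_elements.tsv")
    ) as path:
        return parse_element_library(path)


def iupac_matches(consensus_char: str, seq_char: str) -> bool:
    """Exact-degenerate single-letter match; sequence N only matches
    consensus N."""
    return seq_char in IUPAC[consensus_char]


def _consensus_regex(consensus: str) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all found.
    body = "".join(f"[{IUPAC[c]}]" for c in consensus)
    return re.compile(f"(?=({body}))")


def scan_elements(
    seq: str,
    elements: Iterable[RegElement],
    both_strands: bool = True,
    gene_id: str = "",
) -> list[TFBSHit]:
    """Report every (possibly overlapping) occurrence of each element's
    consensus in ``seq``; with ``both_strands`` the reverse complement of
    the consensus is also scanned, and such hits carry ``strand='-'``."""
    hits: list[TFBSHit] = []
    for el in elements:
        for m in _consensus_regex(el.signal).finditer(seq):
            hits.append(
                TFBSHit(
                    element_name=el.name,
                    gene_id=gene_id,
                    start=m.start() + 1,
                    end=m.start() + el.length,
                    strand="+",
                    matched_seq=m.group(1),
                )
            )
        if both_strands:
            rc = revcomp_iupac(el.signal)
            for m in _consensus_regex(rc).finditer(seq):
                hits.append(
                    TFBSHit(
                        element_name=el.name,
                        gene_id=gene_id,
                        start=m.start() + 1,
                        end=m.start() + el.length,
                        strand="-",
                        matched_seq=m.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end, h.element_name, h.strand))
    return hits
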
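"""Flanking PCR primer design for CNMS loci.

One forward/reverse pair is designed per locus from the sequence flanking
the composite SSR+signal interval, under hard constraints: product size
100-300 bp, primer length 18-24 nt, GC 40-60%, Tm 50-62 degC, 3'-end
self-complementarity of at most 4 nt, and template uniqueness (each
primer's annealing site occurs exactly once in the template). Neither
primer may overlap the locus itself, so a repeat expansion by k units
lengthens the amplicon by exactly k x unit_size bp.

Melting temperature follows the common two-regime convention: Wallace
rule 2(A+T)+4(G+C) below 14 nt, and the GC/length formula
64.9 + 41 x (nG + nC - 16.4)/L at 14 nt and above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import revcomp, round_half_up
from .seq_model import UpstreamSequence

__all__ = ["PrimerConstraints", "PrimerPair", "melting_temp", "gc_fraction",
           "end_self_complement", "design_primers"]


@dataclass(frozen=True)
class PrimerConstraints:
    product_min: int = 100
    product_max: int = 300
    len_min: int = 18
    len_max: int = 24
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 50.0
    tm_max: float = 62.0
    max_end_self_complement: int = 4
    require_unique: bool = True

    def __post_init__(self) -> None:
        if self.product_min >= self.product_max:
            raise ValueError("product_min must be below product_max")
        if self.len_min > self.len_max:
            raise ValueError("len_min must not exceed len_max")


@dataclass(frozen=True)
class PrimerPair:
    """Both primers stored 5'->3' as ordered; template positions are
    1-based inclusive on the plus strand (the stored upstream string)."""

    fwd_seq: str
    rev_seq: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size: int


def melting_temp(primer: str) -> float:
    """Two-regime melting temperature in degC (Wallace below 14 nt)."""
    if len(primer) < 10:
        raise ValueError("primer shorter than 10 nt")
    if "N" in primer:
        raise ValueError("primer contains N")
    gc = primer.count("G") + primer.count("C")
    if len(primer) < 14:
        return float(2 * (len(primer) - gc) + 4 * gc)
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def gc_fraction(primer: str) -> float:
    return (primer.count("G") + primer.count("C")) / len(primer)


def end_self_complement(primer: str) -> int:
    """Length of the longest 3'-end suffix whose reverse complement occurs
    anywhere in the primer (a cheap dimer/hairpin proxy)."""
    best = 0
    for n in range(1, len(primer) + 1):
        if revcomp(primer[-n:]) in primer:
            best = n
        else:
            break
    return best


def _occurrences(template: str, probe: str) -> int:
    count = start = 0
    while True:
        idx = template.find(probe, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def _candidate_ok(site: str, template: str, c: PrimerConstraints,
                  as_reverse: bool) -> bool:
    """Validate the annealing site (plus-strand slice); the reverse primer
    itself is the reverse complement of its site."""
    primer = revcomp(site) if as_reverse else site
    if "N" in primer:
        return False
    gc = gc_fraction(primer)
    if not c.gc_min <= gc <= c.gc_max:
        return False
    tm = melting_temp(primer)
    if not c.tm_min <= tm <= c.tm_max:
        return False
    if end_self_complement(primer) > c.max_end_self_complement:
        return False
    if c.require_unique and _occurrences(template, site) != 1:
        return False
    return True


def design_primers(
    template: UpstreamSequence | str,
    locus_start: int,
    locus_end: int,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair | None:
    """Best qualifying primer pair bracketing ``locus_start..locus_end``
    (1-based inclusive), or None.

    Among all pairs satisfying every constraint, the one whose product
    size is closest to the midpoint of the allowed product range wins;
    ties prefer the smaller product, then the leftmost forward primer,
    then the shorter primers. Fully deterministic.
    """
    if constraints is None:
        constraints = PrimerConstraints()
    c = constraints
    seq = template.seq if isinstance(template, UpstreamSequence) else template
    L = len(seq)
    if not 1 <= locus_start <= locus_end <= L:
        raise ValueError(f"locus {locus_start}-{locus_end} outside template 1..{L}")

    # One deterministic representative candidate per start (forward) or per
    # end (reverse): the shortest valid length.
    fwd_by_start: dict[int, str] = {}  # 0-based start -> site
    for start in range(0, locus_start - 1):
        for plen in range(c.len_min, c.len_max + 1):
            end = start + plen  # exclusive
            if end > locus_start - 1:
                break
            site = seq[start:end]
            if _candidate_ok(site, seq, c, as_reverse=False):
                fwd_by_start[start] = site
                break

    rev_by_end: dict[int, str] = {}  # 0-based inclusive end -> site
    for end in range(locus_end, L):  # 0-based inclusive end index
        for plen in range(c.len_min, c.len_max + 1):
            start = end - plen + 1
            if start < locus_end:  # must not overlap the locus
                continue
            site = seq[start : end + 1]
            if _candidate_ok(site, seq, c, as_reverse=True):
                rev_by_end[end] = site
                break

    if not fwd_by_start or not rev_by_end:
        return None
    rev_ends = sorted(rev_by_end)
    target = (c.product_min + c.product_max) / 2
    best_key: tuple | None = None
    best: tuple[int, int] | None = None
    for fstart in sorted(fwd_by_start):
        lo = fstart + c.product_min - 1
        hi = fstart + c.product_max - 1
        for rend in rev_ends:
            if rend < lo or rend < locus_end:
                continue
            if rend > hi:
                break
            product = rend - fstart + 1
            key = (abs(product - target), product, fstart,
                   len(fwd_by_start[fstart]), len(rev_by_end[rend]))
            if best_key is None or key < best_key:
                best_key = key
                best = (fstart, rend)
    if best is None:
        return None
    fstart, rend = best
    fwd_site = fwd_by_start[fstart]
    rev_site = rev_by_end[rend]
    fwd_seq = fwd_site
    rev_seq = revcomp(rev_site)
    return PrimerPair(
        fwd_seq=fwd_seq,
        rev_seq=rev_seq,
        fwd_start=fstart + 1,
        fwd_end=fstart + len(fwd_site),
        rev_start=rend - len(rev_site) + 2,
        rev_end=rend + 1,
        tm_f=round_half_up(melting_temp(fwd_seq), 2),
        tm_r=round_half_up(melting_temp(rev_seq), 2),
        gc_f=gc_fraction(fwd_seq),
        gc_r=gc_fraction(rev_seq),
        product_size=rend - fstart + 1,
    )
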
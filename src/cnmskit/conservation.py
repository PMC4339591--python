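"""Conserved non-coding sequence (CNS) detection between upstream regions.

An ungapped seed-and-extend comparison of a target upstream sequence with
the upstream sequence of an orthologous/paralogous gene. Every diagonal
holding an exact shared ``seed_k``-mer is examined; a reported block is a
maximal segment on such a diagonal that

* starts and ends on a matching base (trailing mismatches are trimmed),
* has overall identity >= ``min_identity``,
* is at least ``min_len`` bp long, and
* contains at least one run of ``seed_k`` consecutive matches (the seed).

This set of segments is the fixed point of the usual "extend from the seed
while running identity stays above the threshold, then trim back to the
last match" procedure, and is what an exhaustive enumeration of qualifying
diagonal segments yields, so the two can be checked against each other.
Overlapping blocks on a diagonal are resolved deterministically: longer
first, then higher identity, then smaller target start.

Indels are not modelled; the marker-calling use-case only asks whether a
locus sits inside a conserved segment, for which ungapped blocks suffice.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seq_model import UpInterval, UpstreamSequence, to_string_frame

__all__ = ["CNSParams", "CNSBlock", "detect_cns", "conservation_support",
           "support_for_span"]

_EPS = 1e-9


@dataclass(frozen=True)
class CNSParams:
    seed_k: int = 8
    min_len: int = 20
    min_identity: float = 0.70

    def __post_init__(self) -> None:
        if self.seed_k > self.min_len:
            raise ValueError("seed_k must not exceed min_len")
        if not 0.5 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0.5, 1]")


@dataclass(frozen=True)
class CNSBlock:
    """An ungapped conserved segment; all coordinates 1-based inclusive
    string positions. ``identity`` is matches/length over the paired
    segments."""

    target_gene: str
    comparator_species: str
    comparator_gene: str
    t_start: int
    t_end: int
    c_start: int
    c_end: int
    identity: float

    @property
    def length(self) -> int:
        return self.t_end - self.t_start + 1

    def contains_target_span(self, start: int, end: int) -> bool:
        return self.t_start <= start and end <= self.t_end


def _seed_diagonals(t: str, c: str, k: int) -> list[int]:
    """Diagonals (t_offset - c_offset) sharing at least one exact k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(c) - k + 1):
        kmer = c[j : j + k]
        if "N" not in kmer:
            index[kmer].append(j)
    diags: set[int] = set()
    for i in range(len(t) - k + 1):
        kmer = t[i : i + k]
        if "N" not in kmer:
            for j in index.get(kmer, ()):
                diags.add(i - j)
    return sorted(diags)


def _diagonal_segments(
    match: np.ndarray, min_len: int, min_identity: float, seed_k: int
) -> list[tuple[int, int, float]]:
    """Maximal qualifying (start, end, identity) segments on one diagonal,
    0-based inclusive offsets along the diagonal."""
    y_idx = np.flatnonzero(match)
    if len(y_idx) == 0:
        return []
    csum = np.concatenate(([0], np.cumsum(match)))
    # Seed positions: starts of >= seed_k consecutive matches.
    window = csum[seed_k:] - csum[:-seed_k]
    seed_starts = np.flatnonzero(window == seed_k)
    if len(seed_starts) == 0:
        return []
    # Identity of [x, y] is (csum[y+1]-csum[x])/(y-x+1) >= min_identity,
    # rearranged so each endpoint contributes one scalar.
    g = csum[y_idx + 1] - min_identity * (y_idx + 1)
    c = csum[y_idx] - min_identity * y_idx
    ok = (g[None, :] >= c[:, None] - _EPS) & (
        y_idx[None, :] - y_idx[:, None] + 1 >= min_len
    )
    candidates: list[tuple[int, int]] = []
    for i in range(len(y_idx)):
        cols = np.flatnonzero(ok[i])
        if len(cols) == 0:
            continue
        x, y = int(y_idx[i]), int(y_idx[cols[-1]])
        # Require a seed inside [x, y].
        pos = int(np.searchsorted(seed_starts, x, side="left"))
        if pos < len(seed_starts) and seed_starts[pos] + seed_k - 1 <= y:
            candidates.append((x, y))
    # Drop segments contained in an earlier (smaller-start) one.
    maximal: list[tuple[int, int]] = []
    best_y = -1
    for x, y in candidates:
        if y > best_y:
            maximal.append((x, y))
            best_y = y
    out = []
    for x, y in maximal:
        ident = float(csum[y + 1] - csum[x]) / (y - x + 1)
        out.append((x, y, ident))
    return out


def _resolve_overlaps(
    segs: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Keep non-overlapping segments, preferring longer, then higher
    identity, then smaller start."""
    ordered = sorted(segs, key=lambda s: (-(s[1] - s[0] + 1), -s[2], s[0]))
    kept: list[tuple[int, int, float]] = []
    for x, y, ident in ordered:
        if all(y < kx or x > ky for kx, ky, _ in kept):
            kept.append((x, y, ident))
    return sorted(kept)


def detect_cns(
    target: UpstreamSequence,
    comparator: UpstreamSequence,
    params: CNSParams | None = None,
) -> list[CNSBlock]:
    """Find all ungapped conserved blocks between two upstream sequences."""
    if params is None:
        params = CNSParams()
    t, c = target.seq, comparator.seq
    blocks: list[CNSBlock] = []
    for d in _seed_diagonals(t, c, params.seed_k):
        t0 = max(d, 0)
        c0 = t0 - d
        n = min(len(t) - t0, len(c) - c0)
        if n < params.min_len:
            continue
        ta = np.frombuffer(t[t0 : t0 + n].encode(), dtype=np.uint8)
        ca = np.frombuffer(c[c0 : c0 + n].encode(), dtype=np.uint8)
        match = (ta == ca) & (ta != ord("N"))
        segs = _diagonal_segments(
            match, params.min_len, params.min_identity, params.seed_k
        )
        for x, y, ident in _resolve_overlaps(segs):
            blocks.append(
                CNSBlock(
                    target_gene=target.gene_id,
                    comparator_species=comparator.species,
                    comparator_gene=comparator.gene_id,
                    t_start=t0 + x + 1,
                    t_end=t0 + y + 1,
                    c_start=c0 + x + 1,
                    c_end=c0 + y + 1,
                    identity=ident,
                )
            )
    blocks.sort(key=lambda b: (b.t_start, b.t_end, b.c_start))
    return blocks


def support_for_span(
    start: int,
    end: int,
    blocks_by_species: Mapping[str, Sequence[CNSBlock]],
) -> list[str]:
    """Species whose CNS blocks fully contain the string-frame span."""
    supporting = {
        species
        for species, blocks in blocks_by_species.items()
        if any(b.contains_target_span(start, end) for b in blocks)
    }
    return sorted(supporting)


def conservation_support(
    interval: UpInterval,
    blocks_by_species: Mapping[str, Sequence[CNSBlock]],
    target_length: int,
) -> list[str]:
    """Species supporting an ATG-relative interval on the target gene.

    A species supports the interval if one of its blocks fully contains
    it (containment, not mere overlap: the element itself must be
    conserved, not just nearby sequence)."""
    start, end = to_string_frame(interval, target_length)
    return support_for_span(start, end, blocks_by_species)
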
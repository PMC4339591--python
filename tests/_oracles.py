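"""Independent brute-force oracles used to cross-check the fast paths.

Each oracle re-derives the operation's definition by direct enumeration,
without sharing code with the implementation it checks.
"""

from __future__ import annotations

from cnmskit._util import revcomp
from cnmskit.conservation import CNSParams
from cnmskit.ssr import SSRThresholds
from cnmskit.tfbs import IUPAC


def _primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def brute_ssrs(seq: str, thresholds: SSRThresholds) -> set[tuple[int, int, str, int]]:
    """All maximal perfect tandem tracts by per-start enumeration:
    (start, end, unit, repeat_count), 1-based inclusive."""
    found = set()
    n = len(seq)
    for k, min_rep in thresholds.min_repeats.items():
        for s in range(n - k + 1):
            unit = seq[s : s + k]
            if "N" in unit or not _primitive(unit):
                continue
            # left-maximal: the run cannot be slid one base left
            if s > 0 and seq[s - 1] == seq[s + k - 1] and seq[s - 1] != "N":
                continue
            j = s + k
            while j < n and seq[j] == seq[j - k] and seq[j] != "N":
                j += 1
            reps = (j - s) // k
            if reps >= min_rep and reps * k >= thresholds.min_tract_bp:
                found.add((s + 1, s + reps * k, unit, reps))
    return found


def brute_scan(seq: str, signal: str, both_strands: bool = True
               ) -> set[tuple[int, int, str]]:
    """Per-position IUPAC comparison: (start, end, strand), 1-based."""

    def matches_here(s: str, consensus: str, pos: int) -> bool:
        if pos + len(consensus) > len(s):
            return False
        return all(
            s[pos + i] in IUPAC[consensus[i]] for i in range(len(consensus))
        )

    hits = set()
    m = len(signal)
    for pos in range(len(seq)):
        if matches_here(seq, signal, pos):
            hits.add((pos + 1, pos + m, "+"))
    if both_strands:
        for pos in range(len(seq)):
            window = seq[pos : pos + m]
            if len(window) == m and matches_here(revcomp(window), signal, 0):
                hits.add((pos + 1, pos + m, "-"))
    return hits


def brute_cns_blocks(t: str, c: str, params: CNSParams
                     ) -> list[tuple[int, int, int, int, float]]:
    """Exhaustive enumeration of maximal qualifying diagonal segments:
    (t_start, t_end, c_start, c_end, identity), 1-based inclusive.

    A qualifying segment starts/ends on a match, has length >= min_len,
    identity >= min_identity and contains seed_k consecutive matches; it
    is maximal if no larger qualifying segment on the same diagonal
    contains it. Overlaps on a diagonal are resolved preferring length,
    then identity, then position.
    """
    out: list[tuple[int, int, int, int, float]] = []
    for d in range(-(len(c) - 1), len(t)):
        t0 = max(d, 0)
        c0 = t0 - d
        n = min(len(t) - t0, len(c) - c0)
        match = [
            t[t0 + x] == c[c0 + x] and t[t0 + x] != "N" for x in range(n)
        ]
        qualifying = []
        for x in range(n):
            if not match[x]:
                continue
            for y in range(x + params.min_len - 1, n):
                if not match[y]:
                    continue
                ident = sum(match[x : y + 1]) / (y - x + 1)
                if ident + 1e-9 < params.min_identity:
                    continue
                has_seed = any(
                    all(match[r : r + params.seed_k])
                    for r in range(x, y - params.seed_k + 2)
                )
                if has_seed:
                    qualifying.append((x, y, ident))
        maximal = [
            (x, y, ident)
            for (x, y, ident) in qualifying
            if not any(
                (x2 <= x and y <= y2) and (x2, y2) != (x, y)
                for (x2, y2, _) in qualifying
            )
        ]
        kept: list[tuple[int, int, float]] = []
        for x, y, ident in sorted(
            maximal, key=lambda s: (-(s[1] - s[0] + 1), -s[2], s[0])
        ):
            if all(y < kx or x > ky for kx, ky, _ in kept):
                kept.append((x, y, ident))
        for x, y, ident in kept:
            out.append((t0 + x + 1, t0 + y + 1, c0 + x + 1, c0 + y + 1, ident))
    out.sort()
    return out
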
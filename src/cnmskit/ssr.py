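"""Perfect tandem-repeat (SSR / microsatellite) mining and classification.

Finds every maximal perfect tandem run of a primitive 1-6 nt unit that
meets both a per-unit-size minimum repeat count and a minimum tract
length. Runs are broken at N; partial trailing units are trimmed, so a
reported tract is always a whole number of unit copies.

Class convention for marker design: tracts >= 20 bp are hypervariable
class I, tracts of 12-19 bp class II, shorter tracts are kept internally
as ``sub12`` but excluded from marker calling by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "SSRThresholds",
    "SSRLocus",
    "find_ssrs",
    "classify_ssr",
    "repeat_variant_alleles",
    "CLASS_I_MIN_BP",
    "CLASS_II_MIN_BP",
]

CLASS_I_MIN_BP = 20
CLASS_II_MIN_BP = 12

#: Minimum repeat counts by unit size. Chosen so that short reference motifs
#: such as (TTCT)3, (ATGGT)3 and (AAG)4 are discoverable; override to taste.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRThresholds:
    """Search thresholds: per-unit-size minimum repeat count plus a
    tract-length floor; both filters apply independently."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    min_tract_bp: int = 12

    def __post_init__(self) -> None:
        for k, n in self.min_repeats.items():
            if not 1 <= k <= 6:
                raise ValueError(f"unit size {k} outside 1..6")
            if n < 2:
                raise ValueError(f"min_repeats[{k}] must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem tract. ``start``/``end`` are 1-based
    inclusive string positions; ``unit`` is the repeat unit as written on
    the stored strand, phased to its earliest occurrence in the tract."""

    gene_id: str
    unit: str
    repeat_count: int
    start: int
    end: int

    @property
    def unit_size(self) -> int:
        return len(self.unit)

    @property
    def tract_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def ssr_class(self) -> str:
        return classify_ssr(self.tract_bp)


def classify_ssr(tract_bp: int) -> str:
    """Class I (>=20 bp), class II (12-19 bp) or sub12."""
    if tract_bp < 1:
        raise ValueError("tract length must be positive")
    if tract_bp >= CLASS_I_MIN_BP:
        return "I"
    if tract_bp >= CLASS_II_MIN_BP:
        return "II"
    return "sub12"


def _is_primitive(unit: str) -> bool:
    """True unless the unit is itself a repetition of a shorter unit."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def find_ssrs(
    seq: str,
    thresholds: SSRThresholds | None = None,
    gene_id: str = "",
) -> list[SSRLocus]:
    """Mine all qualifying maximal perfect tandem runs from ``seq``.

    A run with period ``k`` is a maximal stretch where ``seq[j] == seq[j-k]``
    (never across an N); its tract is trimmed to whole unit copies from the
    left, and reported once with its smallest (primitive) unit. Results are
    sorted by start position, then unit size.
    """
    if thresholds is None:
        thresholds = SSRThresholds()
    loci: list[SSRLocus] = []
    n = len(seq)
    for k, min_rep in sorted(thresholds.min_repeats.items()):
        j = k
        while j < n:
            if seq[j] != seq[j - k] or seq[j] == "N":
                j += 1
                continue
            run_start = j  # first index where the period-k predicate holds
            while j < n and seq[j] == seq[j - k] and seq[j] != "N":
                j += 1
            total = (j - run_start) + k  # characters covered by the run
            repeats = total // k
            start = run_start - k  # 0-based tract start
            unit = seq[start : start + k]
            if (
                repeats >= min_rep
                and repeats * k >= thresholds.min_tract_bp
                and "N" not in unit
                and _is_primitive(unit)
            ):
                loci.append(
                    SSRLocus(
                        gene_id=gene_id,
                        unit=unit,
                        repeat_count=repeats,
                        start=start + 1,
                        end=start + repeats * k,
                    )
                )
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci


def repeat_variant_alleles(
    unit: str, counts: Sequence[int]
) -> list[tuple[str, int]]:
    """Expand an allele series of repeat counts into (sequence, length-bp)
    pairs; length differences equal unit size times count differences."""
    if any(c < 1 for c in counts):
        raise ValueError("repeat counts must be >= 1")
    return [(unit * c, len(unit) * c) for c in counts]
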
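"""Small shared helpers: rounding and nucleotide complement tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

# Plain-base complement; N maps to N.
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Complement over the full 15-letter IUPAC degenerate alphabet.
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(seq: str) -> str:
    """Reverse complement of a degenerate IUPAC consensus string."""
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention used for all printed
    percentages and cM spacings), avoiding banker's rounding surprises."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
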
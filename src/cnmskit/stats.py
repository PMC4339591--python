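"""Marker informativeness and survey statistics.

Covers the downstream arithmetic of a marker survey: allele frequencies
from a marker x individual genotype matrix of fragment sizes (bp),
polymorphism information content (PIC, Botstein definition), survey
percentages, linkage-map summary tables (per-group intermarker spacing
as map length / marker count), polymorphism flags with optional group
contrasts, and haplotype constitution across the markers of one gene in
inbred lines.

Genotype matrices are pandas DataFrames with marker rows and individual
columns; missing calls are NaN. PIC for allele frequencies p_i is

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "allele_frequencies",
    "pic",
    "survey_percent",
    "summarize_map",
    "polymorphic_flags",
    "constitute_haplotypes",
    "read_genotype_matrix",
    "read_map_table",
]


def allele_frequencies(calls: pd.Series | Sequence) -> dict:
    """Allele frequencies over non-missing calls of one marker row."""
    series = pd.Series(list(calls)).dropna()
    if series.empty:
        name = getattr(calls, "name", None) or "marker"
        raise ValueError(f"{name}: no non-missing calls")
    freq = series.value_counts(normalize=True, sort=False)
    return {allele: float(f) for allele, f in freq.items()}


def pic(freqs: Mapping | Sequence[float]) -> float:
    """Polymorphism information content of one marker (0 if monomorphic)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs,
                   dtype=float)
    if p.size == 0 or p.min() <= 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be positive and sum to 1")
    p2 = p**2
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return float(1.0 - p2.sum() - (p2.sum() ** 2 - (p2**2).sum()))


def survey_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up (e.g. 256 of 631 -> 40.6)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, decimals)


def summarize_map(rows: pd.DataFrame | Sequence[tuple]) -> pd.DataFrame:
    """Linkage-map summary with per-group and total intermarker spacing.

    Input rows carry (linkage_group, n_markers, map_length_cm); spacing is
    map length divided by marker count (the convention that reproduces a
    total-row spacing of total length / total markers), rounded half-up to
    two decimals. A 'Total' row is appended.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(
            rows, columns=["linkage_group", "n_markers", "map_length_cm"]
        )
    df = rows.copy()
    if (df["n_markers"] < 1).any():
        bad = df.loc[df["n_markers"] < 1, "linkage_group"].iloc[0]
        raise ValueError(f"linkage group {bad}: marker count must be >= 1")
    if (df["map_length_cm"] < 0).any():
        raise ValueError("map lengths must be non-negative")
    df["avg_spacing_cm"] = [
        round_half_up(length / n, 2)
        for length, n in zip(df["map_length_cm"], df["n_markers"])
    ]
    total_markers = int(df["n_markers"].sum())
    total_length = float(df["map_length_cm"].sum())
    total = pd.DataFrame(
        {
            "linkage_group": ["Total"],
            "n_markers": [total_markers],
            "map_length_cm": [round_half_up(total_length, 1)],
            "avg_spacing_cm": [round_half_up(total_length / total_markers, 2)],
        }
    )
    return pd.concat([df, total], ignore_index=True)


def polymorphic_flags(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-marker allele counts and polymorphism status.

    With ``groups`` (individual -> group label), also reports whether the
    marker separates the groups (different allele sets between groups) and
    whether it varies within any single group.
    """
    out: dict[str, list] = {"n_alleles": [], "polymorphic": []}
    if groups is not None:
        groups = pd.Series(groups)
        out["between_group_polymorphic"] = []
        out["within_group_polymorphic"] = []
    for _, row in matrix.iterrows():
        alleles = set(row.dropna())
        out["n_alleles"].append(len(alleles))
        out["polymorphic"].append(len(alleles) >= 2)
        if groups is not None:
            sets = {
                g: frozenset(row[members.index].dropna())
                for g, members in groups.groupby(groups)
            }
            nonempty = [s for s in sets.values() if s]
            out["between_group_polymorphic"].append(len(set(nonempty)) >= 2)
            out["within_group_polymorphic"].append(any(len(s) >= 2 for s in nonempty))
    return pd.DataFrame(out, index=matrix.index)


def constitute_haplotypes(
    matrix: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Haplotypes across the markers of one gene in homozygous lines.

    Each individual's haplotype is the ordered tuple of its allele codes
    across the matrix rows; returns (per-individual haplotype, haplotype
    member counts, largest first). Heterozygous calls (cells containing
    '/') and missing calls are rejected: inbred-line material only.
    """
    for marker, row in matrix.iterrows():
        for ind, call in row.items():
            if pd.isna(call):
                raise ValueError(f"{marker}/{ind}: missing call")
            if "/" in str(call):
                raise ValueError(f"{marker}/{ind}: heterozygous call '{call}'")
    haps = pd.Series(
        {ind: tuple(matrix[ind]) for ind in matrix.columns}, name="haplotype"
    )
    counts = haps.value_counts()
    return haps, counts


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read a marker x individual TSV (first column = marker id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_map_table(path: str | Path) -> pd.DataFrame:
    """Read a linkage-map TSV: linkage_group, n_markers, map_length_cm."""
    df = pd.read_csv(path, sep="\t")
    expected = {"linkage_group", "n_markers", "map_length_cm"}
    if not expected.issubset(df.columns):
        raise ValueError(f"map table must have columns {sorted(expected)}")
    return df
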
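"""Grantham-distance analysis of aligned sequence groups.

Grantham's distance scores the physicochemical difference between two
amino-acid side chains as a weighted Euclidean combination of three
properties — atomic-group composition c, polarity p and molecular
volume v:

    D(i, j) = rho * [ alpha (c_i - c_j)^2 + beta (p_i - p_j)^2
                      + gamma (v_i - v_j)^2 ]^(1/2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho = 50.723
normalising the mean over all pairs to 100.  The matrix is regenerated
from the property values at import; rounded entries match the published
integer table (a handful of published entries, e.g. C-W printed as 215
versus the formula's 214.36, differ by one unit from the regenerated
value because of rounding in the original tabulation).

For an alignment split into a low-Tc and a high-Tc group, the residual
inter-group distance at a column is the inter-group mean minus the
larger of the two intra-group means; columns where it exceeds
mean + 3*SD mark substitutions that track the phenotype split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .structure_io import Sequence

__all__ = [
    "GRANTHAM_PROPERTIES",
    "GRANTHAM_MATRIX",
    "grantham_distance",
    "group_pair_counts",
    "ResidualProfile",
    "residual_profile",
]

# (composition, polarity, volume) per amino acid, one-letter keyed (1974 values)
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

_ALPHA = 1.833
_BETA = 0.1018
_GAMMA = 0.000399
_RHO = 50.723  # scales the all-pair mean distance to 100


def _build_matrix() -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for a, (ca, pa, va) in GRANTHAM_PROPERTIES.items():
        for b, (cb, pb, vb) in GRANTHAM_PROPERTIES.items():
            d = _RHO * math.sqrt(
                _ALPHA * (ca - cb) ** 2 + _BETA * (pa - pb) ** 2 + _GAMMA * (va - vb) ** 2
            )
            out[(a, b)] = d
    return out


GRANTHAM_MATRIX: dict[tuple[str, str], float] = _build_matrix()


def grantham_distance(aa1: str, aa2: str, rounded: bool = True) -> float:
    """Grantham distance between two standard amino acids (one-letter codes).

    ``rounded=True`` returns the published integer value; gaps and
    nonstandard codes raise (callers apply their own gap policy).
    """
    a, b = aa1.upper(), aa2.upper()
    if a not in GRANTHAM_PROPERTIES or b not in GRANTHAM_PROPERTIES:
        raise KeyError(f"grantham_distance defined only for standard amino acids, got ({aa1}, {aa2})")
    d = GRANTHAM_MATRIX[(a, b)]
    return float(round(d)) if rounded else d


def group_pair_counts(n_low: int, n_high: int) -> tuple[int, int, int]:
    """(intra-low, intra-high, inter) pair counts for the two group sizes."""
    if n_low < 0 or n_high < 0:
        raise ValueError("group sizes must be >= 0")
    return n_low * (n_low - 1) // 2, n_high * (n_high - 1) // 2, n_low * n_high


@dataclass
class ResidualProfile:
    """Per-column residual inter-group Grantham distances with 3-SD flags."""

    columns: np.ndarray  # 1-based column numbers
    inter_mean: np.ndarray
    intra_low_mean: np.ndarray
    intra_high_mean: np.ndarray
    residual: np.ndarray
    flags: np.ndarray  # residual > mean + n_sd*SD
    gap_dominated: np.ndarray  # columns zeroed by the gap policy
    cutoff: float


def _column_mean(pairs, col_chars) -> tuple[float, int, int]:
    """Mean Grantham distance over the given index pairs at one column.

    Pairs touching a gap or nonstandard residue are dropped.  Returns
    (mean, used pairs, defined pairs requested).
    """
    total, used = 0.0, 0
    for i, j in pairs:
        a, b = col_chars[i], col_chars[j]
        if a in GRANTHAM_PROPERTIES and b in GRANTHAM_PROPERTIES:
            total += GRANTHAM_MATRIX[(a, b)]
            used += 1
    return (total / used if used else 0.0), used, len(pairs)


def residual_profile(
    alignment: list[Sequence],
    low_ids: list[str],
    high_ids: list[str],
    n_sd: float = 3.0,
    gap_fraction: float = 0.5,
) -> ResidualProfile:
    """Residual inter-group Grantham distance per alignment column.

    residual = inter-group mean - max(intra-group means).  Any pair
    touching a gap is dropped from its column's mean; if more than
    ``gap_fraction`` of the inter-group pairs are dropped the column is
    set to 0 and flagged gap-dominated.  Flags mark columns with
    residual > mean + n_sd*SD (statistics over all columns).
    """
    by_id = {s.id: s for s in alignment}
    if set(low_ids) & set(high_ids):
        raise ValueError("a sequence cannot belong to both groups")
    missing = [i for i in list(low_ids) + list(high_ids) if i not in by_id]
    if missing:
        raise KeyError(f"sequences not in alignment: {missing}")
    seqs = [by_id[i] for i in low_ids] + [by_id[i] for i in high_ids]
    n_low, n_high = len(low_ids), len(high_ids)
    n_cols = len(seqs[0])
    low_idx = range(n_low)
    high_idx = range(n_low, n_low + n_high)
    intra_low_pairs = list(combinations(low_idx, 2))
    intra_high_pairs = list(combinations(high_idx, 2))
    inter_pairs = [(i, j) for i in low_idx for j in high_idx]

    inter = np.zeros(n_cols)
    il = np.zeros(n_cols)
    ih = np.zeros(n_cols)
    residual = np.zeros(n_cols)
    gap_dom = np.zeros(n_cols, dtype=bool)
    for c in range(n_cols):
        chars = [s.residues[c] for s in seqs]
        inter_m, used, requested = _column_mean(inter_pairs, chars)
        il_m, _, _ = _column_mean(intra_low_pairs, chars)
        ih_m, _, _ = _column_mean(intra_high_pairs, chars)
        inter[c], il[c], ih[c] = inter_m, il_m, ih_m
        if requested and used < (1.0 - gap_fraction) * requested:
            gap_dom[c] = True
            residual[c] = 0.0
        else:
            residual[c] = inter_m - max(il_m, ih_m)
    cutoff = residual.mean() + n_sd * residual.std(ddof=0)
    flags = residual > cutoff
    return ResidualProfile(
        columns=np.arange(1, n_cols + 1),
        inter_mean=inter,
        intra_low_mean=il,
        intra_high_mean=ih,
        residual=residual,
        flags=flags,
        gap_dominated=gap_dom,
        cutoff=float(cutoff),
    )
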
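"""Embedded Grantham (1974) amino-acid distance matrix.

The matrix combines composition, polarity and molecular volume into a
single physicochemical distance per substitution. Distances range from 5
(Leu/Ile) to 215 (Cys/Trp). The scoring thresholds (64 medium, 109 high)
are configuration constants; :func:`matrix_quartiles` recomputes the
actual median and upper quartile of the 190 pair distances, which are 97
and 134 — the nominal 64/109 do not coincide with any quantile of the
matrix and are kept verbatim as the protocol's published cut points.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_ORDER = "SRLPTAVGIFYCHQNKDEMW"

# Upper triangle in _ORDER, row by row (Grantham 1974, Table 2).
_UPPER = [
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],  # S
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],  # R
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],  # L
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],  # P
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],  # T
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],  # A
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],  # V
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],  # G
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],  # I
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],  # F
    [194, 83, 99, 143, 85, 160, 122, 36, 37],  # Y
    [174, 154, 139, 202, 154, 170, 196, 215],  # C
    [24, 68, 32, 81, 40, 87, 115],  # H
    [46, 53, 61, 29, 101, 130],  # Q
    [94, 23, 42, 142, 174],  # N
    [101, 56, 95, 110],  # K
    [45, 160, 181],  # D
    [126, 152],  # E
    [67],  # M
    [],  # W
]


def _build() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    for i, aa in enumerate(_ORDER):
        table[(aa, aa)] = 0
        for j_off, value in enumerate(_UPPER[i]):
            bb = _ORDER[i + 1 + j_off]
            table[(aa, bb)] = value
            table[(bb, aa)] = value
    return table


_TABLE = _build()


def grantham_distance(ref_aa: str, alt_aa: str) -> int:
    """Physicochemical distance between two amino acids (symmetric)."""
    try:
        return _TABLE[(ref_aa, alt_aa)]
    except KeyError:
        raise ValueError(f"unknown amino acid pair {ref_aa!r}->{alt_aa!r}") from None


def all_pair_distances() -> np.ndarray:
    """The 190 distances over unordered non-identical pairs, sorted."""
    vals = [
        _TABLE[(a, b)]
        for i, a in enumerate(_ORDER)
        for b in _ORDER[i + 1 :]
    ]
    return np.sort(np.asarray(vals))


@lru_cache(maxsize=1)
def matrix_quartiles() -> tuple[int, int]:
    """Median and upper quartile of the 190 possible pair distances.

    Uses the inverted-CDF (type-1) quantile so both values are attained
    matrix entries. Returns (97, 134); note these differ from the 64/109
    scoring thresholds, which are fixed configuration constants.
    """
    vals = all_pair_distances()
    med = int(np.percentile(vals, 50, method="inverted_cdf"))
    q3 = int(np.percentile(vals, 75, method="inverted_cdf"))
    return med, q3
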
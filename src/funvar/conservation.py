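"""Per-column conservation scoring and alignment diversity (DOPS).

Highly conserved alignment columns predict functional sites, but only in
alignments diverse enough for conservation to be informative: a
near-redundant alignment scores every column high. The default column
score is entropy-based with gap down-weighting,

    score(c) = (1 - H_c / ln 20) * (1 - gap_fraction_c),

where H_c is the Shannon entropy of the (weighted) amino-acid
distribution over non-gap symbols. Alignment diversity is summarized by
DOPS, here the percentage of distinct column scores (after rounding to 3
decimals) among all columns; site prediction is gated at DOPS > 70 and
column score > 0.9. Both scorers sit behind a registry so alternative
formulations (e.g. a sum-of-pairs scorer) can be slotted in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .config import Config
from .types import AA20, GAP_CHARS, FunFamBundle

LN20 = math.log(20.0)


@dataclass(frozen=True)
class ConservationProfile:
    scores: tuple[float, ...]  # per column, in [0, 1]
    dops: float  # in [0, 100]
    all_gap_columns: frozenset[int] = frozenset()  # 1-based, flagged score-0


def column_conservation(
    column: Sequence[str], weights: Sequence[float] | None = None
) -> float:
    """Conservation of one alignment column in [0, 1].

    1.0 iff a single residue type and no gaps; 0.0 for an all-gap column
    (flagged upstream) or a uniform distribution over all 20 types.
    """
    if len(column) == 0:
        raise ValueError("empty column")
    if weights is None:
        weights = [1.0] * len(column)
    if len(weights) != len(column) or any(w <= 0 for w in weights):
        raise ValueError("weights must be positive, one per sequence")
    total_w = float(sum(weights))
    gap_w = sum(w for c, w in zip(column, weights) if c in GAP_CHARS)
    nongap_w = total_w - gap_w
    if nongap_w == 0.0:
        return 0.0
    freq: dict[str, float] = {}
    for c, w in zip(column, weights):
        if c in GAP_CHARS:
            continue
        cc = c.upper()
        if cc not in AA20:
            continue  # X / ambiguity codes carry no conservation signal
        freq[cc] = freq.get(cc, 0.0) + w
    denom = sum(freq.values())
    if denom == 0.0:
        return 0.0
    entropy = -sum((w / denom) * math.log(w / denom) for w in freq.values())
    return (1.0 - entropy / LN20) * (1.0 - gap_w / total_w)


def dops(scores: Sequence[float], ndigits: int = 3) -> float:
    """Diversity-of-positions score: % of distinct rounded column scores."""
    if len(scores) == 0:
        raise ValueError("need at least one column score")
    distinct = len({round(s, ndigits) for s in scores})
    return 100.0 * distinct / len(scores)


def henikoff_weights(rows: Sequence[str]) -> list[float]:
    """Position-based sequence weights (Henikoff & Henikoff 1994).

    Each column distributes one unit of weight: a residue type seen in r
    sequences at a column with k distinct types contributes 1/(k*r) to
    each of those sequences. Gaps receive no weight. Weights are
    normalized to mean 1.
    """
    n = len(rows)
    if n == 0:
        raise ValueError("empty alignment")
    length = len(rows[0])
    w = np.zeros(n)
    for col in range(length):
        chars = [r[col].upper() for r in rows]
        counts: dict[str, int] = {}
        for c in chars:
            if c not in GAP_CHARS:
                counts[c] = counts.get(c, 0) + 1
        k = len(counts)
        if k == 0:
            continue
        for i, c in enumerate(chars):
            if c not in GAP_CHARS:
                w[i] += 1.0 / (k * counts[c])
    if w.sum() == 0:
        return [1.0] * n
    w = w * n / w.sum()
    return [float(max(x, 1e-9)) for x in w]


_SCORERS: dict[str, Callable[[Sequence[str], Sequence[float] | None], float]] = {
    "entropy": column_conservation,
}


def register_scorer(name: str, fn: Callable) -> None:
    _SCORERS[name] = fn


def conservation_profile(
    bundle: FunFamBundle,
    method: str = "entropy",
    weighting: str = "uniform",
) -> ConservationProfile:
    """Score every alignment column and summarize alignment diversity."""
    scorer = _SCORERS[method]
    rows = list(bundle.alignment.values())
    length = len(rows[0])
    weights = henikoff_weights(rows) if weighting == "henikoff" else None
    scores = []
    all_gap = set()
    for col in range(length):
        column = [r[col] for r in rows]
        if all(c in GAP_CHARS for c in column):
            all_gap.add(col + 1)
            scores.append(0.0)
        else:
            scores.append(scorer(column, weights))
    return ConservationProfile(tuple(scores), dops(scores), frozenset(all_gap))


def predict_site_columns(profile: ConservationProfile, config: Config) -> frozenset[int]:
    """1-based columns predicted as functional sites.

    Empty when the alignment is insufficiently diverse (DOPS at or below
    the gate); otherwise columns scoring strictly above the conservation
    threshold (strict, on raw scores).
    """
    if profile.dops <= config.dops_threshold:
        return frozenset()
    return frozenset(
        i + 1
        for i, s in enumerate(profile.scores)
        if s > config.conservation_threshold
    )
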
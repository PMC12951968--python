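"""Hill-number diversity of FIE (or background-mutation) abundance
vectors, with exact rarefaction, extrapolation and bootstrap CIs.

Diversity of order q = 1 (Hill-Shannon, exp of Shannon entropy) is the
effective number of equally-abundant genes or families and is the
default throughout; q = 0 (richness) and q = 2 (Hill-Simpson) are
available behind the same interface. Because diversity grows with
sample size, groups of unequal size (e.g. pre- vs post-duplication
FIEs) are compared on rarefaction/extrapolation curves:

* rarefaction (m < n) uses the exact hypergeometric expectation of the
  subsample entropy — not a series approximation — so small-n values
  can be checked against brute-force enumeration;
* extrapolation (m > n) blends the observed entropy with the
  singleton/doubleton-corrected asymptotic entropy estimator of Chao &
  Jost,  H(m) = (n/m) H_obs + (1 - n/m) H_inf,  which is continuous at
  m = n, monotone in m and approaches the asymptote;
* sample coverage  1 - (f1/n) [(n-1) f1 / ((n-1) f1 + 2 f2)]  estimates
  the fraction of the underlying distribution seen;
* percentile bootstrap CIs resample from the coverage-adjusted
  estimated community (observed frequencies shrunk to total coverage C,
  the unseen mass 1 - C split over Chao1-style pseudo-labels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm

from .config import Config


@dataclass(frozen=True)
class AbundanceVector:
    """Counts of FIEs (or mutations) per gene or family label."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must have equal length")
        if len(self.counts) == 0:
            raise ValueError("empty abundance vector")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive integers")

    @classmethod
    def from_counts(cls, counts: dict[str, int] | Sequence[int]) -> "AbundanceVector":
        if isinstance(counts, dict):
            items = sorted(counts.items())
            return cls(tuple(k for k, _ in items), tuple(int(v) for _, v in items))
        return cls(
            tuple(f"label_{i}" for i in range(len(counts))),
            tuple(int(c) for c in counts),
        )

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts if c == 2)


@dataclass(frozen=True)
class DiversityEstimate:
    m: int
    value: float
    mode: str  # interpolated | observed | extrapolated
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def _entropy(counts: Sequence[int]) -> float:
    n = sum(counts)
    return -sum((c / n) * math.log(c / n) for c in counts if c > 0)


def hill_number(v: AbundanceVector, q: float = 1.0) -> float:
    """Observed Hill diversity of order q (effective number of labels)."""
    p = np.asarray(v.counts, dtype=float) / v.n
    if q == 1.0:
        return float(math.exp(-(p * np.log(p)).sum()))
    if q == 0.0:
        return float(len(v.counts))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def hill_shannon(v: AbundanceVector) -> float:
    """exp(Shannon entropy): the effective number of equally-common labels."""
    return hill_number(v, 1.0)


def _rarefied_entropy(v: AbundanceVector, m: int) -> float:
    """Exact expected entropy of a size-m subsample without replacement."""
    n = v.n
    h = 0.0
    # group identical counts to share hypergeometric evaluations
    uniq: dict[int, int] = {}
    for c in v.counts:
        uniq[c] = uniq.get(c, 0) + 1
    for x, mult in uniq.items():
        kmax = min(m, x)
        ks = np.arange(1, kmax + 1)
        pmf = hypergeom.pmf(ks, n, x, m)
        terms = -(ks / m) * np.log(ks / m)
        h += mult * float((pmf * terms).sum())
    return h


def rarefied_hill_shannon(v: AbundanceVector, m: int) -> DiversityEstimate:
    """Hill-Shannon diversity of an exact expected size-m subsample."""
    if not 1 <= m <= v.n:
        raise ValueError(f"m must be in [1, n={v.n}], got {m}")
    if m == v.n:
        return DiversityEstimate(m, hill_shannon(v), "observed")
    return DiversityEstimate(m, math.exp(_rarefied_entropy(v, m)), "interpolated")


def asymptotic_entropy(v: AbundanceVector) -> float:
    """Chao-Jost singleton/doubleton-corrected entropy estimator.

    Returns the observed entropy when f1 = 0 (complete coverage);
    clamped from below at the observed entropy.
    """
    n, f1, f2 = v.n, v.f1, v.f2
    h_obs = _entropy(v.counts)
    if f1 == 0:
        return h_obs
    if f2 > 0:
        a = 2 * f2 / ((n - 1) * f1 + 2 * f2)
    else:
        a = 2 / ((n - 1) * (f1 - 1) + 2)
    part1 = 0.0
    harmonic = np.cumsum(1.0 / np.arange(1, n))  # harmonic[k-1] = sum_{j<=k} 1/j
    for x in v.counts:
        if x <= n - 1:
            # sum_{k=x}^{n-1} 1/k
            s = harmonic[n - 2] - (harmonic[x - 2] if x >= 2 else 0.0)
            part1 += (x / n) * s
    part2 = 0.0
    if a < 1.0:
        r = np.arange(1, n)
        inner = -math.log(a) - float(((1.0 / r) * (1 - a) ** r).sum())
        part2 = (f1 / n) * (1 - a) ** (1 - n) * inner
    return max(h_obs, part1 + part2)


def extrapolated_hill_shannon(v: AbundanceVector, m: int) -> DiversityEstimate:
    """Hill-Shannon diversity extrapolated beyond the observed size."""
    if m <= v.n:
        raise ValueError(f"m must exceed n={v.n} for extrapolation")
    if v.n < 2:
        raise ValueError("need n >= 2 to extrapolate")
    h_obs = _entropy(v.counts)
    if v.f1 == v.n:
        warnings.warn(
            "all labels are singletons: asymptotic entropy undefined; "
            "returning the observed value",
            stacklevel=2,
        )
        return DiversityEstimate(m, math.exp(h_obs), "extrapolated")
    h_inf = asymptotic_entropy(v)
    w = v.n / m
    return DiversityEstimate(m, math.exp(w * h_obs + (1 - w) * h_inf), "extrapolated")


def estimate(v: AbundanceVector, m: int) -> DiversityEstimate:
    """Rarefied, observed or extrapolated Hill-Shannon diversity at m."""
    if m <= v.n:
        return rarefied_hill_shannon(v, m)
    return extrapolated_hill_shannon(v, m)


def sample_coverage(v: AbundanceVector) -> float:
    """Estimated fraction of the label distribution captured by the sample."""
    n, f1, f2 = v.n, v.f1, v.f2
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    c = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2))
    return float(min(max(c, 0.0), 1.0))


def _bootstrap_community(v: AbundanceVector) -> np.ndarray:
    """Estimated complete-community probabilities: observed labels shrunk
    to coverage C plus Chao1-style unseen pseudo-labels sharing 1 - C."""
    n, f1, f2 = v.n, v.f1, v.f2
    c = sample_coverage(v)
    probs = np.asarray(v.counts, dtype=float) / n * c
    if c < 1.0:
        f0 = math.ceil(f1 * f1 / (2.0 * f2)) if f2 > 0 else math.ceil(f1 * (f1 - 1) / 2.0)
        f0 = max(f0, 1)
        probs = np.concatenate([probs, np.full(f0, (1.0 - c) / f0)])
    return probs


def bootstrap_ci(
    v: AbundanceVector,
    m_grid: Sequence[int],
    B: int = 200,
    seed: int = 0,
    conf: float = 0.95,
    method: str = "percentile",
) -> dict[int, tuple[float, float]]:
    """Bootstrap confidence bounds of the diversity curve at each m."""
    if B < 50:
        raise ValueError("B must be >= 50")
    rng = np.random.default_rng(seed)
    probs = _bootstrap_community(v)
    values = np.empty((B, len(m_grid)))
    for b in range(B):
        counts_b = rng.multinomial(v.n, probs)
        counts_b = counts_b[counts_b > 0]
        if counts_b.size == 0:  # pragma: no cover - n >= 1 guarantees nonempty
            counts_b = np.array([v.n])
        vb = AbundanceVector.from_counts([int(x) for x in counts_b])
        with warnings.catch_warnings():
            # replicates may be all-singleton even when the sample is not
            warnings.simplefilter("ignore", UserWarning)
            for j, m in enumerate(m_grid):
                values[b, j] = estimate(vb, int(m)).value
    alpha = 1.0 - conf
    out: dict[int, tuple[float, float]] = {}
    for j, m in enumerate(m_grid):
        if method == "normal":
            point = estimate(v, int(m)).value
            sd = float(values[:, j].std(ddof=1))
            z = float(norm.ppf(1 - alpha / 2))
            lo, hi = point - z * sd, point + z * sd
        else:
            lo = float(np.percentile(values[:, j], 100 * alpha / 2))
            hi = float(np.percentile(values[:, j], 100 * (1 - alpha / 2)))
        out[int(m)] = (max(lo, 1.0), hi)
    return out


@dataclass
class GroupComparison:
    curves: pd.DataFrame
    m_compare: int
    significant: bool
    higher: Optional[str] = None
    warnings: list[str] = field(default_factory=list)


def _m_grid(n: int, m_max: int, points: int = 8) -> list[int]:
    grid = set(np.linspace(1, m_max, points, dtype=int))
    grid.update({1, n, m_max})
    return sorted(grid)


def compare_groups(
    pre: AbundanceVector,
    post: AbundanceVector,
    config: Config | None = None,
    seed: int = 0,
) -> GroupComparison:
    """Paired rarefaction/extrapolation curves with a CI-overlap call.

    Curves run to extrapolation_factor x max(n_pre, n_post); the groups
    are called significantly different when their bootstrap CIs do not
    overlap at that common size. A log2-log2 curve table is emitted for
    plotting.
    """
    config = config or Config()
    warns: list[str] = []
    for name, v in (("pre", pre), ("post", post)):
        if v.n < 5:
            warns.append(f"group {name!r} has n={v.n} < 5: comparison unreliable")
            warnings.warn(warns[-1], stacklevel=2)
    m_max = config.extrapolation_factor * max(pre.n, post.n)
    rows = []
    cis = {}
    for gi, (name, v) in enumerate((("pre", pre), ("post", post))):
        grid = _m_grid(v.n, m_max)
        ci = bootstrap_ci(v, grid, B=config.bootstrap_reps, seed=seed + gi)
        cis[name] = ci
        for m in grid:
            est = estimate(v, m)
            lo, hi = ci[m]
            rows.append(
                {
                    "group": name,
                    "m": m,
                    "mode": est.mode,
                    "value": est.value,
                    "ci_low": lo,
                    "ci_high": hi,
                    "log2_m": math.log2(m),
                    "log2_value": math.log2(max(est.value, 1.0)),
                }
            )
    lo_pre, hi_pre = cis["pre"][m_max]
    lo_post, hi_post = cis["post"][m_max]
    significant = hi_pre < lo_post or hi_post < lo_pre
    higher = None
    if significant:
        higher = "post" if hi_pre < lo_post else "pre"
    return GroupComparison(
        curves=pd.DataFrame(rows),
        m_compare=m_max,
        significant=significant,
        higher=higher,
        warnings=warns,
    )


def abundance_from_table(
    df: pd.DataFrame, group_by: str = "gene", count_col: Optional[str] = None
) -> AbundanceVector:
    """Per-label abundance vector from a long-format FIE/mutation table."""
    if count_col is None:
        counts = df[group_by].value_counts().to_dict()
    else:
        counts = df.groupby(group_by)[count_col].sum().to_dict()
    return AbundanceVector.from_counts({str(k): int(c) for k, c in counts.items() if c > 0})
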
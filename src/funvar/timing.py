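"""Mutation timing relative to gene duplication.

A mutation in a region of allele-specific copy-number gain can be timed
against the gain through its mutation copy number (the estimated number
of chromosomal copies carrying it): a mutation present on more than one
copy (> 1.5) must predate the duplication, a single-copy mutation
(< 1.5) postdates it. Three scenarios apply:

* biallelic gain (major >= 2, minor >= 2): < 1.5 post, > 1.5 pre;
* monoallelic gain with LOH (major >= 2, minor == 0): same rule;
* monoallelic gain without LOH (major >= 2, minor == 1): > 1.5 pre, but
  < 1.5 cannot be timed — it may be a post-duplication mutation on the
  gained allele or an ungained mutation on the minor allele.

No gain (major < 2) yields class no_gain. A copy number of exactly 1.5
is an explicit tie and is left untimed. Across multiple regions of one
tumor, pre in one region and post in another reconciles to post: a truly
pre-duplication mutation sits on every copy of its allele, so wild-type
copies cannot reappear, whereas a subclonal gain can duplicate a
post-duplication mutation in one region only.
"""

from __future__ import annotations

from typing import Optional, Sequence

from scipy.stats import chi2_contingency

from .config import Config
from .types import TimingCall, TimingClass, TimingScenario


def time_mutation(
    major_cn: int,
    minor_cn: int,
    mutation_cn: Optional[float],
    config: Config | None = None,
) -> TimingCall:
    """Classify one mutation against the copy-number scenario truth table."""
    config = config or Config()
    if major_cn < 0 or minor_cn < 0:
        raise ValueError("copy numbers must be non-negative")
    if mutation_cn is not None and mutation_cn < 0:
        raise ValueError("mutation_cn must be non-negative")
    t = config.timing_cn_threshold

    if major_cn < 2:
        return TimingCall(TimingClass.NO_GAIN, TimingScenario.NO_GAIN)

    if minor_cn >= 2:
        scenario = TimingScenario.BIALLELIC_GAIN
    elif minor_cn == 0:
        scenario = TimingScenario.MONOALLELIC_LOH
    else:
        scenario = TimingScenario.MONOALLELIC_NOLOH

    if mutation_cn is None:
        return TimingCall(TimingClass.UNTIMED, scenario, "missing mutation_cn")
    if mutation_cn == t:
        return TimingCall(TimingClass.UNTIMED, scenario, f"mutation_cn == {t} (tie)")
    if mutation_cn > t:
        return TimingCall(TimingClass.PRE, scenario)
    if scenario is TimingScenario.MONOALLELIC_NOLOH:
        return TimingCall(
            TimingClass.UNTIMED,
            scenario,
            "single-copy mutation indistinguishable from ungained minor allele",
        )
    return TimingCall(TimingClass.POST, scenario)


_PRECEDENCE = (
    TimingClass.POST,
    TimingClass.PRE,
    TimingClass.UNTIMED,
    TimingClass.NO_GAIN,
)


def reconcile_regions(calls: Sequence[TimingCall]) -> TimingCall:
    """Reconcile per-region calls for one mutation of one tumor.

    pre + post -> post (see module doc); a timed call beats untimed,
    untimed beats no_gain. Order-invariant and idempotent.
    """
    if len(calls) == 0:
        raise ValueError("no calls to reconcile")
    classes = {c.klass for c in calls}
    for klass in _PRECEDENCE:
        if klass in classes:
            winner = next(c for c in calls if c.klass == klass)
            reason = winner.reason
            if TimingClass.PRE in classes and TimingClass.POST in classes:
                reason = "pre in one region, post in another: reconciled to post"
            return TimingCall(klass, winner.scenario, reason)
    raise AssertionError("unreachable")


def timing_enrichment_test(
    fie_pre: int, fie_post: int, syn_pre: int, syn_post: int
) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on the 2x2 table
    (FIE vs synonymous background) x (pre vs post duplication)."""
    table = [[fie_pre, fie_post], [syn_pre, syn_post]]
    if min(fie_pre + fie_post, syn_pre + syn_post) <= 0:
        raise ValueError("both row sums must be positive")
    if min(fie_pre + syn_pre, fie_post + syn_post) <= 0:
        raise ValueError("both column sums must be positive")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)
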
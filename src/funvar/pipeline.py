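"""End-to-end orchestration: builder cohort -> tunable sites -> scored
FIEs -> duplication timing -> diversity comparison.

Tunable sites are built from a *builder* cohort (pancancer role) and
applied to a *target* cohort (lung role); the two may coincide, in
which case every target mutation inside a tunable site is returned.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import Config
from .conservation import conservation_profile, predict_site_columns
from .diversity import AbundanceVector, GroupComparison, compare_groups
from .mapping import ColumnMap, aggregate_counts, build_column_map, project_sites
from .score import apply_threshold, score_candidate
from .timing import reconcile_regions, time_mutation
from .tunable import (
    call_fies,
    cluster_mutations,
    find_hotspots,
    make_tunable_sites,
    project_to_representative,
)
from .types import (
    CopyNumberState,
    FIERecord,
    FunctionalSiteSet,
    FunFamBundle,
    MutationCluster,
    MutationRecord,
    TimingClass,
    TunableSite,
)

log = logging.getLogger("funvar")


@dataclass
class TunableSiteResult:
    sites: FunctionalSiteSet
    clusters: list[MutationCluster]
    tunable: list[TunableSite]
    cmap: ColumnMap
    hotspot_residues: frozenset[int]


def build_tunable_sites(
    bundle: FunFamBundle,
    builder_muts: Sequence[MutationRecord],
    config: Config | None = None,
    seed: int = 0,
) -> TunableSiteResult:
    """Detect clusters and hotspots in the builder cohort and intersect
    them with known plus conservation-predicted functional sites."""
    config = config or Config()
    cmap = build_column_map(bundle)
    profile = conservation_profile(bundle)
    predicted_cols = predict_site_columns(profile, config)
    sites = project_sites(bundle, predicted_cols)

    agg = aggregate_counts(list(builder_muts), cmap, bundle)
    clusters = cluster_mutations(
        agg.per_residue,
        bundle.structure,
        radius=config.cluster_radius,
        n_perm=config.n_permutations,
        seed=seed,
    )
    hotspots = find_hotspots(list(builder_muts), config.hotspot_min_patients)
    hotspot_residues = set()
    by_gene_pos: dict[tuple[str, int], list[MutationRecord]] = {}
    for m in builder_muts:
        by_gene_pos.setdefault((m.gene, m.residue_pos), []).append(m)
    for gene, pos, _alt in hotspots:
        for m in by_gene_pos.get((gene, pos), []):
            rid = project_to_representative(m, cmap, bundle)
            if rid is not None:
                hotspot_residues.add(rid)
    tunable = make_tunable_sites(
        clusters, frozenset(hotspot_residues), sites, bundle.structure, config
    )
    return TunableSiteResult(sites, clusters, tunable, cmap, frozenset(hotspot_residues))


def score_target_cohort(
    target_muts: Sequence[MutationRecord],
    bundle: FunFamBundle,
    built: TunableSiteResult,
    config: Config | None = None,
    mutfam_flag: Optional[bool] = None,
) -> tuple[list[FIERecord], list[FIERecord]]:
    """Call and score FIEs in the target cohort; returns (retained, below)."""
    config = config or Config()
    target_hotspots = find_hotspots(list(target_muts), config.hotspot_min_patients)
    candidates = call_fies(list(target_muts), built.tunable, built.cmap, bundle)
    records = [
        score_candidate(
            mut,
            rid,
            bundle,
            built.sites,
            built.clusters,
            target_hotspots,
            mutfam_flag=mutfam_flag,
            config=config,
            tunable_source=source,
        )
        for mut, rid, source in candidates
    ]
    return apply_threshold(records, config)


def time_records(
    records: Sequence[FIERecord],
    cn_states: Sequence[CopyNumberState],
    config: Config | None = None,
) -> list[FIERecord]:
    """Attach duplication-timing calls, reconciling multi-region states."""
    config = config or Config()
    by_key: dict[tuple[str, str], list[CopyNumberState]] = {}
    for st in cn_states:
        by_key.setdefault((st.tumor_id, st.gene), []).append(st)
    out = []
    for rec in records:
        m = rec.mutation
        states = by_key.get((m.tumor_id, m.gene), [])
        if not states:
            rec.timing = TimingClass.UNTIMED
            rec.timing_scenario = None
        else:
            calls = [
                time_mutation(st.major_cn, st.minor_cn, m.mutation_cn, config)
                for st in states
            ]
            final = reconcile_regions(calls)
            rec.timing = final.klass
            rec.timing_scenario = final.scenario
        out.append(rec)
    return out


def diversity_by_timing(
    records: Sequence[FIERecord],
    group_by: str = "gene",
    config: Config | None = None,
    seed: int = 0,
) -> GroupComparison:
    """Compare pre- vs post-duplication FIE diversity per gene or family."""
    config = config or Config()
    key = (lambda r: r.mutation.gene) if group_by == "gene" else (lambda r: r.funfam_id)
    counts: dict[str, dict[str, int]] = {"pre": {}, "post": {}}
    for r in records:
        if r.timing in (TimingClass.PRE, TimingClass.POST):
            d = counts[r.timing.value]
            d[key(r)] = d.get(key(r), 0) + 1
    if not counts["pre"] or not counts["post"]:
        raise ValueError("need both pre- and post-duplication events to compare")
    return compare_groups(
        AbundanceVector.from_counts(counts["pre"]),
        AbundanceVector.from_counts(counts["post"]),
        config,
        seed=seed,
    )


@dataclass
class ToyPipelineResult:
    bundle: FunFamBundle
    built: TunableSiteResult
    retained: list[FIERecord]
    below: list[FIERecord]
    comparison: Optional[GroupComparison] = None
    summary: dict = field(default_factory=dict)


def run_toy_pipeline(
    seed: int = 0, config: Config | None = None
) -> ToyPipelineResult:
    """Deterministic end-to-end run on the synthetic world.

    Simulates a toy family with a planted cluster and site, builds
    tunable sites from a builder cohort, scores the same cohort as
    target, plants biallelic-gain timing (mutation copy number 2 for
    pre, 1 for post), and compares pre/post FIE-gene diversity when
    both strata are populated.
    """
    from . import synth  # deferred: synth imports mapping

    config = config or Config()
    rng = np.random.default_rng(seed)
    bundle, truth = synth.make_toy_funfam(seed=seed)
    muts = synth.make_family_mutations(
        bundle, truth, seed=seed + 1, n_cluster_mutations=30
    )
    # plant biallelic-gain timing: ~2 mutant copies pre, ~1 post
    timed_muts = []
    cn_rows = {}
    for m in muts:
        pre = bool(rng.random() < 0.5)
        timed_muts.append(
            dataclasses.replace(m, mutation_cn=2.0 if pre else 1.0)
        )
        cn_rows[(m.tumor_id, m.gene)] = CopyNumberState(m.tumor_id, m.gene, 2, 2)
    built = build_tunable_sites(bundle, timed_muts, config, seed=seed)
    retained, below = score_target_cohort(timed_muts, bundle, built, config)
    timed = time_records(retained, list(cn_rows.values()), config)
    comparison = None
    pre_n = sum(1 for r in timed if r.timing is TimingClass.PRE)
    post_n = sum(1 for r in timed if r.timing is TimingClass.POST)
    if pre_n and post_n:
        comparison = diversity_by_timing(timed, "gene", config, seed=seed)
    summary = {
        "n_builder_mutations": len(timed_muts),
        "n_tunable_sites": len(built.tunable),
        "n_fies": len(retained),
        "n_below_threshold": len(below),
        "n_pre": pre_n,
        "n_post": post_n,
        "planted_cluster": sorted(truth.cluster_residues),
        "top_cluster_p": min((c.p_value for c in built.clusters), default=None),
    }
    return ToyPipelineResult(bundle, built, retained, below, comparison, summary)
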
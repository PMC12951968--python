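"""Spatial mutation clusters, recurrence hotspots and tunable sites.

Aggregated per-residue mutation counts on the representative structure
are scanned for significant spatial clusters with a greedy seed-and-
extend procedure: residues are ranked by the total mutation count in
their spherical neighborhood (default radius 5 Å, ties broken toward the
lower residue_id), each seed claims the unassigned residues within the
radius, and the cluster score (its total mutation count) is referred to
an empirical permutation null that redistributes the observed mutations
uniformly over all structure-eligible residues. Significant clusters
(p <= 0.05, with a highly-significant tier at p <= 0.005) and recurrence
hotspots that fall within 5 Å of a known or predicted functional site
become "tunable sites"; a functional impact event (FIE) is a target-
cohort mutation projecting into a tunable site.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import cdist

from .config import Config
from .mapping import ColumnMap, project_to_representative
from .types import (
    DomainStructure,
    FunctionalSiteSet,
    FunFamBundle,
    MutationCluster,
    MutationRecord,
    SiteKind,
    TunableSite,
)

log = logging.getLogger("funvar")


@lru_cache(maxsize=32)
def _coords(structure: DomainStructure) -> dict[int, np.ndarray]:
    return {
        r.residue_id: np.array([[a.x, a.y, a.z] for a in r.atoms])
        for r in structure.residues
    }


@lru_cache(maxsize=32)
def distance_matrix(structure: DomainStructure) -> tuple[tuple[int, ...], np.ndarray]:
    """Minimum heavy-atom inter-residue distances, symmetric, 0 on diagonal.

    Ca-only structures degenerate naturally to Ca-Ca distances.
    """
    coords = _coords(structure)
    ids = tuple(sorted(coords))
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(coords[ids[i]], coords[ids[j]]).min()
            mat[i, j] = mat[j, i] = d
    return ids, mat


def residue_distance(structure: DomainStructure, r1: int, r2: int) -> float:
    """Minimum distance over heavy-atom pairs of two residues (Å)."""
    if r1 == r2:
        if r1 not in structure:
            raise KeyError(f"residue {r1} not in structure")
        return 0.0
    coords = _coords(structure)
    try:
        return float(cdist(coords[r1], coords[r2]).min())
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]} not in structure") from None


def find_hotspots(
    muts: list[MutationRecord], min_patients: int = 2
) -> frozenset[tuple[str, int, str]]:
    """Recurrent identical changes: (gene, residue_pos, alt_aa) tuples seen
    in >= min_patients distinct patients of a single cancer type."""
    patients: dict[tuple[str, str, int, str], set[str]] = {}
    for m in muts:
        key = (m.cancer_type, m.gene, m.residue_pos, m.alt_aa)
        patients.setdefault(key, set()).add(m.tumor_id)
    return frozenset(
        (gene, pos, alt)
        for (_, gene, pos, alt), tumors in patients.items()
        if len(tumors) >= min_patients
    )


def cluster_mutations(
    counts: dict[int, int],
    structure: DomainStructure,
    radius: float = 5.0,
    n_perm: int = 999,
    seed: int = 0,
    eligible_residues: tuple[int, ...] | None = None,
) -> list[MutationCluster]:
    """Greedy seed-and-extend spatial clusters with permutation p-values.

    The null redistributes the observed total mutation count uniformly
    over the eligible residues (default: every structure residue) and
    records the maximum neighborhood score per permutation; each
    cluster's p-value is (1 + #{perm max >= cluster score}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    total = sum(counts.values())
    if total == 0:
        return []
    ids, dmat = distance_matrix(structure)
    if eligible_residues is not None:
        keep = [i for i, rid in enumerate(ids) if rid in set(eligible_residues)]
        ids = tuple(ids[i] for i in keep)
        dmat = dmat[np.ix_(keep, keep)]
    index = {rid: i for i, rid in enumerate(ids)}
    missing = set(counts) - set(index)
    if missing:
        raise KeyError(f"mutated residues not eligible/present: {sorted(missing)}")
    c = np.zeros(len(ids))
    for rid, k in counts.items():
        c[index[rid]] = k

    if len(ids) < 2:
        return [
            MutationCluster(
                residue_ids=frozenset(ids),
                mutation_count=int(total),
                p_value=1.0,
                seed_residue=ids[0],
            )
        ]

    adj = dmat <= radius  # includes the diagonal
    nbh = adj @ c

    rng = np.random.default_rng(seed)
    perm_counts = rng.multinomial(total, np.full(len(ids), 1.0 / len(ids)), size=n_perm)
    perm_max = (perm_counts @ adj).max(axis=1)

    order = sorted(range(len(ids)), key=lambda i: (-nbh[i], ids[i]))
    assigned = np.zeros(len(ids), dtype=bool)
    clusters: list[MutationCluster] = []
    for i in order:
        if assigned[i] or nbh[i] <= 0:
            continue
        members = np.flatnonzero(adj[i] & ~assigned)
        score = int(c[members].sum())
        assigned[members] = True
        if score < 1:
            continue
        p = float((1 + (perm_max >= score).sum()) / (1 + n_perm))
        clusters.append(
            MutationCluster(
                residue_ids=frozenset(ids[j] for j in members),
                mutation_count=score,
                p_value=p,
                seed_residue=ids[i],
            )
        )
    return clusters


def _min_site_distance(
    residues: frozenset[int],
    site_residues: frozenset[int],
    structure: DomainStructure,
) -> float:
    ids, dmat = distance_matrix(structure)
    index = {rid: i for i, rid in enumerate(ids)}
    ri = [index[r] for r in residues]
    si = [index[s] for s in site_residues]
    if not ri or not si:
        return float("inf")
    return float(dmat[np.ix_(ri, si)].min())


def make_tunable_sites(
    clusters: list[MutationCluster],
    hotspot_residues: frozenset[int] | set[int],
    sites: FunctionalSiteSet,
    structure: DomainStructure,
    config: Config | None = None,
) -> list[TunableSite]:
    """Significant clusters and hotspot residues within the site cutoff."""
    config = config or Config()
    cutoff = config.site_distance_cutoff
    out: list[TunableSite] = []
    if len(sites) == 0:
        return out

    def kinds_within(residues: frozenset[int]) -> frozenset[SiteKind]:
        found = set()
        for e in sites.entries:
            if _min_site_distance(residues, frozenset({e.residue_id}), structure) <= cutoff:
                found.add(e.site_kind)
        return frozenset(found)

    for cl in clusters:
        if cl.tier(config.cluster_sig, config.cluster_high_sig) == "none":
            continue
        d = _min_site_distance(cl.residue_ids, sites.all_residues, structure)
        if d <= cutoff:
            out.append(
                TunableSite(cl.residue_ids, d, "cluster", kinds_within(cl.residue_ids))
            )
    for rid in sorted(hotspot_residues):
        d = _min_site_distance(frozenset({rid}), sites.all_residues, structure)
        if d <= cutoff:
            out.append(
                TunableSite(frozenset({rid}), d, "hotspot", kinds_within(frozenset({rid})))
            )
    return out


def call_fies(
    target_muts: list[MutationRecord],
    tunable: list[TunableSite],
    cmap: ColumnMap,
    bundle: FunFamBundle,
) -> list[tuple[MutationRecord, int, str]]:
    """Target-cohort mutations projecting into a tunable site.

    Returns (mutation, representative residue, tunable-site source)
    triples; mutations at columns gapped in the representative are
    logged and skipped.
    """
    residue_source: dict[int, str] = {}
    for site in tunable:
        for rid in site.residue_ids:
            # a residue covered by both a cluster and a hotspot keeps "cluster"
            residue_source.setdefault(rid, site.source)
    out = []
    n_gapped = 0
    for mut in target_muts:
        rid = project_to_representative(mut, cmap, bundle)
        if rid is None:
            n_gapped += 1
            continue
        if rid in residue_source:
            out.append((mut, rid, residue_source[rid]))
    if n_gapped:
        log.info("call_fies: %d target mutations unprojectable", n_gapped)
    return out
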
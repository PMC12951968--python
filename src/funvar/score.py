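"""Component-wise FIE scoring.

The score of a candidate functional impact event is the plain sum of

* sequence components — Grantham substitution impact {0,1,2} (1 above
  the medium threshold 64, 2 above the high threshold 109, zeroed for
  polymorphic variants with population VAF > 1e-7), target-cohort
  hotspot membership {0,1}, known disease-variant annotation {0,1};
* structure components — on / within 5 Å of a known functional site
  ({0,1} each, "on" implies "near", so a site residue scores 2 and a
  residue that is both a known and a predicted site scores 4), the same
  pair for predicted (conserved) sites, and membership of a highly
  significant (p <= 0.005) mutation cluster {0,1};
* a family component — membership of a mutation-enriched family {0,1}.

Totals therefore lie in [0, 10]; events are retained at total >= 3 by
default, with sub-threshold records kept in a secondary list.
"""

from __future__ import annotations

from typing import Optional, Sequence

from scipy.stats import binomtest, chi2_contingency
from statsmodels.stats.multitest import multipletests

from .config import Config
from .grantham import grantham_distance
from .types import (
    COMPONENT_NAMES,
    DomainStructure,
    FIERecord,
    FunctionalSiteSet,
    FunFamBundle,
    MutationCluster,
    MutationRecord,
)
from .tunable import residue_distance


def grantham_component(
    ref_aa: str, alt_aa: str, pop_vaf: Optional[float], config: Config | None = None
) -> int:
    """Substitution-impact component: 0 (polymorphic or mild), 1, or 2."""
    config = config or Config()
    if pop_vaf is not None and pop_vaf > config.polymorphism_vaf:
        return 0
    d = grantham_distance(ref_aa, alt_aa)
    if d > config.grantham_high:
        return 2
    if d > config.grantham_medium:
        return 1
    return 0


def sequence_components(
    mut: MutationRecord,
    hotspot_set: frozenset[tuple[str, int, str]] | set,
    config: Config | None = None,
) -> dict[str, int]:
    """Grantham + hotspot + disease-variant components (subtotal <= 4).

    ``hotspot_set`` must come from the target cohort: target-cohort
    hotspots are assessed independently of any builder-cohort ones.
    """
    config = config or Config()
    return {
        "grantham": grantham_component(mut.ref_aa, mut.alt_aa, mut.pop_vaf, config),
        "hotspot": int((mut.gene, mut.residue_pos, mut.alt_aa) in hotspot_set),
        "disease_variant": int(mut.disease_variant),
    }


def structure_components(
    rep_residue: int,
    sites: FunctionalSiteSet,
    clusters: Sequence[MutationCluster],
    structure: DomainStructure,
    config: Config | None = None,
) -> dict[str, int]:
    """On/near known and predicted site components plus high-significance
    cluster membership (subtotal <= 5); "on" implies "near"."""
    config = config or Config()
    cutoff = config.site_distance_cutoff

    def on_near(site_residues: frozenset[int]) -> tuple[int, int]:
        if rep_residue in site_residues:
            return 1, 1
        near = any(
            residue_distance(structure, rep_residue, s) <= cutoff
            for s in site_residues
        )
        return 0, int(near)

    on_known, near_known = on_near(sites.known_residues)
    on_pred, near_pred = on_near(sites.predicted_residues)
    in_high = any(
        rep_residue in cl.residue_ids and cl.p_value <= config.cluster_high_sig
        for cl in clusters
    )
    return {
        "on_known": on_known,
        "near_known": near_known,
        "on_predicted": on_pred,
        "near_predicted": near_pred,
        "high_sig_cluster": int(in_high),
    }


def mutfam_enrichment(
    domain_mut_count: int,
    domain_len: int,
    offdomain_mut_count: int,
    offdomain_len: int,
) -> float:
    """One-sided exact binomial p-value for domain mutation enrichment.

    Tests whether mutations concentrate in the family's domain regions
    relative to the member genes' non-domain coding length. The {0,1}
    family flag is assigned after BH correction across families
    (:func:`mutfam_flags`).
    """
    if domain_len <= 0 or offdomain_len <= 0:
        raise ValueError("region lengths must be positive")
    n = domain_mut_count + offdomain_mut_count
    if n == 0:
        return 1.0
    p0 = domain_len / (domain_len + offdomain_len)
    return float(binomtest(domain_mut_count, n, p0, alternative="greater").pvalue)


def mutfam_flags(pvalues: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Benjamini-Hochberg family-enrichment flags across families."""
    if len(pvalues) == 0:
        return []
    reject, _, _, _ = multipletests(list(pvalues), alpha=alpha, method="fdr_bh")
    return [bool(r) for r in reject]


def total_fie_score(components: dict[str, int]) -> int:
    """Sum of the nine components; validates each against its allowed set."""
    allowed = {name: (0, 1) for name in COMPONENT_NAMES}
    allowed["grantham"] = (0, 1, 2)
    missing = set(COMPONENT_NAMES) - set(components)
    if missing:
        raise ValueError(f"components missing: {sorted(missing)}")
    for name in COMPONENT_NAMES:
        if components[name] not in allowed[name]:
            raise ValueError(
                f"component {name}={components[name]} outside {allowed[name]}"
            )
    if components["on_known"] == 1 and components["near_known"] != 1:
        raise ValueError("on_known=1 requires near_known=1")
    if components["on_predicted"] == 1 and components["near_predicted"] != 1:
        raise ValueError("on_predicted=1 requires near_predicted=1")
    return sum(components[name] for name in COMPONENT_NAMES)


def annotate_family_flags(record: FIERecord, bundle: FunFamBundle) -> FIERecord:
    """Diverse-superfamily (> 10 EC numbers) and moonlighting flags."""
    record.diverse_family = bundle.ec_count_superfamily > 10
    record.moonlighting = bundle.moonlighting
    return record


def score_candidate(
    mut: MutationRecord,
    rep_residue: int,
    bundle: FunFamBundle,
    sites: FunctionalSiteSet,
    clusters: Sequence[MutationCluster],
    hotspot_set: frozenset[tuple[str, int, str]] | set,
    mutfam_flag: Optional[bool] = None,
    config: Config | None = None,
    tunable_source: str = "",
) -> FIERecord:
    """Assemble the full component map and total for one candidate."""
    config = config or Config()
    components = sequence_components(mut, hotspot_set, config)
    components.update(
        structure_components(rep_residue, sites, clusters, bundle.structure, config)
    )
    if mutfam_flag is None:
        mutfam_flag = bool(bundle.is_mutfam)
    components["mutfam"] = int(mutfam_flag)
    rec = FIERecord(
        mutation=mut,
        funfam_id=bundle.funfam_id,
        rep_residue=rep_residue,
        components=components,
        total=total_fie_score(components),
        tunable_source=tunable_source,
    )
    return annotate_family_flags(rec, bundle)


def apply_threshold(
    records: Sequence[FIERecord], config: Config | None = None
) -> tuple[list[FIERecord], list[FIERecord]]:
    """Split into (retained, below-threshold) at the FIE score threshold."""
    config = config or Config()
    t = config.fie_score_threshold
    retained = [r for r in records if r.total >= t]
    below = [r for r in records if r.total < t]
    return retained, below


def cancer_gene_enrichment(
    fie_genes: set[str], background_genes: set[str], cancer_genes: set[str]
) -> tuple[float, float]:
    """Chi-squared enrichment of FIE genes in a known cancer-gene list.

    Reporting utility only — never a filter. Returns (statistic, p).
    """
    a = len(fie_genes & cancer_genes)
    b = len(fie_genes - cancer_genes)
    other = background_genes - fie_genes
    c = len(other & cancer_genes)
    d = len(other - cancer_genes)
    stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    return float(stat), float(p)
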
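"""Component-wise FIE scoring, enrichment flags and thresholding."""

import itertools

import pytest

from funvar.config import Config
from funvar.grantham import all_pair_distances, grantham_distance
from funvar.score import (
    annotate_family_flags,
    apply_threshold,
    cancer_gene_enrichment,
    grantham_component,
    mutfam_enrichment,
    mutfam_flags,
    sequence_components,
    structure_components,
    total_fie_score,
)
from funvar.types import (
    AA20,
    Atom,
    COMPONENT_NAMES,
    DomainStructure,
    FIERecord,
    FunctionalSiteSet,
    MutationCluster,
    Residue,
    SiteEntry,
    SiteKind,
)

from conftest import make_bundle, mut


class TestGranthamComponent:
    def test_medium_impact(self):
        assert grantham_distance("L", "R") == 102
        assert grantham_component("L", "R", None) == 1

    def test_high_impact(self):
        assert grantham_distance("C", "W") == 215
        assert grantham_component("C", "W", None) == 2

    def test_polymorphism_zeroes(self):
        assert grantham_component("C", "W", 1e-3) == 0

    def test_below_medium_scores_zero(self):
        assert grantham_distance("L", "I") == 5
        assert grantham_component("L", "I", None) == 0

    def test_unknown_aa_is_error(self):
        with pytest.raises(ValueError):
            grantham_component("L", "B", None)

    def test_symmetric_over_all_pairs(self):
        for a, b in itertools.combinations(AA20, 2):
            assert grantham_distance(a, b) == grantham_distance(b, a)

    def test_matrix_size_and_extremes(self):
        v = all_pair_distances()
        assert len(v) == 190
        assert v.min() == 5 and v.max() == 215


class TestSequenceComponents:
    def test_maximal_subtotal(self):
        m = mut(gene="EGFR", pos=858, ref="C", alt="W", disease_variant=True)
        comps = sequence_components(m, {("EGFR", 858, "W")})
        assert sum(comps.values()) == 4

    def test_mild_non_hotspot_zero(self):
        comps = sequence_components(mut(ref="L", alt="I"), set())
        assert sum(comps.values()) == 0

    def test_hotspot_only(self):
        m = mut(gene="EGFR", pos=858, ref="L", alt="I")
        comps = sequence_components(m, {("EGFR", 858, "I")})
        assert comps == {"grantham": 0, "hotspot": 1, "disease_variant": 0}


def geometry(d_known=0.0, d_pred=0.0):
    """Residue 1 is the query; sites placed at controlled distances."""
    return DomainStructure(
        (
            Residue(1, "A", (Atom("CA", 0, 0, 0),)),
            Residue(2, "A", (Atom("CA", d_known, 0, 0),)),
            Residue(3, "A", (Atom("CA", 0, d_pred, 0),)),
        )
    )


def sites(known_at=2, pred_at=3, extra=()):
    entries = [SiteEntry(known_at, SiteKind.LIGAND, "t"), SiteEntry(pred_at, SiteKind.PREDICTED, "t")]
    entries += [SiteEntry(r, SiteKind(k), "t") for r, k in extra]
    return FunctionalSiteSet(tuple(entries))


class TestStructureComponents:
    def test_on_known_and_predicted_scores_four(self):
        s = geometry(10, 10)
        site_set = sites(known_at=1, pred_at=1)
        comps = structure_components(1, site_set, [], s)
        assert (
            comps["on_known"] + comps["near_known"] + comps["on_predicted"] + comps["near_predicted"]
        ) == 4

    def test_near_known_only(self):
        comps = structure_components(1, sites(), [], geometry(4.9, 40.0))
        assert comps == {
            "on_known": 0,
            "near_known": 1,
            "on_predicted": 0,
            "near_predicted": 0,
            "high_sig_cluster": 0,
        }

    def test_high_sig_cluster_independent_of_sites(self):
        cl = MutationCluster(frozenset({1}), 5, 0.004, 1)
        comps = structure_components(1, sites(), [cl], geometry(7.0, 7.0))
        assert comps["high_sig_cluster"] == 1
        assert sum(v for k, v in comps.items() if k != "high_sig_cluster") == 0

    def test_standard_tier_cluster_not_counted(self):
        cl = MutationCluster(frozenset({1}), 5, 0.02, 1)
        comps = structure_components(1, sites(), [cl], geometry(7.0, 7.0))
        assert comps["high_sig_cluster"] == 0


class TestMutfam:
    def test_extreme_enrichment(self):
        p = mutfam_enrichment(10, 10, 0, 90)
        assert p == pytest.approx(0.1**10, rel=1e-9)

    def test_proportional_not_enriched(self):
        p = mutfam_enrichment(10, 100, 90, 900)
        assert p > 0.4

    def test_zero_mutations(self):
        assert mutfam_enrichment(0, 10, 0, 90) == 1.0

    def test_bad_lengths(self):
        with pytest.raises(ValueError):
            mutfam_enrichment(1, 0, 1, 10)

    def test_bh_flags_across_families(self):
        ps = [1e-8, 0.5, 0.9, 1e-6]
        flags = mutfam_flags(ps, alpha=0.05)
        assert flags == [True, False, False, True]


def full_components(**overrides):
    comps = {name: 0 for name in COMPONENT_NAMES}
    comps.update(overrides)
    return comps


class TestTotalScore:
    def test_maximum_is_ten(self):
        comps = full_components(
            grantham=2, hotspot=1, disease_variant=1, on_known=1, near_known=1,
            on_predicted=1, near_predicted=1, high_sig_cluster=1, mutfam=1,
        )
        assert total_fie_score(comps) == 10

    def test_minimal_fie_is_one(self):
        assert total_fie_score(full_components(near_known=1)) == 1

    def test_component_sum_example(self):
        comps = full_components(grantham=1, hotspot=1, on_known=1, near_known=1)
        assert total_fie_score(comps) == 4

    def test_invalid_component_value(self):
        with pytest.raises(ValueError):
            total_fie_score(full_components(hotspot=2))

    def test_on_implies_near_enforced(self):
        with pytest.raises(ValueError):
            total_fie_score(full_components(on_known=1))

    def test_exhaustive_bounds(self):
        # every legal combination keeps sequence subtotal <= 4,
        # structure subtotal <= 5, total <= 10; 10 and 1 are attained
        totals = set()
        for g in (0, 1, 2):
            for h, d, ok, op, hc, mf in itertools.product((0, 1), repeat=6):
                comps = full_components(
                    grantham=g, hotspot=h, disease_variant=d,
                    on_known=ok, near_known=ok, on_predicted=op,
                    near_predicted=op, high_sig_cluster=hc, mutfam=mf,
                )
                t = total_fie_score(comps)
                totals.add(t)
                assert g + h + d <= 4
                assert 2 * ok + 2 * op + hc <= 5
                assert 0 <= t <= 10
        assert {1, 10} <= totals


class TestThresholdAndFlags:
    def records(self, totals):
        return [
            FIERecord(mutation=mut(pos=i + 1), funfam_id="FF", rep_residue=1, total=t)
            for i, t in enumerate(totals)
        ]

    def test_threshold_three(self):
        kept, below = apply_threshold(self.records([1, 2, 3, 4]))
        assert [r.total for r in kept] == [3, 4]
        assert [r.total for r in below] == [1, 2]

    def test_empty(self):
        assert apply_threshold([]) == ([], [])

    def test_override_to_one_keeps_all(self):
        kept, below = apply_threshold(self.records([1, 2]), Config(fie_score_threshold=1))
        assert len(kept) == 2 and below == []

    def test_monotone_in_threshold(self):
        recs = self.records([1, 2, 3, 4, 5])
        prev = None
        for t in (1, 2, 3, 4, 5, 6):
            kept, _ = apply_threshold(recs, Config(fie_score_threshold=t))
            ids = {id(r) for r in kept}
            if prev is not None:
                assert ids <= prev
            prev = ids

    @pytest.mark.parametrize(
        "ec,expected", [(11, True), (10, False), (0, False)]
    )
    def test_diverse_family_strict_inequality(self, ec, expected):
        bundle = make_bundle({"REP": "ACD"}, "REP", ec_count_superfamily=ec)
        rec = FIERecord(mutation=mut(), funfam_id="FF", rep_residue=1)
        assert annotate_family_flags(rec, bundle).diverse_family is expected

    def test_moonlighting_flag(self):
        bundle = make_bundle({"REP": "ACD"}, "REP", moonlighting=True)
        rec = FIERecord(mutation=mut(), funfam_id="FF", rep_residue=1)
        assert annotate_family_flags(rec, bundle).moonlighting is True

    def test_cancer_gene_enrichment_reports(self):
        fie = {f"G{i}" for i in range(10)}
        background = {f"G{i}" for i in range(100)}
        cancer = {f"G{i}" for i in range(8)} | {"X1"}
        stat, p = cancer_gene_enrichment(fie, background, cancer)
        assert stat > 0 and p < 0.01
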
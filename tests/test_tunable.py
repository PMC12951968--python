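"""Spatial clustering, hotspots, distances and tunable-site calling."""

import itertools

import numpy as np
import pytest

from funvar.config import Config
from funvar.mapping import aggregate_counts, build_column_map
from funvar.tunable import (
    call_fies,
    cluster_mutations,
    distance_matrix,
    find_hotspots,
    make_tunable_sites,
    residue_distance,
)
from funvar.types import (
    Atom,
    DomainStructure,
    FunctionalSiteSet,
    MutationCluster,
    Residue,
    SiteEntry,
    SiteKind,
)

from conftest import ca_chain, make_bundle, mut


class TestResidueDistance:
    def test_self_distance_zero(self):
        s = ca_chain(3)
        assert residue_distance(s, 2, 2) == 0.0

    def test_three_four_five(self):
        s = DomainStructure(
            (
                Residue(1, "A", (Atom("CA", 0, 0, 0),)),
                Residue(2, "A", (Atom("CA", 3, 4, 0),)),
            )
        )
        assert residue_distance(s, 1, 2) == pytest.approx(5.0)

    def test_multi_atom_equals_bruteforce_min(self, rng):
        residues = []
        for rid in (1, 2):
            atoms = tuple(
                Atom(f"X{i}", *rng.normal(scale=4.0, size=3)) for i in range(5)
            )
            residues.append(Residue(rid, "A", atoms))
        s = DomainStructure(tuple(residues))
        brute = min(
            np.linalg.norm(np.array([a.x, a.y, a.z]) - np.array([b.x, b.y, b.z]))
            for a in residues[0].atoms
            for b in residues[1].atoms
        )
        assert residue_distance(s, 1, 2) == pytest.approx(brute)
        assert residue_distance(s, 2, 1) == pytest.approx(brute)  # symmetric


class TestFindHotspots:
    def test_two_patients_same_type(self):
        muts = [
            mut(gene="EGFR", pos=858, ref="L", alt="R", tumor="T1", cancer="LUAD"),
            mut(gene="EGFR", pos=858, ref="L", alt="R", tumor="T2", cancer="LUAD"),
        ]
        assert ("EGFR", 858, "R") in find_hotspots(muts)

    def test_split_across_cancer_types_not_hotspot(self):
        muts = [
            mut(gene="EGFR", pos=858, ref="L", alt="R", tumor="T1", cancer="LUAD"),
            mut(gene="EGFR", pos=858, ref="L", alt="R", tumor="T2", cancer="LUSC"),
        ]
        assert find_hotspots(muts) == frozenset()

    def test_same_patient_two_samples_not_hotspot(self):
        muts = [
            mut(gene="EGFR", pos=858, ref="L", alt="R", tumor="T1", cancer="LUAD"),
            mut(gene="EGFR", pos=858, ref="L", alt="R", tumor="T1", cancer="LUAD"),
        ]
        assert find_hotspots(muts) == frozenset()


class TestClusterMutations:
    def test_planted_cluster_recovered(self):
        structure = ca_chain(50)
        counts = {24: 7, 25: 6, 26: 7}  # 20 mutations on 3 adjacent residues
        clusters = cluster_mutations(counts, structure, radius=5.0, n_perm=999, seed=11)
        top = min(clusters, key=lambda c: (c.p_value, -c.mutation_count))
        assert top.p_value <= 0.005
        assert {24, 25, 26} <= top.residue_ids

    def test_matches_exhaustive_permutation_oracle(self):
        # 6-residue chain, 4 mutations: enumerate all 6^4 uniform
        # assignments and compare the empirical p of the top cluster
        structure = ca_chain(6)
        counts = {1: 2, 2: 1, 5: 1}
        clusters = cluster_mutations(
            counts, structure, radius=5.0, n_perm=20000, seed=5
        )
        top = min(clusters, key=lambda c: c.p_value)
        obs = top.mutation_count

        ids, dmat = distance_matrix(structure)
        adj = dmat <= 5.0
        n_ge = 0
        total = 0
        for assignment in itertools.product(range(6), repeat=4):
            c = np.bincount(assignment, minlength=6)
            if (adj @ c).max() >= obs:
                n_ge += 1
            total += 1
        p_exact = n_ge / total
        assert top.p_value == pytest.approx(p_exact, abs=0.02)

    def test_zero_mutations_empty(self):
        assert cluster_mutations({}, ca_chain(10), n_perm=999, seed=0) == []

    def test_tiny_structure_trivial_cluster(self):
        s = ca_chain(1)
        (cl,) = cluster_mutations({1: 3}, s, n_perm=999, seed=0)
        assert cl.p_value == 1.0 and cl.mutation_count == 3

    def test_deterministic_under_seed(self):
        structure = ca_chain(30)
        counts = {5: 3, 6: 2, 20: 1}
        a = cluster_mutations(counts, structure, n_perm=999, seed=42)
        b = cluster_mutations(counts, structure, n_perm=999, seed=42)
        assert [(c.residue_ids, c.p_value) for c in a] == [
            (c.residue_ids, c.p_value) for c in b
        ]

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            cluster_mutations({1: 1}, ca_chain(5), n_perm=10, seed=0)


def site_set(*entries):
    return FunctionalSiteSet(
        tuple(SiteEntry(rid, SiteKind(kind), "t") for rid, kind in entries)
    )


class TestMakeTunableSites:
    def geometry(self, site_distance):
        # residues 1,2 clustered; residue 9 is the functional site at a
        # controlled distance from residue 2
        return DomainStructure(
            (
                Residue(1, "A", (Atom("CA", 0, 0, 0),)),
                Residue(2, "A", (Atom("CA", 3.8, 0, 0),)),
                Residue(9, "A", (Atom("CA", 3.8 + site_distance, 0, 0),)),
            )
        )

    def test_significant_cluster_near_site_included(self):
        s = self.geometry(3.2)
        cl = MutationCluster(frozenset({1, 2}), 10, 0.01, 1)
        (ts,) = make_tunable_sites([cl], frozenset(), site_set((9, "catalytic")), s)
        assert ts.source == "cluster"
        assert ts.min_site_distance == pytest.approx(3.2)
        assert SiteKind.CATALYTIC in ts.nearest_site_kinds

    def test_cluster_beyond_cutoff_excluded(self):
        s = self.geometry(6.1)
        cl = MutationCluster(frozenset({1, 2}), 10, 0.01, 1)
        assert make_tunable_sites([cl], frozenset(), site_set((9, "ligand")), s) == []

    def test_non_significant_cluster_excluded(self):
        s = self.geometry(1.0)
        cl = MutationCluster(frozenset({1, 2}), 10, 0.2, 1)
        assert make_tunable_sites([cl], frozenset(), site_set((9, "ligand")), s) == []

    def test_hotspot_residue_near_site(self):
        s = self.geometry(4.0)
        out = make_tunable_sites([], frozenset({2}), site_set((9, "ppi")), s)
        assert len(out) == 1 and out[0].source == "hotspot"

    def test_monotone_in_cutoff(self):
        s = self.geometry(6.1)
        cl = MutationCluster(frozenset({1, 2}), 10, 0.01, 1)
        sites = site_set((9, "ligand"))
        narrow = make_tunable_sites([cl], frozenset(), sites, s, Config(site_distance_cutoff=5.0))
        wide = make_tunable_sites([cl], frozenset(), sites, s, Config(site_distance_cutoff=7.0))
        assert len(narrow) <= len(wide) and len(wide) == 1


class TestCallFies:
    def test_self_consistency_on_toy_family(self, toy_bundle):
        from funvar.pipeline import build_tunable_sites
        from funvar.synth import make_family_mutations

        bundle, truth = toy_bundle
        muts = make_family_mutations(bundle, truth, seed=3, n_cluster_mutations=25)
        built = build_tunable_sites(bundle, muts, seed=3)
        assert built.tunable, "planted cluster should survive"
        tunable_residues = set().union(*(t.residue_ids for t in built.tunable))
        fies = call_fies(muts, built.tunable, built.cmap, bundle)
        # every mutation projecting into a tunable residue is returned
        cmap = build_column_map(bundle)
        expected = 0
        from funvar.mapping import project_to_representative

        for m in muts:
            rid = project_to_representative(m, cmap, bundle)
            if rid in tunable_residues:
                expected += 1
        assert len(fies) == expected > 0

    def test_outside_tunable_not_called(self):
        bundle = make_bundle({"REP": "ACDEF"}, "REP", sites=[(1, "ligand")])
        cmap = build_column_map(bundle)
        from funvar.types import TunableSite

        ts = TunableSite(frozenset({1}), 0.0, "cluster", frozenset())
        inside = mut(pid="REP", pos=1, ref="A", alt="V")
        outside = mut(pid="REP", pos=5, ref="F", alt="L")
        out = call_fies([inside, outside], [ts], cmap, bundle)
        assert [(m.residue_pos, rid) for m, rid, _ in out] == [(1, 1)]
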
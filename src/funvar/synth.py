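"""Self-contained synthetic fixtures for every pipeline stage.

The generators state a small but complete world: a toy functional
family whose representative is a Ca-trace chain (3.8 Å between
consecutive residues) carrying a planted spatial cluster coiled around
a planted functional site; a tumor cohort with allele-specific copy
numbers realizing all three duplication-timing scenarios and planted
pre/post mutation copy numbers (~2 pre, ~1 post); and null families
with uniformly scattered mutations for cluster-significance
calibration. Cohort defaults mirror the published setting: whole-genome
doubling in ~75% of tumors, pre-duplication events concentrated in a
handful of driver genes while post-duplication events spread over many
genes, and mostly clonal mutations. All randomness flows through one
seeded generator; equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data.IUPACData import protein_letters_1to3

from .types import (
    AA20,
    Atom,
    Clonality,
    DomainStructure,
    FunctionalSiteSet,
    FunFamBundle,
    MutationRecord,
    Residue,
    SiteEntry,
    SiteKind,
    TimingClass,
)

CA_SPACING = 3.8  # Å, canonical consecutive Ca-Ca distance


@dataclass
class PlantedTruth:
    """Ground truth the generators committed to."""

    cluster_residues: frozenset[int] = frozenset()
    site_residues: frozenset[int] = frozenset()
    hotspot_tuples: frozenset[tuple[str, int, str]] = frozenset()
    mutations: list[MutationRecord] = field(default_factory=list)
    timing: dict[tuple[str, str, int], TimingClass] = field(default_factory=dict)
    diversity_ordering: Optional[str] = None  # e.g. "post>pre"


def _linear_chain(n: int, start_id: int = 1) -> list[tuple[int, np.ndarray]]:
    return [
        (start_id + i, np.array([CA_SPACING * i, 0.0, 0.0])) for i in range(n)
    ]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def make_toy_funfam(
    seed: int = 0,
    n_members: int = 6,
    n_columns: int = 40,
    n_planted_cluster_residues: int = 3,
    site_positions: Sequence[int] = (20,),
    gap_rate: float = 0.1,
    ec_count_superfamily: int = 0,
    moonlighting: bool = False,
) -> tuple[FunFamBundle, PlantedTruth]:
    """A toy family with a planted cluster coiled around a planted site.

    The representative is ungapped (identity seq->struct map). The first
    planted site residue sits at the center of a small ring carrying the
    planted cluster residues (all mutually and site-wise within 5 Å),
    displaced 12 Å off the main chain so no other residue comes near.
    """
    if n_columns < n_planted_cluster_residues + len(site_positions):
        raise ValueError("n_columns too small for the requested plant")
    if not site_positions:
        raise ValueError("need at least one site position")
    s = int(site_positions[0])
    k = n_planted_cluster_residues
    if not 1 <= s <= n_columns - k + 1:
        raise ValueError(
            f"infeasible geometry: site {s} leaves no room for {k} cluster residues"
        )
    rng = np.random.default_rng(seed)

    cluster_ids = list(range(s, s + k))
    center = np.array([CA_SPACING * (s - 1), 12.0, 0.0])
    coords: dict[int, np.ndarray] = {rid: xyz for rid, xyz in _linear_chain(n_columns)}
    coords[s] = center
    ring = [rid for rid in cluster_ids if rid != s]
    for j, rid in enumerate(ring):
        theta = 2.0 * math.pi * j / max(len(ring), 1)
        coords[rid] = center + 2.0 * np.array([math.cos(theta), math.sin(theta), 0.0])

    rep_seq = _random_seq(rng, n_columns)
    residues = tuple(
        Residue(rid, rep_seq[rid - 1], (Atom("CA", *coords[rid]),))
        for rid in range(1, n_columns + 1)
    )
    structure = DomainStructure(residues)

    rep_id = "REP_P00"
    alignment = {rep_id: rep_seq}
    for i in range(1, n_members):
        row = list(rep_seq)
        for c in range(n_columns):
            if rng.random() < 0.2:  # ~80% identity to the representative
                row[c] = rng.choice([a for a in AA20 if a != row[c]])
            if rng.random() < gap_rate:
                row[c] = "-"
        alignment[f"MEM_P{i:02d}"] = "".join(row)

    sites = FunctionalSiteSet(
        tuple(
            SiteEntry(int(p), SiteKind.LIGAND, "planted")
            for p in sorted(site_positions)
        )
    )
    bundle = FunFamBundle(
        funfam_id="FF_TOY",
        superfamily_id="SF_TOY",
        alignment=alignment,
        representative_id=rep_id,
        structure=structure,
        seq_to_struct={i: i for i in range(1, n_columns + 1)},
        known_sites=sites,
        ec_count_superfamily=ec_count_superfamily,
        moonlighting=moonlighting,
    )
    truth = PlantedTruth(
        cluster_residues=frozenset(cluster_ids),
        site_residues=frozenset(int(p) for p in site_positions),
    )
    return bundle, truth


def make_family_mutations(
    bundle: FunFamBundle,
    truth: PlantedTruth,
    seed: int = 0,
    n_cluster_mutations: int = 20,
    n_background_mutations: int = 0,
    cancer_types: Sequence[str] = ("LUAD", "LUSC"),
) -> list[MutationRecord]:
    """Mutations planted on the truth's cluster residues (plus optional
    uniform background), drawn across members, tumors and cancer types.

    Only ungapped member positions aligned to the target residue are
    used, so every planted mutation projects and matches its reference.
    """
    from .mapping import build_column_map  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    cmap = build_column_map(bundle)
    rep = cmap[bundle.representative_id]
    struct_to_seq = {v: k for k, v in bundle.seq_to_struct.items()}

    def draw(rid: int, idx: int) -> Optional[MutationRecord]:
        col = rep.pos_to_col[struct_to_seq[rid]]
        candidates = [
            pid
            for pid in bundle.members
            if col in cmap[pid].col_to_pos
            and bundle.alignment[pid][col - 1].upper() in AA20
        ]
        if not candidates:
            return None
        pid = candidates[int(rng.integers(len(candidates)))]
        pos = cmap[pid].col_to_pos[col]
        ref = bundle.alignment[pid][col - 1].upper()
        alt = rng.choice([a for a in AA20 if a != ref])
        return MutationRecord(
            tumor_id=f"T{idx:03d}",
            cancer_type=str(rng.choice(list(cancer_types))),
            gene=f"G{pid[-2:]}",  # one synthetic gene per paralog member
            protein_id=pid,
            residue_pos=pos,
            ref_aa=ref,
            alt_aa=str(alt),
        )

    muts: list[MutationRecord] = []
    cluster = sorted(truth.cluster_residues)
    i = 0
    while len(muts) < n_cluster_mutations:
        rid = cluster[int(rng.integers(len(cluster)))]
        m = draw(rid, i)
        i += 1
        if m is not None:
            muts.append(m)
    n_bg = 0
    all_res = list(bundle.structure.residue_ids)
    while n_bg < n_background_mutations:
        rid = all_res[int(rng.integers(len(all_res)))]
        m = draw(rid, i)
        i += 1
        if m is not None:
            muts.append(m)
            n_bg += 1
    truth.mutations = muts
    return muts


def make_null_funfam(
    seed: int = 0, n_residues: int = 50, n_mutations: int = 50
) -> tuple[DomainStructure, dict[int, int]]:
    """Linear-chain structure with mutations scattered uniformly, for
    cluster-significance calibration. No sites are planted."""
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    rng = np.random.default_rng(seed)
    chain = _linear_chain(n_residues)
    structure = DomainStructure(
        tuple(Residue(rid, "A", (Atom("CA", *xyz),)) for rid, xyz in chain)
    )
    draws = rng.integers(1, n_residues + 1, size=n_mutations)
    counts: dict[int, int] = {}
    for rid in draws:
        counts[int(rid)] = counts.get(int(rid), 0) + 1
    return structure, counts


_DEFAULT_GENES = tuple(f"GENE{i:02d}" for i in range(1, 31))


def make_cohort(
    seed: int = 0,
    n_tumors: int = 60,
    genes: Sequence[str] = _DEFAULT_GENES,
    frac_wgd: float = 0.75,
    pre_rate: float = 1.0,
    post_rate: float = 1.0,
    background_rate: float = 2.0,
    clonal_frac: float = 0.8,
    noise: float = 0.0,
    n_pre_genes: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """A tumor cohort with planted duplication-timing structure.

    Whole-genome doubling is planted in ``frac_wgd`` of tumors (the
    published NSCLC fraction, ~75%); gained genes realize all three
    timing scenarios. Pre-duplication mutations (copy number ~2, plus
    optional Gaussian noise) concentrate in the first ``n_pre_genes``
    genes — emulating recurrent early drivers — while post-duplication
    mutations (~1 copy) spread uniformly over all genes, the planted
    ordering behind the expected higher post-duplication diversity.
    Per-tumor mutation counts are Poisson with the stated rates.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    pre_genes = genes[:n_pre_genes]
    truth = PlantedTruth(diversity_ordering="post>pre")
    mut_rows = []
    cn_rows = []
    scenarios = [(2, 2), (2, 0), (2, 1)]  # biallelic, LOH, no-LOH gains

    for t in range(n_tumors):
        tumor = f"TUM{t:03d}"
        cancer_type = "LUAD" if t % 2 == 0 else "LUSC"
        wgd = rng.random() < frac_wgd
        gene_cn: dict[str, tuple[int, int]] = {}
        for g in genes:
            if wgd:
                gene_cn[g] = scenarios[int(rng.integers(3))]
            else:
                gene_cn[g] = (1, 1)
        for g, (major, minor) in gene_cn.items():
            cn_rows.append(
                {"tumor_id": tumor, "gene": g, "major_cn": major, "minor_cn": minor}
            )

        def add_mut(gene: str, mut_cn: float, klass: TimingClass) -> None:
            pos = int(rng.integers(1, 301))
            ref = rng.choice(list(AA20))
            alt = rng.choice([a for a in AA20 if a != ref])
            clon = "clonal" if rng.random() < clonal_frac else "subclonal"
            mut_rows.append(
                {
                    "tumor_id": tumor,
                    "cancer_type": cancer_type,
                    "gene": gene,
                    "protein_id": f"{gene}_P",
                    "residue_pos": pos,
                    "ref_aa": str(ref),
                    "alt_aa": str(alt),
                    "mutation_cn": round(max(mut_cn, 0.0), 4),
                    "clonality": clon,
                }
            )
            truth.timing[(tumor, gene, pos)] = klass

        timable = [g for g in genes if gene_cn[g][0] >= 2 and gene_cn[g][1] != 1]
        timable_pre = [g for g in pre_genes if gene_cn[g][0] >= 2]
        if timable_pre:
            for _ in range(rng.poisson(pre_rate)):
                g = timable_pre[int(rng.integers(len(timable_pre)))]
                add_mut(g, 2.0 + noise * rng.standard_normal(), TimingClass.PRE)
        if timable:
            for _ in range(rng.poisson(post_rate)):
                g = timable[int(rng.integers(len(timable)))]
                add_mut(g, 1.0 + noise * rng.standard_normal(), TimingClass.POST)
        ungained = [g for g in genes if gene_cn[g][0] < 2]
        if ungained:
            for _ in range(rng.poisson(background_rate)):
                g = ungained[int(rng.integers(len(ungained)))]
                add_mut(g, 1.0, TimingClass.NO_GAIN)

    mut_df = pd.DataFrame(
        mut_rows,
        columns=[
            "tumor_id",
            "cancer_type",
            "gene",
            "protein_id",
            "residue_pos",
            "ref_aa",
            "alt_aa",
            "mutation_cn",
            "clonality",
        ],
    )
    cn_df = pd.DataFrame(
        cn_rows, columns=["tumor_id", "gene", "major_cn", "minor_cn"]
    )
    return mut_df, cn_df, truth


def write_bundle(bundle: FunFamBundle, directory: str | Path) -> None:
    """Write a bundle directory readable by core_io (deterministic bytes)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "alignment.fasta", "w") as fh:
        for pid, row in bundle.alignment.items():
            fh.write(f">{pid}\n{row}\n")
    with open(d / "structure.pdb", "w") as fh:
        serial = 1
        for res in bundle.structure.residues:
            aa3 = protein_letters_1to3.get(res.aa, "Unk").upper()
            for atom in res.atoms:
                name = atom.name.ljust(3)
                fh.write(
                    f"ATOM  {serial:5d}  {name}{aa3} A{res.residue_id:4d}    "
                    f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}  1.00  0.00\n"
                )
                serial += 1
        fh.write("END\n")
    with open(d / "sites.tsv", "w") as fh:
        fh.write("residue_id\tsite_kind\tprovenance\n")
        for e in bundle.known_sites.entries:
            fh.write(f"{e.residue_id}\t{e.site_kind.value}\t{e.provenance}\n")
    meta = {
        "funfam_id": bundle.funfam_id,
        "superfamily_id": bundle.superfamily_id,
        "representative_id": bundle.representative_id,
        "seq_to_struct": {int(k): int(v) for k, v in sorted(bundle.seq_to_struct.items())},
        "ec_count_superfamily": int(bundle.ec_count_superfamily),
        "moonlighting": bool(bundle.moonlighting),
        "is_mutfam": bundle.is_mutfam,
    }
    (d / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def mutations_to_records(df: pd.DataFrame) -> list[MutationRecord]:
    """Convert a generated cohort frame to records without a file round-trip."""
    out = []
    for _, row in df.iterrows():
        out.append(
            MutationRecord(
                tumor_id=row["tumor_id"],
                cancer_type=row["cancer_type"],
                gene=row["gene"],
                protein_id=row["protein_id"],
                residue_pos=int(row["residue_pos"]),
                ref_aa=row["ref_aa"],
                alt_aa=row["alt_aa"],
                mutation_cn=float(row["mutation_cn"]) if "mutation_cn" in row else None,
                clonality=Clonality(row.get("clonality", "unknown")),
            )
        )
    return out
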
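"""Readers and writers for mutation tables, copy-number states and
functional-family bundles.

A bundle directory contains::

    alignment.fasta   gapped family alignment ("-" gaps)
    structure.pdb     representative domain (PDB or mmCIF, Ca-only accepted)
    sites.tsv         residue_id <tab> site_kind <tab> provenance
    metadata.yaml     funfam_id, superfamily_id, representative_id,
                      seq_to_struct, ec_count_superfamily, moonlighting,
                      is_mutfam
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .types import (
    AA20,
    COMPONENT_NAMES,
    Atom,
    Clonality,
    CopyNumberState,
    DomainStructure,
    FIERecord,
    FunctionalSiteSet,
    FunFamBundle,
    MutationRecord,
    Residue,
    SiteEntry,
    SiteKind,
    TimingClass,
)

log = logging.getLogger("funvar")


class ParseError(ValueError):
    """Raised on malformed input with file/line context."""


_MINIMAL_COLUMNS = {
    "tumor_id",
    "cancer_type",
    "gene",
    "protein_id",
    "residue_pos",
    "ref_aa",
    "alt_aa",
}

# MAF-style column names mapped onto the minimal dialect.
_MAF_RENAME = {
    "Tumor_Sample_Barcode": "tumor_id",
    "Cancer_Type": "cancer_type",
    "Hugo_Symbol": "gene",
    "SWISSPROT": "protein_id",
    "Protein_position": "residue_pos",
    "Reference_AA": "ref_aa",
    "Tumor_AA": "alt_aa",
    "Mutation_CN": "mutation_cn",
    "Clonality": "clonality",
    "gnomAD_VAF": "pop_vaf",
    "Disease_Variant": "disease_variant",
    "Expressed": "expressed",
    "Region": "region",
}

_OPTIONAL_COLUMNS = (
    "mutation_cn",
    "clonality",
    "pop_vaf",
    "disease_variant",
    "expressed",
    "region",
)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and value.strip() in {"", "NA", "."}:
        return None
    return float(value)


def _opt_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"", "na", "."}:
        return None
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"cannot interpret boolean {value!r}")


def read_mutations(path: str | Path, dialect: str = "tsv_minimal") -> list[MutationRecord]:
    """Read a missense mutation table.

    Rows whose ref and alt amino acids coincide (synonymous) or whose alt
    is a stop ("*", nonsense) are dropped with a logged count. Malformed
    rows raise :class:`ParseError` naming the 1-based file line.
    """
    path = Path(path)
    if dialect not in {"tsv_minimal", "maf_like"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if dialect == "maf_like":
        df = df.rename(columns=_MAF_RENAME)
    missing = _MINIMAL_COLUMNS - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    for col in _OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = None

    records: list[MutationRecord] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        ref, alt = str(row["ref_aa"]).strip(), str(row["alt_aa"]).strip()
        if ref == alt or alt == "*" or ref == "*":
            n_dropped += 1
            continue
        try:
            clon = Clonality(str(row["clonality"]).strip().lower()) if (
                row["clonality"] is not None and not pd.isna(row["clonality"])
                and str(row["clonality"]).strip() not in {"", "NA", "."}
            ) else Clonality.UNKNOWN
            pos = int(str(row["residue_pos"]).strip())
            rec = MutationRecord(
                tumor_id=str(row["tumor_id"]),
                cancer_type=str(row["cancer_type"]),
                gene=str(row["gene"]),
                protein_id=str(row["protein_id"]),
                residue_pos=pos,
                ref_aa=ref,
                alt_aa=alt,
                mutation_cn=_opt_float(row["mutation_cn"]),
                clonality=clon,
                pop_vaf=_opt_float(row["pop_vaf"]),
                disease_variant=bool(_opt_bool(row["disease_variant"]) or False),
                expressed=_opt_bool(row["expressed"]),
                region=None if row["region"] is None or pd.isna(row["region"]) else str(row["region"]),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}, line {line_no}: {exc}") from exc
        records.append(rec)
    if n_dropped:
        log.info("read_mutations(%s): dropped %d non-missense rows", path, n_dropped)
    return records


def read_copy_number(path: str | Path) -> list[CopyNumberState]:
    """Read per-(tumor, gene) allele-specific copy numbers.

    major/minor are normalized so major >= minor; reversed rows are
    swapped with a warning. Negative copy numbers raise ParseError.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"tumor_id", "gene", "major_cn", "minor_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    states: list[CopyNumberState] = []
    for idx, row in df.iterrows():
        line_no = idx + 2
        major, minor = int(row["major_cn"]), int(row["minor_cn"])
        if major < 0 or minor < 0:
            raise ParseError(
                f"{path}, line {line_no}: negative copy number ({major}, {minor})"
            )
        if major < minor:
            warnings.warn(
                f"{path}, line {line_no}: major_cn < minor_cn; swapping",
                stacklevel=2,
            )
            major, minor = minor, major
        region = str(row["region"]) if "region" in df.columns and not pd.isna(row.get("region")) else None
        states.append(
            CopyNumberState(
                tumor_id=str(row["tumor_id"]),
                gene=str(row["gene"]),
                major_cn=major,
                minor_cn=minor,
                region=region,
            )
        )
    return states


def _parse_structure(path: Path, min_plddt: Optional[float] = None) -> DomainStructure:
    if path.suffix.lower() in {".cif", ".mmcif"}:
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("rep", str(path)).get_models())
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.id[0].strip():  # skip heteroatoms / waters
                continue
            aa3 = res.get_resname().strip().upper()
            aa = protein_letters_3to1.get(aa3, "X")
            atoms = tuple(
                Atom(a.get_name(), *map(float, a.coord))
                for a in res
                if a.element != "H"
            )
            if not atoms:
                continue
            if min_plddt is not None:
                # AlphaFold-style models carry pLDDT in the B-factor column.
                plddt = max(a.get_bfactor() for a in res)
                if plddt < min_plddt:
                    continue
            residues.append(Residue(res.id[1], aa, atoms))
    if not residues:
        raise ParseError(f"{path}: no polymer residues parsed")
    return DomainStructure(tuple(residues))


def read_sites(path: str | Path, structure: DomainStructure) -> FunctionalSiteSet:
    df = pd.read_csv(path, sep="\t")
    required = {"residue_id", "site_kind"}
    if required - set(df.columns):
        raise ParseError(f"{path}: needs columns residue_id, site_kind")
    entries = []
    bad = []
    known_ids = set(structure.residue_ids)
    for _, row in df.iterrows():
        rid = int(row["residue_id"])
        if rid not in known_ids:
            bad.append(rid)
            continue
        prov = str(row["provenance"]) if "provenance" in df.columns and not pd.isna(row.get("provenance")) else ""
        entries.append(SiteEntry(rid, SiteKind(str(row["site_kind"])), prov))
    if bad:
        raise ParseError(f"{path}: site residues absent from structure: {sorted(set(bad))}")
    return FunctionalSiteSet(tuple(entries))


def read_funfam_bundle(directory: str | Path, min_plddt: Optional[float] = None) -> FunFamBundle:
    """Load a functional-family bundle from a directory (see module doc)."""
    d = Path(directory)
    fasta = d / "alignment.fasta"
    meta_path = d / "metadata.yaml"
    struct_path = next(
        (p for p in (d / "structure.pdb", d / "structure.cif") if p.exists()), None
    )
    for p in (fasta, meta_path):
        if not p.exists():
            raise ParseError(f"bundle {d}: missing {p.name}")
    if struct_path is None:
        raise ParseError(f"bundle {d}: missing structure.pdb / structure.cif")

    alignment = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    if not alignment:
        raise ParseError(f"{fasta}: no sequences")
    meta = yaml.safe_load(meta_path.read_text())
    structure = _parse_structure(struct_path, min_plddt=min_plddt)
    sites_path = d / "sites.tsv"
    sites = read_sites(sites_path, structure) if sites_path.exists() else FunctionalSiteSet(())
    try:
        return FunFamBundle(
            funfam_id=str(meta["funfam_id"]),
            superfamily_id=str(meta.get("superfamily_id", "")),
            alignment=alignment,
            representative_id=str(meta["representative_id"]),
            structure=structure,
            seq_to_struct={int(k): int(v) for k, v in meta["seq_to_struct"].items()},
            known_sites=sites,
            ec_count_superfamily=int(meta.get("ec_count_superfamily", 0)),
            moonlighting=bool(meta.get("moonlighting", False)),
            is_mutfam=meta.get("is_mutfam"),
        )
    except (KeyError, ValueError) as exc:
        raise ParseError(f"bundle {d}: {exc}") from exc


_FIE_COLUMNS = [
    "tumor_id",
    "cancer_type",
    "gene",
    "funfam_id",
    "protein_id",
    "residue_pos",
    "rep_residue",
    "ref_aa",
    "alt_aa",
    "mutation_cn",
    "clonality",
    *COMPONENT_NAMES,
    "total",
    "timing",
    "diverse_family",
    "moonlighting",
    "tunable_source",
]


def write_fie_table(records: list[FIERecord], path: str | Path) -> None:
    """Write scored FIE records as a TSV with a stable column order."""
    rows = []
    for r in records:
        m = r.mutation
        row = {
            "tumor_id": m.tumor_id,
            "cancer_type": m.cancer_type,
            "gene": m.gene,
            "funfam_id": r.funfam_id,
            "protein_id": m.protein_id,
            "residue_pos": m.residue_pos,
            "rep_residue": r.rep_residue,
            "ref_aa": m.ref_aa,
            "alt_aa": m.alt_aa,
            "mutation_cn": m.mutation_cn,
            "clonality": m.clonality.value,
            "total": r.total,
            "timing": r.timing.value,
            "diverse_family": r.diverse_family,
            "moonlighting": r.moonlighting,
            "tunable_source": r.tunable_source,
        }
        row.update({c: r.components.get(c, 0) for c in COMPONENT_NAMES})
        rows.append(row)
    df = pd.DataFrame(rows, columns=_FIE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_fie_table(path: str | Path) -> list[FIERecord]:
    """Inverse of :func:`write_fie_table` (lossy only in mutation payload)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        mut = MutationRecord(
            tumor_id=str(row["tumor_id"]),
            cancer_type=str(row["cancer_type"]),
            gene=str(row["gene"]),
            protein_id=str(row["protein_id"]),
            residue_pos=int(row["residue_pos"]),
            ref_aa=str(row["ref_aa"]),
            alt_aa=str(row["alt_aa"]),
            mutation_cn=_opt_float(row.get("mutation_cn")),
            clonality=Clonality(str(row["clonality"]))
            if "clonality" in df.columns and not pd.isna(row["clonality"])
            else Clonality.UNKNOWN,
        )
        components = {c: int(row[c]) for c in COMPONENT_NAMES}
        out.append(
            FIERecord(
                mutation=mut,
                funfam_id=str(row["funfam_id"]),
                rep_residue=int(row["rep_residue"]),
                components=components,
                total=int(row["total"]),
                timing=TimingClass(str(row["timing"])),
                diverse_family=bool(row["diverse_family"]),
                moonlighting=bool(row["moonlighting"]),
                tunable_source=str(row["tunable_source"]) if not pd.isna(row["tunable_source"]) else "",
            )
        )
    return out
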
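"""Project mutations and site annotations through the family alignment
onto the representative domain structure.

Mutations observed in any paralog member are carried to the alignment
column of their sequence position and from there to the representative's
residue at that column; the family therefore aggregates evidence from
different genes and tumor types at structurally equivalent positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .types import (
    GAP_CHARS,
    FunctionalSiteSet,
    FunFamBundle,
    MutationRecord,
    SiteEntry,
    SiteKind,
)

log = logging.getLogger("funvar")


@dataclass(frozen=True)
class MemberMap:
    """Bijection between ungapped sequence positions and alignment columns."""

    pos_to_col: dict[int, int]
    col_to_pos: dict[int, int]

    def __len__(self) -> int:
        return len(self.pos_to_col)


class ColumnMap:
    """Per-member position<->column bijections for one family alignment."""

    def __init__(self, members: dict[str, MemberMap]):
        self._members = members

    def __getitem__(self, protein_id: str) -> MemberMap:
        try:
            return self._members[protein_id]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} is not a family member") from None

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._members

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self._members)


def build_column_map(bundle: FunFamBundle) -> ColumnMap:
    """Derive each member's position<->column bijection from its gapped row."""
    members = {}
    for pid, row in bundle.alignment.items():
        pos_to_col: dict[int, int] = {}
        pos = 0
        for col, char in enumerate(row, start=1):
            if char not in GAP_CHARS:
                pos += 1
                pos_to_col[pos] = col
        members[pid] = MemberMap(pos_to_col, {c: p for p, c in pos_to_col.items()})
    return ColumnMap(members)


def project_to_representative(
    mut: MutationRecord, cmap: ColumnMap, bundle: FunFamBundle
) -> int | None:
    """Structure residue_id aligned to the mutation, or None when the
    representative is gapped at that column / the position is unmapped."""
    member = cmap[mut.protein_id]
    col = member.pos_to_col.get(mut.residue_pos)
    if col is None:
        raise ValueError(
            f"position {mut.residue_pos} outside ungapped length of "
            f"{mut.protein_id} ({len(member)})"
        )
    rep = cmap[bundle.representative_id]
    rep_pos = rep.col_to_pos.get(col)
    if rep_pos is None:
        return None
    return bundle.seq_to_struct.get(rep_pos)


def member_residue_at(mut: MutationRecord, bundle: FunFamBundle) -> str:
    """Amino acid recorded in the member's alignment row at the mutation."""
    cmap_member = build_column_map(bundle)[mut.protein_id]
    col = cmap_member.pos_to_col[mut.residue_pos]
    return bundle.alignment[mut.protein_id][col - 1]


@dataclass
class AggregatedCounts:
    """Mutation counts per representative-structure residue.

    ``table`` is a long-format frame (residue_id, gene, cancer_type,
    count); ``per_residue`` collapses it. Mutations that cannot be
    projected (representative gap / unmapped position) are returned in
    ``unprojectable``; ref-mismatched mutations (alignment row disagrees
    with the recorded reference amino acid) are excluded and listed in
    ``ref_mismatch``.
    """

    per_residue: dict[int, int]
    table: pd.DataFrame
    unprojectable: list[MutationRecord] = field(default_factory=list)
    ref_mismatch: list[MutationRecord] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.per_residue.values())


def aggregate_counts(
    muts: list[MutationRecord],
    cmap: ColumnMap,
    bundle: FunFamBundle,
    exclude_ref_mismatch: bool = True,
) -> AggregatedCounts:
    """Aggregate member mutations onto representative-structure residues."""
    rows = []
    unprojectable: list[MutationRecord] = []
    mismatched: list[MutationRecord] = []
    for mut in muts:
        member = cmap[mut.protein_id]
        col = member.pos_to_col.get(mut.residue_pos)
        if col is None:
            raise ValueError(
                f"position {mut.residue_pos} outside ungapped length of {mut.protein_id}"
            )
        row_char = bundle.alignment[mut.protein_id][col - 1].upper()
        if exclude_ref_mismatch and row_char != mut.ref_aa:
            mismatched.append(mut)
            continue
        rid = project_to_representative(mut, cmap, bundle)
        if rid is None:
            unprojectable.append(mut)
            continue
        rows.append((rid, mut.gene, mut.cancer_type))
    if mismatched:
        log.info(
            "aggregate_counts: excluded %d ref-mismatched mutations", len(mismatched)
        )
    if rows:
        table = (
            pd.DataFrame(rows, columns=["residue_id", "gene", "cancer_type"])
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["residue_id", "gene", "cancer_type"])
            .reset_index(drop=True)
        )
    else:
        table = pd.DataFrame(columns=["residue_id", "gene", "cancer_type", "count"])
    per_residue: dict[int, int] = {}
    for rid, _, _ in rows:
        per_residue[rid] = per_residue.get(rid, 0) + 1
    return AggregatedCounts(
        per_residue=per_residue,
        table=table,
        unprojectable=unprojectable,
        ref_mismatch=mismatched,
    )


def project_sites(
    bundle: FunFamBundle, predicted_columns: set[int] | frozenset[int] = frozenset()
) -> FunctionalSiteSet:
    """Known sites plus conservation-predicted columns on the representative.

    Predicted columns gapped in the representative are dropped (logged).
    Duplicate (residue, kind) pairs are deduplicated.
    """
    cmap = build_column_map(bundle)
    rep = cmap[bundle.representative_id]
    entries: dict[tuple[int, SiteKind], SiteEntry] = {
        (e.residue_id, e.site_kind): e for e in bundle.known_sites.entries
    }
    dropped = []
    for col in sorted(predicted_columns):
        rep_pos = rep.col_to_pos.get(col)
        rid = bundle.seq_to_struct.get(rep_pos) if rep_pos is not None else None
        if rid is None:
            dropped.append(col)
            continue
        key = (rid, SiteKind.PREDICTED)
        entries.setdefault(key, SiteEntry(rid, SiteKind.PREDICTED, "conservation"))
    if dropped:
        log.info("project_sites: dropped %d predicted columns gapped in representative", len(dropped))
    ordered = sorted(entries.values(), key=lambda e: (e.residue_id, e.site_kind.value))
    return FunctionalSiteSet(tuple(ordered))
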
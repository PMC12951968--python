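"""Core domain types shared by every pipeline stage.

The central objects are the somatic :class:`MutationRecord`, the
per-(tumor, gene) allele-specific :class:`CopyNumberState`, and the
:class:`FunFamBundle` — a functional family (alignment + representative
domain structure + residue maps + functional-site annotations) onto which
mutations from all paralog members are aggregated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")


class Clonality(str, Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"
    UNKNOWN = "unknown"


class SiteKind(str, Enum):
    LIGAND = "ligand"
    NUCLEIC_ACID = "nucleic_acid"
    PPI = "ppi"
    CATALYTIC = "catalytic"
    PREDICTED = "predicted"


KNOWN_SITE_KINDS = frozenset(
    {SiteKind.LIGAND, SiteKind.NUCLEIC_ACID, SiteKind.PPI, SiteKind.CATALYTIC}
)


class TimingClass(str, Enum):
    PRE = "pre"
    POST = "post"
    UNTIMED = "untimed"
    NO_GAIN = "no_gain"


class TimingScenario(str, Enum):
    BIALLELIC_GAIN = "biallelic_gain"
    MONOALLELIC_LOH = "monoallelic_LOH"
    MONOALLELIC_NOLOH = "monoallelic_noLOH"
    NO_GAIN = "no_gain"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic missense mutation.

    ``residue_pos`` is 1-based in the canonical protein sequence.
    ``mutation_cn`` is the estimated number of chromosomal copies carrying
    the mutation (``None`` when unavailable). ``pop_vaf`` is the population
    (e.g. gnomAD) variant allele frequency used by the polymorphism rule.
    """

    tumor_id: str
    cancer_type: str
    gene: str
    protein_id: str
    residue_pos: int
    ref_aa: str
    alt_aa: str
    mutation_cn: Optional[float] = None
    clonality: Clonality = Clonality.UNKNOWN
    pop_vaf: Optional[float] = None
    disease_variant: bool = False
    expressed: Optional[bool] = None
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"not a missense change: {self.ref_aa}->{self.alt_aa} "
                f"at {self.gene} position {self.residue_pos}"
            )
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AA20:
                raise ValueError(f"unknown amino acid code {aa!r}")
        if self.residue_pos < 1:
            raise ValueError(f"residue_pos must be >= 1, got {self.residue_pos}")
        if self.pop_vaf is not None and not (0.0 <= self.pop_vaf <= 1.0):
            raise ValueError(f"pop_vaf outside [0,1]: {self.pop_vaf}")
        if self.mutation_cn is not None and self.mutation_cn < 0:
            raise ValueError(f"mutation_cn must be non-negative: {self.mutation_cn}")


@dataclass(frozen=True)
class CopyNumberState:
    """Allele-specific copy number of one gene in one tumor (region)."""

    tumor_id: str
    gene: str
    major_cn: int
    minor_cn: int
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.minor_cn < 0 or self.major_cn < 0:
            raise ValueError(
                f"negative copy number for {self.tumor_id}/{self.gene}: "
                f"major={self.major_cn}, minor={self.minor_cn}"
            )
        if self.major_cn < self.minor_cn:
            raise ValueError(
                f"major_cn < minor_cn for {self.tumor_id}/{self.gene}; "
                "normalize before constructing"
            )


@dataclass(frozen=True)
class Atom:
    name: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass(frozen=True)
class Residue:
    residue_id: int
    aa: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"residue {self.residue_id} has no atoms")


@dataclass(frozen=True)
class DomainStructure:
    """Ordered residues of one representative domain structure.

    ``residue_id`` is the author numbering from the coordinate file; it is
    never inferred from list order.
    """

    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        ids = [r.residue_id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate residue_ids in structure")

    @property
    def residue_ids(self) -> tuple[int, ...]:
        return tuple(r.residue_id for r in self.residues)

    def residue(self, residue_id: int) -> Residue:
        try:
            return self._by_id[residue_id]
        except AttributeError:
            object.__setattr__(
                self, "_by_id", {r.residue_id: r for r in self.residues}
            )
            return self._by_id[residue_id]

    def __contains__(self, residue_id: int) -> bool:
        return residue_id in {r.residue_id for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteEntry:
    residue_id: int
    site_kind: SiteKind
    provenance: str = ""


@dataclass(frozen=True)
class FunctionalSiteSet:
    """Functional-site annotations on representative-structure residues."""

    entries: tuple[SiteEntry, ...]

    def residues_of_kind(self, *kinds: SiteKind) -> frozenset[int]:
        ks = set(kinds)
        return frozenset(e.residue_id for e in self.entries if e.site_kind in ks)

    @property
    def known_residues(self) -> frozenset[int]:
        return self.residues_of_kind(*KNOWN_SITE_KINDS)

    @property
    def predicted_residues(self) -> frozenset[int]:
        return self.residues_of_kind(SiteKind.PREDICTED)

    @property
    def all_residues(self) -> frozenset[int]:
        return frozenset(e.residue_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FunFamBundle:
    """A functional family: alignment, representative structure and maps.

    ``alignment`` maps member protein accession -> gapped row (equal
    lengths). ``seq_to_struct`` maps 1-based ungapped positions of the
    representative sequence onto structure residue_ids.
    """

    funfam_id: str
    superfamily_id: str
    alignment: dict[str, str]
    representative_id: str
    structure: DomainStructure
    seq_to_struct: dict[int, int]
    known_sites: FunctionalSiteSet
    ec_count_superfamily: int = 0
    moonlighting: bool = False
    is_mutfam: Optional[bool] = None

    def __post_init__(self) -> None:
        lengths = {len(row) for row in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.representative_id not in self.alignment:
            raise ValueError(
                f"representative {self.representative_id!r} absent from alignment"
            )
        rep_row = self.alignment[self.representative_id]
        rep_len = sum(1 for c in rep_row if c not in GAP_CHARS)
        bad_pos = [p for p in self.seq_to_struct if not 1 <= p <= rep_len]
        if bad_pos:
            raise ValueError(
                f"seq_to_struct positions outside representative sequence: {bad_pos}"
            )
        struct_ids = set(self.structure.residue_ids)
        bad_res = sorted(set(self.seq_to_struct.values()) - struct_ids)
        if bad_res:
            raise ValueError(f"seq_to_struct targets missing residues: {bad_res}")
        bad_sites = sorted(
            {e.residue_id for e in self.known_sites.entries} - struct_ids
        )
        if bad_sites:
            raise ValueError(
                f"functional-site residues absent from structure: {bad_sites}"
            )

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self.alignment)


@dataclass(frozen=True)
class MutationCluster:
    """A spatial cluster of aggregated mutations on the representative."""

    residue_ids: frozenset[int]
    mutation_count: int
    p_value: float
    seed_residue: int

    def tier(self, cluster_sig: float = 0.05, cluster_high_sig: float = 0.005) -> str:
        if self.p_value <= cluster_high_sig:
            return "high"
        if self.p_value <= cluster_sig:
            return "standard"
        return "none"


@dataclass(frozen=True)
class TunableSite:
    """Cluster or hotspot residues within the cutoff of a functional site."""

    residue_ids: frozenset[int]
    min_site_distance: float
    source: str  # "cluster" | "hotspot"
    nearest_site_kinds: frozenset[SiteKind]


@dataclass(frozen=True)
class TimingCall:
    klass: TimingClass
    scenario: TimingScenario
    reason: str = ""


COMPONENT_NAMES = (
    "grantham",
    "hotspot",
    "disease_variant",
    "on_known",
    "near_known",
    "on_predicted",
    "near_predicted",
    "high_sig_cluster",
    "mutfam",
)


@dataclass
class FIERecord:
    """A candidate functional impact event with its component-wise score."""

    mutation: MutationRecord
    funfam_id: str
    rep_residue: int
    components: dict[str, int] = field(default_factory=dict)
    total: int = 0
    timing: TimingClass = TimingClass.UNTIMED
    timing_scenario: Optional[TimingScenario] = None
    diverse_family: bool = False
    moonlighting: bool = False
    tunable_source: str = ""
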
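import numpy as np
import pytest

from funvar.config import Config
from funvar.types import (
    Atom,
    DomainStructure,
    FunctionalSiteSet,
    FunFamBundle,
    MutationRecord,
    Residue,
    SiteEntry,
    SiteKind,
)


@pytest.fixture
def config():
    return Config()


def ca_chain(n, spacing=3.8, start_id=1):
    """Linear Ca-trace structure: residue i at x = spacing * (i-1)."""
    return DomainStructure(
        tuple(
            Residue(start_id + i, "A", (Atom("CA", spacing * i, 0.0, 0.0),))
            for i in range(n)
        )
    )


def make_bundle(
    alignment,
    representative_id,
    structure=None,
    seq_to_struct=None,
    sites=(),
    **kwargs,
):
    """Hand-rolled bundle with an identity seq->struct map by default."""
    rep_len = sum(1 for c in alignment[representative_id] if c != "-")
    if structure is None:
        structure = ca_chain(rep_len)
    if seq_to_struct is None:
        seq_to_struct = {i: i for i in range(1, rep_len + 1)}
    site_set = FunctionalSiteSet(
        tuple(SiteEntry(rid, SiteKind(kind), "test") for rid, kind in sites)
    )
    return FunFamBundle(
        funfam_id=kwargs.pop("funfam_id", "FF1"),
        superfamily_id=kwargs.pop("superfamily_id", "SF1"),
        alignment=alignment,
        representative_id=representative_id,
        structure=structure,
        seq_to_struct=seq_to_struct,
        known_sites=site_set,
        **kwargs,
    )


def mut(gene="GENE1", pos=1, ref="L", alt="R", tumor="T1", cancer="LUAD", pid=None, **kw):
    return MutationRecord(
        tumor_id=tumor,
        cancer_type=cancer,
        gene=gene,
        protein_id=pid or f"{gene}_P",
        residue_pos=pos,
        ref_aa=ref,
        alt_aa=alt,
        **kw,
    )


@pytest.fixture
def toy_bundle():
    from funvar.synth import make_toy_funfam

    bundle, truth = make_toy_funfam(seed=7)
    return bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
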
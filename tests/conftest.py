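import numpy as np
import pytest

from proteotyper import (
    CommunitySpec,
    Lineage,
    PeptideTaxonIndex,
    ReferenceProteinRecord,
    Taxonomy,
    generate_community,
)


def make_lineage(tag: str, genus=None, family=None, phylum=None) -> Lineage:
    """Complete seven-rank lineage with shareable upper ranks."""
    phylum = phylum or f"p_{tag}"
    family = family or f"f_{tag}"
    genus = genus or f"g_{tag}"
    return Lineage(
        superkingdom="Bacteria",
        phylum=phylum,
        class_=f"c_{phylum}",
        order=f"o_{family}",
        family=family,
        genus=genus,
        species=tag,
    )


@pytest.fixture(scope="session")
def small_taxonomy() -> Taxonomy:
    """Four species: two share a genus, a third shares only the family,
    the fourth is in a different phylum."""
    return Taxonomy(
        {
            "sp1": make_lineage("sp1", genus="G1", family="F1", phylum="P1"),
            "sp2": make_lineage("sp2", genus="G1", family="F1", phylum="P1"),
            "sp3": make_lineage("sp3", genus="G2", family="F1", phylum="P1"),
            "sp4": make_lineage("sp4", genus="G3", family="F3", phylum="P2"),
        }
    )


def random_records(rng, n_proteins=20, organisms=("sp1", "sp2", "sp3"),
                   length=60):
    """Random proteins over the full 20-residue alphabet."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    records = []
    for i in range(n_proteins):
        seq = "".join(
            alphabet[j] for j in rng.integers(len(alphabet), size=length)
        )
        records.append(
            ReferenceProteinRecord(
                accession=f"prot{i:03d}",
                sequence=seq,
                organism=organisms[i % len(organisms)],
            )
        )
    return records


@pytest.fixture(scope="session")
def metap_community():
    """The 2:1:97 reference design at reduced spectrum count."""
    return generate_community(CommunitySpec.metap(n_spectra=20_000, seed=11))


@pytest.fixture(scope="session")
def metap_index(metap_community):
    return PeptideTaxonIndex.build(
        metap_community.records,
        metap_community.taxonomy,
        metap_community.spec.digestion,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
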
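"""Peptide -> taxon index and rank-level specificity queries.

This is the data structure that turns peptide identifications into
taxonomic evidence.  Every reference protein is digested in silico and
each (normalized) peptide maps to the set of (accession, species)
pairs that can produce it.  A peptide is *specific* to a taxon at a
rank when every source organism agrees on that taxon; specificity
propagates upward, so a species-specific peptide is also specific to
the species' genus, family, and so on (the spePEP notion used in
proteotyping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .digestion import DigestionParams, digest_protein, normalize_peptide
from .taxonomy import RANKS, Taxonomy

INDEX_FORMAT_VERSION = 1


class UnknownOrganismError(ValueError):
    """Reference records name organisms absent from the taxonomy table."""


@dataclass(frozen=True)
class ReferenceProteinRecord:
    """One reference protein: accession, sequence, source species."""

    accession: str
    sequence: str
    organism: str  # species-level taxon id

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")


@dataclass(frozen=True)
class Specificity:
    """Per-rank taxonomic attribution of one peptide.

    ``per_rank[rank]`` is the unique taxon shared by all source
    organisms at that rank, or ``None`` when sources disagree there
    (or the peptide is ambiguous).  ``matched`` is False when the
    peptide is absent from the index altogether.
    """

    peptide: str
    matched: bool
    per_rank: Mapping[str, Optional[str]] = field(default_factory=dict)
    ambiguous: bool = False  # contains X: indexed but never specific

    @property
    def attributed(self) -> bool:
        return any(t is not None for t in self.per_rank.values())

    def deepest_rank(self) -> Optional[str]:
        """Lowest rank at which the peptide is specific, or None."""
        for rank in reversed(RANKS):
            if self.per_rank.get(rank) is not None:
                return rank
        return None


_UNMATCHED_RANKS: dict[str, Optional[str]] = {r: None for r in RANKS}


class PeptideTaxonIndex:
    """Mapping from normalized peptide to its source proteins and taxa.

    Built once from a set of reference proteomes; queried per
    identified peptide.  Normalization (I/L collapsing) is applied
    identically at build and query time, governed by the digestion
    params the index was built with.
    """

    def __init__(self, taxonomy: Taxonomy, params: DigestionParams):
        self.taxonomy = taxonomy
        self.params = params
        self._map: dict[str, set[tuple[str, str]]] = {}

    # ----------------------------------------------------------- building

    @classmethod
    def build(
        cls,
        proteomes: Iterable[ReferenceProteinRecord],
        taxonomy: Taxonomy,
        params: DigestionParams | None = None,
    ) -> "PeptideTaxonIndex":
        params = params or DigestionParams()
        records = list(proteomes)
        missing = sorted({r.organism for r in records} - set(taxonomy.species_ids))
        if missing:
            raise UnknownOrganismError(
                f"organisms absent from taxonomy table: {missing}"
            )
        index = cls(taxonomy, params)
        for record in records:
            for peptide in digest_protein(record.sequence, params):
                key = normalize_peptide(peptide, params.il_equivalent)
                index._map.setdefault(key, set()).add(
                    (record.accession, record.organism)
                )
        return index

    # ------------------------------------------------------------ queries

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, peptide: str) -> bool:
        return self._normalize(peptide) in self._map

    def _normalize(self, peptide: str) -> str:
        return normalize_peptide(peptide, self.params.il_equivalent)

    def query(self, peptide: str) -> frozenset[tuple[str, str]]:
        """All (accession, species) pairs whose digest contains ``peptide``."""
        return frozenset(self._map.get(self._normalize(peptide), ()))

    def species_of(self, peptide: str) -> frozenset[str]:
        return frozenset(sp for _, sp in self.query(peptide))

    @property
    def species_ids(self) -> set[str]:
        return {sp for pairs in self._map.values() for _, sp in pairs}

    def taxa_at(self, rank: str) -> set[str]:
        """Distinct taxa at ``rank`` represented by indexed species."""
        out = set()
        for sp in self.species_ids:
            taxon = self.taxonomy[sp].get(rank)
            if taxon is not None:
                out.add(taxon)
        return out

    def specificity(self, peptide: str) -> Specificity:
        """Per-rank attribution of a peptide (see :class:`Specificity`).

        Peptides containing X are indexed but treated as ambiguous:
        they match, but are never counted as taxon-specific.
        """
        key = self._normalize(peptide)
        pairs = self._map.get(key)
        if not pairs:
            return Specificity(key, matched=False, per_rank=dict(_UNMATCHED_RANKS))
        if "X" in key:
            return Specificity(
                key, matched=True, per_rank=dict(_UNMATCHED_RANKS), ambiguous=True
            )
        lineages = [self.taxonomy[sp] for sp in {sp for _, sp in pairs}]
        per_rank: dict[str, Optional[str]] = {}
        for rank in RANKS:
            values = {lin.get(rank) for lin in lineages}
            taxon = values.pop() if len(values) == 1 else None
            per_rank[rank] = taxon  # None also when sources lack the rank
        return Specificity(key, matched=True, per_rank=per_rank)

    # -------------------------------------------------------- restriction

    def restrict_to_species(self, species_ids: Iterable[str]) -> "PeptideTaxonIndex":
        """Sub-index over a species subset.

        Equivalent to rebuilding from only those species' proteins;
        used by the second round of the cascade search.
        """
        keep = set(species_ids)
        restricted = PeptideTaxonIndex(self.taxonomy, self.params)
        for key, pairs in self._map.items():
            subset = {p for p in pairs if p[1] in keep}
            if subset:
                restricted._map[key] = subset
        return restricted

    # ---------------------------------------------------------------- I/O

    def save(self, path) -> None:
        """Serialize to a versioned, line-oriented text format.

        Line 1: ``#proteotyper-index v<N> <params JSON>``; then one
        line per peptide: ``peptide<TAB>acc:species[;acc:species...]``,
        sources sorted for byte-stable output.  The taxonomy table is
        stored separately (it has its own TSV format).
        """
        from dataclasses import asdict

        with open(path, "w") as fh:
            fh.write(
                f"#proteotyper-index v{INDEX_FORMAT_VERSION} "
                f"{json.dumps(asdict(self.params))}\n"
            )
            for key in sorted(self._map):
                pairs = ";".join(
                    f"{acc}:{sp}" for acc, sp in sorted(self._map[key])
                )
                fh.write(f"{key}\t{pairs}\n")

    @classmethod
    def load(cls, path, taxonomy: Taxonomy) -> "PeptideTaxonIndex":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            prefix = f"#proteotyper-index v{INDEX_FORMAT_VERSION} "
            if not header.startswith(prefix):
                raise ValueError(f"unrecognized index header: {header!r}")
            params = DigestionParams(**json.loads(header[len(prefix):]))
            index = cls(taxonomy, params)
            for line in fh:
                key, _, pairs = line.rstrip("\n").partition("\t")
                index._map[key] = {
                    (acc, sp)
                    for acc, _, sp in (
                        p.partition(":") for p in pairs.split(";") if p
                    )
                }
        return index
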
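"""Seven-rank taxonomic lineages and the species-keyed taxonomy table.

The taxonomic backbone of proteotyping is a fixed hierarchy of seven
ranks, from superkingdom down to species.  Every reference protein is
tied to a species-level taxon; peptide-level specificity is then
evaluated at each rank by walking lineages upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional

import pandas as pd

#: Ranks ordered from highest (most inclusive) to lowest.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Rank name -> position (0 = superkingdom).
RANK_DEPTH: dict[str, int] = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Raised for malformed lineages or inconsistent taxonomy tables."""


@dataclass(frozen=True)
class Lineage:
    """A taxon's identifiers at the seven canonical ranks.

    Identifiers are opaque strings.  A rank may be absent (``None``,
    an unranked placeholder), but if a rank is present every strictly
    higher rank must be present too — a lineage cannot have a genus
    without a family, for instance.
    """

    superkingdom: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        seen_absent = False
        for rank in RANKS:
            value = self.get(rank)
            if value is None:
                seen_absent = True
            elif seen_absent:
                raise TaxonomyError(
                    f"lineage has {rank}={value!r} but a higher rank is absent: {self}"
                )

    def get(self, rank: str) -> Optional[str]:
        """Taxon identifier at ``rank``, or ``None`` if unranked."""
        if rank == "class":
            return self.class_
        if rank not in RANK_DEPTH:
            raise KeyError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def items(self) -> Iterator[tuple[str, Optional[str]]]:
        for rank in RANKS:
            yield rank, self.get(rank)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Optional[str]]) -> "Lineage":
        kwargs = {}
        for rank in RANKS:
            value = mapping.get(rank)
            if value is not None and not isinstance(value, str):
                value = None if pd.isna(value) else str(value)
            kwargs["class_" if rank == "class" else rank] = value or None
        return cls(**kwargs)


class Taxonomy:
    """Species-keyed table of :class:`Lineage` objects.

    The on-disk form is a TSV with a ``species_id`` column followed by
    the seven rank columns; empty cells denote unranked placeholders.
    """

    def __init__(self, lineages: Mapping[str, Lineage]):
        self._lineages: dict[str, Lineage] = dict(lineages)

    def __getitem__(self, species_id: str) -> Lineage:
        return self._lineages[species_id]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def __iter__(self) -> Iterator[str]:
        return iter(self._lineages)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Taxonomy) and self._lineages == other._lineages

    @property
    def species_ids(self) -> list[str]:
        return list(self._lineages)

    def taxa_at(self, rank: str) -> set[str]:
        """All distinct taxon identifiers present at ``rank``."""
        return {
            lin.get(rank)
            for lin in self._lineages.values()
            if lin.get(rank) is not None
        }

    def ancestor(self, species_id: str, rank: str) -> Optional[str]:
        return self._lineages[species_id].get(rank)

    def species_under(self, rank: str, taxon: str) -> set[str]:
        """Species whose lineage carries ``taxon`` at ``rank``."""
        return {
            sp for sp, lin in self._lineages.items() if lin.get(rank) == taxon
        }

    def consistent_with(self, other: "Taxonomy") -> bool:
        """True when overlapping species carry identical lineages."""
        shared = self._lineages.keys() & other._lineages.keys()
        return all(self._lineages[sp] == other._lineages[sp] for sp in shared)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Taxonomy":
        missing = {"species_id", *RANKS} - set(frame.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns: {sorted(missing)}")
        lineages = {}
        for row in frame.to_dict("records"):
            sp = str(row["species_id"])
            if sp in lineages:
                raise TaxonomyError(f"duplicate species_id {sp!r} in taxonomy table")
            lineages[sp] = Lineage.from_mapping(row)
        return cls(lineages)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species_id": sp, **{rank: lin.get(rank) for rank in RANKS}}
            for sp, lin in self._lineages.items()
        ]
        return pd.DataFrame(rows, columns=["species_id", *RANKS])

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        return cls.from_frame(frame)

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(self.to_frame(), path)


def ranks_at_or_above(rank: str) -> tuple[str, ...]:
    """Ranks from superkingdom down to and including ``rank``."""
    return RANKS[: RANK_DEPTH[rank] + 1]
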
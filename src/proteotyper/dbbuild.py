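"""Sample-specific protein database construction.

After proteotyping, a compact search database containing only the
organisms that carry the bulk of the sample's protein biomass makes
deep quantitative (DIA) interpretation tractable.  Selection combines
a biomass-fraction floor with a specific-peptide evidence floor;
either conjunctively or disjunctively — a rare organism backed by many
species-specific peptides can be worth retaining even below the
biomass floor.  The emitted FASTA carries machine-readable taxon
provenance in each header (``>accession organism=<species_id>``) so
downstream protein groups can be resolved back to taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .biomass import BiomassProfile
from .index import ReferenceProteinRecord


class EmptyProteomeError(ValueError):
    """A selected organism has no protein records available."""


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for retaining organisms in the custom database.

    ``combine`` chooses how the biomass and spePEP floors interact:
    ``"or"`` (default) retains an organism passing either; ``"and"``
    requires both.  ``coverage_target`` (percent) switches to a greedy
    mode: passing organisms are added in descending biomass order
    until their cumulative fraction reaches the target.
    """

    min_biomass: float = 0.1
    min_spe_pep: int = 10
    combine: str = "or"
    max_organisms: Optional[int] = None
    coverage_target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_biomass < 0 or self.min_spe_pep < 0:
            raise ValueError("thresholds must be >= 0")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")

    def passes(self, fraction: float, spe_pep: float) -> bool:
        by_biomass = fraction >= self.min_biomass
        by_peptides = spe_pep == spe_pep and spe_pep >= self.min_spe_pep  # NaN-safe
        if self.combine == "or":
            return by_biomass or by_peptides
        return by_biomass and by_peptides


@dataclass
class Selection:
    organisms: list[str]
    coverage: float  # cumulative biomass % of the selected organisms
    warnings: list[str] = field(default_factory=list)


@dataclass
class CustomDatabase:
    """A merged, deduplicated FASTA with its summary statistics."""

    organisms: list[str]
    records: list[ReferenceProteinRecord]
    entry_count: int
    total_amino_acids: int
    per_organism_entries: dict[str, int]
    duplicate_accessions: list[str]
    coverage: Optional[float] = None

    def write(self, path) -> None:
        from .io import write_custom_fasta

        write_custom_fasta(self, path)

    def stats(self) -> dict:
        return {
            "organisms": self.organisms,
            "entry_count": self.entry_count,
            "total_amino_acids": self.total_amino_acids,
            "per_organism_entries": self.per_organism_entries,
            "duplicate_accessions": self.duplicate_accessions,
            "coverage_pct": self.coverage,
        }


def select_organisms(
    profile: BiomassProfile, criteria: SelectionCriteria | None = None
) -> Selection:
    """Choose organisms for the custom database.

    Candidates are taken in descending biomass order (taxon id breaks
    ties); those passing the thresholds are retained.  With a coverage
    target, retention stops at the shortest passing prefix whose
    cumulative fraction meets the target (a warning is recorded if the
    target is unattainable).  ``max_organisms`` caps the list last.
    """
    criteria = criteria or SelectionCriteria()
    frame = profile.frame
    if frame.empty:
        return Selection([], 0.0, warnings=["empty biomass profile"])

    ordered = frame.sort_values(
        ["fraction", "taxon"], ascending=[False, True]
    ).to_dict("records")
    passing = [
        row for row in ordered
        if criteria.passes(float(row["fraction"]), float(row["spe_pep"]))
    ]

    selected: list[dict] = []
    coverage = 0.0
    warnings: list[str] = []
    for row in passing:
        if criteria.coverage_target is not None and coverage >= criteria.coverage_target:
            break
        selected.append(row)
        coverage += float(row["fraction"])
    if (
        criteria.coverage_target is not None
        and coverage < criteria.coverage_target
    ):
        warnings.append(
            f"coverage target {criteria.coverage_target}% unattainable; "
            f"reached {coverage:.2f}%"
        )
    if criteria.max_organisms is not None:
        dropped = selected[criteria.max_organisms:]
        selected = selected[: criteria.max_organisms]
        coverage -= sum(float(row["fraction"]) for row in dropped)
    return Selection([row["taxon"] for row in selected], coverage, warnings)


def build_custom_fasta(
    organisms: Sequence[str],
    proteomes: Iterable[ReferenceProteinRecord],
    coverage: Optional[float] = None,
) -> CustomDatabase:
    """Merge the selected organisms' proteins into one database.

    Records keep their input order within each organism; organisms
    keep the selection order.  Accessions duplicated across organisms
    are kept once (first occurrence) and logged.  An organism with no
    records at all is an error — a database claiming to represent it
    would silently drop its biomass.
    """
    by_organism: dict[str, list[ReferenceProteinRecord]] = {}
    for record in proteomes:
        by_organism.setdefault(record.organism, []).append(record)

    missing = [org for org in organisms if not by_organism.get(org)]
    if missing:
        raise EmptyProteomeError(
            f"selected organisms with zero protein records: {missing}"
        )

    records: list[ReferenceProteinRecord] = []
    seen: set[str] = set()
    duplicates: list[str] = []
    per_organism: dict[str, int] = {}
    for organism in organisms:
        count = 0
        for record in by_organism[organism]:
            if record.accession in seen:
                duplicates.append(record.accession)
                continue
            seen.add(record.accession)
            records.append(record)
            count += 1
        per_organism[organism] = count

    return CustomDatabase(
        organisms=list(organisms),
        records=records,
        entry_count=len(records),
        total_amino_acids=sum(len(r.sequence) for r in records),
        per_organism_entries=per_organism,
        duplicate_accessions=duplicates,
        coverage=coverage,
    )
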
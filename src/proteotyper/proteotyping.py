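"""Taxon-to-Spectrum Match (TSM) assignment and rank-level signal.

A PSM (peptide-spectrum match) becomes a TSM when its peptide is
taxon-specific at some rank: the spectrum then counts as evidence for
that taxon at that rank and for the taxon's ancestors at every higher
rank.  Two signals are tracked per (rank, taxon): the TSM count
(spectra) and the spePEP count (distinct taxon-specific peptide
sequences).  Because specificity can be lost moving down the
hierarchy — a peptide shared by two species of one genus is
genus-specific but not species-specific — the total attributed signal
is non-increasing from superkingdom to species; the per-rank retention
of that signal is itself a diagnostic of how well the reference
database resolves the community.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .index import PeptideTaxonIndex, Specificity
from .taxonomy import RANKS, Taxonomy


class MissingScoreError(ValueError):
    """A PSM lacks the quality score needed for top-N selection."""


class NoSignalError(ValueError):
    """An operation requires attributed signal and found none."""


@dataclass(frozen=True)
class PsmRecord:
    """One identified MS/MS spectrum.

    ``score`` is a spectral quality score (higher is better) used for
    top-N selection; ``intensity`` is the optional precursor intensity
    used by intensity-mode quantification.
    """

    run_id: str
    spectrum_id: str
    peptide: str
    score: Optional[float] = None
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError(
                f"empty peptide for spectrum {self.run_id}/{self.spectrum_id}"
            )


@dataclass(frozen=True)
class TsmAssignment:
    """Per-rank taxonomic attribution of one spectrum."""

    run_id: str
    spectrum_id: str
    peptide: str
    specificity: Specificity

    def taxon_at(self, rank: str) -> Optional[str]:
        return self.specificity.per_rank.get(rank)

    @property
    def attributed(self) -> bool:
        return self.specificity.attributed


class RankSignalProfile:
    """Aggregated TSM and spePEP signal per rank and taxon."""

    def __init__(self) -> None:
        self.tsm: dict[str, Counter] = {r: Counter() for r in RANKS}
        self._spe_pep: dict[str, dict[str, set[str]]] = {r: {} for r in RANKS}
        self.n_spectra = 0
        self.n_unattributed = 0

    def _add(self, assignment: TsmAssignment) -> None:
        self.n_spectra += 1
        if not assignment.attributed:
            self.n_unattributed += 1
            return
        for rank in RANKS:
            taxon = assignment.taxon_at(rank)
            if taxon is None:
                continue
            self.tsm[rank][taxon] += 1
            self._spe_pep[rank].setdefault(taxon, set()).add(assignment.peptide)

    def total(self, rank: str) -> int:
        """Total attributed TSMs at ``rank``."""
        return sum(self.tsm[rank].values())

    def taxa_at(self, rank: str) -> set[str]:
        return set(self.tsm[rank])

    def spe_pep_count(self, rank: str, taxon: str) -> int:
        """Distinct taxon-specific peptide sequences (not spectra)."""
        return len(self._spe_pep[rank].get(taxon, ()))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(rank, taxon) table: tsms and spe_pep counts."""
        rows = [
            {
                "rank": rank,
                "taxon": taxon,
                "tsms": count,
                "spe_pep": self.spe_pep_count(rank, taxon),
            }
            for rank in RANKS
            for taxon, count in sorted(self.tsm[rank].items())
        ]
        return pd.DataFrame(rows, columns=["rank", "taxon", "tsms", "spe_pep"])


def select_top_spectra(psms: Sequence[PsmRecord], n: int) -> list[PsmRecord]:
    """The ``n`` highest-quality spectra.

    Emulates the survey-stage practice of restricting the taxonomic
    search to the best-scoring MS/MS spectra.  Ties are broken by
    (run_id, spectrum_id) so selection is deterministic.  If ``n``
    exceeds the input, everything is returned.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    for record in psms:
        if record.score is None or math.isnan(record.score):
            raise MissingScoreError(
                f"PSM {record.run_id}/{record.spectrum_id} has no quality score"
            )
    ranked = sorted(psms, key=lambda r: (-r.score, r.run_id, r.spectrum_id))
    return ranked[:n]


def assign_tsms(
    psms: Iterable[PsmRecord], index: PeptideTaxonIndex
) -> tuple[list[TsmAssignment], RankSignalProfile]:
    """Attribute each spectrum to taxa at every rank where its peptide
    is specific.

    Spectra whose peptide is unmatched, ambiguous, or specific at no
    rank are counted as unattributed.  Specificity is computed once per
    distinct peptide and reused across spectra.
    """
    cache: dict[str, Specificity] = {}
    assignments: list[TsmAssignment] = []
    profile = RankSignalProfile()
    for psm in psms:
        spec = cache.get(psm.peptide)
        if spec is None:
            spec = index.specificity(psm.peptide)
            cache[psm.peptide] = spec
        assignment = TsmAssignment(psm.run_id, psm.spectrum_id, spec.peptide, spec)
        assignments.append(assignment)
        profile._add(assignment)
    return assignments, profile


def rank_signal_retention(
    profile: RankSignalProfile,
    taxonomy: Optional[Taxonomy] = None,
    per_phylum: bool = False,
) -> pd.DataFrame:
    """Percentage of the superkingdom-level TSM signal retained at
    each lower rank.

    Retention below 100% at a rank means some spectra lose specificity
    there (their peptides are shared across sibling taxa).  With
    ``per_phylum=True`` the same ratio is computed within each phylum,
    which localizes where reference coverage is weak; this requires a
    taxonomy to map rank-level taxa back to their phylum.
    """
    top = profile.total(RANKS[0])
    if top == 0:
        raise NoSignalError("no attributed signal at superkingdom rank")
    rows = [
        {"phylum": "all", "rank": rank, "tsms": profile.total(rank),
         "retention_pct": 100.0 * profile.total(rank) / top}
        for rank in RANKS
    ]
    if per_phylum:
        if taxonomy is None:
            raise ValueError("per-phylum retention requires a taxonomy")
        taxon_phylum: dict[tuple[str, str], str] = {}
        for sp in taxonomy.species_ids:
            lin = taxonomy[sp]
            phylum = lin.get("phylum")
            if phylum is None:
                continue
            for rank in RANKS:
                taxon = lin.get(rank)
                if taxon is not None:
                    taxon_phylum[(rank, taxon)] = phylum
        phyla = sorted(profile.taxa_at("phylum"))
        for phylum in phyla:
            base = profile.tsm["phylum"][phylum]
            if base == 0:
                continue
            for rank in RANKS:
                count = sum(
                    c
                    for taxon, c in profile.tsm[rank].items()
                    if taxon_phylum.get((rank, taxon)) == phylum
                )
                rows.append(
                    {"phylum": phylum, "rank": rank, "tsms": count,
                     "retention_pct": 100.0 * count / base}
                )
    return pd.DataFrame(rows, columns=["phylum", "rank", "tsms", "retention_pct"])
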
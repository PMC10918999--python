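"""Two-round genus -> species cascade search and run merging.

Round 1 assigns TSMs against the full generic index and accepts the
genera with enough evidence.  Round 2 restricts the index to the
species descending from those genera — a much smaller search space in
which peptides regain species-level specificity — reassigns TSMs, and
accepts species by the same evidence thresholds.  Detection is
prior-free: any taxon in the generic index can be accepted, which is
what lets organisms never before reported in a sample type (spiked or
contaminant) be found.

Evidence thresholds are counts of taxon-specific peptides (spePEP) and
TSMs per taxon.  An optional binomial screen rejects taxa whose TSM
count is unsurprising under a uniform-assignment null (each attributed
spectrum equally likely to land on any of the rank's taxa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .index import PeptideTaxonIndex
from .proteotyping import PsmRecord, RankSignalProfile, assign_tsms
from .taxonomy import Taxonomy


@dataclass(frozen=True)
class CascadeThresholds:
    """Acceptance thresholds for each cascade round."""

    min_spe_pep: int = 3
    min_tsm: int = 5
    binomial_alpha: Optional[float] = None  # e.g. 0.05 to enable the screen


@dataclass
class CascadeResult:
    genus_table: pd.DataFrame
    species_table: pd.DataFrame
    accepted_genera: list[str]
    accepted_species: list[str]
    round1_profile: RankSignalProfile
    round2_profile: Optional[RankSignalProfile]
    taxonomy: Taxonomy


def _rank_table(
    profile: RankSignalProfile,
    rank: str,
    thresholds: CascadeThresholds,
    n_candidate_taxa: int,
) -> pd.DataFrame:
    total = profile.total(rank)
    rows = []
    for taxon in sorted(profile.taxa_at(rank)):
        tsms = profile.tsm[rank][taxon]
        spe = profile.spe_pep_count(rank, taxon)
        accepted = tsms >= thresholds.min_tsm and spe >= thresholds.min_spe_pep
        p_value = float("nan")
        if thresholds.binomial_alpha is not None and n_candidate_taxa > 0:
            # P(X >= tsms) for X ~ Binom(total, 1/n_taxa)
            p_value = float(
                stats.binom.sf(tsms - 1, total, 1.0 / n_candidate_taxa)
            )
            accepted = accepted and p_value <= thresholds.binomial_alpha
        rows.append(
            {"taxon": taxon, "tsms": tsms, "spe_pep": spe,
             "p_value": p_value, "accepted": accepted}
        )
    return pd.DataFrame(
        rows, columns=["taxon", "tsms", "spe_pep", "p_value", "accepted"]
    )


def cascade_search(
    psms: Sequence[PsmRecord],
    generic_index: PeptideTaxonIndex,
    thresholds: CascadeThresholds | None = None,
) -> CascadeResult:
    """Run the two-round proteotyping cascade.

    An empty PSM list yields an empty (not erroneous) result.  The
    output tables report every observed candidate taxon with its TSM
    and spePEP counts and acceptance flag, for both rounds.
    """
    thresholds = thresholds or CascadeThresholds()
    taxonomy = generic_index.taxonomy

    _, round1 = assign_tsms(psms, generic_index)
    genus_table = _rank_table(
        round1, "genus", thresholds, len(generic_index.taxa_at("genus"))
    )
    accepted_genera = sorted(genus_table.loc[genus_table["accepted"], "taxon"])

    if not accepted_genera:
        empty = pd.DataFrame(
            columns=["taxon", "tsms", "spe_pep", "p_value", "accepted"]
        )
        return CascadeResult(
            genus_table, empty, [], [], round1, None, taxonomy
        )

    descendants = {
        sp
        for sp in generic_index.species_ids
        if taxonomy[sp].get("genus") in set(accepted_genera)
    }
    restricted = generic_index.restrict_to_species(descendants)
    _, round2 = assign_tsms(psms, restricted)
    species_table = _rank_table(
        round2, "species", thresholds, len(restricted.taxa_at("species"))
    )
    accepted_species = sorted(
        species_table.loc[species_table["accepted"], "taxon"]
    )
    return CascadeResult(
        genus_table,
        species_table,
        accepted_genera,
        accepted_species,
        round1,
        round2,
        taxonomy,
    )


def merge_proteotyping_runs(results: Sequence[CascadeResult]) -> pd.DataFrame:
    """Consolidate per-run cascade results into one taxon list.

    Union of accepted taxa at genus and species ranks; TSM counts
    summed across runs; the best single-run spePEP count retained
    (cross-run peptide identity is not tracked, so summing spePEP
    would double-count sequences seen in several runs).  All runs must
    share a consistent taxonomy.
    """
    if not results:
        return pd.DataFrame(
            columns=["rank", "taxon", "tsms", "spe_pep_best", "n_runs"]
        )
    reference = results[0].taxonomy
    for r in results[1:]:
        if not reference.consistent_with(r.taxonomy):
            raise ValueError("inconsistent taxonomy tables across runs")

    merged: dict[tuple[str, str], dict] = {}
    for result in results:
        for rank, table, accepted in (
            ("genus", result.genus_table, result.accepted_genera),
            ("species", result.species_table, result.accepted_species),
        ):
            accepted_set = set(accepted)
            for row in table.to_dict("records"):
                if row["taxon"] not in accepted_set:
                    continue
                key = (rank, row["taxon"])
                entry = merged.setdefault(
                    key, {"tsms": 0, "spe_pep_best": 0, "n_runs": 0}
                )
                entry["tsms"] += int(row["tsms"])
                entry["spe_pep_best"] = max(
                    entry["spe_pep_best"], int(row["spe_pep"])
                )
                entry["n_runs"] += 1
    rows = [
        {"rank": rank, "taxon": taxon, **entry}
        for (rank, taxon), entry in sorted(merged.items())
    ]
    return pd.DataFrame(
        rows, columns=["rank", "taxon", "tsms", "spe_pep_best", "n_runs"]
    )
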
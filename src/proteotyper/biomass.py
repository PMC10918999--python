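"""Per-taxon biomass estimation from TSM counts or protein intensity.

The share of the attributed proteomic signal carried by each taxon is
used as a surrogate for its protein biomass in the community.  Two
surrogates are supported: the number of taxon-to-spectrum matches
(spectral counting, the DDA-survey route) and the summed intensity of
taxon-resolved protein groups (the DIA quantification route).  With
unbiased sampling of spectra the two converge; shared peptides and
reference-database redundancy can inflate spectral-count estimates for
closely related taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .proteotyping import NoSignalError, RankSignalProfile
from .taxonomy import Taxonomy

MODES = ("tsm_count", "intensity")


@dataclass
class BiomassProfile:
    """Per-taxon biomass fractions with the surrogate signal recorded.

    ``frame`` columns: taxon, fraction (percent of attributed signal),
    signal (TSM count or summed intensity), spe_pep (distinct specific
    peptides; NaN for intensity mode).  Fractions sum to 100 over
    attributed taxa unless ``include_unattributed`` was requested, in
    which case the unattributed remainder is held out of the table.
    """

    frame: pd.DataFrame
    mode: str
    rank: str
    unattributed_signal: float = 0.0
    excluded_groups: list = field(default_factory=list)

    def fraction(self, taxon: str) -> float:
        rows = self.frame.loc[self.frame["taxon"] == taxon, "fraction"]
        return float(rows.iloc[0]) if len(rows) else 0.0

    def spe_pep(self, taxon: str) -> float:
        rows = self.frame.loc[self.frame["taxon"] == taxon, "spe_pep"]
        return float(rows.iloc[0]) if len(rows) else 0.0

    @property
    def taxa(self) -> list[str]:
        return list(self.frame["taxon"])


def _profile_from_signals(
    signals: Mapping[str, float],
    spe_pep: Mapping[str, float],
    mode: str,
    rank: str,
    unattributed: float,
    include_unattributed: bool,
) -> BiomassProfile:
    total = float(sum(signals.values()))
    if total <= 0:
        raise NoSignalError("no attributable signal")
    denom = total + unattributed if include_unattributed else total
    rows = [
        {
            "taxon": taxon,
            "fraction": 100.0 * signal / denom,
            "signal": signal,
            "spe_pep": spe_pep.get(taxon, float("nan")),
        }
        for taxon, signal in sorted(
            signals.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    return BiomassProfile(
        frame=pd.DataFrame(rows, columns=["taxon", "fraction", "signal", "spe_pep"]),
        mode=mode,
        rank=rank,
        unattributed_signal=unattributed,
    )


def estimate_biomass(
    profile: RankSignalProfile,
    rank: str = "species",
    include_unattributed: bool = False,
) -> BiomassProfile:
    """TSM-count biomass at ``rank``.

    fraction(T) = 100 * TSM(T, rank) / total attributed TSMs at rank.
    Spectra not attributed at this rank are excluded from the
    denominator by default (fractions are shares of *attributed*
    biomass); ``include_unattributed=True`` switches the denominator
    to all spectra.
    """
    signals = {taxon: float(c) for taxon, c in profile.tsm[rank].items()}
    spe = {taxon: float(profile.spe_pep_count(rank, taxon)) for taxon in signals}
    unattributed = float(profile.n_spectra - profile.total(rank))
    return _profile_from_signals(
        signals, spe, "tsm_count", rank, unattributed, include_unattributed
    )


def estimate_biomass_intensity(
    quant: pd.DataFrame,
    accession_organism: Mapping[str, str],
    taxonomy: Taxonomy,
    rank: str = "species",
    group_rank: str = "species",
    include_unattributed: bool = False,
) -> BiomassProfile:
    """Intensity-mode biomass from a protein-group quantification table.

    ``quant`` columns: ``protein_group``, ``member_accessions``
    (semicolon-separated), plus one or more numeric intensity columns
    (one per run) which are summed.  A group is taxon-resolved only
    when all member accessions map to the same taxon at ``group_rank``
    (species by default; genus relaxes it); mixed or unmappable groups
    are excluded and their summed intensity reported as unattributed,
    alongside the list of excluded group ids.
    """
    required = {"protein_group", "member_accessions"}
    missing = required - set(quant.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    intensity_cols = [
        c for c in quant.columns
        if c not in required and pd.api.types.is_numeric_dtype(quant[c])
    ]
    if not intensity_cols:
        raise ValueError("quant table has no numeric intensity column")

    signals: dict[str, float] = {}
    unattributed = 0.0
    excluded: list[str] = []
    for row in quant.to_dict("records"):
        members = [m for m in str(row["member_accessions"]).split(";") if m]
        intensity = float(sum(row[c] for c in intensity_cols))
        group_taxa = set()
        resolvable = True
        for acc in members:
            organism = accession_organism.get(acc)
            if organism is None or organism not in taxonomy:
                resolvable = False
                break
            taxon = taxonomy[organism].get(group_rank)
            if taxon is None:
                resolvable = False
                break
            group_taxa.add((organism, taxon))
        if not resolvable or len({t for _, t in group_taxa}) != 1:
            unattributed += intensity
            excluded.append(str(row["protein_group"]))
            continue
        organism = min(group_taxa)[0]  # deterministic pick among same-taxon members
        report_taxon = taxonomy[organism].get(rank)
        if report_taxon is None:
            unattributed += intensity
            excluded.append(str(row["protein_group"]))
            continue
        signals[report_taxon] = signals.get(report_taxon, 0.0) + intensity

    result = _profile_from_signals(
        signals, {}, "intensity", rank, unattributed, include_unattributed
    )
    result.excluded_groups = excluded
    return result
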
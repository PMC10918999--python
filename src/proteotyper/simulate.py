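"""Synthetic communities, PSM tables, and KO fixtures.

The generator emulates the structure of a spike-in metaproteomics
standard: a community of species with known biomass fractions, each
with a proteome of random tryptic-friendly sequences, from which
spectra are sampled proportionally to biomass.  Its default community
(:meth:`CommunitySpec.metap`) is a three-member design mixed at
2:1:97 — two defined bacteria spiked into a dominant background — the
layout used to validate biomass estimation against a known ground
truth.

Design points that matter for testing:

* Proteins are concatenations of generated peptide "units": each unit
  has no internal K/R, does not start with P, and ends in K/R, so a
  fully cleaved tryptic digest recovers exactly the units.  What the
  index discovers is therefore known by construction.
* Cross-taxon peptide sharing is implemented by literally copying a
  fraction ``f`` of units into every species of a sharing scope
  (within-genus, within-family, or global), so shared peptides lose
  rank specificity naturally through the index, not via annotation.
* Spectrum emission samples a species with probability proportional
  to its biomass fraction, then a peptide position uniformly within
  that species' digest; missed-cleavage products are emitted by
  concatenating adjacent units with configurable probabilities
  (default 90.2% none / 9.5% one / 0.3% two, typical of a
  high-quality tryptic digest).  Intensities are log-normal, quality
  scores uniform.
* All randomness flows from the single spec seed through a documented
  ``numpy`` SeedSequence split: child 0 -> community generation,
  child 1 -> spectrum simulation, child 2 -> KO fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .digestion import DigestionParams, normalize_peptide
from .index import ReferenceProteinRecord
from .taxonomy import Lineage, Taxonomy

_BODY = "ACDEFGHLMNPQSTVWY"  # no K/R (cleavage), no I (I/L collapse), no X
_BODY_NO_P = _BODY.replace("P", "")
_TERMINAL = "KR"

SCOPES = ("within-genus", "within-family", "global")


class InfeasibleSpecError(ValueError):
    """The community spec cannot produce valid tryptic peptides."""


@dataclass(frozen=True)
class CommunityMember:
    species_id: str
    lineage: Lineage
    fraction: float  # percent of community biomass


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community and its measurement.

    ``shared_peptide_rate`` is the fraction f of each species' peptide
    units copied across all species in the sharing scope; f = 0 makes
    every peptide species-specific, f = 1 removes species specificity
    entirely within the scope.
    """

    members: tuple[CommunityMember, ...]
    proteins_per_species: int = 40
    mean_protein_length: int = 300
    shared_peptide_rate: float = 0.0
    sharing_scope: str = "within-genus"
    n_spectra: int = 100_000
    intensity_log_mean: float = 13.8  # ln-scale location (~1e6 median)
    intensity_log_sigma: float = 1.0
    missed_cleavage_probs: tuple[float, float, float] = (0.902, 0.095, 0.003)
    digestion: DigestionParams = field(default_factory=DigestionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(m.fraction for m in self.members)
        if self.members and abs(total - 100.0) > 1e-6:
            raise ValueError(f"biomass fractions sum to {total}, expected 100")
        if not 0.0 <= self.shared_peptide_rate <= 1.0:
            raise ValueError("shared_peptide_rate must be in [0, 1]")
        if self.sharing_scope not in SCOPES:
            raise ValueError(f"sharing_scope must be one of {SCOPES}")
        if self.n_spectra < 0:
            raise ValueError("n_spectra must be >= 0")
        if self.mean_protein_length < self.digestion.min_length + 1:
            raise InfeasibleSpecError(
                "mean_protein_length below minimum peptide length: "
                "no in-bounds tryptic peptide can be generated"
            )
        if abs(sum(self.missed_cleavage_probs) - 1.0) > 1e-9:
            raise ValueError("missed_cleavage_probs must sum to 1")

    @classmethod
    def metap(
        cls,
        n_spectra: int = 100_000,
        seed: int = 0,
        shared_peptide_rate: float = 0.0,
        **overrides,
    ) -> "CommunitySpec":
        """The three-member 2:1:97 spike-in reference design.

        Two defined bacteria at 2% and 1% on top of a 97% background
        component, each in its own genus and phylum (synthetic
        stand-ins, not real organisms).
        """

        def lineage(tag: str) -> Lineage:
            return Lineage(
                superkingdom="Bacteria",
                phylum=f"p_{tag}",
                class_=f"c_{tag}",
                order=f"o_{tag}",
                family=f"f_{tag}",
                genus=f"g_{tag}",
                species=tag,
            )

        members = (
            CommunityMember("spike_major", lineage("spike_major"), 2.0),
            CommunityMember("spike_minor", lineage("spike_minor"), 1.0),
            CommunityMember("background", lineage("background"), 97.0),
        )
        return cls(
            members=members,
            n_spectra=n_spectra,
            seed=seed,
            shared_peptide_rate=shared_peptide_rate,
            **overrides,
        )

    @classmethod
    def from_dict(cls, config: dict) -> "CommunitySpec":
        config = dict(config)
        if config.pop("preset", None) == "metap":
            return cls.metap(**config)
        members = tuple(
            CommunityMember(
                species_id=m["species_id"],
                lineage=Lineage.from_mapping(m["lineage"]),
                fraction=float(m["fraction"]),
            )
            for m in config.pop("members")
        )
        if "digestion" in config:
            config["digestion"] = DigestionParams(**config["digestion"])
        if "missed_cleavage_probs" in config:
            config["missed_cleavage_probs"] = tuple(config["missed_cleavage_probs"])
        return cls(members=members, **config)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic tables."""

    fractions: dict[str, float]  # species -> percent
    peptide_taxa: dict[str, set[str]]  # normalized unit -> source species
    species_units: dict[str, list[list[str]]]  # species -> proteins -> units


@dataclass
class Community:
    spec: CommunitySpec
    records: list[ReferenceProteinRecord]
    taxonomy: Taxonomy
    truth: SyntheticTruth


def _scope_key(member: CommunityMember, scope: str) -> str:
    if scope == "within-genus":
        return member.lineage.get("genus") or member.species_id
    if scope == "within-family":
        return member.lineage.get("family") or member.species_id
    return "__global__"


def _draw_unit(rng: np.random.Generator, params: DigestionParams) -> str:
    """One tryptic peptide unit: [^KRP] [^KR]* [KR], in length bounds."""
    max_len = min(params.max_length, 20)
    length = int(rng.integers(params.min_length, max_len + 1))
    first = _BODY_NO_P[rng.integers(len(_BODY_NO_P))]
    body = "".join(
        _BODY[i] for i in rng.integers(len(_BODY), size=length - 2)
    )
    terminal = _TERMINAL[rng.integers(len(_TERMINAL))]
    return first + body + terminal


def _draw_unique_unit(
    rng: np.random.Generator, params: DigestionParams, seen: set[str]
) -> str:
    for _ in range(1000):
        unit = _draw_unit(rng, params)
        key = normalize_peptide(unit, params.il_equivalent)
        if key not in seen:
            seen.add(key)
            return unit
    raise InfeasibleSpecError("could not generate a fresh peptide unit")


def generate_community(spec: CommunitySpec) -> Community:
    """Generate proteomes, taxonomy, and ground truth for a spec.

    Deterministic given the spec seed: regenerating the same spec
    yields byte-identical FASTA and taxonomy output.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_community, _, _ = root.spawn(3)
    rng = np.random.default_rng(ss_community)
    params = spec.digestion

    units_per_protein = max(1, round(spec.mean_protein_length / 15))
    n_units = spec.proteins_per_species * units_per_protein
    n_shared = round(spec.shared_peptide_rate * n_units)

    seen: set[str] = set()
    shared_pools: dict[str, list[str]] = {}
    for member in spec.members:
        key = _scope_key(member, spec.sharing_scope)
        if key not in shared_pools:
            shared_pools[key] = [
                _draw_unique_unit(rng, params, seen) for _ in range(n_shared)
            ]

    records: list[ReferenceProteinRecord] = []
    peptide_taxa: dict[str, set[str]] = {}
    species_units: dict[str, list[list[str]]] = {}
    for member in spec.members:
        pool = shared_pools[_scope_key(member, spec.sharing_scope)]
        units = list(pool) + [
            _draw_unique_unit(rng, params, seen)
            for _ in range(n_units - len(pool))
        ]
        order = rng.permutation(len(units))
        units = [units[i] for i in order]
        proteins = [
            list(chunk)
            for chunk in np.array_split(np.array(units, dtype=object),
                                        spec.proteins_per_species)
            if len(chunk)
        ]
        species_units[member.species_id] = proteins
        for i, protein_units in enumerate(proteins):
            records.append(
                ReferenceProteinRecord(
                    accession=f"{member.species_id}_P{i:04d}",
                    sequence="".join(protein_units),
                    organism=member.species_id,
                )
            )
        for unit in units:
            key = normalize_peptide(unit, params.il_equivalent)
            peptide_taxa.setdefault(key, set()).add(member.species_id)

    taxonomy = Taxonomy(
        {m.species_id: m.lineage for m in spec.members}
    )
    truth = SyntheticTruth(
        fractions={m.species_id: m.fraction for m in spec.members},
        peptide_taxa=peptide_taxa,
        species_units=species_units,
    )
    return Community(spec, records, taxonomy, truth)


def simulate_psms(
    community: Community,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    run_id: str = "run1",
    dia: bool = False,
) -> tuple[pd.DataFrame, list[str], Optional[pd.DataFrame]]:
    """Sample a PSM table from a community.

    Each spectrum draws a source species proportionally to biomass,
    then a peptide position uniformly within that species' proteome;
    adjacent units are concatenated to emit missed-cleavage products.
    Returns ``(psms, sources, quant)`` — the PSM table (run,
    spectrum_id, peptide, score, intensity), the per-spectrum true
    source species, and (in DIA mode) a protein-group quantification
    table aggregating spectrum intensities per protein, else None.
    """
    spec = community.spec
    if n is None:
        n = spec.n_spectra
    root = np.random.SeedSequence(spec.seed)
    _, ss_psms, _ = root.spawn(3)
    if seed is not None:
        ss_psms = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss_psms)

    species = [m.species_id for m in spec.members]
    probs = np.array([m.fraction for m in spec.members]) / 100.0

    # per-species flat occurrence list: (protein index, slot index)
    occurrences: dict[str, list[tuple[int, int]]] = {}
    for sp in species:
        occ = []
        for p_idx, protein_units in enumerate(community.truth.species_units[sp]):
            occ.extend((p_idx, s) for s in range(len(protein_units)))
        occurrences[sp] = occ

    if n == 0:
        empty = pd.DataFrame(
            columns=["run", "spectrum_id", "peptide", "score", "intensity"]
        )
        quant = (
            pd.DataFrame(
                columns=["protein_group", "member_accessions",
                         f"intensity_{run_id}"]
            )
            if dia
            else None
        )
        return empty, [], quant

    source_idx = rng.choice(len(species), size=n, p=probs)
    mc_draws = rng.choice(3, size=n, p=np.array(spec.missed_cleavage_probs))
    intensities = rng.lognormal(
        spec.intensity_log_mean, spec.intensity_log_sigma, size=n
    )
    scores = rng.uniform(0.0, 1.0, size=n)
    occ_draws = rng.random(size=n)

    rows = []
    sources: list[str] = []
    protein_intensity: dict[str, float] = {}
    for i in range(n):
        sp = species[source_idx[i]]
        occ = occurrences[sp]
        p_idx, slot = occ[int(occ_draws[i] * len(occ))]
        protein_units = community.truth.species_units[sp][p_idx]
        end = min(slot + int(mc_draws[i]) + 1, len(protein_units))
        peptide = "".join(protein_units[slot:end])
        rows.append(
            {
                "run": run_id,
                "spectrum_id": f"scan{i:06d}",
                "peptide": peptide,
                "score": scores[i],
                "intensity": intensities[i],
            }
        )
        sources.append(sp)
        if dia:
            accession = f"{sp}_P{p_idx:04d}"
            protein_intensity[accession] = (
                protein_intensity.get(accession, 0.0) + float(intensities[i])
            )

    psms = pd.DataFrame(rows, columns=["run", "spectrum_id", "peptide",
                                       "score", "intensity"])
    quant = None
    if dia:
        quant = pd.DataFrame(
            [
                {
                    "protein_group": acc,
                    "member_accessions": acc,
                    f"intensity_{run_id}": value,
                }
                for acc, value in sorted(protein_intensity.items())
            ],
            columns=["protein_group", "member_accessions", f"intensity_{run_id}"],
        )
    return psms, sources, quant


_CATEGORIES = (
    "metabolism",
    "genetic information processing",
    "environmental information processing",
    "cellular processes",
    "human diseases",
)


def generate_ko_fixture(
    n_pathways: int = 30,
    kos_per_pathway: int = 8,
    n_proteins: int = 200,
    annotation_rate: float = 0.7,
    taxa: Sequence[str] = ("taxon_a", "taxon_b", "taxon_c"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """KO annotation and pathway definition tables with ground truth.

    Pathways draw their KO sets from a shared universe sized so that
    some KOs belong to several pathways (exercising the many-to-many
    mapping).  Each protein is annotated with probability
    ``annotation_rate``.  The returned truth dict records the expected
    coverage per pathway, recounted directly from the emitted tables.
    """
    if min(n_pathways, kos_per_pathway, n_proteins) <= 0:
        raise ValueError("fixture sizes must be positive")
    if not 0.0 <= annotation_rate <= 1.0:
        raise ValueError("annotation_rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])

    universe_size = max(kos_per_pathway, int(0.8 * n_pathways * kos_per_pathway))
    universe = [f"K{i:05d}" for i in range(universe_size)]

    pathway_rows = []
    pathway_kos: dict[str, set[str]] = {}
    for p in range(n_pathways):
        pathway = f"map{p:05d}"
        category = _CATEGORIES[p % len(_CATEGORIES)]
        kos = rng.choice(universe_size, size=kos_per_pathway, replace=False)
        pathway_kos[pathway] = {universe[k] for k in kos}
        pathway_rows.extend(
            {"pathway": pathway, "category": category, "ko": universe[k]}
            for k in sorted(kos)
        )
    pathways = pd.DataFrame(pathway_rows, columns=["pathway", "category", "ko"])

    annotation_rows = []
    for i in range(n_proteins):
        annotated = rng.random() < annotation_rate
        ko = universe[rng.integers(universe_size)] if annotated else None
        annotation_rows.append(
            {
                "protein_group": f"PG{i:05d}",
                "ko": ko,
                "taxon": taxa[int(rng.integers(len(taxa)))],
                "abundance": float(rng.lognormal(0.0, 1.0)),
            }
        )
    annotations = pd.DataFrame(
        annotation_rows, columns=["protein_group", "ko", "taxon", "abundance"]
    )

    observed = set(annotations["ko"].dropna())
    truth = {
        "expected_coverage": {
            pathway: 100.0 * len(observed & kos) / len(kos)
            for pathway, kos in pathway_kos.items()
        },
        "annotated_count": int(annotations["ko"].notna().sum()),
    }
    return annotations, pathways, truth
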
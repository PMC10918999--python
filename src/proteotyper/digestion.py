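"""In-silico tryptic digestion of protein sequences.

Trypsin cleaves C-terminal of lysine (K) and arginine (R); by default a
following proline (P) blocks the cut, which is the behaviour of most
search engines.  Digestion enumerates every contiguous run of fully
cleaved fragments spanning up to ``missed_cleavages`` internal sites,
filtered to a length window.

Peptides are compared after optional I/L normalization: leucine and
isoleucine are isobaric and indistinguishable by the tandem mass
spectrometry that produces the identifications this package consumes,
so they are collapsed (I -> L) when building and querying the
peptide-taxon index.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The 20 proteinogenic residues plus X (unknown/ambiguous).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the amino-acid alphabet."""


@dataclass(frozen=True)
class DigestionParams:
    """Digestion and peptide-normalization settings.

    Defaults follow common metaproteomic database-search practice:
    up to 2 missed cleavages, peptide length 7-30 residues, trypsin
    with the proline block, I/L treated as equivalent.
    """

    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 30
    proline_block: bool = True
    il_equivalent: bool = True

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError(
                f"invalid length bounds {self.min_length}..{self.max_length}"
            )


def validate_sequence(sequence: str) -> None:
    """Reject sequences containing characters outside the alphabet.

    The error names the first offending character and its 0-based
    position, which is what a user needs to fix a malformed FASTA.
    """
    if not sequence:
        raise InvalidResidueError("empty sequence")
    for pos, char in enumerate(sequence):
        if char not in VALID_RESIDUES:
            raise InvalidResidueError(
                f"invalid residue {char!r} at position {pos} "
                f"(allowed: 20 amino acids plus X, uppercase)"
            )


def normalize_peptide(peptide: str, il_equivalent: bool = True) -> str:
    """Collapse I to L when I/L equivalence is enabled."""
    return peptide.replace("I", "L") if il_equivalent else peptide


def cleavage_sites(sequence: str, proline_block: bool = True) -> list[int]:
    """0-based positions at which trypsin cuts (cut is before the index).

    A site ``i`` means the bond between ``sequence[i-1]`` and
    ``sequence[i]`` is cleaved.  The C-terminus is not a site.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_block and sequence[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def digest_protein(sequence: str, params: DigestionParams) -> list[str]:
    """Enumerate tryptic peptides of one protein.

    Returns every product with 0..``missed_cleavages`` internal sites
    whose length falls within the configured bounds, ordered by start
    position then length, each distinct peptide retained once (set
    semantics per protein, first occurrence kept).  Peptides are
    returned un-normalized; I/L collapsing happens at index build and
    query time.
    """
    validate_sequence(sequence)
    boundaries = [0, *cleavage_sites(sequence, params.proline_block), len(sequence)]
    fragments = [
        (boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)
    ]
    peptides: list[str] = []
    seen: set[str] = set()
    for i in range(len(fragments)):
        start = fragments[i][0]
        for j in range(i, min(i + params.missed_cleavages + 1, len(fragments))):
            end = fragments[j][1]
            if end - start > params.max_length:
                break
            if end - start < params.min_length:
                continue
            peptide = sequence[start:end]
            if peptide not in seen:
                seen.add(peptide)
                peptides.append(peptide)
    return peptides
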
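"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a result by the most direct method available —
enumeration, linear scan, full sort, or set arithmetic — without
touching the implementation's data structures, so agreement is
evidence and not tautology.
"""

from __future__ import annotations

from proteotyper.digestion import DigestionParams, normalize_peptide
from proteotyper.taxonomy import RANKS


def brute_force_digest(sequence: str, params: DigestionParams) -> set[str]:
    """All cleavage windows with <= missed_cleavages internal sites.

    Enumerates every (start, end) pair of cleavage boundaries directly
    from the site list, with no fragment bookkeeping.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if params.proline_block and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    boundaries = [0, *sites, len(sequence)]
    out = set()
    for a in range(len(boundaries) - 1):
        for b in range(a + 1, len(boundaries)):
            internal = b - a - 1
            if internal > params.missed_cleavages:
                continue
            start, end = boundaries[a], boundaries[b]
            if params.min_length <= end - start <= params.max_length:
                out.add(sequence[start:end])
    return out


def linear_scan_query(peptide, records, params):
    """(accession, organism) pairs containing the peptide, by scanning
    every protein's brute-force digest."""
    key = normalize_peptide(peptide, params.il_equivalent)
    hits = set()
    for record in records:
        digest = {
            normalize_peptide(p, params.il_equivalent)
            for p in brute_force_digest(record.sequence, params)
        }
        if key in digest:
            hits.add((record.accession, record.organism))
    return hits


def scan_specificity(peptide, records, taxonomy, params):
    """Normalize-then-scan per-rank attribution (None = not specific)."""
    key = normalize_peptide(peptide, params.il_equivalent)
    species = {org for _, org in linear_scan_query(peptide, records, params)}
    if not species or "X" in key:
        return {rank: None for rank in RANKS}
    result = {}
    for rank in RANKS:
        values = {taxonomy[sp].get(rank) for sp in species}
        result[rank] = values.pop() if len(values) == 1 else None
    return result


def top_n_by_full_sort(psms, n):
    """Full stable sort on (-score, run, spectrum)."""
    return sorted(psms, key=lambda r: (-r.score, r.run_id, r.spectrum_id))[:n]


def coverage_by_set_arithmetic(annotations, pathways):
    """pathway -> coverage %, recomputed from raw python sets."""
    observed = {
        row["ko"] for row in annotations.to_dict("records")
        if row["ko"] is not None and row["ko"] == row["ko"]
    }
    totals: dict[str, set[str]] = {}
    for row in pathways.to_dict("records"):
        totals.setdefault(row["pathway"], set()).add(row["ko"])
    return {
        pathway: 100.0 * len(observed & kos) / len(kos)
        for pathway, kos in totals.items()
    }
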
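"""KEGG-orthology pathway coverage and abundance-weighted profiles.

Inputs are protein-group level annotations — each protein group with
at most one KO term, a source taxon, and a mean abundance across
replicates — and pathway definitions as KO sets grouped in the five
functional categories (metabolism, genetic information processing,
environmental information processing, cellular processes, human
diseases).  Coverage measures functional depth (how much of a pathway
is observed); abundance weights measure how much proteomic signal the
pathway carries and for whom.

KO-to-pathway mapping is many-to-many: a protein whose KO belongs to
k pathways contributes its full abundance to each, the standard KEGG
convention.  A uniqueness-weighted variant (abundance split equally
among the KO's pathways) is available for analyses where conservation
of total abundance across pathways matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .taxonomy import Taxonomy

ANNOTATION_COLUMNS = ["protein_group", "ko", "taxon", "abundance"]
PATHWAY_COLUMNS = ["pathway", "category", "ko"]


def _check_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return annotations


def _check_pathways(pathways: pd.DataFrame) -> pd.DataFrame:
    missing = set(PATHWAY_COLUMNS) - set(pathways.columns)
    if missing:
        raise ValueError(f"pathway table missing columns: {sorted(missing)}")
    return pathways


@dataclass
class CoverageReport:
    """Per-pathway coverage plus the bookkeeping around it."""

    frame: pd.DataFrame  # pathway, category, n_observed, n_total, coverage_pct
    n_unannotated: int  # proteins without a KO (excluded from coverage)
    unmapped_kos: list[str]  # observed KOs absent from every pathway

    def coverage(self, pathway: str) -> float:
        rows = self.frame.loc[self.frame["pathway"] == pathway, "coverage_pct"]
        return float(rows.iloc[0]) if len(rows) else 0.0


def compute_pathway_coverage(
    annotations: pd.DataFrame, pathways: pd.DataFrame
) -> CoverageReport:
    """Coverage = 100 * |observed KOs in pathway| / |pathway KO set|.

    Proteins without a KO are excluded from the observed set and
    counted; observed KOs mapping to no pathway are retained in the
    report as unmapped rather than erroring.
    """
    annotations = _check_annotations(annotations)
    pathways = _check_pathways(pathways)
    observed = set(annotations["ko"].dropna())
    n_unannotated = int(annotations["ko"].isna().sum())

    rows = []
    all_pathway_kos: set[str] = set()
    for (pathway, category), group in pathways.groupby(
        ["pathway", "category"], sort=True
    ):
        total = set(group["ko"])
        all_pathway_kos |= total
        hit = observed & total
        rows.append(
            {
                "pathway": pathway,
                "category": category,
                "n_observed": len(hit),
                "n_total": len(total),
                "coverage_pct": 100.0 * len(hit) / len(total),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["pathway", "category", "n_observed", "n_total", "coverage_pct"],
    )
    return CoverageReport(
        frame=frame,
        n_unannotated=n_unannotated,
        unmapped_kos=sorted(observed - all_pathway_kos),
    )


def pathway_abundance(
    annotations: pd.DataFrame,
    pathways: pd.DataFrame,
    groups: Optional[Mapping[str, str]] = None,
    uniqueness_weighted: bool = False,
) -> pd.DataFrame:
    """Summed mean protein abundance per (pathway, group).

    ``groups`` maps taxon id -> group label (e.g. host / microbiota);
    when omitted, each taxon is its own group.  The abundance of a
    protein is counted in full for every pathway containing its KO,
    unless ``uniqueness_weighted`` divides it by the KO's pathway
    multiplicity.  Returns columns pathway, category, group, weight.
    """
    annotations = _check_annotations(annotations)
    pathways = _check_pathways(pathways)
    annotated = annotations.dropna(subset=["ko"]).copy()
    if groups is not None:
        annotated["group"] = annotated["taxon"].map(
            lambda t: groups.get(t, "unclassified")
        )
    else:
        annotated["group"] = annotated["taxon"]

    joined = annotated.merge(pathways, on="ko", how="inner")
    if joined.empty:
        return pd.DataFrame(columns=["pathway", "category", "group", "weight"])
    if uniqueness_weighted:
        multiplicity = pathways.groupby("ko")["pathway"].nunique()
        joined["abundance"] = joined["abundance"] / joined["ko"].map(multiplicity)
    out = (
        joined.groupby(["pathway", "category", "group"], sort=True)["abundance"]
        .sum()
        .reset_index()
        .rename(columns={"abundance": "weight"})
    )
    return out


def taxon_function_matrix(
    annotations: pd.DataFrame,
    pathways: pd.DataFrame,
    taxonomy: Taxonomy,
    rank: str = "genus",
) -> pd.DataFrame:
    """Genus (or other rank) x functional-category abundance matrix.

    Rows are taxa resolved to ``rank`` (species ids not resolvable
    there land in an ``unclassified`` row); columns are the pathway
    categories; cells are summed pathway weights — the table a chord
    diagram (Circos-style) of taxon-function contributions is drawn
    from.
    """
    annotations = _check_annotations(annotations)

    def resolve(taxon: str) -> str:
        if taxon in taxonomy:
            value = taxonomy[taxon].get(rank)
            if value is not None:
                return value
        return "unclassified"

    groups = {t: resolve(t) for t in annotations["taxon"].unique()}
    weights = pathway_abundance(annotations, pathways, groups=groups)
    if weights.empty:
        return pd.DataFrame()
    matrix = weights.pivot_table(
        index="group", columns="category", values="weight",
        aggfunc="sum", fill_value=0.0,
    )
    matrix.index.name = rank
    return matrix.sort_index()


@dataclass
class TaxonComparison:
    """Shared and taxon-specific KO repertoires of two taxa."""

    shared: set[str]
    a_only: set[str]
    b_only: set[str]
    pathway_labels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["pathway", "label"])
    )


def compare_taxa_pathways(
    annotations: pd.DataFrame,
    taxon_a: str,
    taxon_b: str,
    pathways: Optional[pd.DataFrame] = None,
) -> TaxonComparison:
    """Partition the observed KOs of two taxa into shared / A-only /
    B-only, and label each pathway by which partitions it draws on.

    The three KO sets are disjoint and their union is everything
    observed in either taxon.  A pathway touching exactly one
    partition is labelled by it; one touching several is ``mixed``;
    pathways with no observed KO are omitted.
    """
    annotations = _check_annotations(annotations)
    kos_a = set(
        annotations.loc[annotations["taxon"] == taxon_a, "ko"].dropna()
    )
    kos_b = set(
        annotations.loc[annotations["taxon"] == taxon_b, "ko"].dropna()
    )
    shared = kos_a & kos_b
    a_only = kos_a - kos_b
    b_only = kos_b - kos_a

    labels = []
    if pathways is not None:
        pathways = _check_pathways(pathways)
        for pathway, group in pathways.groupby("pathway", sort=True):
            total = set(group["ko"])
            touches = [
                label
                for label, kos in (
                    ("shared", shared), ("a_only", a_only), ("b_only", b_only)
                )
                if total & kos
            ]
            if not touches:
                continue
            labels.append(
                {"pathway": pathway,
                 "label": touches[0] if len(touches) == 1 else "mixed"}
            )
    return TaxonComparison(
        shared=shared,
        a_only=a_only,
        b_only=b_only,
        pathway_labels=pd.DataFrame(labels, columns=["pathway", "label"]),
    )


def annotation_rate(
    annotations: pd.DataFrame, groups: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Fraction of protein groups carrying a KO term, per group.

    Empty groups are reported with zero counts and a null percentage
    rather than raising.
    """
    annotations = _check_annotations(annotations)
    work = annotations.copy()
    if groups is not None:
        work["group"] = work["taxon"].map(lambda t: groups.get(t, "unclassified"))
    else:
        work["group"] = work["taxon"]
    rows = []
    for group, sub in work.groupby("group", sort=True):
        total = len(sub)
        annotated = int(sub["ko"].notna().sum())
        rows.append(
            {
                "group": group,
                "annotated": annotated,
                "total": total,
                "pct": 100.0 * annotated / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["group", "annotated", "total", "pct"])
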